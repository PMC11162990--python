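"""Acquisition scheme: b-values and (for the fractional-order spatial model)
diffusion-gradient timing.

A multi-b-value DWI protocol is described by its ascending list of b-values
(s/mm²), starting at b=0.  The fractional-order calculus (FROC) signal model
additionally needs the gradient duration δ, the gradient separation Δ (both
ms) and the per-b product γ·G_d (gyromagnetic ratio times gradient
amplitude).  When only b-values are known, γ·G_d·δ is derived per b from the
Stejskal–Tanner relation b = (γ G_d δ)²·(Δ − δ/3), which makes the FROC model
with β = 1 collapse exactly onto the mono-exponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 11-b acquisition grid (s/mm²) used throughout as the default protocol.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 500.0, 800.0, 1000.0,
                    1500.0, 2000.0, 2500.0)


@dataclass(frozen=True)
class BValueScheme:
    """Diffusion weighting scheme.

    Parameters
    ----------
    b_values
        Non-negative, strictly increasing b-values in s/mm²; first entry 0.
    delta
        Gradient duration δ in ms (needed for FROC with β ≠ 1).
    Delta
        Gradient separation Δ in ms; must satisfy Δ > δ/3 > 0.
    """

    b_values: tuple = field(default=DEFAULT_B_VALUES)
    delta: float | None = 20.0
    Delta: float | None = 40.0

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two b-values")
        if b[0] != 0:
            raise ValueError("first b-value must be 0")
        if np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be non-negative and strictly increasing")
        object.__setattr__(self, "b_values", tuple(b))
        if (self.delta is None) != (self.Delta is None):
            raise ValueError("delta and Delta must be given together")
        if self.delta is not None:
            if not (self.Delta > self.delta / 3.0 > 0):
                raise ValueError("gradient timing requires Delta > delta/3 > 0")

    @property
    def b(self) -> np.ndarray:
        """b-values as a float array (s/mm²)."""
        return np.asarray(self.b_values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.b_values)

    @property
    def has_timing(self) -> bool:
        return self.delta is not None

    def q_values(self) -> np.ndarray:
        """Per-b gradient wavenumbers q = γ·G_d·δ (mm⁻¹).

        Derived from b = q²·(Δ − δ/3) with the timing converted to seconds,
        so that q² (Δ − δ/3) reproduces b exactly.
        """
        if not self.has_timing:
            raise ValueError("scheme has no gradient timing (delta/Delta)")
        diff_time = (self.Delta - self.delta / 3.0) * 1e-3  # s
        return np.sqrt(self.b / diff_time)


def read_bval(path) -> np.ndarray:
    """Read an FSL-style whitespace-separated .bval text file."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"empty bval file: {path}")
    return np.array([float(t) for t in tokens])


def write_bval(path, b_values) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in np.asarray(b_values, float)) + "\n")


def scheme_from_bval(path, delta: float | None = 20.0,
                     Delta: float | None = 40.0) -> BValueScheme:
    return BValueScheme(tuple(read_bval(path)), delta=delta, Delta=Delta)
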