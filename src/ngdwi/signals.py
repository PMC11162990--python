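"""Forward signal equations for multi-b-value DWI.

Six scalar-b decay models are provided: the Gaussian mono-exponential (ADC)
and five non-Gaussian models —

* IVIM (intravoxel incoherent motion):  S = S₀·[f·exp(−b·D*) + (1−f)·exp(−b·D)]
* DKI  (diffusion kurtosis):            S = S₀·exp[−b·D + (1/6)·K·(b·D)²]
* SEM  (stretched exponential):         S = S₀·exp[−(b·DDC)^α]
* FROC (fractional-order calculus):     S = S₀·exp[−D·μ^{2(β−1)}·(γG_dδ)^{2β}·(Δ − ((2β−1)/(2β+1))·δ)]
* CTRW (continuous-time random walk):   S = S₀·E_α[−(b·D)^β]

All diffusivities are in mm²/s and b in s/mm²; μ is in mm; gradient timing
in ms (converted internally).  Each model reduces exactly to the
mono-exponential when its non-Gaussian parameters take their Gaussian limit
(f = 0, K = 0, α = 1, β = 1).

The module exposes both typed parameter containers with validation
(`signal_<model>(params, scheme)`) and raw broadcastable kernels used by the
fitting and phantom-rendering code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mittag import mittag_leffler
from .scheme import BValueScheme

__all__ = [
    "MonoExpParams", "IVIMParams", "DKIParams", "SEMParams", "FROCParams",
    "CTRWParams", "signal_monoexp", "signal_ivim", "signal_dki",
    "signal_sem", "signal_froc", "signal_ctrw", "MODEL_IDS",
]

MODEL_IDS = ("ADC", "IVIM", "DKI", "SEM", "FROC", "CTRW")


class InvalidParameterError(ValueError):
    """Raised when signal-model parameters violate their physical domain."""


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class MonoExpParams:
    S0: float
    ADC: float  # mm²/s

    def __post_init__(self):
        if self.S0 <= 0:
            raise InvalidParameterError(f"S0 must be > 0, got {self.S0}")
        if not 0 < self.ADC <= 0.01:
            raise InvalidParameterError(f"ADC must be in (0, 0.01], got {self.ADC}")


@dataclass(frozen=True)
class IVIMParams:
    S0: float
    f: float       # perfusion fraction
    D: float       # tissue diffusivity, mm²/s
    Dstar: float   # pseudo-diffusivity, mm²/s

    def __post_init__(self):
        if self.S0 <= 0:
            raise InvalidParameterError(f"S0 must be > 0, got {self.S0}")
        if not 0 <= self.f <= 1:
            raise InvalidParameterError(f"f must be in [0, 1], got {self.f}")
        if not 0 < self.D < self.Dstar:
            raise InvalidParameterError(
                f"require 0 < D < D*, got D={self.D}, D*={self.Dstar}")


@dataclass(frozen=True)
class DKIParams:
    S0: float
    D: float  # mm²/s
    K: float  # kurtosis, dimensionless

    def __post_init__(self):
        if self.S0 <= 0 or self.D <= 0:
            raise InvalidParameterError("S0 and D must be > 0")
        if self.K < 0:
            raise InvalidParameterError(f"K must be >= 0, got {self.K}")


@dataclass(frozen=True)
class SEMParams:
    S0: float
    DDC: float    # mm²/s
    alpha: float  # stretching exponent

    def __post_init__(self):
        if self.S0 <= 0 or self.DDC <= 0:
            raise InvalidParameterError("S0 and DDC must be > 0")
        if not 0 < self.alpha <= 1:
            raise InvalidParameterError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class FROCParams:
    S0: float
    D: float     # mm²/s
    beta: float  # spatial fractional-order index
    mu: float    # spatial constant, mm

    def __post_init__(self):
        if self.S0 <= 0 or self.D <= 0 or self.mu <= 0:
            raise InvalidParameterError("S0, D and mu must be > 0")
        if not 0 < self.beta <= 1:
            raise InvalidParameterError(f"beta must be in (0, 1], got {self.beta}")


@dataclass(frozen=True)
class CTRWParams:
    S0: float
    D: float      # mm²/s
    alpha: float  # temporal fractional order
    beta: float   # spatial fractional order

    def __post_init__(self):
        if self.S0 <= 0 or self.D <= 0:
            raise InvalidParameterError("S0 and D must be > 0")
        if not 0 < self.alpha <= 1 or not 0 < self.beta <= 1:
            raise InvalidParameterError("alpha and beta must be in (0, 1]")


# ---------------------------------------------------------------------------
# raw kernels (broadcastable; no validation — used by fitting/rendering)

def _bcast(b, *params):
    """Broadcast voxel-wise parameter arrays against the b axis."""
    arrs = [np.asarray(p, float)[..., None] for p in params]
    return (np.asarray(b, float),) + tuple(arrs)


def monoexp_kernel(b, S0, ADC):
    b, S0, ADC = _bcast(b, S0, ADC)
    return np.squeeze(S0 * np.exp(-b * ADC))


def ivim_kernel(b, S0, f, D, Dstar):
    b, S0, f, D, Dstar = _bcast(b, S0, f, D, Dstar)
    return np.squeeze(S0 * (f * np.exp(-b * Dstar) + (1 - f) * np.exp(-b * D)))


def dki_kernel(b, S0, D, K):
    b, S0, D, K = _bcast(b, S0, D, K)
    bD = b * D
    return np.squeeze(S0 * np.exp(-bD + K * bD ** 2 / 6.0))


def sem_kernel(b, S0, DDC, alpha):
    b, S0, DDC, alpha = _bcast(b, S0, DDC, alpha)
    return np.squeeze(S0 * np.exp(-(b * DDC) ** alpha))


def froc_exponent(b, D, beta, mu, delta_ms, Delta_ms):
    """FROC decay exponent (negative), timing in ms, per-b q derived from b."""
    b, D, beta, mu = _bcast(b, D, beta, mu)
    delta = delta_ms * 1e-3
    Delta = Delta_ms * 1e-3
    q = np.sqrt(b / (Delta - delta / 3.0))  # = γ·G_d·δ, mm⁻¹
    eff_time = Delta - (2 * beta - 1) / (2 * beta + 1) * delta
    return np.squeeze(-D * mu ** (2 * (beta - 1)) * q ** (2 * beta) * eff_time)


def froc_kernel(b, S0, D, beta, mu, delta_ms, Delta_ms):
    expo = froc_exponent(b, D, beta, mu, delta_ms, Delta_ms)
    S0 = np.asarray(S0, float)
    if S0.ndim:
        S0 = S0[..., None]
    return np.squeeze(S0 * np.exp(expo))


def ctrw_kernel(b, S0, D, alpha, beta):
    """CTRW decay; alpha must be scalar (one Mittag-Leffler order per call)."""
    alpha = float(alpha)
    b, S0, D, beta = _bcast(b, S0, D, beta)
    arg = -(b * D) ** beta
    return np.squeeze(S0 * mittag_leffler(alpha, arg))


# ---------------------------------------------------------------------------
# typed forward operations

def signal_monoexp(params: MonoExpParams, scheme: BValueScheme) -> np.ndarray:
    """Mono-exponential (Gaussian) decay S₀·exp(−b·ADC)."""
    return params.S0 * np.exp(-scheme.b * params.ADC)


def signal_ivim(params: IVIMParams, scheme: BValueScheme) -> np.ndarray:
    """Bi-exponential IVIM decay."""
    b = scheme.b
    return params.S0 * (params.f * np.exp(-b * params.Dstar)
                        + (1 - params.f) * np.exp(-b * params.D))


def signal_dki(params: DKIParams, scheme: BValueScheme) -> np.ndarray:
    """Kurtosis-corrected decay S₀·exp[−bD + (1/6)K(bD)²]."""
    bD = scheme.b * params.D
    return params.S0 * np.exp(-bD + params.K * bD ** 2 / 6.0)


def signal_sem(params: SEMParams, scheme: BValueScheme) -> np.ndarray:
    """Stretched-exponential decay S₀·exp[−(b·DDC)^α]."""
    return params.S0 * np.exp(-(scheme.b * params.DDC) ** params.alpha)


def signal_froc(params: FROCParams, scheme: BValueScheme) -> np.ndarray:
    """Fractional-order-calculus decay.

    Requires gradient timing on the scheme when β ≠ 1; the per-b gradient
    factor γG_dδ is derived from b = (γG_dδ)²(Δ − δ/3), which makes β = 1
    coincide exactly with exp(−bD).
    """
    if params.beta != 1.0 and not scheme.has_timing:
        raise ValueError("FROC with beta != 1 requires scheme gradient timing")
    delta = scheme.delta if scheme.has_timing else 20.0
    Delta = scheme.Delta if scheme.has_timing else 40.0
    expo = froc_exponent(scheme.b, params.D, params.beta, params.mu, delta, Delta)
    return params.S0 * np.exp(expo)


def signal_ctrw(params: CTRWParams, scheme: BValueScheme) -> np.ndarray:
    """CTRW decay S₀·E_α[−(bD)^β]."""
    return params.S0 * mittag_leffler(params.alpha,
                                      -(scheme.b * params.D) ** params.beta)
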