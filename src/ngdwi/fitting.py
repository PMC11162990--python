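"""Voxel-wise nonlinear fitting of the six diffusion decay models.

Strategy
--------
Every voxel is fitted by bounded nonlinear least squares, initialized from
a weighted log-linear mono-exponential fit of that voxel (a weighted
quadratic log fit for DKI; a segmented high-b start for IVIM); shape
parameters start at fixed physiologic values (α = β = 0.9, K = 0.5,
f = 0.1).  Models with closed-form Jacobians (ADC, IVIM, DKI, SEM) run
through a batched, bounds-projected Levenberg-Marquardt engine that solves
all voxels of a volume simultaneously; FROC and CTRW (whose Jacobians
involve the Mittag-Leffler function) use scipy's trust-region-reflective
solver per voxel.  Voxels that fail to converge are retried up to
``n_restarts`` times from seeded random initializations within bounds.

Signals are normalized per voxel (divided by the voxel's maximum) before
optimization, so S0 is dimensionless during the fit and the parameter
bounds are scale-free.  Diffusivities are optimized in units of
10⁻³ mm²/s (= μm²/ms); emitted maps keep that reporting scale, while the
typed parameter containers carry SI units (mm²/s).

IVIM by default uses only b ≤ 1000 s/mm² to limit kurtosis contamination
at high b; all other models use the full b range.  Degenerate voxels
(non-positive S(0), all-zero series, rising decay) are flagged and excluded
from downstream histogram analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .batchlm import batch_lm
from .mittag import mittag_leffler
from .scheme import BValueScheme
from .signals import (CTRWParams, DKIParams, FROCParams, IVIMParams,
                      MonoExpParams, SEMParams)

__all__ = ["FitOptions", "VoxelFitResult", "ParameterMapSet", "fit_voxel",
           "fit_volume", "fit_signals", "fit_all_models", "MODEL_METRICS",
           "MAP_NAMES", "RATE_METRICS"]

#: metrics emitted per model, in canonical order
MODEL_METRICS = {
    "ADC": ("ADC",),
    "IVIM": ("f", "D", "Dstar"),
    "DKI": ("K", "D"),
    "SEM": ("alpha", "DDC"),
    "FROC": ("beta", "mu", "D"),
    "CTRW": ("alpha", "beta", "D"),
}

#: the 14 canonical map names (ADC + 13 non-Gaussian metrics)
MAP_NAMES = ("ADC",) + tuple(
    f"{m}-{metric}" for m in ("IVIM", "DKI", "SEM", "FROC", "CTRW")
    for metric in MODEL_METRICS[m])

#: metrics carried in 10⁻³ mm²/s on emitted maps
RATE_METRICS = frozenset({"ADC", "D", "Dstar", "DDC"})

#: optimizer-scale parameter vectors per model (S0 normalized; D in 1e-3 mm²/s)
_PARAM_NAMES = {
    "ADC": ("S0", "ADC"),
    "IVIM": ("S0", "f", "D", "Dstar"),
    "DKI": ("S0", "D", "K"),
    "SEM": ("S0", "DDC", "alpha"),
    "FROC": ("S0", "D", "beta", "mu"),
    "CTRW": ("S0", "D", "alpha", "beta"),
}

_DEFAULT_BOUNDS = {
    "S0": (1e-9, 10.0),          # normalized signal units
    "ADC": (1e-3, 5.0),
    "D": (1e-3, 5.0),
    "DDC": (1e-3, 5.0),
    "Dstar": (3.0, 100.0),
    "f": (0.0, 0.5),
    "K": (0.0, 3.0),
    "alpha": (0.01, 1.0),
    "beta": (0.01, 1.0),
    "mu": (1e-4, 0.02),          # mm
}

_SHAPE_INIT = {"f": 0.1, "K": 0.5, "alpha": 0.9, "beta": 0.9,
               "mu": 5e-3, "Dstar": 15.0}


@dataclass(frozen=True)
class FitOptions:
    """Options controlling voxel-wise fitting.

    ``b_max`` limits the b-subset in s/mm² (None → model default: 1000 for
    IVIM, all b otherwise).  ``bounds`` overrides per-parameter bounds on
    the optimizer scale.
    """
    b_max: float | None = None
    n_restarts: int = 3
    seed: int = 0
    max_nfev: int = 200
    bounds: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VoxelFitResult:
    model_id: str
    params: object            # the matching *Params container (SI units)
    residual_rms: float
    converged: bool
    n_points_used: int
    degenerate: bool = False


def _bounds(model_id, overrides):
    names = _PARAM_NAMES[model_id]
    lo = np.array([overrides.get(n, _DEFAULT_BOUNDS[n])[0] for n in names])
    hi = np.array([overrides.get(n, _DEFAULT_BOUNDS[n])[1] for n in names])
    return names, lo, hi


def _param_container(model_id, values, scale):
    """Typed container from optimizer-scale values; S0 de-normalized."""
    v = np.asarray(values, float)
    s0 = float(v[0] * scale)
    if model_id == "ADC":
        return MonoExpParams(S0=s0, ADC=float(v[1]) * 1e-3)
    if model_id == "IVIM":
        d = min(float(v[2]), float(v[3]) * 0.999)  # keep D < D*
        return IVIMParams(S0=s0, f=float(v[1]), D=d * 1e-3,
                          Dstar=float(v[3]) * 1e-3)
    if model_id == "DKI":
        return DKIParams(S0=s0, D=float(v[1]) * 1e-3, K=float(v[2]))
    if model_id == "SEM":
        return SEMParams(S0=s0, DDC=float(v[1]) * 1e-3, alpha=float(v[2]))
    if model_id == "FROC":
        return FROCParams(S0=s0, D=float(v[1]) * 1e-3, beta=float(v[2]),
                          mu=float(v[3]))
    if model_id == "CTRW":
        return CTRWParams(S0=s0, D=float(v[1]) * 1e-3, alpha=float(v[2]),
                          beta=float(v[3]))
    raise ValueError(f"unknown model: {model_id}")


# ---------------------------------------------------------------------------
# batched forward/Jacobian on the optimizer scale (bs = b·1e-3)

def _batch_predict(model_id, X, bs, timing=None):
    X = np.atleast_2d(X)
    if model_id == "ADC":
        S0, A = X[:, :1], X[:, 1:2]
        return S0 * np.exp(-bs * A)
    if model_id == "IVIM":
        S0, f, D, Ds = (X[:, i:i + 1] for i in range(4))
        return S0 * (f * np.exp(-bs * Ds) + (1 - f) * np.exp(-bs * D))
    if model_id == "DKI":
        S0, D, K = (X[:, i:i + 1] for i in range(3))
        x = bs * D
        return S0 * np.exp(-x + K * x * x / 6.0)
    if model_id == "SEM":
        S0, DDC, a = (X[:, i:i + 1] for i in range(3))
        return S0 * np.exp(-(bs * DDC) ** a)
    if model_id == "FROC":
        S0, D, beta, mu = (X[:, i:i + 1] for i in range(4))
        delta, Delta = timing
        d_s, D_s = delta * 1e-3, Delta * 1e-3
        q = np.sqrt(bs * 1e3 / (D_s - d_s / 3.0))
        T = D_s - (2 * beta - 1) / (2 * beta + 1) * d_s
        return S0 * np.exp(-(D * 1e-3) * mu ** (2 * (beta - 1))
                           * q ** (2 * beta) * T)
    if model_id == "CTRW":
        X = np.atleast_2d(X)
        out = np.empty((X.shape[0], bs.size))
        for i, (S0, D, a, beta) in enumerate(X):
            out[i] = S0 * mittag_leffler(float(a), -(bs * D) ** beta)
        return out
    raise ValueError(model_id)


def _batch_jac(model_id, X, bs):
    X = np.atleast_2d(X)
    if model_id == "ADC":
        S0, A = X[:, :1], X[:, 1:2]
        e = np.exp(-bs * A)
        return np.stack([e, -bs * S0 * e], axis=-1)
    if model_id == "IVIM":
        S0, f, D, Ds = (X[:, i:i + 1] for i in range(4))
        ef, ed = np.exp(-bs * Ds), np.exp(-bs * D)
        return np.stack([
            f * ef + (1 - f) * ed,
            S0 * (ef - ed),
            -S0 * (1 - f) * bs * ed,
            -S0 * f * bs * ef,
        ], axis=-1)
    if model_id == "DKI":
        S0, D, K = (X[:, i:i + 1] for i in range(3))
        x = bs * D
        e = np.exp(-x + K * x * x / 6.0)
        return np.stack([
            e,
            S0 * e * (-bs + K * bs * x / 3.0),
            S0 * e * x * x / 6.0,
        ], axis=-1)
    if model_id == "SEM":
        S0, DDC, a = (X[:, i:i + 1] for i in range(3))
        x = bs * DDC
        u = x ** a
        e = np.exp(-u)
        with np.errstate(divide="ignore", invalid="ignore"):
            logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), 0.0)
        return np.stack([
            e,
            -S0 * e * a * u / DDC,
            -S0 * e * u * logx,
        ], axis=-1)
    raise ValueError(model_id)


_BATCH_MODELS = ("ADC", "IVIM", "DKI", "SEM")


# ---------------------------------------------------------------------------
# vectorized initializations (signals already normalized)

def _loglinear_batch(bs, S):
    """Per-voxel weighted log-linear fit; returns (s0, adc) arrays."""
    pos = S > 0
    w = np.where(pos, S, 0.0)
    y = np.log(np.where(pos, S, 1.0))
    W = w.sum(axis=1)
    ok = pos.sum(axis=1) >= 2
    W = np.where(W > 0, W, 1.0)
    mb = (w * bs).sum(axis=1) / W
    my = (w * y).sum(axis=1) / W
    var = (w * (bs - mb[:, None]) ** 2).sum(axis=1)
    cov = (w * (bs - mb[:, None]) * (y - my[:, None])).sum(axis=1)
    slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    adc = np.clip(-slope, 1e-3, 5.0)
    s0 = np.exp(my - slope * mb)
    s0 = np.where(ok, s0, np.nanmax(np.abs(S), axis=1))
    return np.clip(s0, 1e-6, 10.0), np.where(ok, adc, 1.0)


def _dki_init_batch(bs, S):
    """Weighted quadratic log fit: log S = c0 + c1·bs + c2·bs²."""
    pos = S > 0
    w = np.where(pos, S, 0.0)
    y = np.log(np.where(pos, S, 1.0))
    Z = np.stack([np.ones_like(bs), bs, bs ** 2], axis=-1)   # (nb, 3)
    A = np.einsum("ij,jp,jq->ipq", w, Z, Z)
    rhs = np.einsum("ij,jp,ij->ip", w, Z, y)
    ok = pos.sum(axis=1) >= 3
    A[~ok] = np.eye(3)
    rhs[~ok] = 0.0
    try:
        C = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        C = np.linalg.lstsq(A.reshape(-1, 3, 3)[0], rhs.T, rcond=None)[0].T
    d0 = np.clip(-C[:, 1], 1e-3, 5.0)
    k0 = np.clip(6.0 * C[:, 2] / d0 ** 2, 0.0, 3.0)
    s00 = np.clip(np.exp(np.clip(C[:, 0], -20, 3)), 1e-6, 10.0)
    s0_fallback, adc = _loglinear_batch(bs, S)
    return (np.where(ok, s00, s0_fallback),
            np.where(ok, d0, adc),
            np.where(ok, k0, _SHAPE_INIT["K"]))


def _initial_batch(model_id, bs, S):
    """(n, p) initial parameters on the optimizer scale."""
    n = S.shape[0]
    s0, adc = _loglinear_batch(bs, S)
    si = _SHAPE_INIT
    if model_id == "ADC":
        return np.column_stack([s0, adc])
    if model_id == "DKI":
        s00, d0, k0 = _dki_init_batch(bs, S)
        return np.column_stack([s00, d0, k0])
    if model_id == "SEM":
        return np.column_stack([s0, adc, np.full(n, si["alpha"])])
    if model_id == "IVIM":
        hi = bs >= 0.2      # b >= 200 s/mm²
        if hi.sum() >= 2:
            s0_hi, d_tis = _loglinear_batch(bs[hi], S[:, hi])
            s_b0 = S[:, 0]
            f0 = np.clip(1.0 - s0_hi / np.maximum(s_b0, 1e-12), 0.0, 0.5)
            return np.column_stack([np.maximum(s_b0, 1e-6), f0, d_tis,
                                    np.full(n, si["Dstar"])])
        return np.column_stack([s0, np.full(n, si["f"]), adc,
                                np.full(n, si["Dstar"])])
    if model_id == "FROC":
        return np.column_stack([s0, adc, np.full(n, si["beta"]),
                                np.full(n, si["mu"])])
    if model_id == "CTRW":
        return np.column_stack([s0, adc, np.full(n, si["alpha"]),
                                np.full(n, si["beta"])])
    raise ValueError(model_id)


def _degenerate_batch(S):
    nb = S.shape[1]
    any_pos = (S > 0).any(axis=1)
    s0_pos = S[:, 0] > 0
    lo = S[:, : nb // 2].mean(axis=1)
    hi = S[:, nb // 2:].mean(axis=1)
    return ~any_pos | ~s0_pos | (hi > lo)


# ---------------------------------------------------------------------------
# core batched fit

def fit_signals(model_id: str, signals, scheme: BValueScheme,
                options: FitOptions | None = None):
    """Fit one model to a stack of voxel signals.

    Parameters
    ----------
    signals
        (n_voxels, n_b) array matching the scheme.

    Returns
    -------
    dict with optimizer-scale parameter block ``theta`` (n, p), per-voxel
    ``scale`` (signal normalization), ``rms``, ``converged``,
    ``degenerate`` and ``n_points_used``.
    """
    model_id = model_id.upper()
    options = options or FitOptions()
    S_raw = np.atleast_2d(np.asarray(signals, float))
    b_all = scheme.b
    if S_raw.shape[1] != b_all.size:
        raise ValueError(f"signal length {S_raw.shape[1]} != scheme length "
                         f"{b_all.size}")

    b_max = options.b_max if options.b_max is not None else (
        1000.0 if model_id == "IVIM" else np.inf)
    use = b_all <= b_max
    n_used = int(use.sum())
    p = len(_PARAM_NAMES[model_id])
    if n_used < p + 1:
        raise ValueError(f"{model_id}: need more than {p} points, got {n_used}")
    if model_id == "FROC" and not scheme.has_timing:
        raise ValueError("FROC fitting requires scheme gradient timing")
    timing = (scheme.delta, scheme.Delta) if scheme.has_timing else (20.0, 40.0)

    bs = b_all[use] * 1e-3
    S_sub = S_raw[:, use]
    scale = np.max(np.abs(S_sub), axis=1)
    scale = np.where(scale > 0, scale, 1.0)
    S = S_sub / scale[:, None]

    n = S.shape[0]
    names, lo, hi = _bounds(model_id, options.bounds)
    theta = np.tile((lo + hi) / 2.0, (n, 1))
    rms = np.zeros(n)
    converged = np.zeros(n, bool)
    degen = _degenerate_batch(S_sub)
    good = ~degen

    if good.any():
        Sg = S[good]
        x0 = np.clip(_initial_batch(model_id, bs, Sg), lo, hi)
        if model_id in _BATCH_MODELS:
            pred = lambda X: _batch_predict(model_id, X, bs)      # noqa: E731
            jacf = lambda X: _batch_jac(model_id, X, bs)          # noqa: E731
            x, cost, conv = batch_lm(pred, jacf, x0, lo, hi, Sg)
            rng = np.random.default_rng(options.seed)
            for _ in range(options.n_restarts):
                todo = ~conv
                if not todo.any():
                    break
                x0r = lo + (hi - lo) * rng.random((int(todo.sum()), len(lo)))
                xr, cr, convr = batch_lm(pred, jacf, x0r, lo, hi, Sg[todo])
                better = cr < cost[todo]
                sub = np.flatnonzero(todo)
                x[sub[better]] = xr[better]
                cost[sub[better]] = cr[better]
                conv[sub[better]] = convr[better]
        else:
            x, cost, conv = _fit_scipy_loop(model_id, x0, lo, hi, Sg, bs,
                                            timing, options)
        if model_id == "IVIM":
            x[:, 2] = np.minimum(x[:, 2], x[:, 3] * 0.999)  # keep D < D*
        theta[good] = x
        rms[good] = np.sqrt(cost / n_used)
        converged[good] = conv

    # degenerate voxels keep bounds-midpoint parameters
    if degen.any():
        mid_pred = _batch_predict(model_id, theta[degen], bs, timing)
        r = mid_pred - S[degen]
        rms[degen] = np.sqrt(np.einsum("ij,ij->i", r, r) / n_used)

    return {"theta": theta, "scale": scale, "rms": rms * scale,
            "converged": converged, "degenerate": degen,
            "n_points_used": n_used}


def _fit_scipy_loop(model_id, x0, lo, hi, S, bs, timing, options):
    """Per-voxel trust-region fits for models without closed-form Jacobians."""
    n = S.shape[0]
    x_out = np.empty_like(x0)
    cost = np.empty(n)
    conv = np.zeros(n, bool)
    eps = 1e-12
    rng = np.random.default_rng(options.seed)
    for i in range(n):
        sig = S[i]

        def residual(th):
            return _batch_predict(model_id, th[None, :], bs, timing)[0] - sig

        best = None
        for attempt in range(1 + options.n_restarts):
            start = x0[i] if attempt == 0 else lo + (hi - lo) * rng.random(len(lo))
            try:
                res = least_squares(residual, np.clip(start, lo + eps, hi - eps),
                                    bounds=(lo, hi), method="trf",
                                    max_nfev=options.max_nfev)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
            if best.status > 0:
                break
        if best is None:
            x_out[i] = (lo + hi) / 2.0
            cost[i] = np.sum(residual(x_out[i]) ** 2)
            conv[i] = False
        else:
            x_out[i] = best.x
            cost[i] = 2.0 * best.cost
            conv[i] = best.status > 0
    return x_out, cost, conv


# ---------------------------------------------------------------------------
# public entry points

def fit_voxel(model_id: str, signal, scheme: BValueScheme,
              options: FitOptions | None = None) -> VoxelFitResult:
    """Fit one model to a single voxel's multi-b signal.

    Returns a :class:`VoxelFitResult` whose ``params`` container holds the
    estimates in physical units (mm²/s for diffusivities).  Degenerate
    voxels are flagged and carry bounds-midpoint parameters.
    """
    model_id = model_id.upper()
    out = fit_signals(model_id, np.asarray(signal, float)[None, :], scheme,
                      options)
    params = _param_container(model_id, out["theta"][0], out["scale"][0])
    return VoxelFitResult(model_id, params, float(out["rms"][0]),
                          bool(out["converged"][0]), out["n_points_used"],
                          degenerate=bool(out["degenerate"][0]))


class ParameterMapSet:
    """The 14 per-voxel metric maps on a shared grid.

    Maps are stored in reporting units: diffusivities in 10⁻³ mm²/s, μ in
    mm, fractions/exponents dimensionless.  Exactly one ADC map and 13
    non-Gaussian metric maps are carried.
    """

    def __init__(self, maps: dict, voxel_size=(1.0, 1.0, 1.0)):
        missing = set(MAP_NAMES) - set(maps)
        extra = set(maps) - set(MAP_NAMES)
        if missing or extra:
            raise ValueError(f"map set mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        shapes = {np.asarray(v).shape for v in maps.values()}
        if len(shapes) != 1:
            raise ValueError(f"maps must share one grid, got shapes {shapes}")
        self.maps = {k: np.asarray(maps[k], float) for k in MAP_NAMES}
        self.voxel_size = tuple(float(v) for v in voxel_size)

    @property
    def shape(self):
        return self.maps["ADC"].shape

    @property
    def non_gaussian_names(self):
        return tuple(n for n in MAP_NAMES if n != "ADC")

    def __getitem__(self, name):
        return self.maps[name]

    def voxel_volume(self):
        return float(np.prod(self.voxel_size))


def fit_volume(model_id: str, dwi, mask, scheme: BValueScheme,
               options: FitOptions | None = None):
    """Fit one model voxel-wise over a masked 4D volume.

    Returns ``(maps, qc, degenerate)``: a dict of 3D metric maps (reporting
    units, NaN outside the mask), a QC summary, and the 3D degenerate-voxel
    flag volume.
    """
    model_id = model_id.upper()
    dwi = np.asarray(dwi, float)
    mask = np.asarray(mask).astype(bool)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, b)")
    if dwi.shape[:3] != mask.shape:
        raise ValueError(f"grid mismatch: dwi {dwi.shape[:3]} vs mask "
                         f"{mask.shape}")
    if dwi.shape[3] != scheme.n:
        raise ValueError(f"4th axis {dwi.shape[3]} != number of b-values "
                         f"{scheme.n}")

    metrics = MODEL_METRICS[model_id]

    def key(metric):
        return "ADC" if model_id == "ADC" else f"{model_id}-{metric}"

    maps = {key(m): np.full(mask.shape, np.nan) for m in metrics}
    degenerate = np.zeros(mask.shape, bool)
    idx = np.argwhere(mask)
    if idx.size == 0:
        warnings.warn("empty mask: no voxels fitted")
        return maps, {"n_voxels": 0, "fraction_converged": 0.0,
                      "n_degenerate": 0}, degenerate

    signals = dwi[mask]
    out = fit_signals(model_id, signals, scheme, options)
    names = _PARAM_NAMES[model_id]
    for m in metrics:
        col = names.index(m)
        vals = out["theta"][:, col].copy()
        if names[col] == "S0":
            vals *= out["scale"]
        maps[key(m)][mask] = vals
    degenerate[mask] = out["degenerate"]

    n_degen = int(out["degenerate"].sum())
    n_usable = max(len(idx) - n_degen, 1)
    n_conv = int(out["converged"].sum())
    qc = {"n_voxels": int(len(idx)),
          "fraction_converged": float(n_conv / n_usable),
          "n_degenerate": n_degen}
    if qc["fraction_converged"] < 0.95:
        warnings.warn(f"{model_id}: only {qc['fraction_converged']:.1%} of "
                      "usable voxels converged")
    return maps, qc, degenerate


def fit_all_models(dwi, mask, scheme, models=("ADC", "IVIM", "DKI", "SEM",
                                              "FROC", "CTRW"),
                   options: FitOptions | None = None):
    """Fit several models; returns (maps, qc, degenerate) where ``maps``
    accumulates every fitted metric map and ``degenerate`` is the union of
    per-model degenerate flags."""
    all_maps, qc = {}, {}
    degen = np.zeros(np.asarray(mask).shape, bool)
    for m in models:
        maps_m, qc_m, degen_m = fit_volume(m, dwi, mask, scheme, options)
        all_maps.update(maps_m)
        qc[m.upper()] = qc_m
        degen |= degen_m
    return all_maps, qc, degen
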