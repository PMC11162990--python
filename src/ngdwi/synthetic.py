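"""Synthetic multi-b-value DWI phantoms with known ground truth.

Every downstream stage (fitting, histogram features, ICC filtering,
modeling, evaluation) is testable without patient data by generating
two-class cohorts of ellipsoidal "tumors":

* per-patient diffusion parameters drawn from class-specific distributions
  (normal / lognormal / beta families);
* within-tumor spatial texture from a smoothed Gaussian random field, with
  an optional two-component mixture that injects positive skewness into the
  voxel-value distribution (emulating the heterogeneity contrasts that
  drive skewness features in invasive tumors);
* signal rendered voxel-wise through the chosen forward model and corrupted
  with Rician noise (magnitude-MRI realism), SNR defined as S₀_ref/σ;
* a second-rater mask obtained by random boundary erosion/dilation with a
  Dice-overlap floor, emulating inter-observer segmentation variability;
* an optional interior "necrosis" ellipsoid exported as an exclusion mask.

All stages are deterministic given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .scheme import BValueScheme
from .signals import (dki_kernel, froc_kernel, ivim_kernel, monoexp_kernel,
                      sem_kernel)
from .mittag import mittag_leffler

__all__ = ["MetricSpec", "GroupParameterSpec", "SyntheticPatient",
           "SyntheticCohort", "sample_parameter_maps", "render_signal",
           "add_rician_noise", "perturb_mask", "generate_cohort",
           "mibc_like_specs", "hg_like_specs"]

#: physical clip ranges per parameter (SI units: mm²/s, mm)
PARAM_BOUNDS = {
    "S0": (1e-3, np.inf),
    "D": (1e-6, 5e-3),
    "DDC": (1e-6, 5e-3),
    "ADC": (1e-6, 5e-3),
    "Dstar": (3e-3, 0.1),
    "f": (0.0, 0.5),
    "K": (0.0, 3.0),
    "alpha": (0.01, 1.0),
    "beta": (0.01, 1.0),
    "mu": (1e-4, 0.02),
}

#: parameters required per generator model
GENERATOR_PARAMS = {
    "ADC": ("S0", "ADC"),
    "IVIM": ("S0", "f", "D", "Dstar"),
    "DKI": ("S0", "D", "K"),
    "SEM": ("S0", "DDC", "alpha"),
    "FROC": ("S0", "D", "beta", "mu"),
    "CTRW": ("S0", "D", "alpha", "beta"),
}


@dataclass(frozen=True)
class MetricSpec:
    """Sampling law for one diffusion parameter: patient-level mean drawn
    from ``dist(loc, scale)``; within-tumor voxel variation is relative
    (``voxel_cv``) around that mean."""
    loc: float
    scale: float = 0.0
    dist: str = "normal"   # normal | lognormal | beta
    voxel_cv: float = 0.05

    def sample_mean(self, rng) -> float:
        if self.scale == 0:
            return self.loc
        if self.dist == "normal":
            return float(rng.normal(self.loc, self.scale))
        if self.dist == "lognormal":
            sigma2 = np.log1p((self.scale / self.loc) ** 2)
            mu = np.log(self.loc) - sigma2 / 2.0
            return float(rng.lognormal(mu, np.sqrt(sigma2)))
        if self.dist == "beta":
            # beta on [0,1] with given mean/sd
            m, s = self.loc, self.scale
            nu = m * (1 - m) / s ** 2 - 1.0
            if nu <= 0:
                raise ValueError("beta spec variance too large")
            return float(rng.beta(m * nu, (1 - m) * nu))
        raise ValueError(f"unknown distribution {self.dist!r}")


@dataclass(frozen=True)
class GroupParameterSpec:
    """Class-conditional generative description of the tumor parameters."""
    generator_model: str
    params: dict                     # name -> MetricSpec
    smooth_sigma: float = 1.0        # voxels, spatial texture scale
    skew_weight: float = 0.0         # mixture weight of the shifted mode
    skew_shift: float = 0.6          # shift in units of the parameter mean
    skew_params: tuple = ("D",)      # parameters receiving the skew mixture

    def __post_init__(self):
        model = self.generator_model.upper()
        object.__setattr__(self, "generator_model", model)
        missing = set(GENERATOR_PARAMS[model]) - set(self.params)
        if missing:
            raise ValueError(f"spec missing parameters: {sorted(missing)}")
        for name, ms in self.params.items():
            lo, hi = PARAM_BOUNDS[name]
            if not lo <= ms.loc <= hi:
                raise ValueError(f"{name} location {ms.loc} outside bounds "
                                 f"[{lo}, {hi}]")


@dataclass(frozen=True)
class SyntheticPatient:
    dwi: np.ndarray                  # 4D, noisy magnitude signal
    mask: np.ndarray                 # rater-A VOI
    mask_b: np.ndarray               # rater-B VOI (perturbed)
    exclusion_mask: np.ndarray | None
    truth: dict                      # param name -> 3D map (SI units)
    label: int
    cohort: str                      # "training" | "testing"
    seed: int


@dataclass(frozen=True)
class SyntheticCohort:
    patients: tuple
    scheme: BValueScheme
    voxel_size: tuple = (2.0, 2.0, 2.0)

    def subset(self, cohort: str):
        return [p for p in self.patients if p.cohort == cohort]


def _smooth_field(shape, sigma, rng):
    """Unit-variance smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def sample_parameter_maps(spec: GroupParameterSpec, shape, mask, rng) -> dict:
    """Draw ground-truth parameter maps for one patient.

    In-mask voxels get patient mean × spatial texture (plus the optional
    skew mixture); values are clipped to physical bounds.  Out-of-mask
    voxels are NaN.
    """
    mask = np.asarray(mask, bool)
    truth = {}
    for name in GENERATOR_PARAMS[spec.generator_model]:
        ms = spec.params[name]
        mean = ms.sample_mean(rng)
        lo, hi = PARAM_BOUNDS[name]
        mean = float(np.clip(mean, lo, min(hi, np.finfo(float).max)))
        fld = _smooth_field(shape, spec.smooth_sigma, rng)
        vals = mean * (1.0 + ms.voxel_cv * fld)
        if spec.skew_weight > 0 and name in spec.skew_params:
            shifted = rng.random(shape) < spec.skew_weight
            vals = np.where(shifted, vals + spec.skew_shift * abs(mean), vals)
        vals = np.clip(vals, lo, hi if np.isfinite(hi) else None)
        m = np.full(shape, np.nan)
        m[mask] = vals[mask]
        truth[name] = m
    if spec.generator_model == "IVIM":
        # enforce D < D* voxel-wise
        d, ds = truth["D"], truth["Dstar"]
        bad = d >= ds
        truth["D"] = np.where(bad, ds * 0.5, d)
    return truth


def render_signal(truth: dict, scheme: BValueScheme,
                  generator_model: str) -> np.ndarray:
    """Noiseless 4D volume from ground-truth maps via the forward model."""
    model = generator_model.upper()
    needed = GENERATOR_PARAMS[model]
    missing = [p for p in needed if p not in truth]
    if missing:
        raise ValueError(f"truth maps missing {missing} for {model}")
    shape = np.asarray(truth[needed[0]]).shape
    b = scheme.b
    out = np.zeros(shape + (scheme.n,))
    valid = np.all([np.isfinite(truth[p]) for p in needed], axis=0)
    idx = np.where(valid)
    if idx[0].size == 0:
        return out
    p = {k: np.asarray(truth[k], float)[idx] for k in needed}
    if model == "ADC":
        sig = monoexp_kernel(b, p["S0"], p["ADC"])
    elif model == "IVIM":
        sig = ivim_kernel(b, p["S0"], p["f"], p["D"], p["Dstar"])
    elif model == "DKI":
        sig = dki_kernel(b, p["S0"], p["D"], p["K"])
    elif model == "SEM":
        sig = sem_kernel(b, p["S0"], p["DDC"], p["alpha"])
    elif model == "FROC":
        delta = scheme.delta if scheme.has_timing else 20.0
        Delta = scheme.Delta if scheme.has_timing else 40.0
        sig = froc_kernel(b, p["S0"], p["D"], p["beta"], p["mu"], delta, Delta)
    elif model == "CTRW":
        sig = np.empty((idx[0].size, scheme.n))
        for i in range(idx[0].size):
            sig[i] = p["S0"][i] * mittag_leffler(
                float(p["alpha"][i]), -(b * p["D"][i]) ** p["beta"][i])
    else:
        raise ValueError(model)
    out[idx] = np.atleast_2d(sig)
    return out


def add_rician_noise(volume, snr: float, rng, s0_ref: float | None = None):
    """Rician-corrupt a magnitude volume: √((S+σε₁)² + (σε₂)²).

    σ = s0_ref / snr; when ``s0_ref`` is omitted it defaults to the maximum
    of the b=0 volume (4D input) or of the volume itself.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    vol = np.asarray(volume, float)
    if s0_ref is None:
        ref = vol[..., 0] if vol.ndim == 4 else vol
        s0_ref = float(np.max(ref))
    sigma = s0_ref / snr
    if sigma == 0 or not np.isfinite(sigma):
        return vol.copy()
    e1 = rng.standard_normal(vol.shape)
    e2 = rng.standard_normal(vol.shape)
    return np.sqrt((vol + sigma * e1) ** 2 + (sigma * e2) ** 2)


def perturb_mask(mask, rng, magnitude: float = 0.3,
                 dice_floor: float = 0.85, max_retries: int = 5):
    """Second-rater mask: randomly erode/dilate boundary voxels.

    Each inner-boundary voxel may be removed and each outer-boundary voxel
    added, independently with probability ``magnitude``.  Retries with a
    halved magnitude until the Dice overlap with the original is at least
    ``dice_floor`` and the mask is non-empty.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if magnitude == 0:
        return mask.copy()
    mag = magnitude
    for _ in range(max_retries):
        inner = mask & ~ndimage.binary_erosion(mask)
        outer = ndimage.binary_dilation(mask) & ~mask
        out = mask.copy()
        out[inner] &= rng.random(int(inner.sum())) >= mag
        out[outer] |= rng.random(int(outer.sum())) < mag
        inter = np.sum(out & mask)
        dice = 2.0 * inter / (out.sum() + mask.sum()) if out.any() else 0.0
        if out.any() and dice >= dice_floor:
            return out
        mag /= 2.0
    raise RuntimeError("mask perturbation failed to respect the Dice floor")


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return acc <= 1.0


def _random_tumor(shape, radius_range, rng, necrosis_prob=0.0):
    shape = np.asarray(shape)
    semi = rng.uniform(*radius_range, size=3)
    lo = np.ceil(semi) + 1
    hi = shape - lo - 1
    center = np.array([rng.uniform(l, max(h, l + 1e-6))
                       for l, h in zip(lo, hi)])
    mask = _ellipsoid_mask(tuple(shape), center, semi)
    excl = None
    if rng.random() < necrosis_prob:
        excl = _ellipsoid_mask(tuple(shape), center,
                               np.maximum(semi * rng.uniform(0.2, 0.4), 0.8))
        excl &= mask
        if excl.sum() >= mask.sum():
            excl = None
    return mask, excl


def generate_cohort(n_per_class: int, spec0: GroupParameterSpec,
                    spec1: GroupParameterSpec, scheme: BValueScheme,
                    snr: float = 50.0, seed: int = 0,
                    shape=(20, 20, 10), radius_range=(2.5, 4.0),
                    n_test_per_class: int | None = None,
                    necrosis_prob: float = 0.0,
                    rater_magnitude: float = 0.3) -> SyntheticCohort:
    """Generate a two-class cohort, optionally split train/test.

    ``n_per_class`` patients per class form the training cohort; when
    ``n_test_per_class`` is given, that many additional patients per class
    form an independently seeded testing cohort (emulating a second
    scanner).
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 patients per class")
    patients = []
    plan = [("training", n_per_class)]
    if n_test_per_class:
        plan.append(("testing", n_test_per_class))
    pid = 0
    for cohort, n_count in plan:
        for label, spec in ((0, spec0), (1, spec1)):
            for i in range(n_count):
                pseed = seed * 1000003 + pid * 7919 + 13
                pseed %= 2 ** 31
                rng = np.random.default_rng(pseed)
                mask, excl = _random_tumor(shape, radius_range, rng,
                                           necrosis_prob)
                truth = sample_parameter_maps(spec, shape, mask, rng)
                clean = render_signal(truth, scheme, spec.generator_model)
                s0_ref = float(np.nanmax(truth["S0"]))
                dwi = add_rician_noise(clean, snr, rng, s0_ref=s0_ref)
                mask_b = perturb_mask(mask, rng, magnitude=rater_magnitude)
                patients.append(SyntheticPatient(
                    dwi=dwi, mask=mask, mask_b=mask_b, exclusion_mask=excl,
                    truth=truth, label=label, cohort=cohort, seed=pseed))
                pid += 1
    return SyntheticCohort(tuple(patients), scheme)


# ---------------------------------------------------------------------------
# preset class contrasts

def _base_params(model: str) -> dict:
    common = {"S0": MetricSpec(100.0, 5.0)}
    if model == "ADC":
        return {**common, "ADC": MetricSpec(1.3e-3, 0.15e-3)}
    if model == "IVIM":
        return {**common, "f": MetricSpec(0.10, 0.02),
                "D": MetricSpec(1.3e-3, 0.15e-3),
                "Dstar": MetricSpec(15e-3, 2e-3)}
    if model == "DKI":
        return {**common, "D": MetricSpec(1.5e-3, 0.15e-3),
                "K": MetricSpec(0.8, 0.1)}
    if model == "SEM":
        return {**common, "DDC": MetricSpec(1.3e-3, 0.15e-3),
                "alpha": MetricSpec(0.85, 0.04)}
    if model == "FROC":
        return {**common, "D": MetricSpec(1.3e-3, 0.15e-3),
                "beta": MetricSpec(0.85, 0.04),
                "mu": MetricSpec(5e-3, 0.2e-3)}
    if model == "CTRW":
        return {**common, "D": MetricSpec(1.3e-3, 0.15e-3),
                "alpha": MetricSpec(0.88, 0.04),
                "beta": MetricSpec(0.88, 0.04)}
    raise ValueError(model)


def mibc_like_specs(generator_model: str = "DKI"):
    """(spec0, spec1) with muscle-invasive-like contrasts in class 1:
    ~30% lower tissue diffusivity and a heavier skew mixture (greater
    within-tumor heterogeneity)."""
    model = generator_model.upper()
    p0 = _base_params(model)
    p1 = dict(p0)
    dkey = {"ADC": "ADC", "SEM": "DDC"}.get(model, "D")
    ms = p0[dkey]
    p1[dkey] = replace(ms, loc=ms.loc * 0.7, scale=ms.scale * 0.7)
    spec0 = GroupParameterSpec(model, p0, skew_weight=0.05,
                               skew_params=(dkey,))
    spec1 = GroupParameterSpec(model, p1, skew_weight=0.25,
                               skew_params=(dkey,))
    return spec0, spec1


def hg_like_specs():
    """(spec0, spec1) with high-grade-like contrasts in class 1: higher
    perfusion fraction f and lower tissue diffusivity (IVIM generator)."""
    p0 = _base_params("IVIM")
    p1 = dict(p0)
    p1["f"] = MetricSpec(0.18, 0.03)
    p1["D"] = MetricSpec(1.0e-3, 0.12e-3)
    return (GroupParameterSpec("IVIM", p0, skew_weight=0.05),
            GroupParameterSpec("IVIM", p1, skew_weight=0.15))
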