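"""Whole-VOI first-order histogram features.

Eighteen first-order statistics are computed from the distribution of
in-VOI voxel values of each metric map, following the standard radiomics
first-order definitions (population moments, fixed-bin-count discretization
for the probability-based features).  With 14 metric maps (ADC plus 13
non-Gaussian metrics) this yields 252 features per participant.

Feature list (names used in column headers):
energy, TE (total energy = voxel volume × energy), entropy, min, 10P, 90P,
max, mean, median, IQR, range, MAD (mean absolute deviation), rMAD (robust
MAD over the 10th–90th percentile subset), RMS, skewness, kurtosis
(non-excess; a normal distribution scores 3), variance, uniformity.

Skewness and kurtosis use population (biased) moments; zero-variance input
has skewness 0 and kurtosis 0 by convention.  Entropy/uniformity use a
fixed bin count (default 64) spanning the in-VOI min–max, which keeps the
discretization scale-free across metrics with heterogeneous units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import MAP_NAMES

__all__ = ["FeatureConfig", "VoxelSample", "FIRST_ORDER_FEATURES",
           "percentile", "discretize", "extract_first_order",
           "build_feature_table", "feature_columns"]

FIRST_ORDER_FEATURES = (
    "energy", "TE", "entropy", "min", "10P", "90P", "max", "mean", "median",
    "IQR", "range", "MAD", "rMAD", "RMS", "skewness", "kurtosis",
    "variance", "uniformity",
)


class EmptyVOIError(ValueError):
    """Raised when a VOI contains no usable voxels."""


@dataclass(frozen=True)
class FeatureConfig:
    n_bins: int = 64


@dataclass(frozen=True)
class VoxelSample:
    """In-VOI values of one metric map plus the voxel volume (mm³)."""
    values: np.ndarray
    voxel_volume: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values, float).ravel()
        if v.size == 0:
            raise EmptyVOIError("empty VOI")
        if not np.all(np.isfinite(v)):
            raise ValueError("VOI values must be finite")
        object.__setattr__(self, "values", v)


def percentile(values, q: float) -> float:
    """q-th percentile with linear interpolation between closest ranks."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise EmptyVOIError("empty VOI")
    if not 0 <= q <= 100:
        raise ValueError(f"q must be in [0, 100], got {q}")
    return float(np.percentile(v, q, method="linear"))


def discretize(values, n_bins: int) -> np.ndarray:
    """Bin probabilities over ``n_bins`` equal-width bins spanning [min, max].

    A constant input occupies a single bin with probability 1.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise EmptyVOIError("empty VOI")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        p = np.zeros(n_bins)
        p[0] = 1.0
        return p
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    return counts / counts.sum()


def extract_first_order(sample: VoxelSample,
                        config: FeatureConfig = FeatureConfig()) -> dict:
    """Compute the 18 first-order features of one VOI sample."""
    v = sample.values
    mean = float(v.mean())
    dev = v - mean
    constant = np.ptp(v) == 0
    var = 0.0 if constant else float(np.mean(dev ** 2))
    energy = float(np.sum(v ** 2))
    p10, p25, p75, p90 = (percentile(v, q) for q in (10, 25, 75, 90))
    if var > 0:
        skew = float(np.mean(dev ** 3) / var ** 1.5)
        kurt = float(np.mean(dev ** 4) / var ** 2)
    else:
        skew, kurt = 0.0, 0.0
    core = v[(v >= p10) & (v <= p90)]
    rmad = float(np.mean(np.abs(core - core.mean()))) if core.size else 0.0
    probs = discretize(v, config.n_bins)
    nz = probs[probs > 0]
    return {
        "energy": energy,
        "TE": sample.voxel_volume * energy,
        "entropy": float(-np.sum(nz * np.log2(nz))),
        "min": float(v.min()),
        "10P": p10,
        "90P": p90,
        "max": float(v.max()),
        "mean": mean,
        "median": percentile(v, 50),
        "IQR": p75 - p25,
        "range": float(v.max() - v.min()),
        "MAD": float(np.mean(np.abs(dev))),
        "rMAD": rmad,
        "RMS": float(np.sqrt(np.mean(v ** 2))),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": var,
        "uniformity": float(np.sum(nz ** 2)),
    }


def feature_columns(map_names=MAP_NAMES) -> list:
    """Deterministic column order: canonical map order × sorted features.

    With the full 14-map set this is the 252-column layout (14 × 18)."""
    return [f"{m}-{f}" for m in map_names for f in sorted(FIRST_ORDER_FEATURES)]


def extract_participant(maps: dict, mask, exclusion_mask=None,
                        voxel_size=(1.0, 1.0, 1.0),
                        config: FeatureConfig = FeatureConfig(),
                        degenerate=None, map_names=MAP_NAMES) -> dict:
    """Extract the first-order features for one participant.

    ``maps`` must contain every map named in ``map_names`` (default: all 14
    canonical maps → 252 features); voxels in the optional exclusion mask
    (necrosis/stalk) and voxels flagged degenerate by the fitting stage are
    removed from the VOI before feature computation.
    """
    missing = [m for m in map_names if m not in maps]
    if missing:
        raise ValueError(f"participant is missing maps: {missing}")
    mask = np.asarray(mask).astype(bool)
    keep = mask.copy()
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask).astype(bool)
    if degenerate is not None:
        keep &= ~np.asarray(degenerate).astype(bool)
    vol = float(np.prod(voxel_size))
    out = {}
    for m in map_names:
        vals = np.asarray(maps[m], float)[keep]
        vals = vals[np.isfinite(vals)]
        feats = extract_first_order(VoxelSample(vals, vol), config)
        for fname in sorted(FIRST_ORDER_FEATURES):
            out[f"{m}-{fname}"] = feats[fname]
    return out


def build_feature_table(map_sets, masks, labels, exclusion_masks=None,
                        voxel_size=(1.0, 1.0, 1.0),
                        config: FeatureConfig = FeatureConfig(),
                        ids=None, map_names=MAP_NAMES,
                        degenerate_masks=None) -> pd.DataFrame:
    """Assemble the per-participant feature table.

    Parameters
    ----------
    map_sets
        Sequence of per-participant map dicts (each with all 14 maps).
    masks, labels
        VOI mask and binary outcome per participant.

    Returns
    -------
    DataFrame with 252 feature columns plus a ``label`` column.
    """
    if exclusion_masks is None:
        exclusion_masks = [None] * len(map_sets)
    if degenerate_masks is None:
        degenerate_masks = [None] * len(map_sets)
    rows = []
    for i, (maps, mask, excl, degen) in enumerate(
            zip(map_sets, masks, exclusion_masks, degenerate_masks)):
        try:
            rows.append(extract_participant(maps, mask, excl, voxel_size,
                                            config, degenerate=degen,
                                            map_names=map_names))
        except (ValueError, EmptyVOIError) as exc:
            raise ValueError(f"participant {i}: {exc}") from exc
    df = pd.DataFrame(rows, columns=feature_columns(map_names))
    df.index = ids if ids is not None else range(len(rows))
    lab = np.asarray(labels)
    if not set(np.unique(lab)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    df["label"] = lab
    return df
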