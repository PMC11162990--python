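"""Diagnostic-model building: per-diffusion-model LASSO feature selection
with stratified 10-fold cross-validation, unpenalized logistic refit with
Wald p-values, Spearman/ICC redundancy pruning, and the combined model.

The chain mirrors a standard radiomics modeling protocol:

1. per diffusion model, L1-penalized logistic regression over a 100-point
   log-spaced λ grid from λ_max = max|Xᵀ(y−ȳ)|/n down to 10⁻³·λ_max,
   choosing the λ that minimizes mean cross-validated binomial deviance
   (features standardized inside each training fold);
2. an unpenalized maximum-likelihood logistic refit on the selected
   features (raw scale), with Wald p-values;
3. pooling of significant features (p < 0.05) across models, dropping the
   lower-ICC member of every pair with |Spearman ρ| > 0.70;
4. a final logistic fit on the survivors (the combined model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .evaluation import auc

__all__ = ["SelectionResult", "DiagnosticModel", "CombinedSpec",
           "lasso_select", "fit_logistic", "significant_features",
           "spearman_rho", "prune_redundant", "build_combined_model"]


@dataclass(frozen=True)
class SelectionResult:
    model_id: str
    selected: tuple
    lambda_used: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray


@dataclass(frozen=True)
class DiagnosticModel:
    feature_names: tuple
    intercept: float
    coefficients: np.ndarray      # log-odds per raw feature unit
    p_values: np.ndarray          # Wald, one per feature (intercept excluded)
    intercept_p: float
    training_auc: float
    separation: bool = False

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X) -> np.ndarray:
        eta = np.clip(self.linear_predictor(X), -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class CombinedSpec:
    selected: tuple
    audit: tuple = field(default_factory=tuple)  # (dropped, kept, rho, icc_d, icc_k)


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(feature_names) if feature_names is not None else \
        [f"x{i}" for i in range(X.shape[1])]
    return X, names


def lasso_lambda_max(X, y) -> float:
    """Smallest λ at which the L1-penalized logistic solution is all-zero,
    computed on the standardized design: λ_max = max|X_stdᵀ(y − ȳ)|/n."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))


def lasso_select(X, y, n_folds: int = 10, seed: int = 0,
                 model_id: str = "", n_lambda: int = 100,
                 lambda_min_ratio: float = 1e-3,
                 feature_names=None) -> SelectionResult:
    """L1-penalized logistic feature selection with stratified CV.

    Returns the features with nonzero coefficients at the deviance-minimizing
    λ, together with the full CV curve.  Deterministic given ``seed``.
    """
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y, int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    n = len(y)
    if n < 2 * n_folds:
        raise ValueError(f"need n >= {2 * n_folds} samples for {n_folds}-fold CV")

    lam_max = lasso_lambda_max(Xm, y)
    if lam_max == 0:
        return SelectionResult(model_id, (), 0.0, np.array([]), np.array([]))
    lam_grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xm, y))
    standardized = []
    for tr, va in folds:
        mu, sd = Xm[tr].mean(axis=0), Xm[tr].std(axis=0)
        sd[sd == 0] = 1.0
        standardized.append(((Xm[tr] - mu) / sd, (Xm[va] - mu) / sd))
    eps = 1e-12
    mean_dev = np.full(n_lambda, np.nan)
    best, best_dev = 0, np.inf
    # walk the path from sparse to dense; stop once the CV deviance has not
    # improved for 30 consecutive lambdas (the dense tail cannot win)
    for li, lam in enumerate(lam_grid):
        fold_dev = np.empty(n_folds)
        for fi, (tr, va) in enumerate(folds):
            Xtr, Xva = standardized[fi]
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                     C=1.0 / (len(tr) * lam), max_iter=300,
                                     tol=1e-5, intercept_scaling=100.0,
                                     random_state=0)
            clf.fit(Xtr, y[tr])
            p = np.clip(clf.predict_proba(Xva)[:, 1], eps, 1 - eps)
            fold_dev[fi] = -2.0 * np.mean(y[va] * np.log(p)
                                          + (1 - y[va]) * np.log(1 - p))
        mean_dev[li] = fold_dev.mean()
        if mean_dev[li] < best_dev:
            best, best_dev = li, mean_dev[li]
        if li - best >= 30:
            break
    lam = float(lam_grid[best])

    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                             C=1.0 / (n * lam), max_iter=1000, tol=1e-7,
                             intercept_scaling=100.0, random_state=0)
    clf.fit((Xm - mu) / sd, y)
    nz = np.flatnonzero(np.abs(clf.coef_[0]) > 0)
    return SelectionResult(model_id, tuple(names[i] for i in nz), lam,
                           lam_grid, mean_dev)


def fit_logistic(X, y, feature_names=None) -> DiagnosticModel:
    """Maximum-likelihood logistic regression with Wald p-values.

    Perfect (or quasi-) separation is detected and handled by falling back
    to a lightly ridge-stabilized IRLS fit (flagged in the result) so that
    small cohorts never hard-fail.
    """
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y, int)
    design = sm.add_constant(Xm, has_constant="add")
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params, bse = fit.params, fit.bse
        if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 50):
            raise _SeparationError
    except Exception:
        separation = True
        params, bse = _ridge_logistic(design, y)
        warnings.warn("separation or non-convergence detected; "
                      "ridge-stabilized logistic fit used")
    z = params / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    model = DiagnosticModel(
        feature_names=tuple(names),
        intercept=float(params[0]),
        coefficients=np.asarray(params[1:], float),
        p_values=np.asarray(pvals[1:], float),
        intercept_p=float(pvals[0]),
        training_auc=float("nan"),
        separation=separation,
    )
    probs = model.predict_proba(Xm)
    tr_auc = auc(probs, y).auc if np.unique(y).size == 2 else float("nan")
    object.__setattr__(model, "training_auc", tr_auc)
    return model


class _SeparationError(Exception):
    pass


def _ridge_logistic(design, y, alpha=1e-2, n_iter=200):
    """IRLS with a small L2 penalty (intercept unpenalized)."""
    n, p = design.shape
    beta = np.zeros(p)
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(n_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu) + 1e-10
        H = design.T @ (design * w[:, None]) + pen
        g = design.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(design @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu) + 1e-10
    H = design.T @ (design * w[:, None]) + pen
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


def significant_features(model: DiagnosticModel, alpha: float = 0.05):
    """Feature names with Wald p < alpha (intercept excluded)."""
    return [n for n, p in zip(model.feature_names, model.p_values) if p < alpha]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def prune_redundant(features, feature_matrix: pd.DataFrame, icc_lookup: dict,
                    rho_threshold: float = 0.70) -> CombinedSpec:
    """Drop the lower-ICC member of every feature pair with |ρ| > threshold.

    Greedy: repeatedly resolve the currently most-correlated offending pair
    until no surviving pair exceeds the threshold.  The audit trail records
    each drop.
    """
    features = list(features)
    missing = [f for f in features if f not in icc_lookup]
    if missing:
        raise ValueError(f"no ICC available for features: {missing}")
    survivors = sorted(features)
    audit = []
    while True:
        worst = None
        for i in range(len(survivors)):
            for j in range(i + 1, len(survivors)):
                rho = spearman_rho(feature_matrix[survivors[i]],
                                   feature_matrix[survivors[j]])
                if np.isnan(rho):
                    continue
                if abs(rho) > rho_threshold and (
                        worst is None or abs(rho) > abs(worst[2])):
                    worst = (survivors[i], survivors[j], rho)
        if worst is None:
            break
        fi, fj, rho = worst
        drop, keep = (fi, fj) if icc_lookup[fi] < icc_lookup[fj] else (fj, fi)
        if icc_lookup[fi] == icc_lookup[fj]:
            keep, drop = sorted([fi, fj])
        audit.append((drop, keep, float(rho),
                      float(icc_lookup[drop]), float(icc_lookup[keep])))
        survivors.remove(drop)
    return CombinedSpec(tuple(survivors), tuple(audit))


def build_combined_model(per_model_significant: dict,
                         feature_matrix: pd.DataFrame, icc_lookup: dict,
                         y, rho_threshold: float = 0.70):
    """Pool significant features across diffusion models, prune redundancy,
    and fit the combined logistic model.

    Returns ``(spec, model)``.
    """
    pool = sorted({f for feats in per_model_significant.values() for f in feats})
    if not pool:
        raise ValueError("no significant features pooled across models")
    spec = prune_redundant(pool, feature_matrix, icc_lookup, rho_threshold)
    model = fit_logistic(feature_matrix[list(spec.selected)], y,
                         feature_names=spec.selected)
    return spec, model
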