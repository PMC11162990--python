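"""End-to-end orchestration: phantom cohort → voxel fitting → two-rater
histogram features → ICC filter → per-model LASSO + logistic regression →
significance pooling and redundancy pruning → combined model → held-out
evaluation (AUC/DeLong, Youden, decision curve, Hosmer-Lemeshow,
bootstrap calibration error).

The stage order mirrors the diagnostic-model-building protocol for
multi-b-value bladder DWI: reproducibility filtering on two raters'
segmentations precedes any supervised step, feature selection runs
separately within each diffusion model, and only logistic-significant
features compete for the combined model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (auc, calibration_mae_bootstrap, decision_curve,
                         delong_ci, delong_paired_test, hosmer_lemeshow,
                         youden_operating_point)
from .features import FeatureConfig, build_feature_table, feature_columns
from .fitting import MODEL_METRICS, FitOptions, fit_all_models
from .modeling import (DiagnosticModel, build_combined_model, fit_logistic,
                       lasso_select, significant_features)
from .reliability import filter_by_icc, icc_lookup
from .scheme import BValueScheme
from .synthetic import (GroupParameterSpec, generate_cohort, mibc_like_specs)

__all__ = ["PipelineConfig", "run_pipeline", "model_map_names",
           "fit_cohort_features"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one synthetic end-to-end run.

    Loadable from YAML via :meth:`from_yaml`; list-valued fields are
    normalized to tuples so configs stay hashable and reports serializable.
    """
    task: str = "invasion"                     # invasion | grade
    models: tuple = ("ADC", "IVIM", "DKI", "SEM", "FROC", "CTRW")
    generator_model: str = "DKI"
    null_cohort: bool = False                  # no injected class difference
    n_train_per_class: int = 100
    n_test_per_class: int = 25
    snr: float = 50.0
    seed: int = 0
    shape: tuple = (20, 20, 10)
    radius_range: tuple = (2.5, 4.0)
    necrosis_prob: float = 0.0
    icc_threshold: float = 0.80
    rho_threshold: float = 0.70
    alpha: float = 0.05
    n_folds: int = 10
    n_bins: int = 64
    n_restarts: int = 1
    calibration_B: int = 200
    voxel_size: tuple = (2.0, 2.0, 2.0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "shape", "radius_range", "voxel_size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "models" in raw:
            raw["models"] = tuple(m.upper() for m in raw["models"])
        return cls(**raw)


def model_map_names(models) -> list:
    """Metric-map names produced by the given diffusion models."""
    names = []
    for m in models:
        m = m.upper()
        if m == "ADC":
            names.append("ADC")
        else:
            names.extend(f"{m}-{metric}" for metric in MODEL_METRICS[m])
    return names


def fit_cohort_features(cohort, models, fit_options, feature_config,
                        voxel_size=(2.0, 2.0, 2.0)):
    """Fit all requested models for every patient and extract features with
    both raters' masks.  Returns (table_a, table_b) DataFrames."""
    map_names = model_map_names(models)
    maps_list, degen_list = [], []
    for p in cohort.patients:
        fit_mask = p.mask | p.mask_b
        maps, _qc, degen = fit_all_models(p.dwi, fit_mask, cohort.scheme,
                                          models=models, options=fit_options)
        maps_list.append(maps)
        degen_list.append(degen)
    labels = [p.label for p in cohort.patients]
    excl = [p.exclusion_mask for p in cohort.patients]
    kw = dict(exclusion_masks=excl, voxel_size=voxel_size,
              config=feature_config, map_names=map_names,
              degenerate_masks=degen_list)
    table_a = build_feature_table(maps_list, [p.mask for p in cohort.patients],
                                  labels, **kw)
    table_b = build_feature_table(maps_list,
                                  [p.mask_b for p in cohort.patients],
                                  labels, **kw)
    cohorts = pd.Series([p.cohort for p in cohort.patients])
    table_a["cohort"] = cohorts.values
    table_b["cohort"] = cohorts.values
    return table_a, table_b


def _intercept_only(y) -> DiagnosticModel:
    rate = float(np.clip(np.mean(y), 1e-9, 1 - 1e-9))
    return DiagnosticModel(feature_names=(), intercept=float(np.log(rate / (1 - rate))),
                           coefficients=np.zeros(0), p_values=np.zeros(0),
                           intercept_p=float("nan"), training_auc=0.5)


def _evaluate(model: DiagnosticModel, table: pd.DataFrame, B, seed):
    y = table["label"].to_numpy(int)
    if model.feature_names:
        probs = model.predict_proba(table[list(model.feature_names)].to_numpy())
    else:
        probs = np.full(len(y), model.predict_proba(np.zeros((1, 0)))[0])
    roc = auc(probs, y)
    try:
        ci = delong_ci(probs, y)
    except ValueError:
        ci = (roc.auc, roc.auc)
    op = youden_operating_point(probs, y)
    out = {
        "auc": roc.auc, "ci95": ci,
        "accuracy": op.accuracy, "sensitivity": op.sensitivity,
        "specificity": op.specificity, "threshold": op.threshold,
    }
    return probs, out


def run_pipeline(config: PipelineConfig,
                 spec0: GroupParameterSpec | None = None,
                 spec1: GroupParameterSpec | None = None,
                 out_dir=None) -> dict:
    """Run the whole chain on a generated cohort; returns the run report.

    When ``spec0``/``spec1`` are omitted they default to the
    muscle-invasion-like preset (or a null cohort with identical specs when
    ``config.null_cohort`` is set).
    """
    models = tuple(m.upper() for m in config.models)
    if spec0 is None or spec1 is None:
        s0, s1 = mibc_like_specs(config.generator_model)
        spec0 = spec0 or s0
        spec1 = spec1 or (s0 if config.null_cohort else s1)

    scheme = BValueScheme()
    cohort = generate_cohort(
        config.n_train_per_class, spec0, spec1, scheme, snr=config.snr,
        seed=config.seed, shape=config.shape,
        radius_range=config.radius_range,
        n_test_per_class=config.n_test_per_class,
        necrosis_prob=config.necrosis_prob)

    fit_options = FitOptions(n_restarts=config.n_restarts, seed=config.seed)
    feature_config = FeatureConfig(n_bins=config.n_bins)
    table_a, table_b = fit_cohort_features(cohort, models, fit_options,
                                           feature_config, config.voxel_size)

    train_a = table_a[table_a["cohort"] == "training"].drop(columns="cohort")
    train_b = table_b[table_b["cohort"] == "training"].drop(columns="cohort")
    test_a = table_a[table_a["cohort"] == "testing"].drop(columns="cohort")
    y_train = train_a["label"].to_numpy(int)

    map_names = model_map_names(models)
    n_features = len(feature_columns(map_names))

    # 1. two-rater reproducibility filter (training cohort)
    retained, icc_results = filter_by_icc(train_a, train_b,
                                          config.icc_threshold)
    iccs = icc_lookup(icc_results)

    # 2. per-diffusion-model LASSO selection + logistic refit
    per_model = {}
    significant = {}
    for m in models:
        cols = [c for c in retained if c.startswith(f"{m}-")]
        entry = {"icc_retained": cols, "selected": [], "card": None}
        if cols:
            sel = lasso_select(train_a[cols], y_train,
                               n_folds=config.n_folds, seed=config.seed,
                               model_id=m)
            entry["selected"] = list(sel.selected)
            entry["lambda"] = sel.lambda_used
        if entry["selected"]:
            fit = fit_logistic(train_a[entry["selected"]], y_train,
                               feature_names=entry["selected"])
        else:
            fit = _intercept_only(y_train)
        entry["card"] = _model_card(fit)
        entry["model"] = fit
        per_model[m] = entry
        significant[m] = significant_features(fit, config.alpha)

    # 3. pool, prune, combined model
    pool = sorted({f for feats in significant.values() for f in feats})
    if pool:
        spec, combined = build_combined_model(
            significant, train_a, iccs, y_train, config.rho_threshold)
        prune_audit = list(spec.audit)
    else:
        warnings.warn("no significant features pooled; combined model is "
                      "intercept-only")
        combined = _intercept_only(y_train)
        prune_audit = []

    # 4. held-out evaluation
    evaluation = {}
    probs = {}
    for m in models:
        probs[m], evaluation[m] = _evaluate(per_model[m]["model"], test_a,
                                            config.calibration_B, config.seed)
    probs_c, evaluation["combined"] = _evaluate(combined, test_a,
                                                config.calibration_B,
                                                config.seed)
    y_test = test_a["label"].to_numpy(int)
    comparisons = {}
    for m in models:
        try:
            _z, p = delong_paired_test(probs[m], probs_c, y_test)
        except ValueError:
            p = float("nan")
        comparisons[f"{m}_vs_combined"] = p

    dca = decision_curve(np.clip(probs_c, 0, 1), y_test)
    hl = (hosmer_lemeshow(probs_c, y_test)
          if np.ptp(probs_c) > 0 and len(y_test) >= 20 else None)
    cal_mae = (calibration_mae_bootstrap(probs_c, y_test,
                                         B=config.calibration_B,
                                         seed=config.seed)
               if np.ptp(probs_c) > 0 else float("nan"))

    report = {
        "config": asdict(config),
        "feature_count": {
            "n_maps": len(map_names), "n_features_per_map": 18,
            "n_features": n_features,
            "line": f"{len(map_names)} maps × 18 features = {n_features}",
        },
        "icc": {"threshold": config.icc_threshold,
                "n_retained": len(retained),
                "n_excluded": len(icc_results) - len(retained)},
        "per_model": {m: {k: v for k, v in e.items() if k != "model"}
                      for m, e in per_model.items()},
        "significant": significant,
        "combined": {"pool": pool, "prune_audit": prune_audit,
                     "card": _model_card(combined)},
        "evaluation": evaluation,
        "delong_vs_combined": comparisons,
        "hosmer_lemeshow": (None if hl is None else
                            {"statistic": hl.hl_statistic, "df": hl.hl_df,
                             "p": hl.hl_p}),
        "calibration_mae": cal_mae,
        "decision_curve": {"thresholds": dca.thresholds.tolist(),
                           "net_benefit_model": dca.net_benefit_model.tolist(),
                           "net_benefit_all": dca.net_benefit_all.tolist()},
        "seeds": {"pipeline": config.seed},
    }
    report["_models"] = {m: per_model[m]["model"] for m in models}
    report["_models"]["combined"] = combined
    report["_tables"] = {"train_a": train_a, "train_b": train_b,
                         "test_a": test_a}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in report.items()
                        if not k.startswith("_")}
        with open(out / "report.json", "w") as fh:
            json.dump(serializable, fh, indent=2, default=_jsonify)
        train_a.to_csv(out / "features_training_raterA.csv")
        train_b.to_csv(out / "features_training_raterB.csv")
        test_a.to_csv(out / "features_testing.csv")
    return report


def _model_card(model: DiagnosticModel) -> dict:
    """Table-style card: intercept and per-feature coefficient/p-value."""
    rows = [{"feature": "Intercept", "coef": model.intercept,
             "p": model.intercept_p}]
    rows += [{"feature": n, "coef": float(c), "p": float(p)}
             for n, c, p in zip(model.feature_names, model.coefficients,
                                model.p_values)]
    return {"rows": rows, "training_auc": model.training_auc,
            "separation": model.separation}


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
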