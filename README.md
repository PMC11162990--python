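# ngdwi

Non-Gaussian diffusion MRI analysis for multi-b-value DWI: voxel-wise model
fitting, whole-tumor histogram radiomics, and diagnostic-model building with
honest statistical evaluation.

## Who this is for

Quantitative-imaging researchers working with multi-b-value
diffusion-weighted MRI of tumors (the design target is bladder-cancer
staging/grading: muscle-invasive vs non-muscle-invasive disease, and
high vs low histological grade), who need a reproducible, testable
implementation of the full chain from raw 4D DWI to a validated logistic
diagnostic model — plus synthetic phantoms with known ground truth so each
stage can be verified before touching patient data.

## What it computes

1. **Six diffusion decay models**, fitted per voxel from an 11-b-value
   protocol (0-2500 s/mm²):
   - mono-exponential **ADC**: S = S₀·exp(−b·ADC)
   - **IVIM**: S = S₀·[f·e^(−bD*) + (1−f)·e^(−bD)]
   - **DKI**: S = S₀·exp[−bD + (1/6)K(bD)²]
   - **SEM** (stretched exponential): S = S₀·exp[−(b·DDC)^α]
   - **FROC** (fractional-order calculus):
     S = S₀·exp[−D·μ^{2(β−1)}(γG_dδ)^{2β}(Δ − ((2β−1)/(2β+1))δ)]
   - **CTRW** (continuous-time random walk): S = S₀·E_α[−(bD)^β], with a
     Talbot-contour Mittag-Leffler evaluator accurate to ≤10⁻⁸ on the
     completely monotone branch.

   Together: one ADC map and 13 non-Gaussian metric maps per subject.
2. **252 first-order histogram features** per participant (14 maps × 18
   features) over the whole-tumor VOI, with necrosis-exclusion masks and
   degenerate-voxel screening.
3. **Two-rater ICC(2,1) reproducibility filter** (threshold 0.80).
4. **Per-model LASSO (10-fold CV) → logistic refit with Wald p-values →
   p<0.05 pooling → Spearman/ICC redundancy pruning → combined model.**
5. **Evaluation**: AUC with DeLong 95% CI, paired DeLong tests between
   models, Youden operating point (accuracy/sensitivity/specificity),
   decision-curve analysis, Hosmer-Lemeshow calibration, bootstrap
   calibration MAE, and Mann-Whitney/chi-square cohort-balance tests.
6. **Synthetic cohorts**: ellipsoidal phantoms with class-conditional
   parameter distributions, within-tumor skewness-inducing texture, Rician
   noise, second-rater mask perturbation, and train/test splits — fully
   deterministic under seeds.

See `docs/methods.md` for models, conventions, numerical choices, and
limitations (including the exact D-μ unidentifiability of FROC under
scalar-b protocols).

## Worked example

End-to-end run on a synthetic two-class cohort (60 training / 20 testing
patients per class; class 1 has 12% lower tissue diffusivity D and a
heavier within-tumor skew mixture; ADC and DKI fitted):

```python
from dataclasses import replace
from ngdwi.pipeline import PipelineConfig, run_pipeline
from ngdwi.synthetic import mibc_like_specs

spec0, spec1 = mibc_like_specs("DKI")
d0 = spec0.params["D"]
spec1 = replace(spec1,
                params={**spec1.params, "D": replace(d0, loc=d0.loc * 0.88)},
                skew_weight=0.12)
cfg = PipelineConfig(models=("ADC", "DKI"), n_train_per_class=60,
                     n_test_per_class=20, shape=(14, 14, 8),
                     radius_range=(1.5, 2.5), seed=11)
report = run_pipeline(cfg, spec0=spec0, spec1=spec1)
```

Output (held-out testing cohort):

```
ICC: {'threshold': 0.8, 'n_retained': 22, 'n_excluded': 32}
ADC:      AUC 0.802 CI (0.663, 0.942)  acc 0.78  sens 0.85  spec 0.70
DKI:      AUC 0.825 CI (0.695, 0.955)  acc 0.78  sens 0.80  spec 0.75
combined: AUC 0.718 CI (0.553, 0.882)  acc 0.72  sens 0.60  spec 0.85
significant: {'ADC': ['ADC-median', 'ADC-90P'],
              'DKI': ['DKI-D-median', 'DKI-D-90P']}
delong vs combined: {'ADC_vs_combined': 0.339, 'DKI_vs_combined': 0.315}
HL: statistic 5.49, df 8, p 0.704
```

Reading this: the reproducibility filter kept 22 of 54 features (two
fitted models → 54 columns; small phantoms make boundary-sensitive
features irreproducible between raters).  LASSO + logistic refit found the
central-tendency features of the diffusivity maps significant in both
models — exactly the injected contrast (lower D in class 1).  Both
single-model AUCs beat chance clearly; the DeLong tests show the combined
model is not significantly different from either single model on 40 test
subjects; the Hosmer-Lemeshow p of 0.70 flags no miscalibration.

The same chain is scriptable from the shell:

```bash
ngdwi run-all --out demo/ --n-train 25 --n-test 10 --seed 7 --models adc,dki
ngdwi fit --dwi dwi.nii.gz --mask voi.nii.gz --bval scheme.bval \
          --models adc,ivim,dki,sem,froc,ctrw --out maps/
ngdwi features --maps maps/ --mask voi.nii.gz --out features.csv
```

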