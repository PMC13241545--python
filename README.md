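# mbdwi — multi-b-value diffusion MRI models for zone-aware prostate cancer risk

Quantitative diffusion-weighted MRI probes tissue microstructure by how the
signal S(b) decays as the diffusion weighting b (s/mm²) increases. The
conventional apparent diffusion coefficient assumes Gaussian diffusion
(S = S0·e^(−b·ADC)), which under-describes the heterogeneous
microenvironment of clinically significant prostate cancer (csPCa, ISUP
grade group ≥ 2) — especially in the transition zone (TZ), where dense
stromal barriers make water diffusion markedly non-Gaussian.

`mbdwi` is a library + analysis project for radiology researchers working
with multi-b-value prostate DWI. It implements:

- **Seven diffusion signal models** — mono-exponential (MEM), stretched
  exponential (SEM), intravoxel incoherent motion (IVIM), diffusion
  kurtosis (DKI), hybrid IVIM-DKI, continuous-time random walk
  (CTRW, S = S0·E_α(−(bD)^β) via a validated Mittag-Leffler evaluator),
  and fractional order calculus (FROC) — yielding 18 named metrics
  (`MEM_ADC`, `CTRW_alpha`, …).
- **Constrained model fitting** (voxel-wise or ROI-wise; NIfTI in/out)
  with deterministic multi-start, segmented IVIM / IVIM-DKI strategies and
  an optional Rician noise-floor term.
- **A calibrated synthetic cohort generator** reproducing the structure of
  a two-centre study (162 patients / ~224 lesions plus a 76-patient
  cross-vendor cohort): clustered lesions, zone-specific csPCa prevalence,
  PI-RADS and grade-group conditional tables, two-reader replicates, and
  vendor batch effects. No patient data are required anywhere.
- **The statistical chain**: inter-reader ICC(2,1) gating at 0.80,
  Mann-Whitney/chi-square comparisons with Benjamini-Hochberg FDR,
  Spearman correlation with grade group per zone, bootstrap-LASSO
  stability selection, GEE logistic inference over patient clusters,
  three nested risk models (Clinical / Clinical+ADC / Clinical+Multib-DWI)
  with ROC, DeLong tests and decision-curve analysis, subgroup analyses,
  and an exploratory zone-aware split model (ADC for the peripheral zone,
  CTRW α for the transition zone).
- **ComBat harmonization** (parametric empirical Bayes, biology-protected)
  with a cross-vendor consistency check and frozen-model external
  validation; verified against Bioconductor `sva::ComBat`.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from mbdwi import (CohortConfig, generate_cohort,
                   PipelineConfig, run_analysis)

cohort = generate_cohort(CohortConfig(
    seed=11, effect_metrics=["MEM_ADC", "CTRW_alpha"]))  # planted-signal mode
result = run_analysis(cohort, PipelineConfig(seed=11, n_boot_lasso=100))
rep = result["report"]
print(rep["stable_metrics"])
print({r["term"]: round(r["or"], 3) for r in rep["gee"] if r["term"].endswith("_z")})
print({k: round(v["auc"], 3) for k, v in rep["model_eval"]["test"].items()})
```

prints

```
['MEM_ADC', 'CTRW_alpha']
{'MEM_ADC_z': 0.042, 'CTRW_alpha_z': 0.062}
{'clinical': 0.887, 'clinical_adc': 0.959, 'clinical_multib': 0.966}
```

meaning: on a 162-patient synthetic cohort where only MEM_ADC and
CTRW_alpha carry group differences, stability selection recovers exactly
those two metrics; after clinical adjustment their GEE odds ratios per SD
are well below 1 (lower ADC and lower α mean higher csPCa risk); and adding
the selected diffusion metrics to the clinical model raises the held-out
test AUC from 0.89 to 0.97.

The numbered drivers under `analysis/` walk the full study:
`01_simulate_cohorts.py` → `02_fit_recovery.py` → `03_reliability_gate.py`
→ `04_group_comparisons.py` → `05_stability_selection.py` →
`06_risk_models.py` → `07_cross_vendor.py`, each writing its tables to
`results/`. A thin CLI wraps the same stages:

```bash
mbdwi simulate --out-dir runs/demo --seed 11
mbdwi analyze  --cohort runs/demo/primary_lesions.csv \
               --reader-pairs runs/demo/primary_reader_pairs.csv \
               --out-dir runs/demo --seed 11
mbdwi validate --models-dir runs/demo \
               --external runs/demo/external_lesions.csv \
               --out-dir runs/demo --seed 11
```

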