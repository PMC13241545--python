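# Methods

`mbdwi` implements a complete lesion-level analysis chain for multi-b-value
diffusion-weighted MRI (DWI) of the prostate: seven diffusion signal models
yielding 18 quantitative metrics, constrained model fitting, inter-reader
reliability gating, bootstrap-LASSO stability selection, clustered logistic
inference (GEE), nested risk models with ROC / decision-curve evaluation,
and ComBat cross-vendor harmonization. Because the motivating clinical
dataset is private, the package ships a calibrated synthetic cohort
generator that reproduces the statistical structure of a two-centre study
(162 patients / ~224 lesions on the primary scanner, 76 / ~84 on a second
vendor), so every stage is exercised end to end with no external data.

## Signal models

The diffusion-weighted signal of a voxel or ROI decays with the diffusion
weighting b (s/mm²). The seven forward models and their parameters (18
metrics named `ModelName_ParameterName`):

| family | signal equation | parameters |
|---|---|---|
| MEM | S0·exp(−b·ADC) | MEM_ADC |
| SEM | S0·exp(−(b·DDC)^α) | SEM_DDC, SEM_alpha |
| IVIM | S0·[f·e^(−b·D*) + (1−f)·e^(−b·D)] | IVIM_D, IVIM_Dstar, IVIM_f |
| DKI | S0·exp(−b·D + (b·D)²·K/6) | DKI_D, DKI_K |
| IVIM-DKI | S0·[f·e^(−b·Dp) + (1−f)·e^(−bD+(bD)²K/6)] | IVIM-DKI_{D, Dp, f, K} |
| CTRW | S0·E_α(−(b·D)^β) | CTRW_D, CTRW_alpha, CTRW_beta |
| FROC | S0·exp(−D·μ^(2(β−1))·b^β) | FROC_D, FROC_beta, FROC_mu |

Units: diffusivities are stored throughout in the reporting unit
×10⁻³ mm²/s and converted to mm²/s only inside the forward evaluations, so
the same numbers flow from tables to statistics without conversion.
α, β, f, K are dimensionless; FROC μ is treated numerically as reported
(~7.2–7.8; interpreted as μm and converted to mm so the β = 1 limit is
exactly mono-exponential — the literature is not consistent about this
unit, and nothing downstream depends on the choice). Each model family is
a named strategy, so a variant formulation can be swapped in.

The default acquisition is a 12-point scheme
{0, 50, 100, 150, 200, 500, 800, 1000, 1500, 2000, 2500, 3000} s/mm²
(configurable). The quadratic kurtosis expansion is trusted only to
`b_max_dki` = 2000 s/mm² (beyond that a validity warning is attached, not
an exception); the non-Gaussian families require a maximum b ≥ 2000.

### Mittag-Leffler numerics

The CTRW decay needs the one-parameter Mittag-Leffler function E_α(z) for
0 < α ≤ 1 on the negative real axis, where it is completely monotone. The
power series Σ z^k/Γ(αk+1) suffers catastrophic cancellation once its
largest term (~e^{|z|^{1/α}}) dwarfs the result, so evaluation is split:

1. α = 1: `exp(z)` exactly.
2. Guarded power series: accepted only while max|term|/|sum| < 10⁴
   (relative error ≲ 10⁻¹⁰ in double precision).
3. Otherwise, trapezoidal quadrature of the spectral representation
   E_α(−x) = sin(απ)/(απ) ∫₀^∞ e^{−t·q^{1/α}} / (q² + 2q·cos(απ) + 1) dq,
   t = x^{1/α}, on a logarithmic grid. The integrand is positive (no
   cancellation) and analytic in a strip of half-width
   d = min(απ/2, π(1−α)); with step h = d/8 the discretisation error is
   O(e^{−16π}) and accuracy is round-off limited. The spectral density
   develops a near-pole at q = 1 as α → 1, so for α within 5·10⁻⁴ of 1 the
   integral is evaluated by adaptive quadrature with a breakpoint at the
   peak instead.

The quadrature paths certify themselves by step-halving (raising
`MittagLefflerError` beyond 10⁻⁸ relative disagreement); `check=False`
skips the second pass inside fitting loops. Validated against an
arbitrary-precision mpmath series (and, where the series needs more than
10⁶ terms, mpmath's independent Talbot Laplace inversion): worst relative
error 2·10⁻¹¹ over α ∈ [0.05, 1], |z| ≤ 30. A Taylor-plus-asymptotic
scheme was considered and rejected: the asymptotic expansion of E_α(−x)
cannot reach 10⁻⁸ relative accuracy in the mid range x ∈ (2, 30) for
mid-range α, which is exactly the CTRW fitting domain (|z| ≤ ~12).

## Fitting

Every family except MEM is fitted by bounded trust-region-reflective least
squares with a deterministic 5-point Latin-hypercube multi-start (fixed
seed; ties in residual sum of squares broken lexicographically, so a fit is
a pure function of data and configuration). MEM_ADC has a closed form:
weighted linear regression of log-signal on b with weights S², which
matches the original-domain least squares to first order. Default bounds:
D-type ∈ [0.05, 4]×10⁻³ mm²/s, D*/Dp ∈ [3, 100]×10⁻³, f ∈ [0, 0.5],
α, β ∈ [0.1, 1], K ∈ [0, 3], μ ∈ [1, 20] μm. Per-family b-subsets
(configurable): IVIM uses b ≤ 1000 (perfusion lives at low b), the
kurtosis families b ≤ 2000, the rest the full scheme.

Design choices that matter:

- **Segmented IVIM** (default strategy): D from the b ≥ 200 s/mm²
  mono-exponential tail, then (S0, f, D*) with D fixed, iterated three
  times with perfusion subtraction — a single pass leaves a ~3% D bias
  from perfusion contamination at b ∈ [200, 500]. The joint 4-parameter
  fit (used for exact noiseless recovery) and the segmented fit agree to
  ~1–2% on clean decays.
- **Segmented IVIM-DKI** (default): tissue (D, K) from b ≥ 200 first, then
  (f, Dp) with tissue fixed. The joint 5-parameter fit has a K ≈ 0
  collapse mode under noise (~25% of decays at SNR 50: the perfusion
  fraction absorbs the kurtosis curvature), which the segmentation
  removes.
- **FROC identifiability**: with b-value data alone, D and μ enter the
  simplified FROC form only through D·μ^{2(β−1)} at any fixed β, so the
  pair lies on an exact ridge. The fit therefore holds μ at a fixed
  reference (default 7.4 μm, a typical prostate-tissue value) and
  estimates D and β; `froc_mu_fixed=None` exposes the free, degenerate
  fit. The identifiable composite rate is recovered exactly for any
  generating μ.
- **Rician floor** (opt-in per family): magnitude-MRI noise imposes a
  signal floor σ√(π/2); at prostate-typical parameters the FROC decay
  falls below it near b = 3000, biasing D low by ~5% at SNR 50. With
  `rician_floor=("FROC",)` the model predicts √(S² + (π/2)σ_n²) with σ_n
  an extra bounded parameter. It is not enabled for families whose decay
  stays well above the floor — there the extra freedom only destabilises
  weakly identified parameters.

Voxel-wise maps are fitted independently (no spatial regularisation) and
ROIs aggregate by the mean over converged voxels, with per-metric voxel
counts reported. Volumes are NIfTI with FSL-style single-row b-value
sidecars; affines pass through untouched.

## Synthetic cohort generator

The generator is the canonical test input and defines the study
conditions; its defaults are calibrated once to the published lesion-level
summaries and are not tuning knobs.

- **Patients**: age ~ normal, PSA and prostate volume ~ log-normal matched
  to the published medians/IQRs; PSAD = PSA/volume; DRE positive with the
  published frequency; a logit-scale random intercept (sd 0.5) makes
  lesions of one patient correlated. Lesion counts per patient
  {1: 0.717, 2: 0.184, 3: 0.099} reproduce the published 224/162
  lesion-to-patient ratio in expectation.
- **Lesions**: zone PZ with probability 0.442; csPCa via
  logit(p) = logit(zone prevalence) + log(2)·log2(PSAD/median) + patient
  intercept (the PSAD odds ratio of 2 per doubling is an assumption — the
  study reports marginals, not effect sizes); grade group and PI-RADS from
  the published conditional tables; csPCa ⇔ grade group ≥ 2 everywhere.
- **Metrics**: each of the 18 metrics is drawn from a log-normal (positive
  metrics) or logit-normal (unit-interval metrics) margin whose median
  equals the published zone- and group-specific median and whose IQR
  matches via σ = log-scale IQR / 1.349 — chosen because the source
  reports skewed median (IQR) summaries. A Gaussian copula couples the
  seven diffusivity-type metrics (latent correlation 0.7, configurable;
  the true inter-metric correlation is unreported) and lesion diameter
  with volume (0.8).
- **Planted-signal mode** (`effect_metrics=[...]`): only the listed
  metrics keep group-specific margins; all others are drawn from the
  overall benign margin — group- *and* zone-independent, and latently
  decoupled from the planted metrics. Both provisos matter: zone-specific
  "null" margins would proxy the zone-dependent csPCa prevalence, and a
  null latently correlated with a planted metric becomes a suppressor
  variable; either way the nulls would carry real conditional signal and
  the planted-recovery experiment would be testing the wrong thing.
- **Measurement layers**: two readers observe each lesion-metric with
  multiplicative and additive jitter; additive sds are derived from the
  variance-components identity σ_e = σ_b·√(1/ICC − 1) for a target ICC
  (default 0.94, matching the reported "all ICCs > 0.80"). The analysis
  uses the reader average. Signal decays add Rician noise (magnitude of a
  complex Gaussian perturbation, σ = S0/SNR, default SNR 50). The
  cross-vendor cohort receives a location/scale batch effect (default:
  scale 1.15, shift 6% of each metric's benign median — magnitudes are
  assumptions, the study only states that a vendor effect existed).

All randomness derives from one root seed via `numpy` SeedSequence
spawning (separate streams for patients, labels, metrics, readers,
decays), so identical seeds give identical tables.

What the generator does *not* emulate: image-level anatomy and artifacts,
registration error, radiologist behaviour beyond the PI-RADS conditional
table, inter-metric correlations beyond the copula, or any dependence of
metric values on the *same* underlying decay (each family's parameters are
drawn jointly from the copula, not derived from one signal). Passing tests
therefore demonstrate that the analysis chain recovers structure it is
designed for — not that it would perform identically on patient data.

## Reliability gating

Inter-reader agreement per metric is ICC(2,1) — two-way random effects,
absolute agreement, single rater — computed from the classical
mean-squares decomposition; the source cites threshold conventions but not
the variant, and ICC(2,1) is the conservative standard for continuous
radiology measurements (ICC(2,k) is available). Metrics pass at
ICC ≥ 0.80; exclusions are logged and the gate runs before feature
selection.

## Statistical chain

- **Split**: patient-level 70/30 (floor rule: 162 patients → 113/49);
  lesions inherit their patient's split, never straddling it.
- **Comparisons**: two-sided Mann-Whitney U (continuous) or chi-square
  (categorical), Benjamini-Hochberg FDR within each comparison column
  (each zone stratum is its own family, matching per-column adjusted
  summaries); Spearman ρ of each metric with grade group per zone.
- **Stability selection**: bootstrap resampling of *patients* (preserving
  lesion clusters; lesion-level available), metrics z-scored within each
  resample, L1-penalised logistic fit, selection frequency over resamples,
  stable set = frequency > 0.5. The per-resample penalty is the
  universal threshold λ = √(2·log p)·√(ȳ(1−ȳ)/n) — the fixed-penalty
  practice of the stability-selection literature. Cross-validated
  penalties are provided as options (`cv_min`, `cv_1se`) but are not the
  default: CV inside bootstrap resamples is optimistic (duplicated
  lesions leak across folds) and empirically the CV-minimum rule admits
  pure-noise features in 60–95% of iterations in planted-signal
  experiments, which contradicts both the intended operating
  characteristics (planted frequency > 0.9, null frequency < 0.5) and the
  motivating study's own outcome of exactly two stable metrics. With the
  universal threshold, ten independent generator seeds give planted
  frequencies ≥ 0.98 and maximal null frequencies ≤ 0.28.
- **GEE**: binomial-logit generalized estimating equations with an
  exchangeable working correlation over patients and robust sandwich
  errors; covariates are age, PSAD, DRE, PI-RADS dummies (category 3
  reference), zone, lesion volume, plus the stable metrics z-scored on the
  training split (so odds ratios are per SD). With singleton clusters GEE
  coincides with ordinary logistic regression (tested to 10⁻⁶). A fully
  calibrated cohort can yield a stable set so jointly informative that the
  outcome separates; the pipeline then reports the failure and retries
  with the two most frequently selected metrics (logged).
- **Risk models**: three nested logistic models — Clinical (age, PSAD,
  DRE, zone, lesion volume, PI-RADS dummies), Clinical+ADC (+MEM_ADC),
  Clinical+Multib-DWI (+stable metrics). Separation triggers an L2
  fallback, flagged. The operating threshold is Youden's J on the
  training predictions, frozen for test and external evaluation (the
  source reports operating-point metrics without stating a rule).
- **Evaluation**: AUC by the Mann-Whitney estimator (equal to exhaustive
  concordant-pair counting; midranks for ties) with a 2000-replicate
  stratified bootstrap CI; DeLong structural-components test for paired
  AUCs; decision curves NB(t) = TP/n − (FP/n)·t/(1−t) with treat-all /
  treat-none references; subgroup analyses in PZ, TZ, PI-RADS 3,
  PI-RADS 4–5 and TZ∩PI-RADS 3 (the latter with both cancer vs benign and
  csPCa vs non outcomes; small strata flagged, single-class strata
  skipped); and an exploratory zone-aware split model routing PZ lesions
  to a Clinical+MEM_ADC model and TZ lesions to a Clinical+CTRW_alpha
  model.

## Harmonization

ComBat models each feature as α_g + Xβ_g + γ_gi + δ_gi·ε and removes the
batch location γ and scale δ with parametric empirical-Bayes shrinkage
(normal prior on γ, inverse-gamma on δ²; `eb=False` for plain per-feature
alignment). csPCa status is a protected covariate by default (the
downstream consistency check conditions on pathology); no reference batch
is designated. The implementation matches Bioconductor `sva::ComBat` to
6·10⁻⁸ on a shared fixture (tested through Rscript).

Two finite-sample properties worth knowing:

- The reference algorithm divides the pooled residual variance by N but
  batch variances by n−1, so harmonizing twice differs from harmonizing
  once at O(1/N) — it is *not* idempotent to machine precision.
  `sigma_df="unbiased"` divides by N − rank(design) instead, making the
  no-EB, no-covariate pass exactly idempotent.
- EB shrinkage intentionally leaves part of each feature's scale estimate
  in the prior, so per-feature variance ratios after harmonization spread
  ±~20% at n = 200/arm even when the true scale effect is common; the
  non-EB estimator aligns them to within a few percent. Neither mode can
  "de-noise": both batches end at the pooled noise level, so standardized
  effect sizes shrink by exactly the pooled-σ inflation.

The cross-vendor consistency check runs Mann-Whitney per metric within
each pathology group across vendors (consistent = all groups p > 0.05).
With two *independently sampled* ~150-lesion arms the check performs 36
tests at the 5% level, so sampling noise alone fails ≥ 2 metrics about
half the time regardless of harmonization quality; the packaged
planted-shift experiment therefore uses a twin-arm design (the same
lesions under both vendor labels, one arm shifted/scaled), which isolates
removal of the planted effect and robustly restores ≥ 17/18 consistency.
External validation applies the frozen training models (coefficients and
thresholds) to the harmonized external cohort without refitting.

## Problem sizes and tolerances

Defaults used by the analysis drivers and acceptance runs, chosen to keep
a full desk-scale replication in minutes: 162-patient primary cohort,
76-patient external cohort, 100–500 bootstrap resamples for selection
(the planted-recovery experiment uses 100), 200 Rician decays per family
at SNR 50, 500–2000 bootstrap replicates for AUC CIs. Noiseless
round-trips are asserted at ≤ 1% (interior parameters, joint strategies),
Rician median biases at ≤ 5% (diffusivities) and ≤ 10% (shape
parameters), the reduction lattice at ≤ 10⁻¹⁰, and Mittag-Leffler values
at ≤ 10⁻⁸ against arbitrary-precision oracles.

## Known limitations

- The simplified b-space FROC form cannot separate D from μ; fitted
  FROC_mu is a convention, and only the composite rate is estimable from
  b-value data.
- Synthetic metric vectors are copula draws, not re-fits of one shared
  decay, so fit-induced correlations between families are absent from the
  cohort tables (the fitting path is exercised separately).
- GEE on a fully calibrated cohort can separate; the fallback reports a
  reduced model rather than failing the run.
- Voxel fits are independent; no spatial regularisation, denoising,
  motion/eddy correction or registration is attempted.
- The consistency check's 17/18-style counts are only meaningful under
  the twin-arm design; across independently sampled cohorts they carry
  irreducible multiple-testing noise.
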