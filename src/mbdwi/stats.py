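"""Inferential chain of the lesion-level csPCa analysis.

Order of operations, mirroring the study design: patient-level cohort
split; Mann-Whitney / chi-square group comparisons with Benjamini-Hochberg
FDR within each metric family; Spearman correlation of metrics with
Gleason grade group per zone; bootstrap-LASSO stability selection of
diffusion predictors; GEE logistic regression with an exchangeable working
correlation over patients (multiple lesions per patient are correlated);
three nested logistic risk models (Clinical, Clinical+ADC,
Clinical+Multib-DWI); ROC evaluation with DeLong model comparison;
decision-curve analysis; zone / PI-RADS subgroup analyses; and the
exploratory zone-aware split model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "split_cohort", "compare_groups", "spearman_by_zone",
    "bootstrap_lasso_select", "StabilityResult", "gee_fit",
    "prepare_design", "CLINICAL_COVARIATES", "LogisticModel", "fit_risk_models",
    "auc_mannwhitney", "youden_threshold", "roc_metrics", "ModelEval",
    "delong_test", "decision_curve", "subgroup_analysis", "zone_aware_predict",
    "bh_adjust",
]

#: covariates of the Clinical base model (after ``prepare_design``)
CLINICAL_COVARIATES = ["age", "psad", "dre", "zone_tz", "volume", "pirads_4", "pirads_5"]


# ---------------------------------------------------------------- splitting

def split_cohort(table: pd.DataFrame, train_fraction: float = 0.7,
                 seed: int = 0) -> pd.DataFrame:
    """Random patient-level train/test split (lesions inherit the label).

    The training set holds ``floor(train_fraction * n_patients)`` patients;
    no patient ever straddles the two splits.
    """
    patients = np.sort(table["patient_id"].unique())
    if len(patients) < 2:
        raise ValueError("patient-level split needs at least 2 patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients)
    n_train = int(np.floor(train_fraction * len(patients)))
    train_set = set(perm[:n_train])
    out = table.copy()
    out["split"] = np.where(out["patient_id"].isin(train_set), "train", "test")
    assert not (out.groupby("patient_id")["split"].nunique() > 1).any(), \
        "patient straddles the split"
    return out


# ---------------------------------------------------------- group comparisons

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(table: pd.DataFrame, metrics, group_col: str = "cspca",
                   categorical=()) -> pd.DataFrame:
    """Two-group comparison per metric with FDR across the metric family.

    Continuous metrics: two-sided Mann-Whitney U.  Metrics listed in
    ``categorical``: chi-square on the contingency table.  The BH
    adjustment spans exactly the metrics passed in one call (one
    comparison column = one FDR family).
    """
    groups = np.sort(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"{group_col} must have exactly 2 levels, got {groups}")
    g0 = table[table[group_col] == groups[0]]
    g1 = table[table[group_col] == groups[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("empty comparison group")
    rows = []
    for m in metrics:
        if m in categorical:
            ct = pd.crosstab(table[m], table[group_col])
            stat, p, _, expected = sps.chi2_contingency(ct)
            if (expected < 1).any():
                log.warning("chi-square for %s has expected counts < 1", m)
        else:
            if len(g0) < 3 or len(g1) < 3:
                raise ValueError("Mann-Whitney needs >= 3 per group")
            stat, p = sps.mannwhitneyu(g1[m], g0[m], alternative="two-sided")
        rows.append({"metric": m, "stat": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"])
    return out


def spearman_by_zone(table: pd.DataFrame, metrics, zone: str,
                     grade_col: str = "gg") -> pd.DataFrame:
    """Spearman rank correlation of each metric with grade group in a zone."""
    sub = table[table["zone"] == zone]
    if len(sub) < 5:
        raise ValueError(f"zone {zone!r} has fewer than 5 lesions")
    rows = []
    for m in metrics:
        if sub[m].nunique() < 2:
            rows.append({"metric": m, "rho": np.nan, "p": np.nan, "constant": True})
            continue
        rho, p = sps.spearmanr(sub[m], sub[grade_col])
        rows.append({"metric": m, "rho": float(rho), "p": float(p), "constant": False})
    out = pd.DataFrame(rows)
    ok = ~out["p"].isna()
    out["p_fdr"] = np.nan
    out.loc[ok, "p_fdr"] = bh_adjust(out.loc[ok, "p"])
    return out


# ------------------------------------------------- stability selection (LASSO)

@dataclass(frozen=True)
class StabilityResult:
    """Bootstrap-LASSO output: selection frequencies and the stable set."""

    frequencies: pd.Series        # metric -> selection frequency in [0, 1]
    stable: tuple                 # metrics with frequency > threshold
    threshold: float
    n_boot: int
    lambdas: tuple                # chosen penalty per bootstrap iteration
    n_redrawn: int                # degenerate (single-class) resamples redrawn


def _universal_penalty(y: np.ndarray, p: int) -> float:
    """Universal-threshold L1 penalty for standardized logistic designs.

    Under the global null the per-sample score of each standardized feature
    has sd ``sqrt(ybar*(1-ybar)/n)``; scaling by ``sqrt(2*log p)`` (the
    expected maximum of p standard normals) yields a penalty that excludes
    pure-noise features with high probability while admitting strong
    signals.  Returns the per-sample lambda.
    """
    n = len(y)
    ybar = y.mean()
    return float(np.sqrt(2.0 * np.log(p)) * np.sqrt(ybar * (1.0 - ybar) / n))


def _cv_penalty(X: np.ndarray, y: np.ndarray, rule: str, rng) -> float:
    """Per-sample lambda from 5-fold CV over a log-spaced path
    (rule = "cv_min": lowest mean CV deviance; "cv_1se": strongest penalty
    within one standard error of the minimum)."""
    c_grid = np.logspace(-2.5, 2.0, 31)
    cv = StratifiedKFold(n_splits=5, shuffle=True,
                         random_state=int(rng.integers(2**31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = LogisticRegressionCV(
            Cs=c_grid, cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", max_iter=200,
        ).fit(X, y)
    scores = model.scores_[list(model.scores_)[0]]
    mean = scores.mean(axis=0)
    best = int(np.argmax(mean))
    if rule == "cv_min":
        c_star = c_grid[best]
    else:
        se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
        c_star = c_grid[int(np.flatnonzero(mean >= mean[best] - se[best])[0])]
    return float(1.0 / (c_star * len(y)))


def bootstrap_lasso_select(table: pd.DataFrame, metrics, outcome: str = "cspca",
                           cluster: str = "patient_id", n_boot: int = 500,
                           freq_threshold: float = 0.5, seed: int = 0,
                           resample_unit: str = "patients",
                           lambda_rule: str = "universal") -> StabilityResult:
    """Stability selection: L1-penalised logistic regression on bootstrap
    resamples, keeping metrics selected in more than ``freq_threshold`` of
    iterations.

    Each resample draws patients (default; preserves lesion clustering) or
    lesions with replacement, z-scores the metrics within the resample,
    fits the L1 path at the chosen penalty and records the non-zero
    coefficients.  ``lambda_rule``:

    - "universal" (default): fixed per-resample universal-threshold
      penalty; calibrated to keep pure-noise features out with high
      probability (planted-signal frequency > 0.9, null frequency < 0.5).
    - "cv_min" / "cv_1se": penalty re-chosen per resample by 5-fold CV
      (lowest mean CV deviance, or the one-standard-error rule).  CV
      inside bootstrap resamples is optimistic — duplicated lesions leak
      across folds — so "cv_min" over-selects; it is kept as the literal
      textbook variant.

    Resamples containing a single outcome class are redrawn (and counted).
    """
    if resample_unit not in ("patients", "lesions"):
        raise ValueError("resample_unit must be 'patients' or 'lesions'")
    if lambda_rule not in ("universal", "cv_min", "cv_1se"):
        raise ValueError("lambda_rule must be 'universal', 'cv_min' or 'cv_1se'")
    metrics = list(metrics)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_boot)
    by_patient = {pid: grp for pid, grp in table.groupby(cluster)}
    patients = np.sort(table[cluster].unique())
    counts = np.zeros(len(metrics))
    lambdas = []
    n_redrawn = 0

    for stream in streams:
        rng = np.random.default_rng(stream)
        for _attempt in range(100):
            if resample_unit == "patients":
                chosen = rng.choice(patients, size=len(patients), replace=True)
                sub = pd.concat([by_patient[p] for p in chosen], ignore_index=True)
            else:
                idx = rng.integers(0, len(table), size=len(table))
                sub = table.iloc[idx].reset_index(drop=True)
            y = sub[outcome].to_numpy()
            if 0 < y.mean() < 1:
                break
            n_redrawn += 1
            log.info("degenerate bootstrap resample redrawn")
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")

        X = sub[metrics].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        if lambda_rule == "universal":
            lam = _universal_penalty(y, len(metrics))
        else:
            lam = _cv_penalty(X, y, lambda_rule, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = LogisticRegression(
                C=1.0 / (lam * len(y)), penalty="l1", solver="liblinear",
                max_iter=200,
            ).fit(X, y)
        counts += (np.abs(fitted.coef_[0]) > 1e-8)
        lambdas.append(lam)

    freq = pd.Series(counts / n_boot, index=metrics, name="frequency")
    stable = tuple(m for m in metrics if freq[m] > freq_threshold)
    return StabilityResult(frequencies=freq, stable=stable,
                           threshold=freq_threshold, n_boot=n_boot,
                           lambdas=tuple(lambdas), n_redrawn=n_redrawn)


# --------------------------------------------------------------------- GEE

def gee_fit(table: pd.DataFrame, covariates, outcome: str = "cspca",
            cluster: str = "patient_id") -> pd.DataFrame:
    """Binomial-logit GEE with exchangeable working correlation.

    Returns one row per covariate (plus intercept): coefficient, odds
    ratio, robust (sandwich) standard error and two-sided p-value.
    Equivalent to ordinary logistic regression when all clusters have
    size 1.
    """
    exog = sm.add_constant(table[list(covariates)].astype(float), has_constant="add")
    endog = table[outcome].astype(float)
    model = sm.GEE(endog, exog, groups=table[cluster],
                   family=sm.families.Binomial(),
                   cov_struct=sm.cov_struct.Exchangeable())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
    except Exception as exc:
        raise RuntimeError(
            f"GEE did not converge (covariates={list(covariates)}): {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise RuntimeError(
            "GEE produced non-finite estimates; separation suspected "
            f"(covariates={list(covariates)})")
    if np.any(np.abs(res.params.drop("const", errors="ignore")) > 15):
        log.warning("GEE coefficients are extreme; possible separation")
    out = pd.DataFrame({
        "coefficient": res.params,
        "or": np.exp(res.params),
        "std_error": res.bse,
        "p": res.pvalues,
    })
    return out


# ----------------------------------------------------------- logistic models

def prepare_design(table: pd.DataFrame) -> pd.DataFrame:
    """Add model-ready columns: TZ indicator and PI-RADS dummies with
    category 3 as the reference."""
    out = table.copy()
    out["zone_tz"] = (out["zone"] == "TZ").astype(float)
    out["pirads_4"] = (out["pirads"] == 4).astype(float)
    out["pirads_5"] = (out["pirads"] == 5).astype(float)
    return out


@dataclass(frozen=True)
class LogisticModel:
    """Frozen logistic risk model: coefficients plus the training scaler."""

    name: str
    covariates: tuple
    params: pd.Series                       # includes "const"
    scaler: dict = field(default_factory=dict)  # col -> (mean, sd)
    penalized: bool = False
    threshold: float | None = None          # operating point (training Youden)

    def design(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.covariates if c not in table.columns]
        if missing:
            raise KeyError(f"missing covariate columns: {missing}")
        X = table[list(self.covariates)].astype(float).copy()
        for col, (mu, sd) in self.scaler.items():
            X[col] = (X[col] - mu) / sd
        return sm.add_constant(X, has_constant="add")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = self.design(table)
        eta = X.to_numpy() @ self.params.reindex(X.columns).to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_logistic(name: str, table: pd.DataFrame, covariates, outcome: str,
                  scale_cols=()) -> LogisticModel:
    scaler = {}
    work = table.copy()
    for col in scale_cols:
        mu = float(work[col].mean())
        sd = float(work[col].std(ddof=0)) or 1.0
        scaler[col] = (mu, sd)
        work[col] = (work[col] - mu) / sd
    X = sm.add_constant(work[list(covariates)].astype(float), has_constant="add")
    y = work[outcome].astype(float)
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = res.params
        if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 30):
            raise RuntimeError("separation suspected")
    except Exception:
        # ridge fallback keeps the model usable under (quasi-)separation
        log.warning("logistic model %r: separation detected, using L2 fallback", name)
        from sklearn.linear_model import LogisticRegression
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ridge = LogisticRegression(C=1.0, max_iter=2000).fit(
                X.drop(columns="const").to_numpy(), y.to_numpy())
        params = pd.Series(
            np.concatenate([[ridge.intercept_[0]], ridge.coef_[0]]),
            index=["const"] + [c for c in X.columns if c != "const"])
        penalized = True
    return LogisticModel(name=name, covariates=tuple(covariates),
                         params=params, scaler=scaler, penalized=penalized)


def fit_risk_models(train: pd.DataFrame, stable_metrics,
                    outcome: str = "cspca") -> dict:
    """The three nested logistic models on the training lesions.

    Clinical: age, PSAD, DRE, zone, lesion volume, PI-RADS dummies.
    Clinical+ADC: clinical covariates plus the mono-exponential ADC.
    Clinical+Multib_DWI: clinical covariates plus the stable diffusion
    predictors from stability selection (z-scored with training moments).
    An empty stable set degrades the third model to the Clinical one.
    """
    train = prepare_design(train)
    stable = [m for m in stable_metrics]
    models = {}
    models["clinical"] = _fit_logistic(
        "clinical", train, CLINICAL_COVARIATES, outcome)
    models["clinical_adc"] = _fit_logistic(
        "clinical_adc", train, CLINICAL_COVARIATES + ["MEM_ADC"], outcome,
        scale_cols=["MEM_ADC"])
    models["clinical_multib"] = _fit_logistic(
        "clinical_multib", train, CLINICAL_COVARIATES + stable, outcome,
        scale_cols=stable)
    # freeze the training operating point (Youden) on each model
    y = train[outcome].to_numpy()
    frozen = {}
    for key, model in models.items():
        thr = youden_threshold(model.predict(train), y)
        frozen[key] = LogisticModel(
            name=model.name, covariates=model.covariates, params=model.params,
            scaler=model.scaler, penalized=model.penalized, threshold=thr)
    return frozen


# ----------------------------------------------------------------- ROC / AUC

def auc_mannwhitney(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (midranks for ties)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_threshold(scores, labels) -> float:
    """Operating threshold maximising Youden's J = sens + spec - 1.

    Evaluated at every observed score; the lowest score achieving the
    maximal J is returned (deterministic tie-break).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    n1 = y.sum()
    n0 = len(y) - n1
    best_j, best_t = -np.inf, s_sorted[0]
    # candidate thresholds: each unique score (predict positive when >= t)
    uniq = np.unique(s_sorted)
    for t in uniq:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        j = tp / n1 - fp / n0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


@dataclass(frozen=True)
class ModelEval:
    """ROC-derived performance at a frozen operating threshold."""

    auc: float
    auc_ci: tuple
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n: int
    prevalence: float

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("auc", "threshold", "accuracy", "sensitivity", "specificity",
              "ppv", "npv", "n", "prevalence")}
        d["auc_ci_low"], d["auc_ci_high"] = self.auc_ci
        return d


def roc_metrics(scores, labels, threshold: float | None = None,
                n_boot: int = 2000, seed: int = 0) -> ModelEval:
    """AUC with stratified-bootstrap CI plus confusion metrics at a threshold.

    When ``threshold`` is None it is chosen by Youden's J on these scores
    (training usage); otherwise the given (frozen) threshold is applied
    (test / external usage).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc = auc_mannwhitney(s, y)
    if threshold is None:
        threshold = youden_threshold(s, y)

    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([bp, bn])
        boots[i] = auc_mannwhitney(s[idx], y[idx])
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))

    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    n = len(y)
    return ModelEval(
        auc=float(auc), auc_ci=ci, threshold=float(threshold),
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        npv=tn / (tn + fn) if tn + fn else np.nan,
        n=n, prevalence=float(y.mean()),
    )


# -------------------------------------------------------------- DeLong test

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_test(scores_a, scores_b, labels) -> dict:
    """DeLong comparison of two paired AUCs (structural components).

    Returns the AUC difference (A - B), its standard error, the two-sided
    z-test p-value, and both AUCs.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores must be paired on identical lesions")
    pos, neg = sa[y == 1], sa[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((sa, sb)):
        p, q = s[y == 1], s[y == 0]
        all_r = _midrank(np.concatenate([p, q]))
        rp, rq = _midrank(p), _midrank(q)
        auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[k] = auc
        v10[k] = (all_r[:m] - rp) / n
        v01[k] = 1.0 - (all_r[m:] - rq) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        p_value = 1.0 if abs(diff) < 1e-12 else 0.0
        se = 0.0
    else:
        se = float(np.sqrt(var))
        z = diff / se
        p_value = float(2 * sps.norm.sf(abs(z)))
    return {"auc_a": float(aucs[0]), "auc_b": float(aucs[1]),
            "diff": float(diff), "se": se, "p": p_value}


# --------------------------------------------------------------- decision curve

def decision_curve(scores_by_model: dict, labels,
                   thresholds=None) -> pd.DataFrame:
    """Net benefit NB(t) = TP/n - (FP/n) * t/(1-t) over a threshold grid.

    Includes treat-all and treat-none reference policies.  ``t = 1`` is
    excluded (the weight diverges).
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    prev = y.mean()
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.96, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    rows = {"threshold": thresholds, "treat_none": np.zeros_like(thresholds),
            "treat_all": prev - (1 - prev) * thresholds / (1 - thresholds)}
    for name, scores in scores_by_model.items():
        s = np.asarray(scores, dtype=float)
        nb = np.empty_like(thresholds)
        for i, t in enumerate(thresholds):
            pred = s >= t
            tp = (pred & (y == 1)).sum() / n
            fp = (pred & (y == 0)).sum() / n
            nb[i] = tp - fp * t / (1 - t)
        rows[name] = nb
    return pd.DataFrame(rows)


# ------------------------------------------------------------- subgroups

def subgroup_analysis(table: pd.DataFrame, metrics, min_n: int = 15,
                      seed: int = 0) -> dict:
    """Per-stratum metric comparisons and single-metric discrimination.

    Strata: PZ, TZ, PI-RADS 3, PI-RADS 4-5, and TZ PI-RADS 3 (the latter
    with both PCa-vs-benign and csPCa-vs-non outcomes).  Single-metric AUC
    is reported direction-free (max(AUC, 1-AUC)).  Strata with one outcome
    class are skipped with a log entry; small strata are flagged.
    """
    strata = {
        "PZ": table["zone"] == "PZ",
        "TZ": table["zone"] == "TZ",
        "PIRADS3": table["pirads"] == 3,
        "PIRADS45": table["pirads"] >= 4,
        "TZ_PIRADS3": (table["zone"] == "TZ") & (table["pirads"] == 3),
    }
    out = {}
    for name, mask in strata.items():
        sub = table[mask]
        outcomes = {"cspca": sub.get("cspca")}
        if name == "TZ_PIRADS3":
            outcomes["pca"] = (sub["gg"] >= 1).astype(int)
        for oc_name, oc in outcomes.items():
            key = f"{name}:{oc_name}"
            if sub.empty or oc is None or oc.nunique() < 2:
                log.warning("subgroup %s skipped (empty or single-class)", key)
                out[key] = None
                continue
            work = sub.assign(_outcome=np.asarray(oc))
            comp = compare_groups(work, metrics, group_col="_outcome")
            aucs = []
            for m in metrics:
                a = auc_mannwhitney(work[m], work["_outcome"])
                aucs.append(max(a, 1.0 - a))
            comp["auc"] = aucs
            out[key] = {
                "n": int(len(work)),
                "n_positive": int(work["_outcome"].sum()),
                "small_stratum": bool(len(work) < min_n
                                      or work["_outcome"].sum() < 10),
                "table": comp,
            }
    return out


def zone_aware_predict(table: pd.DataFrame, pz_model: LogisticModel,
                       tz_model: LogisticModel) -> np.ndarray:
    """Route each lesion to its zone's model (exploratory split model)."""
    zones = set(table["zone"].unique())
    unknown = zones - {"PZ", "TZ"}
    if unknown:
        raise ValueError(f"unseen zone labels: {sorted(unknown)}")
    table = prepare_design(table)
    scores = np.empty(len(table))
    pz_mask = (table["zone"] == "PZ").to_numpy()
    if pz_mask.any():
        scores[pz_mask] = pz_model.predict(table[pz_mask])
    if (~pz_mask).any():
        scores[~pz_mask] = tz_model.predict(table[~pz_mask])
    return scores
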