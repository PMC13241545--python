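"""Statistical chain: exact small-sample oracles, null calibration, and
planted-signal recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mbdwi import stats as S
from mbdwi.models import METRICS


# ------------------------------------------------------------------- split

def test_split_published_counts(calibrated_cohort):
    les = S.split_cohort(calibrated_cohort.lesions, 0.7, seed=0)
    train_p = les.loc[les.split == "train", "patient_id"].nunique()
    test_p = les.loc[les.split == "test", "patient_id"].nunique()
    assert (train_p, test_p) == (113, 49)


def test_split_floor_rule_and_clustering():
    table = pd.DataFrame({
        "patient_id": np.repeat(np.arange(10), 3),
        "cspca": np.tile([0, 1, 0], 10),
    })
    out = S.split_cohort(table, 0.7, seed=1)
    assert out.loc[out.split == "train", "patient_id"].nunique() == 7
    assert out.loc[out.split == "test", "patient_id"].nunique() == 3
    assert (out.groupby("patient_id")["split"].nunique() == 1).all()
    with pytest.raises(ValueError):
        S.split_cohort(table[table.patient_id == 0], 0.7, seed=1)


# ------------------------------------------------------- comparisons / FDR

def test_bh_fixture_hand_applied():
    # step-up: 0.04*4/4=0.04; 0.03*4/3=0.04; 0.02*4/2=0.04; 0.01*4/1=0.04
    adj = S.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_monotone_and_never_below_raw():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=40)
    adj = S.bh_adjust(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_compare_groups_identical_and_separated():
    rng = np.random.default_rng(1)
    x = rng.normal(size=40)
    same = pd.DataFrame({"g": [0] * 20 + [1] * 20, "m": np.concatenate([x[:20], x[:20]])})
    res = S.compare_groups(same, ["m"], group_col="g")
    assert res["p"].iloc[0] > 0.9

    apart = pd.DataFrame({"g": [0] * 20 + [1] * 20,
                          "m": np.concatenate([x[:20], x[:20] + 50])})
    res2 = S.compare_groups(apart, ["m"], group_col="g")
    assert res2["p"].iloc[0] < 0.001

    with pytest.raises(ValueError):
        S.compare_groups(same.assign(g=0), ["m"], group_col="g")


def test_spearman_exact_and_brute_force():
    table = pd.DataFrame({
        "zone": ["PZ"] * 8,
        "gg": [0, 1, 2, 3, 4, 5, 2, 1],
        "up": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 2.0, 1.0],
        "down": [0.0, -1.0, -2.0, -3.0, -4.0, -5.0, -2.0, -1.0],
        "hand": [1.3, 0.9, 1.8, 0.4, 2.2, 0.1, 1.1, 2.0],
    })
    res = S.spearman_by_zone(table, ["up", "down", "hand"], "PZ").set_index("metric")
    assert res.loc["up", "rho"] == pytest.approx(1.0)
    assert res.loc["down", "rho"] == pytest.approx(-1.0)
    # brute-force rank formula (Pearson correlation of midranks)
    from scipy.stats import rankdata
    r1, r2 = rankdata(table["hand"]), rankdata(table["gg"])
    rho = np.corrcoef(r1, r2)[0, 1]
    assert res.loc["hand", "rho"] == pytest.approx(rho, rel=1e-12)


# ----------------------------------------------------------------- AUC / ROC

def _auc_pairs(scores, labels):
    """Exhaustive concordant-pair counting with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_equals_exhaustive_pair_count():
    rng = np.random.default_rng(2)
    for trial in range(5):
        n = int(rng.integers(10, 50))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.normal(size=n), 1)         # coarse grid forces ties
        assert S.auc_mannwhitney(s, y) == pytest.approx(_auc_pairs(s, y), abs=1e-12)


def test_roc_perfect_and_null():
    y = np.array([0] * 50 + [1] * 50)
    s = y.astype(float)
    ev = S.roc_metrics(s, y, n_boot=50)
    assert ev.auc == 1.0 and ev.sensitivity == 1.0 and ev.specificity == 1.0
    rng = np.random.default_rng(3)
    y2 = rng.integers(0, 2, 2000)
    s2 = rng.normal(size=2000)
    assert 0.45 < S.auc_mannwhitney(s2, y2) < 0.55
    with pytest.raises(ValueError):
        S.auc_mannwhitney(s2, np.zeros(2000))


def test_confusion_identities_at_threshold():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 300)
    s = y + rng.normal(0, 0.8, 300)
    ev = S.roc_metrics(s, y, threshold=0.5, n_boot=50)
    pred = s >= 0.5
    tp = int((pred & (y == 1)).sum()); tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum()); fn = int((~pred & (y == 1)).sum())
    assert ev.accuracy == pytest.approx((tp + tn) / 300)
    assert ev.sensitivity == pytest.approx(tp / (tp + fn))
    assert ev.specificity == pytest.approx(tn / (tn + fp))
    assert ev.ppv == pytest.approx(tp / (tp + fp))
    assert ev.npv == pytest.approx(tn / (tn + fn))
    assert ev.auc_ci[0] <= ev.auc <= ev.auc_ci[1]


def test_youden_threshold_maximises_j():
    y = np.array([0, 0, 0, 1, 1, 1, 0, 1])
    s = np.array([0.1, 0.2, 0.6, 0.5, 0.7, 0.9, 0.3, 0.4])
    t = S.youden_threshold(s, y)
    def j_at(th):
        pred = s >= th
        return (pred & (y == 1)).sum() / 4 - (pred & (y == 0)).sum() / 4
    assert all(j_at(t) >= j_at(v) - 1e-12 for v in np.unique(s))


# -------------------------------------------------------------------- DeLong

def test_delong_self_comparison():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 200)
    s = y + rng.normal(0, 1, 200)
    res = S.delong_test(s, s, y)
    assert res["diff"] == 0.0 and res["p"] == 1.0


def test_delong_perfect_vs_random():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 500)
    perfect = y.astype(float)
    random = rng.normal(size=500)
    res = S.delong_test(perfect, random, y)
    assert res["p"] < 0.001 and res["diff"] > 0.3


def test_delong_variance_against_bootstrap():
    """DeLong SE of the AUC difference agrees with a bootstrap estimate."""
    rng = np.random.default_rng(7)
    n = 150
    y = rng.integers(0, 2, n)
    a = y + rng.normal(0, 1.2, n)
    b = y + rng.normal(0, 1.8, n)
    res = S.delong_test(a, b, y)
    boots = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        if y[idx].min() == y[idx].max():
            continue
        boots.append(S.auc_mannwhitney(a[idx], y[idx])
                     - S.auc_mannwhitney(b[idx], y[idx]))
    assert res["se"] == pytest.approx(np.std(boots, ddof=1), rel=0.2)
    with pytest.raises(ValueError):
        S.delong_test(a[:-1], b, y)


# ------------------------------------------------------------ decision curve

def test_net_benefit_closed_forms():
    y = np.array([1] * 30 + [0] * 70)
    prev = 0.3
    grid = np.arange(0.05, 0.95, 0.05)
    dca = S.decision_curve({"perfect": y.astype(float)}, y, thresholds=grid)
    assert np.allclose(dca["treat_none"], 0.0)
    assert np.allclose(dca["treat_all"], prev - (1 - prev) * grid / (1 - grid))
    assert np.allclose(dca["perfect"], prev)
    assert (dca["perfect"] <= prev + 1e-12).all()
    with pytest.raises(ValueError):
        S.decision_curve({"m": y.astype(float)}, y, thresholds=[0.5, 1.0])


# ----------------------------------------------------------------------- GEE

def test_gee_singleton_clusters_equal_logistic():
    rng = np.random.default_rng(8)
    n = 400
    x = rng.normal(size=n)
    y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 + 0.8 * x))))
    table = pd.DataFrame({"patient_id": np.arange(n), "x": x, "cspca": y})
    gee = S.gee_fit(table, ["x"])
    logit = sm.Logit(y.astype(float), sm.add_constant(pd.DataFrame({"x": x}))).fit(disp=0)
    assert gee.loc["x", "coefficient"] == pytest.approx(logit.params["x"], abs=1e-6)
    assert gee.loc["const", "coefficient"] == pytest.approx(logit.params["const"], abs=1e-6)
    assert gee.loc["x", "or"] == pytest.approx(np.exp(gee.loc["x", "coefficient"]))


def test_gee_recovers_planted_coefficient():
    """Clustered cohort with known marginal-scale structure: the estimate of
    a planted coefficient of -1.0 lands within +-0.15."""
    rng = np.random.default_rng(9)
    n_pat = 1000
    rows = []
    for pid in range(n_pat):
        u = rng.normal(0, 0.5)
        for _ in range(rng.integers(1, 4)):
            x = rng.normal()
            eta = 0.2 - 1.0 * x + u
            rows.append({"patient_id": pid, "x": x,
                         "cspca": rng.binomial(1, 1 / (1 + np.exp(-eta)))})
    table = pd.DataFrame(rows)
    gee = S.gee_fit(table, ["x"])
    # marginal (population-averaged) slope is mildly attenuated vs -1.0
    assert gee.loc["x", "coefficient"] == pytest.approx(-1.0, abs=0.15)
    assert gee.loc["x", "p"] < 1e-6


def test_gee_null_covariate_is_calibrated():
    rng = np.random.default_rng(10)
    pvals = []
    for rep in range(20):
        n = 300
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-0.5 * x)))
        table = pd.DataFrame({"patient_id": np.arange(n), "x": x, "z": z, "cspca": y})
        pvals.append(S.gee_fit(table, ["x", "z"]).loc["z", "p"])
    assert min(pvals) > 1e-4          # no spurious ultra-significance
    assert 0.2 < np.mean(np.array(pvals) < 0.5) < 0.8


# ---------------------------------------------------- stability selection

def test_stability_selection_planted_recovery(planted_cohort):
    les = S.split_cohort(planted_cohort.lesions, seed=5)
    train = les[les.split == "train"]
    res = S.bootstrap_lasso_select(train, list(METRICS), n_boot=60, seed=0)
    assert res.frequencies["MEM_ADC"] > 0.9
    assert res.frequencies["CTRW_alpha"] > 0.9
    nulls = res.frequencies.drop(["MEM_ADC", "CTRW_alpha"])
    assert (nulls < 0.5).all()
    assert set(res.stable) == {"MEM_ADC", "CTRW_alpha"}


def test_stability_selection_null_design():
    rng = np.random.default_rng(12)
    n = 200
    table = pd.DataFrame(rng.normal(size=(n, 18)), columns=list(METRICS))
    table["patient_id"] = np.arange(n)
    table["cspca"] = rng.integers(0, 2, n)
    res = S.bootstrap_lasso_select(table, list(METRICS), n_boot=40, seed=1)
    assert len(res.stable) == 0


def test_stability_selection_deterministic(planted_cohort):
    les = S.split_cohort(planted_cohort.lesions, seed=5)
    train = les[les.split == "train"]
    a = S.bootstrap_lasso_select(train, list(METRICS), n_boot=15, seed=3)
    b = S.bootstrap_lasso_select(train, list(METRICS), n_boot=15, seed=3)
    pd.testing.assert_series_equal(a.frequencies, b.frequencies)
    assert a.stable == b.stable and a.lambdas == b.lambdas


# ------------------------------------------------------------- risk models

def test_risk_models_nesting_and_fallbacks(planted_cohort):
    les = S.split_cohort(planted_cohort.lesions, seed=5)
    train = les[les.split == "train"]
    models = S.fit_risk_models(train, ["MEM_ADC", "CTRW_alpha"])
    design = S.prepare_design(train)
    y = design["cspca"].to_numpy()

    def deviance(model):
        p = np.clip(model.predict(design), 1e-12, 1 - 1e-12)
        return -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    d1 = deviance(models["clinical"])
    d2 = deviance(models["clinical_adc"])
    d3 = deviance(models["clinical_multib"])
    assert d2 <= d1 + 1e-6
    assert d3 <= d2 + 1e-6

    # empty stable set: the multi-b model degrades to the clinical covariates
    empty = S.fit_risk_models(train, [])
    assert empty["clinical_multib"].covariates == empty["clinical"].covariates


def test_zone_aware_identity_and_routing(planted_cohort):
    les = S.prepare_design(S.split_cohort(planted_cohort.lesions, seed=5))
    train = les[les.split == "train"]
    models = S.fit_risk_models(train, ["MEM_ADC"])
    pooled = models["clinical_adc"]
    same = S.zone_aware_predict(train, pooled, pooled)
    assert np.allclose(same, pooled.predict(train))
    # single-zone table reduces to that zone's model
    pz_only = train[train.zone == "PZ"]
    assert np.allclose(S.zone_aware_predict(pz_only, pooled, pooled),
                       pooled.predict(pz_only))
    with pytest.raises(ValueError):
        S.zone_aware_predict(train.assign(zone="apex"), pooled, pooled)


def test_subgroup_full_table_matches_global(planted_cohort):
    les = planted_cohort.lesions
    sub = S.subgroup_analysis(les, ["MEM_ADC", "CTRW_alpha"], min_n=5)
    # the PZ and TZ strata partition the cohort
    assert sub["PZ:cspca"]["n"] + sub["TZ:cspca"]["n"] == len(les)
    global_comp = S.compare_groups(les, ["MEM_ADC"]).set_index("metric")
    # re-running the same machinery on the full table gives the global result
    full = S.subgroup_analysis(les.assign(pirads=3), ["MEM_ADC"], min_n=5)
    t = full["PIRADS3:cspca"]["table"].set_index("metric")
    assert t.loc["MEM_ADC", "p"] == pytest.approx(global_comp.loc["MEM_ADC", "p"])


def test_subgroup_planted_zone_effect():
    """A TZ-only planted effect yields higher TZ than PZ discrimination."""
    rng = np.random.default_rng(13)
    n = 1000
    zone = np.where(rng.random(n) < 0.5, "PZ", "TZ")
    y = rng.integers(0, 2, n)
    metric = rng.normal(size=n)
    tz = zone == "TZ"
    metric[tz] -= 1.2 * y[tz]          # effect only in TZ
    table = pd.DataFrame({
        "patient_id": np.arange(n), "zone": zone, "cspca": y,
        "pirads": 4, "gg": y * 2, "CTRW_alpha": metric,
    })
    sub = S.subgroup_analysis(table, ["CTRW_alpha"], min_n=5)
    auc_tz = sub["TZ:cspca"]["table"]["auc"].iloc[0]
    auc_pz = sub["PZ:cspca"]["table"]["auc"].iloc[0]
    assert auc_tz > auc_pz + 0.15
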