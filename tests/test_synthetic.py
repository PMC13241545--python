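"""Generator calibration, noise models, reader/vendor layers, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from mbdwi import models as M
from mbdwi.stats import auc_mannwhitney
from mbdwi.synthetic import (
    CohortConfig, ReaderEffect, VendorEffect, apply_vendor_effect,
    draw_lesion_params, generate_cohort, generate_decay, generate_study,
    reader_effect_for_icc, simulate_two_readers,
)
from mbdwi.tables import METRIC_SUMMARIES, apply_exclusions


def test_exclusion_arithmetic():
    flow = apply_exclusions()
    assert flow["screened"] == 245
    assert flow["enrolled"] == 162
    # running totals after each exclusion reason
    assert flow["after_prior_intervention"] == 220
    assert flow["after_acute_prostatitis"] == 205
    assert flow["after_incomplete_imaging"] == 172
    assert flow["after_severe_artifacts"] == 162


@pytest.mark.parametrize("metric, group, zone", [
    ("MEM_ADC", "cspca", "overall"),
    ("CTRW_alpha", "non", "overall"),
    ("IVIM_f", "cspca", "PZ"),
    ("DKI_K", "non", "TZ"),
])
def test_marginal_calibration(metric, group, zone):
    """10,000 draws reproduce the published median and quartiles."""
    rng = np.random.default_rng(123)
    draws = draw_lesion_params(group, zone, rng, n=10_000)
    vals = np.array([d.metrics[metric] for d in draws])
    med, q1, q3 = METRIC_SUMMARIES[metric][zone][group]
    assert np.median(vals) == pytest.approx(med, rel=0.02)
    assert np.quantile(vals, 0.25) == pytest.approx(q1, rel=0.04)
    assert np.quantile(vals, 0.75) == pytest.approx(q3, rel=0.04)


def test_degenerate_spread_returns_median(monkeypatch):
    import mbdwi.synthetic as syn
    frozen = {m: {z: {g: (v[0], v[0], v[0]) for g, v in zz.items()}
                  for z, zz in mm.items()}
              for m, mm in METRIC_SUMMARIES.items()}
    monkeypatch.setattr(syn.T, "METRIC_SUMMARIES", frozen)
    rng = np.random.default_rng(0)
    draws = draw_lesion_params("cspca", "PZ", rng, n=50)
    vals = [d.metrics["MEM_ADC"] for d in draws]
    assert np.ptp(vals) < 1e-12
    assert vals[0] == pytest.approx(METRIC_SUMMARIES["MEM_ADC"]["PZ"]["cspca"][0])


def test_direction_fidelity(calibrated_cohort):
    """csPCa lesions run lower on ADC and CTRW alpha (published ordering)."""
    les = calibrated_cohort.lesions
    assert len(les) >= 200
    for metric in ("MEM_ADC", "CTRW_alpha", "SEM_DDC", "IVIM_D"):
        auc = auc_mannwhitney(les[metric], les["cspca"])
        assert auc < 0.5, metric       # lower values in csPCa
    assert auc_mannwhitney(les["DKI_K"], les["cspca"]) > 0.5   # K runs higher


def test_label_consistency(calibrated_cohort):
    les = calibrated_cohort.lesions
    assert ((les["gg"] >= 2) == (les["cspca"] == 1)).all()


def test_all_cspca_config_forces_gg():
    cfg = CohortConfig(n_patients=30, cspca_prevalence={"PZ": 1.0, "TZ": 1.0},
                       psad_log_or=0.0, patient_intercept_sd=0.0, seed=2)
    cohort = generate_cohort(cfg)
    assert (cohort.lesions["gg"] >= 2).all()
    assert (cohort.lesions["cspca"] == 1).all()


def test_cohort_counts_and_expectation():
    cohort = generate_cohort(CohortConfig(seed=0))
    assert cohort.lesions["patient_id"].nunique() == 162
    # lesion count ~224 in expectation over seeds
    counts = [len(generate_cohort(CohortConfig(seed=s)).lesions) for s in range(8)]
    assert 210 < np.mean(counts) < 238


def test_same_seed_identical_tables():
    a = generate_cohort(CohortConfig(seed=9))
    b = generate_cohort(CohortConfig(seed=9))
    pd.testing.assert_frame_equal(a.lesions, b.lesions)
    pd.testing.assert_frame_equal(a.reader_pairs, b.reader_pairs)


def test_clustering_shares_patient_covariates(calibrated_cohort):
    les = calibrated_cohort.lesions
    multi = les.groupby("patient_id").filter(lambda g: len(g) > 1)
    assert len(multi) > 0
    for col in ("age", "psa", "psad", "dre"):
        assert (multi.groupby("patient_id")[col].nunique() == 1).all()


def test_patient_intercept_induces_risk_correlation():
    """With a strong patient intercept, lesions of the same patient agree on
    csPCa more often than lesions of different patients."""
    cfg = CohortConfig(n_patients=400, patient_intercept_sd=2.0, psad_log_or=0.0,
                       lesions_per_patient={2: 1.0}, seed=21)
    les = generate_cohort(cfg).lesions
    wide = les.groupby("patient_id")["cspca"].apply(list)
    same = np.mean([a == b for a, b in wide])
    prev = les["cspca"].mean()
    expected_independent = prev ** 2 + (1 - prev) ** 2
    assert same > expected_independent + 0.05


def test_rician_decay_properties():
    params = M.MEMParams(1.0, 1.0)
    # infinite SNR returns the exact forward signal
    exact = generate_decay(params, M.DEFAULT_SCHEME, np.inf)
    assert np.allclose(exact, M.mem_signal(params, M.DEFAULT_SCHEME.array))
    # fixed seed reproducibility
    a = generate_decay(params, M.DEFAULT_SCHEME, 50.0, rng=7)
    b = generate_decay(params, M.DEFAULT_SCHEME, 50.0, rng=7)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        generate_decay(params, M.DEFAULT_SCHEME, 0.0)


def test_rician_mean_bias_closed_form():
    """At b=0 the Rician mean is ~ S0*(1 + 1/(2*snr²)) for large SNR."""
    params = M.MEMParams(1.0, 1.0)
    rng = np.random.default_rng(4)
    snr = 5.0        # strong noise so the bias is resolvable
    vals = np.array([generate_decay(params, M.DEFAULT_SCHEME, snr, rng)[0]
                     for _ in range(20_000)])
    expected = 1.0 + 0.5 / snr ** 2
    assert vals.mean() == pytest.approx(expected, rel=0.005)


def test_vendor_effect_identities():
    df = pd.DataFrame({
        "vendor": ["A"] * 50 + ["B"] * 50,
        "MEM_ADC": np.concatenate([np.random.default_rng(0).normal(1.0, 0.1, 50)] * 2),
    })
    ident = apply_vendor_effect(df, VendorEffect(batch="B"))
    pd.testing.assert_frame_equal(ident, df)

    shifted = apply_vendor_effect(df, VendorEffect(batch="B", shift={"MEM_ADC": 0.1}))
    delta = shifted.loc[df.vendor == "B", "MEM_ADC"].mean() - \
        df.loc[df.vendor == "B", "MEM_ADC"].mean()
    assert delta == pytest.approx(0.1, abs=1e-12)
    assert (shifted.loc[df.vendor == "A", "MEM_ADC"]
            == df.loc[df.vendor == "A", "MEM_ADC"]).all()

    scaled = apply_vendor_effect(df, VendorEffect(batch="B", scale={"MEM_ADC": 1.2}))
    v0 = df.loc[df.vendor == "B", "MEM_ADC"].var()
    v1 = scaled.loc[df.vendor == "B", "MEM_ADC"].var()
    assert v1 / v0 == pytest.approx(1.44, rel=1e-10)

    with pytest.raises(KeyError):
        apply_vendor_effect(df, VendorEffect(batch="B", shift={"nope": 1.0}))


def test_two_reader_simulation(calibrated_cohort):
    truth = calibrated_cohort.truth
    # zero jitter: both readers identical
    pairs = simulate_two_readers(truth, ReaderEffect(), rng=0)
    assert np.array_equal(pairs["reader1"], pairs["reader2"])
    assert np.array_equal(pairs["reader1"],
                          pairs.merge(truth.melt("lesion_id", var_name="metric"),
                                      on=["lesion_id", "metric"])["value"])
    # seeded reproducibility
    effect = reader_effect_for_icc(truth[list(M.METRICS)], 0.85)
    p1 = simulate_two_readers(truth, effect, rng=3)
    p2 = simulate_two_readers(truth, effect, rng=3)
    pd.testing.assert_frame_equal(p1, p2)


def test_reader_jitter_hits_target_icc():
    """Jitter derived from the variance-components identity lands near the
    target ICC on a large cohort."""
    from mbdwi.reliability import icc_two_way
    cfg = CohortConfig(n_patients=800, seed=31)
    truth = generate_cohort(cfg).truth
    effect = reader_effect_for_icc(truth[list(M.METRICS)], 0.80)
    pairs = simulate_two_readers(truth, effect, rng=11)
    grp = pairs[pairs["metric"] == "MEM_ADC"]
    icc = icc_two_way(grp[["reader1", "reader2"]].to_numpy())
    assert icc == pytest.approx(0.80, abs=0.03)


def test_generate_study_structure():
    study = generate_study(seed=2)
    assert study["primary"].lesions["patient_id"].nunique() == 162
    assert study["external"].lesions["patient_id"].nunique() == 76
    assert set(study["external"].lesions["vendor"]) == {"GE"}
    # vendor effect applied: external measured metrics shifted vs truth
    ext = study["external"]
    merged = ext.lesions.merge(ext.truth, on="lesion_id", suffixes=("_m", "_t"))
    assert merged["MEM_ADC_m"].mean() > merged["MEM_ADC_t"].mean() * 1.05


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_patients=0)
    with pytest.raises(ValueError):
        CohortConfig(lesions_per_patient={1: 0.6, 2: 0.2})       # not summing to 1
    with pytest.raises(ValueError):
        CohortConfig(cspca_prevalence={"PZ": 1.4, "TZ": 0.3})
    with pytest.raises(ValueError):
        CohortConfig(snr=-5)
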