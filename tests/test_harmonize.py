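"""ComBat behaviour: exact location removal, idempotence, effect
preservation, an independent R (sva) oracle, and the cross-vendor chain."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from mbdwi.harmonize import (
    HarmonizationSpec, combat_harmonize, cross_vendor_consistency_check,
    external_validate,
)
from mbdwi.models import METRICS
from mbdwi.stats import fit_risk_models, prepare_design, roc_metrics, split_cohort
from mbdwi.synthetic import (
    CohortConfig, VendorEffect, apply_vendor_effect, generate_cohort,
)


def _toy_table(n_per_batch=100, n_metrics=4, shift=0.0, scale=1.0,
               effect=0.3, seed=0):
    """Location/scale batch effect conforming to the ComBat model: the scale
    acts on the noise term, the shift on the batch mean; the biological
    (csPCa) effect is common to both batches."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_batch
    batch = np.array(["A"] * n_per_batch + ["B"] * n_per_batch)
    csp = rng.integers(0, 2, n)
    cols = {}
    for g in range(n_metrics):
        noise = rng.normal(0.0, 0.2, n)
        noise[batch == "B"] *= scale
        x = 1.0 + effect * csp + noise
        x[batch == "B"] += shift
        cols[f"m{g}"] = x
    table = pd.DataFrame(cols)
    table["vendor"] = batch
    table["cspca"] = csp
    return table


def _spec(n_metrics=4, eb=True, covariates=("cspca",), sigma_df="pooled"):
    return HarmonizationSpec(batch_col="vendor", covariates=covariates,
                             metrics=tuple(f"m{g}" for g in range(n_metrics)),
                             eb=eb, sigma_df=sigma_df)


def test_single_batch_is_identity():
    table = _toy_table().assign(vendor="A")
    out = combat_harmonize(table, _spec())
    pd.testing.assert_frame_equal(out, table)


def test_additive_shift_removed_exactly_without_eb():
    # no biological covariates in play: batch means must align exactly
    table = _toy_table(shift=0.25, effect=0.0)
    out = combat_harmonize(table, _spec(eb=False, covariates=()))
    for g in range(4):
        means = out.groupby("vendor")[f"m{g}"].mean()
        assert abs(means["A"] - means["B"]) < 1e-6


def test_idempotence():
    """With the unbiased variance divisor the (no-EB, no-covariate) pass is
    exactly idempotent; the reference pooled divisor repeats to O(1/N)."""
    table = _toy_table(shift=0.2, scale=1.3)
    m = [f"m{g}" for g in range(4)]

    exact = _spec(eb=False, covariates=(), sigma_df="unbiased")
    once = combat_harmonize(table, exact)
    twice = combat_harmonize(once, exact)
    assert np.max(np.abs(once[m].to_numpy() - twice[m].to_numpy())) < 1e-8

    default = _spec()
    o1 = combat_harmonize(table, default)
    o2 = combat_harmonize(o1, default)
    per_pass = np.max(np.abs(o1[m].to_numpy() - o2[m].to_numpy()))
    assert per_pass < 5.0 / len(table)       # O(1/N) repeat drift


def test_scale_effect_recovered():
    # pure scale effect (no biological signal); enough features for the
    # inverse-gamma prior to be estimable
    table = _toy_table(n_per_batch=200, n_metrics=12, scale=1.5, effect=0.0, seed=3)
    out = combat_harmonize(table, _spec(n_metrics=12, eb=False))
    ratios = np.array([
        out.groupby("vendor")[f"m{g}"].var().pipe(lambda v: v["B"] / v["A"])
        for g in range(12)])
    assert np.all((0.9 < ratios) & (ratios < 1.1))
    # empirical-Bayes shrinkage intentionally leaves part of the per-feature
    # scale estimate in the prior, so its residual spread is wider
    out_eb = combat_harmonize(table, _spec(n_metrics=12, eb=True))
    ratios_eb = np.array([
        out_eb.groupby("vendor")[f"m{g}"].var().pipe(lambda v: v["B"] / v["A"])
        for g in range(12)])
    assert np.all((0.75 < ratios_eb) & (ratios_eb < 1.3))
    assert np.median(np.abs(np.log(ratios_eb))) < np.log(1.5) / 2


def test_biological_effect_preserved():
    """A planted csPCa effect survives harmonization of a location/scale
    batch effect: the group mean difference is untouched (< 10% change) and
    the standardized mean difference moves only by the unavoidable
    re-standardization to the pooled noise level (kept < 10% by using a mild
    scale factor)."""
    table = _toy_table(n_per_batch=200, n_metrics=12, shift=0.3, scale=1.1,
                       effect=0.35, seed=5)
    out = combat_harmonize(table, _spec(n_metrics=12))

    def smd(df, col):
        a = df.loc[df.cspca == 1, col]
        b = df.loc[df.cspca == 0, col]
        pooled = np.sqrt((a.var() + b.var()) / 2)
        return (a.mean() - b.mean()) / pooled

    clean = _toy_table(n_per_batch=200, n_metrics=12, shift=0.0, scale=1.0,
                       effect=0.35, seed=5)
    for g in range(12):
        delta_out = (out.loc[out.cspca == 1, f"m{g}"].mean()
                     - out.loc[out.cspca == 0, f"m{g}"].mean())
        delta_ref = (clean.loc[clean.cspca == 1, f"m{g}"].mean()
                     - clean.loc[clean.cspca == 0, f"m{g}"].mean())
        assert abs(delta_out - delta_ref) / abs(delta_ref) < 0.10
        s_out, s_ref = smd(out, f"m{g}"), smd(clean, f"m{g}")
        assert abs(s_out - s_ref) / abs(s_ref) < 0.10


def test_singular_design_names_columns():
    table = _toy_table()
    table["dup"] = table["cspca"]
    spec = HarmonizationSpec(batch_col="vendor", covariates=("cspca", "dup"),
                             metrics=("m0", "m1"))
    with pytest.raises(ValueError, match="dup"):
        combat_harmonize(table, spec)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_against_sva_combat(tmp_path):
    """Independent oracle: Bioconductor sva::ComBat on the same fixture."""
    table = _toy_table(n_per_batch=30, n_metrics=6, shift=0.2, scale=1.3, seed=42)
    metrics = [f"m{g}" for g in range(6)]
    fixture = tmp_path / "fixture.csv"
    table.to_csv(fixture, index=False)
    script = tmp_path / "combat.R"
    script.write_text(f"""
suppressMessages(library(sva))
df <- read.csv("{fixture}")
dat <- t(as.matrix(df[, paste0("m", 0:5)]))
mod <- model.matrix(~cspca, data=df)
res <- ComBat(dat=dat, batch=df$vendor, mod=mod, par.prior=TRUE)
write.csv(t(res), "{tmp_path}/combat_r.csv", row.names=FALSE)
""")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "combat_r.csv").to_numpy()
    out = combat_harmonize(table, _spec(n_metrics=6))
    got = out[metrics].to_numpy()
    assert np.max(np.abs(got - ref)) < 1e-5


def test_consistency_check_trivial_cases():
    rng = np.random.default_rng(6)
    base = pd.DataFrame({
        "m0": rng.normal(1, 0.1, 200), "cspca": rng.integers(0, 2, 200)})
    # identical samples pass; a shifted clone fails
    res = cross_vendor_consistency_check(base, base.copy(), metrics=("m0",))
    assert res["consistent"].all()
    shifted = base.assign(m0=base["m0"] + 1.0)
    res2 = cross_vendor_consistency_check(base, shifted, metrics=("m0",))
    assert not res2["consistent"].any()


def test_end_to_end_vendor_shift_removed():
    """Twin-arm control: the same ~150 lesions labelled as two vendors, one
    arm carrying a planted location/scale effect.  Harmonization must bring
    at least 17 of 18 metrics back to cross-vendor consistency (the twin
    design isolates shift removal from cohort sampling noise)."""
    arm_a = generate_cohort(CohortConfig(n_patients=110, seed=8)).lesions
    arm_b = arm_a.copy()
    arm_b["vendor"] = "GE"
    arm_b["patient_id"] = arm_b["patient_id"] + 10_000
    shift = {m: 0.08 for m in METRICS}
    scale = {m: 1.2 for m in METRICS}
    arm_b = apply_vendor_effect(arm_b, VendorEffect("GE", shift, scale))

    # positive control: the shifted arm fails the consistency check broadly
    before = cross_vendor_consistency_check(arm_a, arm_b)
    assert before["consistent"].sum() < 6

    combined = pd.concat([arm_a, arm_b], ignore_index=True)
    spec = HarmonizationSpec(batch_col="vendor", covariates=("cspca",))
    harmonized = combat_harmonize(combined, spec)
    h_a = harmonized[harmonized.vendor != "GE"]
    h_b = harmonized[harmonized.vendor == "GE"]
    after = cross_vendor_consistency_check(h_a, h_b)
    assert after["consistent"].sum() >= 17


def test_external_validate_identity(planted_cohort):
    les = split_cohort(planted_cohort.lesions, seed=5)
    train = les[les.split == "train"]
    models = fit_risk_models(train, ["MEM_ADC", "CTRW_alpha"])
    res = external_validate(models, train, n_boot=50, seed=0)
    design = prepare_design(train)
    for name, model in models.items():
        direct = roc_metrics(model.predict(design), design["cspca"].to_numpy(),
                             threshold=model.threshold, n_boot=50, seed=0)
        assert res["evals"][name].auc == pytest.approx(direct.auc, abs=1e-12)
        assert res["evals"][name].accuracy == pytest.approx(direct.accuracy)
    with pytest.raises(KeyError):
        external_validate(models, train.drop(columns=["psad"]), n_boot=10)
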