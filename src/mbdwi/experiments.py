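"""Canned study-scale experiments: recovery benchmarks and end-to-end runs.

These functions re-create the study conditions (published parameter
medians, 12-point b-scheme, SNR 50, 162-patient cohorts) and measure how
well the estimation chain recovers known ground truth.  They back the
analysis drivers and the acceptance script; the tolerances asserted on
their outputs live in the test-suite.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from . import models as M
from .fitting import FitConfig, SignalDecay, fit_all_models, fit_model
from .pipeline import PipelineConfig, run_analysis
from .synthetic import CohortConfig, generate_cohort, generate_decay

__all__ = [
    "STUDY_MEDIANS", "reduction_lattice_error", "noiseless_recovery",
    "rician_recovery", "pipeline_recovery", "harmonization_experiment",
    "determinism_check", "D_TYPE_FIELDS",
]

#: per-family parameter sets at the csPCa-group medians of the lesion summaries
STUDY_MEDIANS = {
    "MEM": M.MEMParams(1.0, 0.87),
    "SEM": M.SEMParams(1.0, 1.02, 0.69),
    "IVIM": M.IVIMParams(1.0, 0.81, 13.43, 0.16),
    "DKI": M.DKIParams(1.0, 1.18, 0.73),
    "IVIM_DKI": M.IVIMDKIParams(1.0, 0.92, 20.93, 0.18, 0.59),
    "CTRW": M.CTRWParams(1.0, 1.01, 0.83, 0.76),
    "FROC": M.FROCParams(1.0, 1.01, 0.75, 7.40),
}

#: diffusivity-type fields (tighter recovery tolerance than shape fields)
D_TYPE_FIELDS = {"adc", "ddc", "d", "dstar", "dp"}


def reduction_lattice_error(n_points: int = 61) -> float:
    """Max relative deviation of each family from the mono-exponential decay
    in its reduction limit, over b in [0, 3000]."""
    b = np.linspace(0.0, 3000.0, n_points)
    mem = M.mem_signal(M.MEMParams(1.0, 1.11), b)
    reduced = [
        M.SEMParams(1.0, 1.11, 1.0),
        M.IVIMParams(1.0, 1.11, 15.0, 0.0),
        M.DKIParams(1.0, 1.11, 0.0),
        M.IVIMDKIParams(1.0, 1.11, 20.0, 0.0, 0.0),
        M.CTRWParams(1.0, 1.11, 1.0, 1.0),
        M.FROCParams(1.0, 1.11, 1.0, 7.4),
    ]
    worst = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", M.DkiValidityWarning)
        for params in reduced:
            err = np.max(np.abs(M.signal(params, b) - mem) / mem)
            worst = max(worst, float(err))
    return worst


def _clean_decay(params) -> SignalDecay:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", M.DkiValidityWarning)
        sig = M.signal(params, M.DEFAULT_SCHEME.array)
    return SignalDecay(M.DEFAULT_SCHEME, tuple(sig))


def noiseless_recovery(config: FitConfig | None = None) -> dict:
    """Noiseless round-trip error per family at the study medians.

    Returns {family: max relative parameter error}.  The joint IVIM
    strategy is used (the segmented two-step has its own, looser contract).
    """
    config = replace(config or FitConfig(), ivim_strategy="joint")
    out = {}
    for family, truth in STUDY_MEDIANS.items():
        res = fit_model(_clean_decay(truth), family, config)
        true_m = M.metrics_from_params(truth)
        est = res.metrics
        out[family] = max(abs(est[k] - true_m[k]) / abs(true_m[k]) for k in true_m)
    return out


def rician_recovery(n: int = 200, snr: float = 50.0, seed: int = 0,
                    config: FitConfig | None = None) -> pd.DataFrame:
    """Monte-Carlo recovery under Rician noise at the study medians.

    ``n`` decays per family; returns one row per (family, parameter) with
    the median relative bias and whether the parameter is diffusivity-type.
    The noise-robust estimator defaults are used: segmented IVIM and
    IVIM-DKI fits, and the Rician floor term for FROC (whose decay drops
    below the noise floor at prostate-typical parameters).
    """
    config = config or FitConfig(rician_floor=("FROC",))
    root = np.random.SeedSequence(seed)
    rows = []
    for family, truth in STUDY_MEDIANS.items():
        stream = np.random.default_rng(root.spawn(1)[0])
        true_m = M.metrics_from_params(truth)
        fields = list(M.FAMILY_METRICS[family].items())
        estimates = {k: [] for _, k in fields}
        for _ in range(n):
            sig = generate_decay(truth, M.DEFAULT_SCHEME, snr, stream)
            decay = SignalDecay(M.DEFAULT_SCHEME, tuple(np.maximum(sig, 1e-9)))
            res = fit_model(decay, family, config)
            if not res.converged:
                continue
            for _, k in fields:
                estimates[k].append(res.metrics[k])
        for field, k in fields:
            est = np.asarray(estimates[k])
            med_bias = (np.median(est) - true_m[k]) / abs(true_m[k])
            rows.append({
                "family": family, "metric": k,
                "median_relative_bias": float(med_bias),
                "d_type": field in D_TYPE_FIELDS,
                "n_converged": int(est.size),
            })
    return pd.DataFrame(rows)


def pipeline_recovery(seed: int = 11, n_boot: int = 100,
                      n_patients: int = 162) -> dict:
    """End-to-end planted-signal run: a cohort with effects on MEM_ADC and
    CTRW_alpha only, through gating, selection and GEE.

    Returns the stable set, selection frequencies, and the GEE odds ratios
    and p-values of the two planted metrics.
    """
    cohort = generate_cohort(CohortConfig(
        seed=seed, n_patients=n_patients,
        effect_metrics=["MEM_ADC", "CTRW_alpha"]))
    res = run_analysis(cohort, PipelineConfig(
        seed=seed, n_boot_lasso=n_boot, n_boot_auc=200))
    rep = res["report"]
    gee = {row["term"]: row for row in (rep["gee"] or [])}
    out = {
        "stable": sorted(rep["stable_metrics"]),
        "frequencies": rep["selection_frequencies"],
        "report": rep,
    }
    for metric in ("MEM_ADC", "CTRW_alpha"):
        term = f"{metric}_z"
        out[f"or_{metric}"] = gee[term]["or"] if term in gee else None
        out[f"p_{metric}"] = gee[term]["p"] if term in gee else None
    return out


def harmonization_experiment(seed: int = 8, n_patients: int = 110) -> dict:
    """Twin-arm vendor-shift experiment: identical lesions labelled as two
    vendors, one arm given a location/scale effect; ComBat must restore
    cross-vendor consistency."""
    from .harmonize import HarmonizationSpec, combat_harmonize, cross_vendor_consistency_check
    from .synthetic import VendorEffect, apply_vendor_effect

    arm_a = generate_cohort(CohortConfig(n_patients=n_patients, seed=seed)).lesions
    arm_b = arm_a.copy()
    arm_b["vendor"] = "GE"
    arm_b["patient_id"] += 10_000
    effect = VendorEffect("GE", {m: 0.08 for m in M.METRICS},
                          {m: 1.2 for m in M.METRICS})
    arm_b = apply_vendor_effect(arm_b, effect)

    before = cross_vendor_consistency_check(arm_a, arm_b)
    combined = pd.concat([arm_a, arm_b], ignore_index=True)
    spec = HarmonizationSpec(batch_col="vendor", covariates=("cspca",))
    harmonized = combat_harmonize(combined, spec)
    h_a = harmonized[harmonized.vendor != "GE"]
    h_b = harmonized[harmonized.vendor == "GE"]
    after = cross_vendor_consistency_check(h_a, h_b)

    shift_only = combat_harmonize(
        combined, replace(spec, eb=False, covariates=()))
    gaps = [abs(shift_only[shift_only.vendor != "GE"][m].mean()
                - shift_only[shift_only.vendor == "GE"][m].mean())
            for m in M.METRICS]
    return {
        "n_lesions_per_arm": int(len(arm_a)),
        "consistent_before": int(before["consistent"].sum()),
        "consistent_after": int(after["consistent"].sum()),
        "n_metrics": len(M.METRICS),
        "max_batch_mean_gap_no_eb": float(max(gaps)),
    }


def determinism_check(seed: int = 0, n_boot: int = 50) -> dict:
    """Simulate + analyze twice from one seed; report hashes must agree."""
    hashes = []
    for _ in range(2):
        cohort = generate_cohort(CohortConfig(seed=seed))
        res = run_analysis(cohort, PipelineConfig(seed=seed, n_boot_lasso=n_boot,
                                                  n_boot_auc=200))
        payload = json.dumps(res["report"], sort_keys=True, default=float)
        hashes.append(hashlib.sha256(payload.encode()).hexdigest())
    return {"hashes": hashes, "identical": hashes[0] == hashes[1]}
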