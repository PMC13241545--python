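"""End-to-end orchestration: gating -> comparisons -> selection -> GEE ->
risk models -> ROC/DeLong -> decision curves -> subgroups -> zone-aware
model, plus the cross-vendor validation chain.

Every run is a pure function of (input tables, config): the JSON report
embeds the root seed and a hash of the configuration, and contains no
timestamps, so double runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import stats as S
from .harmonize import HarmonizationSpec, combat_harmonize, cross_vendor_consistency_check, external_validate
from .models import METRICS
from .reliability import filter_by_icc, icc_table
from .synthetic import SyntheticCohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_analysis", "run_validation", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the lesion-level analysis chain."""

    seed: int = 0
    icc_threshold: float = 0.80
    skip_gating: bool = False
    train_fraction: float = 0.7
    n_boot_lasso: int = 500
    freq_threshold: float = 0.5
    n_boot_auc: int = 2000
    min_subgroup_n: int = 15
    resample_unit: str = "patients"

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_boot_lasso < 1 or self.n_boot_auc < 1:
            raise ValueError("bootstrap counts must be >= 1")


def config_hash(config) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _df_records(df: pd.DataFrame) -> list:
    return json.loads(df.to_json(orient="records"))


def run_analysis(cohort, config: PipelineConfig | None = None) -> dict:
    """Full statistical chain on one cohort.

    ``cohort`` is a :class:`~mbdwi.synthetic.SyntheticCohort` (reader pairs
    available -> ICC gating runs) or a bare lesion DataFrame (gating is
    skipped; all metrics enter).  Returns a JSON-serialisable report plus
    the fitted models under the "models" key (not serialised).
    """
    config = config or PipelineConfig()
    if isinstance(cohort, SyntheticCohort):
        lesions = cohort.lesions
        pairs = cohort.reader_pairs
    else:
        lesions, pairs = cohort, None

    report = {"seed": config.seed, "config_hash": config_hash(config),
              "n_patients": int(lesions["patient_id"].nunique()),
              "n_lesions": int(len(lesions))}

    # 1. reliability gating
    if pairs is not None and not config.skip_gating:
        icc = icc_table(pairs[pairs["metric"].isin(METRICS)])
        gated = filter_by_icc(icc, config.icc_threshold, metrics=list(METRICS))
        report["icc"] = _df_records(icc)
    else:
        gated = list(METRICS)
        report["icc"] = None
    report["gated_metrics"] = gated

    # 2. patient-level split
    lesions = S.split_cohort(lesions, config.train_fraction, seed=config.seed)
    train = lesions[lesions["split"] == "train"].reset_index(drop=True)
    test = lesions[lesions["split"] == "test"].reset_index(drop=True)
    report["n_train_patients"] = int(train["patient_id"].nunique())
    report["n_test_patients"] = int(test["patient_id"].nunique())
    report["n_train_lesions"] = int(len(train))
    report["n_test_lesions"] = int(len(test))

    # 3. group comparisons (overall and per zone), Spearman vs grade group
    comparisons = {"overall": S.compare_groups(lesions, gated)}
    for zone in ("PZ", "TZ"):
        sub = lesions[lesions["zone"] == zone]
        if sub["cspca"].nunique() == 2:
            comparisons[zone] = S.compare_groups(sub, gated)
    report["comparisons"] = {k: _df_records(v) for k, v in comparisons.items()}
    report["spearman"] = {
        zone: _df_records(S.spearman_by_zone(lesions, gated, zone))
        for zone in ("PZ", "TZ")
    }

    # 4. stability selection on the training lesions
    stability = S.bootstrap_lasso_select(
        train, gated, n_boot=config.n_boot_lasso,
        freq_threshold=config.freq_threshold, seed=config.seed,
        resample_unit=config.resample_unit)
    report["selection_frequencies"] = {
        m: float(f) for m, f in stability.frequencies.items()}
    report["stable_metrics"] = list(stability.stable)
    report["n_degenerate_resamples"] = stability.n_redrawn

    # 5. GEE with clinical adjustment (stable metrics z-scored on train)
    train_design = S.prepare_design(train)
    gee_covs = ["age", "psad", "dre", "pirads_4", "pirads_5", "zone_tz", "volume"]
    gee_table = train_design.copy()
    for m in stability.stable:
        mu, sd = train_design[m].mean(), train_design[m].std(ddof=0) or 1.0
        gee_table[f"{m}_z"] = (train_design[m] - mu) / sd
    metric_terms = [f"{m}_z" for m in stability.stable]
    try:
        gee_res = S.gee_fit(gee_table, gee_covs + metric_terms)
        report["gee"] = _df_records(gee_res.reset_index(names="term"))
        report["gee_metrics_used"] = list(stability.stable)
    except RuntimeError as exc:
        # a large, mutually informative stable set can separate the outcome;
        # fall back to the two most frequently selected metrics
        log.warning("GEE on full stable set failed (%s); retrying with top-2", exc)
        top2 = list(stability.frequencies.sort_values(ascending=False).index[:2])
        try:
            gee_res = S.gee_fit(gee_table, gee_covs + [f"{m}_z" for m in top2])
            report["gee"] = _df_records(gee_res.reset_index(names="term"))
            report["gee_metrics_used"] = top2
            report["gee_note"] = f"full stable set failed: {exc}"
        except RuntimeError as exc2:
            report["gee"] = None
            report["gee_metrics_used"] = []
            report["gee_note"] = f"GEE failed: {exc2}"

    # 6. nested risk models; evaluation on train and test
    models = S.fit_risk_models(train, stability.stable)
    evals, scores = {}, {}
    for split_name, part in (("train", train), ("test", test)):
        part_design = S.prepare_design(part)
        y = part_design["cspca"].to_numpy()
        evals[split_name], scores[split_name] = {}, {}
        for name, model in models.items():
            s = model.predict(part_design)
            scores[split_name][name] = s
            thr = None if split_name == "train" else model.threshold
            evals[split_name][name] = S.roc_metrics(
                s, y, threshold=thr if split_name != "train" else model.threshold,
                n_boot=config.n_boot_auc, seed=config.seed)
    report["model_eval"] = {
        split: {name: ev.as_dict() for name, ev in d.items()}
        for split, d in evals.items()}

    # 7. DeLong comparisons on the test set
    y_test = test["cspca"].to_numpy()
    pairs_to_test = [("clinical", "clinical_adc"),
                     ("clinical", "clinical_multib"),
                     ("clinical_adc", "clinical_multib")]
    report["delong_test"] = {
        f"{a}_vs_{b}": S.delong_test(scores["test"][a], scores["test"][b], y_test)
        for a, b in pairs_to_test}

    # 8. decision curves on the test set
    dca = S.decision_curve(scores["test"], y_test)
    report["decision_curve_test"] = _df_records(dca)

    # 9. subgroups
    sub = S.subgroup_analysis(lesions, gated, min_n=config.min_subgroup_n)
    report["subgroups"] = {
        key: (None if v is None else {
            "n": v["n"], "n_positive": v["n_positive"],
            "small_stratum": v["small_stratum"], "table": _df_records(v["table"])})
        for key, v in sub.items()}

    # 10. exploratory zone-aware split model (PZ: ADC; TZ: CTRW alpha)
    zone_models = {}
    for zone, metric in (("PZ", "MEM_ADC"), ("TZ", "CTRW_alpha")):
        ztrain = train[train["zone"] == zone]
        if ztrain["cspca"].nunique() == 2:
            zone_models[zone] = S._fit_logistic(
                f"zone_{zone}", S.prepare_design(ztrain),
                S.CLINICAL_COVARIATES + [metric], "cspca", scale_cols=[metric])
    if len(zone_models) == 2:
        za_scores = {
            split_name: S.zone_aware_predict(part, zone_models["PZ"], zone_models["TZ"])
            for split_name, part in (("train", train), ("test", test))}
        thr = S.youden_threshold(za_scores["train"], train["cspca"].to_numpy())
        report["zone_aware_eval"] = {
            split_name: S.roc_metrics(
                za_scores[split_name],
                (train if split_name == "train" else test)["cspca"].to_numpy(),
                threshold=thr, n_boot=config.n_boot_auc, seed=config.seed).as_dict()
            for split_name in ("train", "test")}
        models["zone_aware_pz"] = zone_models["PZ"]
        models["zone_aware_tz"] = zone_models["TZ"]
    else:
        report["zone_aware_eval"] = None

    return {"report": report, "models": models, "lesions": lesions,
            "stability": stability}


def run_validation(models: dict, primary: pd.DataFrame, external: pd.DataFrame,
                   spec: HarmonizationSpec | None = None,
                   n_boot_auc: int = 2000, seed: int = 0) -> dict:
    """Cross-vendor chain: ComBat over the combined table, consistency
    check within pathology groups, then frozen-model external evaluation."""
    spec = spec or HarmonizationSpec()
    combined = pd.concat([primary, external], ignore_index=True)
    harmonized, audit = combat_harmonize(combined, spec, return_estimates=True)
    vendors = external["vendor"].unique()
    h_primary = harmonized[~harmonized["vendor"].isin(vendors)].reset_index(drop=True)
    h_external = harmonized[harmonized["vendor"].isin(vendors)].reset_index(drop=True)
    consistency = cross_vendor_consistency_check(h_primary, h_external,
                                                 metrics=spec.metrics)
    risk_models = {k: v for k, v in models.items()
                   if k in ("clinical", "clinical_adc", "clinical_multib")}
    ext = external_validate(risk_models, h_external, n_boot=n_boot_auc, seed=seed)
    report = {
        "consistency": _df_records(consistency),
        "n_consistent": int(consistency["consistent"].sum()),
        "n_metrics": int(len(consistency)),
        "external_eval": {k: v.as_dict() for k, v in ext["evals"].items()},
        "decision_curve_external": _df_records(ext["decision_curve"]),
        "combat_audit": {b: _df_records(df.reset_index(names="metric"))
                         for b, df in audit.items()},
    }
    return {"report": report, "harmonized_external": h_external,
            "harmonized_primary": h_primary}
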