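"""Synthetic cohort generator with the statistical structure of a
two-centre prostate multi-b-value DWI study.

The generator draws clustered patients and lesions (multiple lesions share
their patient's covariates and a patient-level risk intercept), assigns
zone / PI-RADS / Gleason grade-group / csPCa labels from the published
conditional tables, and samples the 18 diffusion metrics per
pathology-group x zone from log-normal (positive metrics) or logit-normal
(unit-interval metrics) marginals whose median and IQR are calibrated to
the published lesion summaries (:mod:`mbdwi.tables`).  A Gaussian copula
couples the seven diffusivity-type metrics (rank correlation ~0.7 by
default); metric margins are group-independent for metrics outside the
configured ``effect_metrics`` set, which lets planted-signal experiments
switch every other metric into pure noise.

Measurement layers: two-reader replicates with configurable multiplicative
and additive jitter (reader-averaged values are what the analysis uses),
multi-b-value signal decays with Rician noise for the fitting pipeline,
and a two-vendor location/scale batch effect for harmonization tests.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` stream splitting: patients, lesion labels,
metric draws, reader jitter and decay noise each consume a dedicated
child stream, so any layer can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import tables as T
from .models import METRICS, DEFAULT_SCHEME, BValueScheme, params_from_metrics, signal
from .tables import BOUNDED_METRICS

__all__ = [
    "CohortConfig", "LesionTruth", "VendorEffect", "ReaderEffect",
    "SyntheticCohort", "draw_lesion_params", "generate_decay",
    "generate_cohort", "apply_vendor_effect", "simulate_two_readers",
    "reader_effect_for_icc", "default_vendor_effect", "generate_study",
    "DEFAULT_EXTERNAL_CONFIG",
]

_NORM_IQR = 1.3489795003921634   # q3 - q1 of the standard normal

#: the seven diffusivity-type metrics sharing the latent rank correlation
D_TYPE = ("MEM_ADC", "SEM_DDC", "IVIM_D", "DKI_D", "IVIM-DKI_D", "CTRW_D", "FROC_D")


@dataclass(frozen=True)
class ReaderEffect:
    """Per-reader measurement jitter: multiplicative sd (dimensionless) and
    additive sd per metric (metric units)."""

    mult_sd: float = 0.0
    add_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mult_sd < 0 or any(v < 0 for v in self.add_sd.values()):
            raise ValueError("jitter standard deviations must be >= 0")


@dataclass(frozen=True)
class VendorEffect:
    """Location/scale batch effect of one scanner vendor."""

    batch: str
    shift: dict = field(default_factory=dict)   # metric -> additive shift
    scale: dict = field(default_factory=dict)   # metric -> multiplicative factor

    def __post_init__(self):
        if any(v <= 0 for v in self.scale.values()):
            raise ValueError("scale factors must be > 0")


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth of one simulated lesion."""

    metrics: dict                  # the 18 true metric values
    zone: str                      # "PZ" | "TZ"
    gg: int                        # grade group 0-5
    cspca: int                     # 1 iff gg >= 2
    diameter: float                # cm
    volume: float                  # cm³

    def __post_init__(self):
        if self.cspca != int(self.gg >= 2):
            raise ValueError("csPCa label must equal (grade group >= 2)")

    def params(self, family: str, s0: float = 1.0):
        """The family's ModelParamSet at this lesion's true metric values."""
        return params_from_metrics(family, self.metrics, s0=s0)


def _default_pirads():
    return {k: dict(v) for k, v in T.PIRADS_GIVEN_CSPCA.items()}


def _default_gg():
    return {k: dict(v) for k, v in T.GG_GIVEN_CSPCA.items()}


def _default_lesion_dist():
    return dict(T.LESIONS_PER_PATIENT)


def _default_prevalence():
    return dict(T.COHORT_COUNTS["cspca_prevalence"])


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Defaults reproduce the primary cohort: 162 patients, ~224 lesions,
    44.2% PZ, zone-specific csPCa prevalence, and published PI-RADS / GG
    conditional tables.  ``effect_metrics`` = "all" calibrates every metric
    to its group-specific summary; a list restricts the group difference to
    those metrics (all others become group-independent noise).
    """

    n_patients: int = 162
    lesions_per_patient: dict = field(default_factory=_default_lesion_dist)
    pz_fraction: float = T.COHORT_COUNTS["pz_fraction"]
    cspca_prevalence: dict = field(default_factory=_default_prevalence)
    pirads_given_cspca: dict = field(default_factory=_default_pirads)
    gg_given_cspca: dict = field(default_factory=_default_gg)
    effect_metrics: object = "all"
    metric_rank_corr: float = 0.7        # latent corr among D-type metrics
    patient_intercept_sd: float = 0.5    # logit-scale random intercept
    psad_log_or: float = float(np.log(2.0))  # csPCa odds ratio per PSAD doubling
    reader_target_icc: float = 0.94
    reader_mult_sd: float = 0.0
    snr: float = 50.0
    vendor: str = "SIEMENS"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, dist in (("lesions_per_patient", self.lesions_per_patient),):
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must be >= 0 and sum to 1")
        if not 0.0 <= self.pz_fraction <= 1.0:
            raise ValueError("pz_fraction must be in [0, 1]")
        for zone, p in self.cspca_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"cspca_prevalence[{zone!r}] must be in [0, 1]")
        for label, table in (("pirads_given_cspca", self.pirads_given_cspca),
                             ("gg_given_cspca", self.gg_given_cspca)):
            for outcome, dist in table.items():
                total = sum(dist.values())
                if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"{label}[{outcome}] probabilities must be >= 0 and sum to 1")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


#: cross-vendor validation cohort: 76 patients / ~84 lesions on the GE scanner
DEFAULT_EXTERNAL_CONFIG = CohortConfig(
    n_patients=T.COHORT_COUNTS["external_patients"],
    lesions_per_patient=dict(T.COHORT_COUNTS["external_lesions_per_patient"]),
    vendor="GE",
    seed=1,
)


def _marginal_params(summary: tuple, bounded: bool) -> tuple[float, float]:
    """(location, scale) of the latent normal from a median/(q1,q3) summary."""
    med, q1, q3 = summary
    if bounded:
        loc = logit(med)
        scale = (logit(q3) - logit(q1)) / _NORM_IQR
    else:
        loc = np.log(med)
        scale = (np.log(q3) - np.log(q1)) / _NORM_IQR
    return float(loc), float(scale)


def _transform(z: np.ndarray, summary: tuple, bounded: bool) -> np.ndarray:
    loc, scale = _marginal_params(summary, bounded)
    lat = loc + scale * z
    return expit(lat) if bounded else np.exp(lat)


def _latent_correlation(corr_d: float) -> np.ndarray:
    """Latent copula correlation: ``corr_d`` among D-type metrics, diameter
    and volume coupled at 0.8, everything else independent."""
    names = list(METRICS) + ["diameter", "volume"]
    k = len(names)
    R = np.eye(k)
    idx = [names.index(m) for m in D_TYPE]
    for i in idx:
        for j in idx:
            if i != j:
                R[i, j] = corr_d
    di, vi = names.index("diameter"), names.index("volume")
    R[di, vi] = R[vi, di] = 0.8
    return R


def _summary_for(metric: str, zone: str, group: str, effect_metrics) -> tuple:
    """Marginal summary of a metric.

    Full calibration (``effect_metrics="all"``): the zone- and
    group-specific published margin.  Planted mode: metrics outside the
    planted set use the overall benign margin for every lesion — zone- and
    group-independent — so they are genuinely uninformative (zone-specific
    margins would proxy the zone-dependent csPCa prevalence).
    """
    table = T.METRIC_SUMMARIES.get(metric) or T.MORPHOLOGY_SUMMARIES[metric]
    if effect_metrics != "all" and metric not in effect_metrics:
        return table["overall"]["non"]
    return table[zone][group]


def draw_lesion_params(group: str, zone: str, rng=None, *,
                       effect_metrics="all", metric_rank_corr: float = 0.7,
                       gg: int | None = None, n: int = 1):
    """Draw lesion ground truth for one pathology-group x zone cell.

    ``group`` is "cspca" or "non"; the metric margins are the published
    zone-specific medians/IQRs (log- or logit-normal), coupled through a
    Gaussian copula.  Returns a :class:`LesionTruth` (or a list when n > 1).
    """
    if group not in ("cspca", "non"):
        raise ValueError(f"unknown pathology group {group!r}")
    if zone not in ("PZ", "TZ", "overall"):
        raise ValueError(f"unknown zone {zone!r}")
    rng = np.random.default_rng(rng)
    names = list(METRICS) + ["diameter", "volume"]
    R = _latent_correlation(metric_rank_corr)
    if effect_metrics != "all":
        # planted-signal experiments need the remaining metrics to be pure
        # noise: a null metric latently correlated with a planted one would
        # act as a suppressor variable and carry conditional signal
        for m in effect_metrics:
            if m in names:
                j = names.index(m)
                R[j, :] = R[:, j] = 0.0
                R[j, j] = 1.0
    z = rng.multivariate_normal(np.zeros(len(names)), R, size=n, method="cholesky")
    cspca = int(group == "cspca")
    if gg is None:
        gg = 2 if cspca else 0
    out = []
    for row in z:
        vals = {}
        for j, name in enumerate(names):
            summary = _summary_for(name, zone, group, effect_metrics)
            vals[name] = float(_transform(np.asarray(row[j]), summary,
                                          name in BOUNDED_METRICS))
        # honour the pseudo-diffusion > tissue-diffusion invariant
        vals["IVIM_Dstar"] = max(vals["IVIM_Dstar"], vals["IVIM_D"] * 1.5)
        vals["IVIM-DKI_Dp"] = max(vals["IVIM-DKI_Dp"], vals["IVIM-DKI_D"] * 1.5)
        diameter = max(vals.pop("diameter"), 0.3)   # >= 3 mm inclusion gate
        volume = vals.pop("volume")
        out.append(LesionTruth(metrics=vals, zone=zone if zone != "overall" else "PZ",
                               gg=int(gg), cspca=cspca,
                               diameter=diameter, volume=volume))
    return out[0] if n == 1 else out


def generate_decay(params, scheme: BValueScheme = DEFAULT_SCHEME,
                   snr: float = 50.0, rng=None):
    """Rician-noised signal decay of one parameter set.

    Magnitude-MRI noise: ``|S(b) + e1 + i*e2|`` with independent Gaussian
    channels of sd ``S0/snr``.  ``snr = inf`` returns the exact forward
    signal.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        clean = signal(params, scheme.array)
    if not np.isfinite(snr):
        return clean
    rng = np.random.default_rng(rng)
    sigma = params.s0 / snr
    e1 = rng.normal(0.0, sigma, size=clean.shape)
    e2 = rng.normal(0.0, sigma, size=clean.shape)
    return np.abs(clean + e1 + 1j * e2)


def _draw_categorical(rng, dist: dict, size: int) -> np.ndarray:
    keys = sorted(dist)
    p = np.asarray([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.asarray(keys)[rng.choice(len(keys), size=size, p=p)]


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: analysis table, ground truth and reader replicates."""

    lesions: pd.DataFrame       # measured (reader-averaged) analysis table
    truth: pd.DataFrame         # true metric values per lesion
    reader_pairs: pd.DataFrame  # long table: lesion_id, metric, reader1, reader2
    config: CohortConfig


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a clustered patient/lesion cohort.

    Patients carry age, PSA, prostate volume (hence PSAD), DRE status and a
    logit-scale random intercept; each of their lesions gets a zone, a
    csPCa label (probability = zone prevalence adjusted by PSAD and the
    patient intercept), grade group and PI-RADS from the conditional
    tables, morphology, and true + reader-averaged measured metrics.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    s_pat, s_lab, s_met, s_read = root.spawn(4)
    rng_pat = np.random.default_rng(s_pat)
    rng_lab = np.random.default_rng(s_lab)
    rng_met = np.random.default_rng(s_met)

    n = config.n_patients
    age_med, age_q1, age_q3 = T.CLINICAL_SUMMARIES["age"]
    age = rng_pat.normal(age_med, (age_q3 - age_q1) / _NORM_IQR, size=n)
    psa = _transform(rng_pat.normal(size=n), T.CLINICAL_SUMMARIES["psa"], False)
    pvol = _transform(rng_pat.normal(size=n), T.CLINICAL_SUMMARIES["prostate_volume"], False)
    psad = psa / pvol
    dre = (rng_pat.random(n) < T.CLINICAL_SUMMARIES["dre_positive"]).astype(int)
    intercept = rng_pat.normal(0.0, config.patient_intercept_sd, size=n)
    n_lesions = _draw_categorical(rng_pat, config.lesions_per_patient, n).astype(int)

    psad_ref = T.CLINICAL_SUMMARIES["psa"][0] / T.CLINICAL_SUMMARIES["prostate_volume"][0]

    rows, truth_rows = [], []
    lesion_id = 0
    for i in range(n):
        for _ in range(n_lesions[i]):
            zone = "PZ" if rng_lab.random() < config.pz_fraction else "TZ"
            base = logit(np.clip(config.cspca_prevalence[zone], 1e-9, 1 - 1e-9))
            eta = (base + config.psad_log_or * np.log2(psad[i] / psad_ref)
                   + intercept[i])
            cspca = int(rng_lab.random() < expit(eta))
            gg = int(_draw_categorical(rng_lab, config.gg_given_cspca[cspca], 1)[0])
            pirads = int(_draw_categorical(rng_lab, config.pirads_given_cspca[cspca], 1)[0])
            truth = draw_lesion_params(
                "cspca" if cspca else "non", zone, rng_met,
                effect_metrics=config.effect_metrics,
                metric_rank_corr=config.metric_rank_corr, gg=gg,
            )
            rows.append({
                "patient_id": i, "lesion_id": lesion_id,
                "age": age[i], "psa": psa[i], "prostate_volume": pvol[i],
                "psad": psad[i], "dre": dre[i],
                "zone": zone, "pirads": pirads, "gg": gg, "cspca": cspca,
                "diameter": truth.diameter, "volume": truth.volume,
                "vendor": config.vendor,
            })
            truth_rows.append({"lesion_id": lesion_id, **truth.metrics})
            lesion_id += 1

    lesions = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    effect = reader_effect_for_icc(truth[list(METRICS)], config.reader_target_icc,
                                   mult_sd=config.reader_mult_sd)
    pairs = simulate_two_readers(truth, effect, rng=np.random.default_rng(s_read))
    measured = average_reader_pairs(pairs)
    lesions = lesions.merge(measured, on="lesion_id", validate="one_to_one")
    return SyntheticCohort(lesions=lesions, truth=truth, reader_pairs=pairs,
                           config=config)


def reader_effect_for_icc(metric_table: pd.DataFrame, target_icc: float,
                          mult_sd: float = 0.0) -> ReaderEffect:
    """Additive jitter sds producing a target single-rater ICC.

    From the variance-components identity ``ICC = s_b² / (s_b² + s_e²)``
    the per-metric error sd is ``s_b * sqrt(1/ICC - 1)`` with ``s_b`` the
    between-lesion sd of the true values.
    """
    if not 0.0 < target_icc <= 1.0:
        raise ValueError("target ICC must be in (0, 1]")
    factor = np.sqrt(1.0 / target_icc - 1.0)
    add_sd = {
        m: float(metric_table[m].std(ddof=1) * factor)
        for m in metric_table.columns if m != "lesion_id"
    }
    return ReaderEffect(mult_sd=mult_sd, add_sd=add_sd)


def simulate_two_readers(truth: pd.DataFrame, effect: ReaderEffect,
                         rng=None) -> pd.DataFrame:
    """Two independent noisy measurements of each lesion-metric.

    Reader ``j`` observes ``x * (1 + m_j) + a_j`` with ``m_j ~ N(0, mult_sd²)``
    and ``a_j ~ N(0, add_sd[metric]²)``.  Returns a long table with columns
    lesion_id, metric, reader1, reader2.
    """
    rng = np.random.default_rng(rng)
    metrics = [c for c in truth.columns if c != "lesion_id"]
    frames = []
    for m in metrics:
        x = truth[m].to_numpy(dtype=float)
        add = effect.add_sd.get(m, 0.0)
        readers = []
        for _ in range(2):
            mult = rng.normal(0.0, effect.mult_sd, size=x.shape) if effect.mult_sd else 0.0
            noise = rng.normal(0.0, add, size=x.shape) if add else 0.0
            readers.append(x * (1.0 + mult) + noise)
        frames.append(pd.DataFrame({
            "lesion_id": truth["lesion_id"].to_numpy(),
            "metric": m, "reader1": readers[0], "reader2": readers[1],
        }))
    return pd.concat(frames, ignore_index=True)


def average_reader_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Wide per-lesion table of reader-averaged values."""
    mean = pairs.assign(value=(pairs["reader1"] + pairs["reader2"]) / 2.0)
    wide = mean.pivot(index="lesion_id", columns="metric", values="value")
    return wide.reset_index().rename_axis(None, axis=1)


def apply_vendor_effect(table: pd.DataFrame, effect: VendorEffect) -> pd.DataFrame:
    """``metric' = metric * scale + shift`` on rows of the effect's batch."""
    for m in list(effect.shift) + list(effect.scale):
        if m not in table.columns:
            raise KeyError(f"unknown metric column {m!r}")
    out = table.copy()
    mask = out["vendor"] == effect.batch
    for m, sc in effect.scale.items():
        out.loc[mask, m] = out.loc[mask, m] * sc
    for m, sh in effect.shift.items():
        out.loc[mask, m] = out.loc[mask, m] + sh
    return out


def default_vendor_effect(batch: str = "GE") -> VendorEffect:
    """Moderate location/scale scanner effect: 15% scale inflation plus a
    shift of 6% of each metric's benign median (magnitudes are assumptions;
    the study reports only that a non-biological vendor effect existed)."""
    shift = {m: 0.06 * T.METRIC_SUMMARIES[m]["overall"]["non"][0] for m in METRICS}
    scale = {m: 1.15 for m in METRICS}
    return VendorEffect(batch=batch, shift=shift, scale=scale)


def generate_study(seed: int = 0, primary: CohortConfig | None = None,
                   external: CohortConfig | None = None,
                   vendor_effect: VendorEffect | None = None) -> dict:
    """Primary (Siemens) + cross-vendor (GE) cohorts from one root seed.

    The external cohort's measured metrics receive the vendor batch effect;
    harmonization is expected to remove it downstream.
    """
    root = np.random.SeedSequence(seed)
    s_primary, s_external = root.spawn(2)
    primary = replace(primary or CohortConfig(),
                      seed=int(s_primary.generate_state(1)[0] % (2**31)))
    external = replace(external or DEFAULT_EXTERNAL_CONFIG,
                       seed=int(s_external.generate_state(1)[0] % (2**31)))
    cohort_p = generate_cohort(primary)
    cohort_e = generate_cohort(external)
    effect = vendor_effect or default_vendor_effect(batch=external.vendor)
    lesions_e = apply_vendor_effect(cohort_e.lesions, effect)
    cohort_e = SyntheticCohort(lesions=lesions_e, truth=cohort_e.truth,
                               reader_pairs=cohort_e.reader_pairs, config=external)
    return {"primary": cohort_p, "external": cohort_e, "vendor_effect": effect}
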