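"""Published cohort summaries used to calibrate the synthetic generator.

The generator emulates a two-centre prostate multi-b-value DWI study:
224 lesions in 162 patients on the primary (Siemens) scanner and 84
lesions in 76 patients on a cross-vendor (GE) scanner.  Lesion-level
diffusion metrics are reported as median (Q1-Q3) per pathology group
(csPCa = ISUP grade group >= 2 vs non-csPCa) and per prostate zone
(peripheral PZ / transition TZ); those summaries, together with the
clinical marginals and the PI-RADS / grade-group conditional tables,
are transcribed here and are the single source the sampler inverts.

Units: diffusivities x10⁻³ mm²/s; alpha/beta/f/K dimensionless;
FROC_mu reported numerically (~7.2-7.8); diameter cm; volume cm³.
"""

from __future__ import annotations

__all__ = [
    "METRIC_SUMMARIES", "MORPHOLOGY_SUMMARIES", "CLINICAL_SUMMARIES",
    "PIRADS_GIVEN_CSPCA", "GG_GIVEN_CSPCA", "LESIONS_PER_PATIENT",
    "ENROLLMENT", "COHORT_COUNTS", "BOUNDED_METRICS",
]

# (median, q1, q3) keyed [metric][zone][group]; zone in {"overall","PZ","TZ"},
# group in {"cspca","non"}
METRIC_SUMMARIES = {
    "MEM_ADC": {
        "overall": {"cspca": (0.87, 0.78, 0.97), "non": (1.11, 1.02, 1.19)},
        "PZ": {"cspca": (0.88, 0.76, 0.96), "non": (1.11, 1.00, 1.22)},
        "TZ": {"cspca": (0.84, 0.80, 0.97), "non": (1.11, 1.04, 1.18)},
    },
    "SEM_DDC": {
        "overall": {"cspca": (1.02, 0.89, 1.20), "non": (1.37, 1.26, 1.48)},
        "PZ": {"cspca": (1.07, 0.89, 1.27), "non": (1.42, 1.22, 1.54)},
        "TZ": {"cspca": (0.99, 0.90, 1.12), "non": (1.36, 1.29, 1.47)},
    },
    "SEM_alpha": {
        "overall": {"cspca": (0.69, 0.65, 0.71), "non": (0.70, 0.67, 0.73)},
        "PZ": {"cspca": (0.68, 0.64, 0.70), "non": (0.71, 0.67, 0.74)},
        "TZ": {"cspca": (0.69, 0.66, 0.71), "non": (0.70, 0.67, 0.73)},
    },
    "IVIM_D": {
        "overall": {"cspca": (0.81, 0.72, 0.89), "non": (1.03, 0.93, 1.10)},
        "PZ": {"cspca": (0.80, 0.71, 0.91), "non": (1.04, 0.93, 1.14)},
        "TZ": {"cspca": (0.81, 0.74, 0.89), "non": (1.03, 0.94, 1.09)},
    },
    "IVIM_Dstar": {
        "overall": {"cspca": (13.43, 11.07, 15.90), "non": (14.73, 12.31, 18.72)},
        "PZ": {"cspca": (13.41, 11.07, 15.95), "non": (14.40, 11.89, 18.45)},
        "TZ": {"cspca": (13.52, 11.19, 15.75), "non": (15.10, 12.48, 18.93)},
    },
    "IVIM_f": {
        "overall": {"cspca": (0.16, 0.14, 0.19), "non": (0.19, 0.17, 0.22)},
        "PZ": {"cspca": (0.17, 0.14, 0.20), "non": (0.18, 0.15, 0.21)},
        "TZ": {"cspca": (0.16, 0.14, 0.18), "non": (0.20, 0.17, 0.23)},
    },
    "DKI_D": {
        "overall": {"cspca": (1.18, 1.03, 1.33), "non": (1.52, 1.42, 1.62)},
        "PZ": {"cspca": (1.20, 1.01, 1.37), "non": (1.53, 1.34, 1.62)},
        "TZ": {"cspca": (1.14, 1.07, 1.24), "non": (1.51, 1.44, 1.62)},
    },
    "DKI_K": {
        "overall": {"cspca": (0.73, 0.66, 0.80), "non": (0.64, 0.60, 0.68)},
        "PZ": {"cspca": (0.72, 0.65, 0.80), "non": (0.62, 0.55, 0.66)},
        "TZ": {"cspca": (0.74, 0.68, 0.81), "non": (0.64, 0.61, 0.69)},
    },
    "IVIM-DKI_D": {
        "overall": {"cspca": (0.92, 0.83, 1.09), "non": (1.25, 1.14, 1.33)},
        "PZ": {"cspca": (0.93, 0.82, 1.10), "non": (1.25, 1.10, 1.33)},
        "TZ": {"cspca": (0.91, 0.85, 1.07), "non": (1.24, 1.14, 1.32)},
    },
    "IVIM-DKI_Dp": {
        "overall": {"cspca": (20.93, 18.68, 23.46), "non": (21.46, 17.95, 24.02)},
        "PZ": {"cspca": (20.56, 18.51, 23.15), "non": (19.61, 16.10, 22.24)},
        "TZ": {"cspca": (21.65, 19.20, 24.14), "non": (21.85, 19.57, 24.37)},
    },
    "IVIM-DKI_f": {
        "overall": {"cspca": (0.18, 0.17, 0.21), "non": (0.19, 0.17, 0.21)},
        "PZ": {"cspca": (0.19, 0.17, 0.22), "non": (0.21, 0.18, 0.22)},
        "TZ": {"cspca": (0.17, 0.16, 0.20), "non": (0.18, 0.17, 0.21)},
    },
    "IVIM-DKI_K": {
        "overall": {"cspca": (0.59, 0.50, 0.65), "non": (0.55, 0.47, 0.59)},
        "PZ": {"cspca": (0.56, 0.50, 0.65), "non": (0.50, 0.44, 0.57)},
        "TZ": {"cspca": (0.60, 0.53, 0.67), "non": (0.56, 0.51, 0.60)},
    },
    "CTRW_D": {
        "overall": {"cspca": (1.01, 0.91, 1.15), "non": (1.30, 1.21, 1.39)},
        "PZ": {"cspca": (1.02, 0.90, 1.18), "non": (1.31, 1.15, 1.42)},
        "TZ": {"cspca": (0.98, 0.92, 1.14), "non": (1.30, 1.23, 1.38)},
    },
    "CTRW_alpha": {
        "overall": {"cspca": (0.83, 0.79, 0.88), "non": (0.92, 0.89, 0.93)},
        "PZ": {"cspca": (0.84, 0.79, 0.89), "non": (0.90, 0.88, 0.93)},
        "TZ": {"cspca": (0.82, 0.79, 0.88), "non": (0.92, 0.90, 0.94)},
    },
    "CTRW_beta": {
        "overall": {"cspca": (0.76, 0.72, 0.80), "non": (0.76, 0.71, 0.79)},
        "PZ": {"cspca": (0.76, 0.72, 0.80), "non": (0.77, 0.73, 0.81)},
        "TZ": {"cspca": (0.77, 0.73, 0.80), "non": (0.75, 0.71, 0.79)},
    },
    "FROC_D": {
        "overall": {"cspca": (1.01, 0.90, 1.14), "non": (1.29, 1.22, 1.39)},
        "PZ": {"cspca": (1.03, 0.88, 1.18), "non": (1.30, 1.15, 1.40)},
        "TZ": {"cspca": (1.01, 0.92, 1.07), "non": (1.29, 1.23, 1.37)},
    },
    "FROC_beta": {
        "overall": {"cspca": (0.75, 0.71, 0.78), "non": (0.76, 0.71, 0.78)},
        "PZ": {"cspca": (0.75, 0.71, 0.78), "non": (0.77, 0.75, 0.80)},
        "TZ": {"cspca": (0.74, 0.72, 0.76), "non": (0.74, 0.71, 0.78)},
    },
    "FROC_mu": {
        "overall": {"cspca": (7.40, 7.22, 7.59), "non": (7.64, 7.48, 7.80)},
        "PZ": {"cspca": (7.40, 7.22, 7.62), "non": (7.59, 7.45, 7.78)},
        "TZ": {"cspca": (7.39, 7.24, 7.56), "non": (7.66, 7.49, 7.80)},
    },
}

# metrics bounded in (0, 1): sampled on the logit scale
BOUNDED_METRICS = frozenset(
    {"SEM_alpha", "IVIM_f", "IVIM-DKI_f", "CTRW_alpha", "CTRW_beta", "FROC_beta"}
)

# lesion morphology, median (Q1-Q3) per group/zone
MORPHOLOGY_SUMMARIES = {
    "diameter": {
        "overall": {"cspca": (2.38, 1.57, 3.28), "non": (1.61, 1.34, 2.12)},
        "PZ": {"cspca": (2.13, 1.51, 3.04), "non": (1.54, 1.31, 2.05)},
        "TZ": {"cspca": (2.76, 2.07, 4.09), "non": (1.65, 1.34, 2.16)},
    },
    "volume": {
        "overall": {"cspca": (2.94, 0.93, 6.46), "non": (1.10, 0.68, 2.04)},
        "PZ": {"cspca": (2.10, 0.70, 4.76), "non": (0.77, 0.53, 1.91)},
        "TZ": {"cspca": (4.32, 2.11, 14.27), "non": (1.23, 0.78, 2.18)},
    },
}

# patient-level clinical marginals, median (Q1-Q3) of the primary cohort
CLINICAL_SUMMARIES = {
    "age": (67.0, 61.3, 73.0),                 # years
    "psa": (13.27, 8.34, 23.21),               # ng/mL
    "prostate_volume": (45.61, 30.79, 63.15),  # mL
    "dre_positive": 0.487,                     # fraction DRE-positive
}

# lesion-level conditional tables (counts over the 224 primary lesions)
PIRADS_GIVEN_CSPCA = {
    1: {3: 24 / 107, 4: 36 / 107, 5: 47 / 107},
    0: {3: 100 / 117, 4: 12 / 117, 5: 5 / 117},
}
GG_GIVEN_CSPCA = {
    1: {2: 37 / 107, 3: 32 / 107, 4: 15 / 107, 5: 23 / 107},
    0: {0: 88 / 117, 1: 29 / 117},
}

# number of MRI-suspicious lesions per patient: 71.7% single; the multi-lesion
# mix reproduces the 224/162 lesion-to-patient ratio in expectation
LESIONS_PER_PATIENT = {1: 0.717, 2: 0.184, 3: 0.099}

# patient-selection flow of the primary cohort
ENROLLMENT = {
    "screened": 245,
    "exclusions": {
        "prior_intervention": 25,
        "acute_prostatitis": 15,
        "incomplete_imaging": 33,
        "severe_artifacts": 10,
    },
}

COHORT_COUNTS = {
    "primary_patients": 162,
    "primary_lesions": 224,
    "train_patients": 113,
    "test_patients": 49,
    "external_patients": 76,
    "external_lesions": 84,
    "pz_fraction": 99 / 224,
    "cspca_prevalence": {"PZ": 61 / 99, "TZ": 46 / 125},
    "external_lesions_per_patient": {1: 0.895, 2: 0.105},
}


def apply_exclusions(screened: int | None = None, exclusions: dict | None = None) -> dict:
    """Patient-selection arithmetic: screened minus per-reason exclusions.

    Returns a dict with the running total after each exclusion step and the
    final enrolled count.  Defaults reproduce the primary-cohort flow
    (245 screened -> 162 enrolled).
    """
    screened = ENROLLMENT["screened"] if screened is None else screened
    exclusions = dict(ENROLLMENT["exclusions"] if exclusions is None else exclusions)
    flow = {"screened": screened}
    remaining = screened
    for reason, n in exclusions.items():
        if n < 0 or n > remaining:
            raise ValueError(f"invalid exclusion count for {reason!r}: {n}")
        remaining -= n
        flow[f"after_{reason}"] = remaining
    flow["enrolled"] = remaining
    return flow
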