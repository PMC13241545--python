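import logging
import warnings

import numpy as np
import pytest

from mbdwi import models as M
from mbdwi.fitting import FitConfig, SignalDecay
from mbdwi.synthetic import CohortConfig, generate_cohort

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", category=FutureWarning)


#: csPCa-group median parameter sets of the published lesion summaries
CSPCA_PARAMS = {
    "MEM": M.MEMParams(1.0, 0.87),
    "SEM": M.SEMParams(1.0, 1.02, 0.69),
    "IVIM": M.IVIMParams(1.0, 0.81, 13.43, 0.16),
    "DKI": M.DKIParams(1.0, 1.18, 0.73),
    "IVIM_DKI": M.IVIMDKIParams(1.0, 0.92, 20.93, 0.18, 0.59),
    "CTRW": M.CTRWParams(1.0, 1.01, 0.83, 0.76),
    "FROC": M.FROCParams(1.0, 1.01, 0.75, 7.40),
}

NONCSPCA_PARAMS = {
    "MEM": M.MEMParams(1.0, 1.11),
    "SEM": M.SEMParams(1.0, 1.37, 0.70),
    "IVIM": M.IVIMParams(1.0, 1.03, 14.73, 0.19),
    "DKI": M.DKIParams(1.0, 1.52, 0.64),
    "IVIM_DKI": M.IVIMDKIParams(1.0, 1.25, 21.46, 0.19, 0.55),
    "CTRW": M.CTRWParams(1.0, 1.30, 0.92, 0.76),
    "FROC": M.FROCParams(1.0, 1.29, 0.76, 7.64),
}


def clean_decay(params, scheme=M.DEFAULT_SCHEME) -> SignalDecay:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", M.DkiValidityWarning)
        sig = M.signal(params, scheme.array)
    return SignalDecay(scheme, tuple(sig))


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()


@pytest.fixture(scope="session")
def planted_cohort():
    """162-patient cohort with effects planted on MEM_ADC and CTRW_alpha only."""
    return generate_cohort(
        CohortConfig(seed=11, effect_metrics=["MEM_ADC", "CTRW_alpha"]))


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Fully calibrated 162-patient cohort (every metric group-specific)."""
    return generate_cohort(CohortConfig(seed=7))
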