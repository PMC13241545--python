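"""Forward signal equations for seven multi-b-value diffusion MRI models.

The models describe the decay of the diffusion-weighted signal ``S(b)`` of
a voxel or ROI as the diffusion weighting ``b`` (s/mm²) increases:

=========  ===================================================  ==========================
family     signal equation                                      parameters (18 metrics)
=========  ===================================================  ==========================
MEM        ``S0 * exp(-b*ADC)``                                 MEM_ADC
SEM        ``S0 * exp(-(b*DDC)**alpha)``                        SEM_DDC, SEM_alpha
IVIM       ``S0 * [f*exp(-b*D*) + (1-f)*exp(-b*D)]``            IVIM_D, IVIM_Dstar, IVIM_f
DKI        ``S0 * exp(-b*D + (b*D)**2*K/6)``                    DKI_D, DKI_K
IVIM_DKI   ``S0 * [f*exp(-b*Dp) + (1-f)*exp(-b*D+(b*D)²K/6)]``  IVIM-DKI_{D,Dp,f,K}
CTRW       ``S0 * E_alpha(-(b*D)**beta)``                       CTRW_D, CTRW_alpha, CTRW_beta
FROC       ``S0 * exp(-D * mu**(2*(beta-1)) * b**beta)``        FROC_D, FROC_beta, FROC_mu
=========  ===================================================  ==========================

Diffusivities (``ADC, DDC, D, D*, Dp``) are stored in the reporting unit
x10⁻³ mm²/s throughout the package and converted to mm²/s inside the
forward evaluation, so ``b*D`` is dimensionless.  ``E_alpha`` is the
one-parameter Mittag-Leffler function (see :mod:`mbdwi.mittag`).  The
FROC heterogeneity length ``mu`` is reported numerically (~7.2-7.8 in
prostate); it is treated as micrometres and converted to mm so that the
``beta = 1`` limit reduces exactly to the mono-exponential model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mittag import mittag_leffler

__all__ = [
    "BValueScheme", "DEFAULT_SCHEME", "METRICS", "DkiValidityWarning",
    "MEMParams", "SEMParams", "IVIMParams", "DKIParams", "IVIMDKIParams",
    "CTRWParams", "FROCParams", "params_from_metrics", "FAMILIES",
    "mem_signal", "sem_signal", "ivim_signal", "dki_signal",
    "ivim_dki_signal", "ctrw_signal", "froc_signal", "signal",
]

#: the 18 quantitative metrics, named ModelName_ParameterName
METRICS = (
    "MEM_ADC",
    "SEM_DDC", "SEM_alpha",
    "IVIM_D", "IVIM_Dstar", "IVIM_f",
    "DKI_D", "DKI_K",
    "IVIM-DKI_D", "IVIM-DKI_Dp", "IVIM-DKI_f", "IVIM-DKI_K",
    "CTRW_D", "CTRW_alpha", "CTRW_beta",
    "FROC_D", "FROC_beta", "FROC_mu",
)

_UNIT = 1e-3   # reporting unit of diffusivities, mm²/s


class DkiValidityWarning(UserWarning):
    """Kurtosis signal requested beyond the validity range of the expansion."""


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion weightings (s/mm²) of an acquisition."""

    b_values: tuple[float, ...]

    def __post_init__(self):
        b = tuple(float(v) for v in self.b_values)
        object.__setattr__(self, "b_values", b)
        arr = np.asarray(b)
        if arr.size < 4:
            raise ValueError("a b-value scheme needs at least 4 values")
        if np.any(arr < 0):
            raise ValueError("b-values must be >= 0")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("b-values must be strictly increasing")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.b_values)

    @property
    def max_b(self) -> float:
        return self.b_values[-1]

    def supports_non_gaussian(self) -> bool:
        """High-b coverage (>= 2000 s/mm²) needed by the non-Gaussian models."""
        return self.max_b >= 2000.0

    def subset(self, b_max: float | None = None, b_min: float = 0.0) -> "BValueScheme":
        keep = [b for b in self.b_values if b >= b_min and (b_max is None or b <= b_max)]
        return BValueScheme(tuple(keep))


#: 12-point scheme spanning 0-3000 s/mm² (configurable; high b >= 2000
#: required by the non-Gaussian families)
DEFAULT_SCHEME = BValueScheme((0, 50, 100, 150, 200, 500, 800, 1000, 1500, 2000, 2500, 3000))


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class MEMParams:
    """Mono-exponential (Gaussian) model: ADC in x10⁻³ mm²/s."""
    s0: float
    adc: float
    family = "MEM"

    def __post_init__(self):
        _check(self.s0 > 0, "s0 must be > 0")
        _check(self.adc > 0, "ADC must be > 0")


@dataclass(frozen=True)
class SEMParams:
    """Stretched-exponential model: DDC (x10⁻³ mm²/s), heterogeneity alpha."""
    s0: float
    ddc: float
    alpha: float
    family = "SEM"

    def __post_init__(self):
        _check(self.s0 > 0, "s0 must be > 0")
        _check(self.ddc > 0, "DDC must be > 0")
        _check(0 < self.alpha <= 1, "alpha must be in (0, 1]")


@dataclass(frozen=True)
class IVIMParams:
    """Bi-exponential IVIM: tissue D, pseudo-diffusion D*, perfusion fraction f."""
    s0: float
    d: float
    dstar: float
    f: float
    family = "IVIM"

    def __post_init__(self):
        _check(self.s0 > 0, "s0 must be > 0")
        _check(self.d > 0, "D must be > 0")
        _check(0 <= self.f < 1, "f must be in [0, 1)")
        _check(self.dstar > self.d, "D* must exceed D")


@dataclass(frozen=True)
class DKIParams:
    """Kurtosis model: D (x10⁻³ mm²/s) and excess kurtosis K >= 0."""
    s0: float
    d: float
    k: float
    family = "DKI"

    def __post_init__(self):
        _check(self.s0 > 0, "s0 must be > 0")
        _check(self.d > 0, "D must be > 0")
        _check(self.k >= 0, "K must be >= 0")


@dataclass(frozen=True)
class IVIMDKIParams:
    """Hybrid IVIM-DKI: perfusion compartment plus kurtosis tissue decay."""
    s0: float
    d: float
    dp: float
    f: float
    k: float
    family = "IVIM_DKI"

    def __post_init__(self):
        _check(self.s0 > 0, "s0 must be > 0")
        _check(self.d > 0, "D must be > 0")
        _check(0 <= self.f < 1, "f must be in [0, 1)")
        _check(self.dp > self.d, "Dp must exceed D")
        _check(self.k >= 0, "K must be >= 0")


@dataclass(frozen=True)
class CTRWParams:
    """Continuous-time random walk: D, temporal alpha, spatial beta."""
    s0: float
    d: float
    alpha: float
    beta: float
    family = "CTRW"

    def __post_init__(self):
        _check(self.s0 > 0, "s0 must be > 0")
        _check(self.d > 0, "D must be > 0")
        _check(0 < self.alpha <= 1, "alpha must be in (0, 1]")
        _check(0 < self.beta <= 1, "beta must be in (0, 1]")


@dataclass(frozen=True)
class FROCParams:
    """Fractional-order-calculus model: D, order beta, spatial constant mu (μm)."""
    s0: float
    d: float
    beta: float
    mu: float
    family = "FROC"

    def __post_init__(self):
        _check(self.s0 > 0, "s0 must be > 0")
        _check(self.d > 0, "D must be > 0")
        _check(0 < self.beta <= 1, "beta must be in (0, 1]")
        _check(self.mu > 0, "mu must be > 0")


FAMILIES = ("MEM", "SEM", "IVIM", "DKI", "IVIM_DKI", "CTRW", "FROC")

_PARAM_CLASSES = {
    "MEM": MEMParams, "SEM": SEMParams, "IVIM": IVIMParams, "DKI": DKIParams,
    "IVIM_DKI": IVIMDKIParams, "CTRW": CTRWParams, "FROC": FROCParams,
}

#: metric name for each (family, field) pair; the union enumerates METRICS
FAMILY_METRICS = {
    "MEM": {"adc": "MEM_ADC"},
    "SEM": {"ddc": "SEM_DDC", "alpha": "SEM_alpha"},
    "IVIM": {"d": "IVIM_D", "dstar": "IVIM_Dstar", "f": "IVIM_f"},
    "DKI": {"d": "DKI_D", "k": "DKI_K"},
    "IVIM_DKI": {"d": "IVIM-DKI_D", "dp": "IVIM-DKI_Dp", "f": "IVIM-DKI_f", "k": "IVIM-DKI_K"},
    "CTRW": {"d": "CTRW_D", "alpha": "CTRW_alpha", "beta": "CTRW_beta"},
    "FROC": {"d": "FROC_D", "beta": "FROC_beta", "mu": "FROC_mu"},
}


def params_from_metrics(family: str, metrics: dict, s0: float = 1.0):
    """Build the parameter set of one family from a named 18-metric mapping."""
    mapping = FAMILY_METRICS[family]
    kwargs = {field: metrics[name] for field, name in mapping.items()}
    return _PARAM_CLASSES[family](s0=s0, **kwargs)


def metrics_from_params(params) -> dict:
    """Named metric values of a parameter set (inverse of params_from_metrics)."""
    mapping = FAMILY_METRICS[params.family]
    return {name: getattr(params, field) for field, name in mapping.items()}


def _b(b) -> np.ndarray:
    arr = np.asarray(b, dtype=float)
    if np.any(arr < 0):
        raise ValueError("b must be >= 0")
    return arr


def mem_signal(params: MEMParams, b):
    """Mono-exponential decay ``S0 * exp(-b*ADC)``."""
    return params.s0 * np.exp(-_b(b) * params.adc * _UNIT)


def sem_signal(params: SEMParams, b):
    """Stretched-exponential decay; reduces to MEM at alpha = 1."""
    return params.s0 * np.exp(-((_b(b) * params.ddc * _UNIT) ** params.alpha))


def ivim_signal(params: IVIMParams, b):
    """Bi-exponential perfusion + diffusion decay; reduces to MEM at f = 0."""
    barr = _b(b)
    return params.s0 * (
        params.f * np.exp(-barr * params.dstar * _UNIT)
        + (1.0 - params.f) * np.exp(-barr * params.d * _UNIT)
    )


def _kurtosis_exponent(b: np.ndarray, d_rep: float, k: float) -> np.ndarray:
    bd = b * d_rep * _UNIT
    return -bd + bd * bd * k / 6.0


def dki_signal(params: DKIParams, b, b_max_dki: float = 2000.0):
    """Kurtosis decay; the quadratic expansion is only valid up to ``b_max_dki``.

    Beyond that limit a :class:`DkiValidityWarning` is emitted (the value is
    still returned, flagged rather than raised, so map pipelines can decide).
    """
    barr = _b(b)
    if np.any(barr > b_max_dki):
        warnings.warn(
            f"DKI signal evaluated beyond its validity range (b > {b_max_dki:g} s/mm²)",
            DkiValidityWarning, stacklevel=2,
        )
    return params.s0 * np.exp(_kurtosis_exponent(barr, params.d, params.k))


def ivim_dki_signal(params: IVIMDKIParams, b, b_max_dki: float = 2000.0):
    """Hybrid decay: perfusion exponential plus kurtosis tissue compartment."""
    barr = _b(b)
    if np.any(barr > b_max_dki):
        warnings.warn(
            f"IVIM-DKI signal evaluated beyond its validity range (b > {b_max_dki:g} s/mm²)",
            DkiValidityWarning, stacklevel=2,
        )
    return params.s0 * (
        params.f * np.exp(-barr * params.dp * _UNIT)
        + (1.0 - params.f) * np.exp(_kurtosis_exponent(barr, params.d, params.k))
    )


def ctrw_signal(params: CTRWParams, b, check: bool = False):
    """CTRW decay through the Mittag-Leffler function.

    Reduces to SEM for alpha = 1 (with DDC = D and SEM alpha = beta) and to
    MEM for alpha = beta = 1.  ``check=True`` turns on the quadrature
    self-certification of the Mittag-Leffler evaluation.
    """
    z = -((_b(b) * params.d * _UNIT) ** params.beta)
    return params.s0 * mittag_leffler(params.alpha, z, check=check)


def froc_signal(params: FROCParams, b):
    """Simplified fractional-order-calculus decay.

    ``S0 * exp(-D * mu**(2*(beta-1)) * b**beta)`` with D in mm²/s and mu
    (μm) converted to mm; at beta = 1 the mu factor vanishes and the decay
    is mono-exponential.
    """
    barr = _b(b)
    mu_mm = params.mu * 1e-3
    expo = params.d * _UNIT * mu_mm ** (2.0 * (params.beta - 1.0)) * barr ** params.beta
    return params.s0 * np.exp(-expo)


_SIGNALS = {
    "MEM": mem_signal, "SEM": sem_signal, "IVIM": ivim_signal, "DKI": dki_signal,
    "IVIM_DKI": ivim_dki_signal, "CTRW": ctrw_signal, "FROC": froc_signal,
}


def signal(params, b, **kwargs):
    """Dispatch the forward model of ``params.family``."""
    return _SIGNALS[params.family](params, b, **kwargs)
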