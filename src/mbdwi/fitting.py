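"""Constrained nonlinear least-squares estimation of the diffusion models.

Each lesion (or voxel) contributes one multi-b-value signal decay; every
model family is fitted independently by trust-region-reflective least
squares inside physiological bounds, with a deterministic Latin-hypercube
multi-start to avoid local minima.  The mono-exponential ADC has a closed
form (weighted log-linear regression) and is never iterated.

Fitting one decay with all seven families yields the named 18-metric
feature vector used by the downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import models as M
from .models import BValueScheme, METRICS

__all__ = [
    "SignalDecay", "FitConfig", "FitResult", "MultiModelFit",
    "fit_mem", "fit_model", "fit_ivim_segmented", "fit_all_models",
    "roi_aggregate", "DEFAULT_BOUNDS",
]

#: default parameter bounds in reporting units
DEFAULT_BOUNDS = {
    "d": (0.05, 4.0),        # tissue diffusivity, x10⁻³ mm²/s
    "dstar": (3.0, 100.0),   # pseudo-diffusion
    "dp": (3.0, 100.0),
    "f": (0.0, 0.5),
    "alpha": (0.1, 1.0),
    "ddc": (0.05, 4.0),
    "beta": (0.1, 1.0),
    "k": (0.0, 3.0),
    "mu": (1.0, 20.0),
    "adc": (0.0, 4.0),
}

#: free parameters per family, in optimisation order (s0 is always first)
_FAMILY_FIELDS = {
    "MEM": ("adc",),
    "SEM": ("ddc", "alpha"),
    "IVIM": ("d", "dstar", "f"),
    "DKI": ("d", "k"),
    "IVIM_DKI": ("d", "dp", "f", "k"),
    "CTRW": ("d", "alpha", "beta"),
    "FROC": ("d", "beta", "mu"),
}

#: families whose information lives at high b; they are not fitted when the
#: scheme stops short of 2000 s/mm²
_HIGH_B_FAMILIES = frozenset({"SEM", "DKI", "IVIM_DKI", "CTRW", "FROC"})


@dataclass(frozen=True)
class SignalDecay:
    """Observed intensities over a b-value scheme (arbitrary units)."""

    scheme: BValueScheme
    signal: tuple[float, ...]

    def __post_init__(self):
        sig = tuple(float(v) for v in self.signal)
        object.__setattr__(self, "signal", sig)
        arr = np.asarray(sig)
        if arr.size != len(self.scheme.b_values):
            raise ValueError("signal length must match the b-value scheme")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("signal intensities must be positive and finite")

    @property
    def b(self) -> np.ndarray:
        return self.scheme.array

    @property
    def s(self) -> np.ndarray:
        return np.asarray(self.signal)

    def restrict(self, b_max: float | None = None) -> "SignalDecay":
        if b_max is None:
            return self
        keep = self.b <= b_max
        return SignalDecay(BValueScheme(tuple(self.b[keep])), tuple(self.s[keep]))


def _default_subsets() -> dict:
    # IVIM is perfusion-sensitive: restrict to b <= 1000 (includes all b < 200);
    # the kurtosis expansion is trusted to b <= 2000; the rest use the full scheme.
    return {"IVIM": 1000.0, "DKI": 2000.0, "IVIM_DKI": 2000.0}


@dataclass(frozen=True)
class FitConfig:
    """Settings shared by all model fits.

    ``b_subsets`` maps a family to the maximum b-value it is fitted on
    (None = full scheme).  ``n_starts`` Latin-hypercube restarts are run
    from a fixed ``seed`` so results are reproducible bit for bit.
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    b_subsets: dict = field(default_factory=_default_subsets)
    n_starts: int = 5
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-12
    ivim_strategy: str = "segmented"   # {"segmented", "joint"}
    b_split: float = 200.0             # perfusion/diffusion separation point
    b_max_dki: float = 2000.0
    # identification convention for the simplified FROC form: with b-value
    # data alone only D*mu**(2*(beta-1)) is identifiable, so mu is held at a
    # fixed reference (μm; 7.4 is the typical prostate value).  Set to None
    # for the free - degenerate - 4-parameter fit.
    froc_mu_fixed: float | None = 7.4
    # magnitude-MRI noise floor: for the listed families the NLS model
    # predicts the Rician magnitude moment sqrt(S² + (pi/2)·sigma_n²) with
    # the noise sd sigma_n fitted as an extra bounded parameter.  Useful for
    # families whose decay drops below the noise floor at high b (FROC at
    # prostate-typical parameters); superfluous freedom destabilises the
    # others, so it is opt-in per family.
    rician_floor: tuple = ()

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")
        if self.ivim_strategy not in ("segmented", "joint"):
            raise ValueError("ivim_strategy must be 'segmented' or 'joint'")


@dataclass(frozen=True)
class FitResult:
    """One family's fit: parameters, residual, and convergence bookkeeping."""

    params: object
    rss: float
    converged: bool
    n_iter: int
    at_bound: dict
    note: str = ""

    @property
    def metrics(self) -> dict:
        return M.metrics_from_params(self.params)


@dataclass(frozen=True)
class MultiModelFit:
    """All seven families fitted to one decay: the 18-metric vector."""

    results: dict                     # family -> FitResult (may be missing)
    notes: dict                       # family -> reason when absent/failed

    @property
    def metrics(self) -> dict:
        out = {name: np.nan for name in METRICS}
        for fam, res in self.results.items():
            if res is not None and res.converged:
                out.update(res.metrics)
        return out

    @property
    def converged(self) -> dict:
        return {
            fam: (res is not None and res.converged)
            for fam, res in self.results.items()
        }


def _loglinear(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Weighted linear regression of log-signal on b (weights s²).

    Weighting by the squared signal makes the log-domain fit agree with the
    original-domain least squares to first order.  Returns (slope, intercept).
    """
    y = np.log(s)
    w = s * s
    wsum = w.sum()
    bw = (w * b).sum() / wsum
    yw = (w * y).sum() / wsum
    var = (w * (b - bw) ** 2).sum()
    if var == 0:
        return 0.0, float(yw)
    slope = float((w * (b - bw) * (y - yw)).sum() / var)
    return slope, float(yw - slope * bw)


def fit_mem(decay: SignalDecay, config: FitConfig | None = None) -> FitResult:
    """Closed-form mono-exponential ADC (weighted log-linear regression)."""
    b, s = decay.b, decay.s
    if len(np.unique(b)) < 2:
        raise ValueError("ADC estimation needs at least 2 distinct b-values")
    slope, intercept = _loglinear(b, s)
    adc = -slope * 1e3        # slope is -ADC in mm²/s; report x10⁻³ mm²/s
    at_bound = {"adc": adc <= 0.0}
    adc = max(adc, 1e-12)     # clipped at (numerically) zero
    params = M.MEMParams(s0=float(np.exp(intercept)), adc=adc)
    rss = float(((M.mem_signal(params, b) - s) ** 2).sum())
    return FitResult(params=params, rss=rss, converged=True, n_iter=0, at_bound=at_bound)


def _auto_start(fields: tuple, decay: SignalDecay, bounds: dict) -> np.ndarray:
    """Heuristic initial point: log-linear ADC for diffusivities, literature
    mid-range values for shape parameters."""
    b, s = decay.b, decay.s
    s0 = float(s[b.argmin()])
    high = b >= 200
    if high.sum() >= 2:
        slope, _ = _loglinear(b[high], s[high])
        d0 = float(np.clip(-slope * 1e3, *bounds["d"]))
    else:
        d0 = 1.0
    defaults = {
        "d": d0, "ddc": d0, "adc": d0, "dstar": 15.0, "dp": 20.0,
        "f": 0.15, "alpha": 0.8, "beta": 0.8, "k": 0.7, "mu": 7.5,
    }
    start = [s0] + [
        float(np.clip(defaults[name], bounds[name][0] + 1e-9, bounds[name][1] - 1e-9))
        for name in fields
    ]
    return np.asarray(start)


def _free_bounds(fields: tuple, decay: SignalDecay, config: FitConfig):
    s0_est = float(decay.s.max())
    lo = [0.05 * s0_est]
    hi = [3.0 * s0_est]
    for name in fields:
        b_lo, b_hi = config.bounds[name]
        lo.append(b_lo)
        hi.append(b_hi)
    return np.asarray(lo), np.asarray(hi)


def _build_params_kw(family: str, s0: float, kwargs: dict):
    note = ""
    # enforce the pseudo-diffusion > tissue-diffusion invariant defensively
    for fast in ("dstar", "dp"):
        if fast in kwargs and kwargs[fast] <= kwargs.get("d", -np.inf):
            kwargs[fast] = kwargs["d"] * (1.0 + 1e-6)
            note = f"{fast} clipped above d"
    cls = M._PARAM_CLASSES[family]
    return cls(s0=s0, **{k: float(v) for k, v in kwargs.items()}), note


def _residual_fn(family: str, fields: tuple, fixed: dict,
                 b: np.ndarray, s: np.ndarray, rician_floor: bool = False):
    _HALF_PI = np.pi / 2.0

    def clean(theta):
        kwargs = dict(zip(fields, theta[1:1 + len(fields)]))
        kwargs.update(fixed)
        params, _ = _build_params_kw(family, float(theta[0]), kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", M.DkiValidityWarning)
            return M.signal(params, b)

    if family == "CTRW":
        from .mittag import mittag_leffler

        def clean(theta):  # noqa: F811 - fast path avoiding object construction
            s0, d, alpha, beta = theta[:4]
            z = -((b * d * 1e-3) ** beta)
            return s0 * mittag_leffler(alpha, z, check=False)

    if rician_floor:
        def resid(theta):
            base = clean(theta)
            sigma_n = theta[-1]
            return np.sqrt(base * base + _HALF_PI * sigma_n * sigma_n) - s
        return resid

    def resid(theta):
        return clean(theta) - s
    return resid


def fit_model(decay: SignalDecay, family: str, config: FitConfig | None = None) -> FitResult:
    """Fit one family by bounded NLS with deterministic multi-start.

    The decay is restricted to the family's configured b-subset.  Multi-start
    candidates are ranked by residual sum of squares with a lexicographic
    tie-break so the result is a pure function of (decay, config).
    """
    config = config or FitConfig()
    if family not in _FAMILY_FIELDS:
        raise ValueError(f"unknown model family {family!r}")
    if family == "MEM":
        return fit_mem(decay, config)
    if family == "IVIM" and config.ivim_strategy == "segmented":
        return fit_ivim_segmented(decay, config)
    if family == "IVIM_DKI" and config.ivim_strategy == "segmented":
        return fit_ivim_dki_segmented(decay, config)
    fixed = {}
    if family == "FROC" and config.froc_mu_fixed is not None:
        fixed["mu"] = float(config.froc_mu_fixed)
    return _fit_nls(decay, family, config, fixed)


def _fit_nls(decay: SignalDecay, family: str, config: FitConfig,
             fixed: dict | None = None) -> FitResult:
    fixed = fixed or {}
    sub = decay.restrict(config.b_subsets.get(family))
    fields = tuple(f for f in _FAMILY_FIELDS[family] if f not in fixed)
    use_floor = family in config.rician_floor
    n_free = 1 + len(fields) + int(use_floor)
    if len(sub.b) < n_free + 1:
        raise ValueError(
            f"{family}: {len(sub.b)} b-values cannot constrain {n_free} parameters"
        )
    b, s = sub.b, sub.s
    lo, hi = _free_bounds(fields, sub, config)
    s0_est = float(sub.s.max())
    if use_floor:
        lo = np.append(lo, 0.0)
        hi = np.append(hi, 0.3 * s0_est)
    resid = _residual_fn(family, fields, fixed, b, s, rician_floor=use_floor)

    auto = _auto_start(fields, sub, config.bounds)
    if use_floor:
        auto = np.append(auto, 0.02 * s0_est)
    starts = [auto]
    if config.n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(lo), seed=config.seed)
        extra = qmc.scale(sampler.random(config.n_starts - 1), lo, hi)
        starts.extend(np.clip(extra, lo + 1e-12, hi - 1e-12))

    candidates = []
    for x0 in starts:
        try:
            sol = least_squares(
                resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                xtol=config.tol, ftol=config.tol, gtol=config.tol,
                max_nfev=config.max_iter,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if np.isfinite(rss):
            candidates.append((rss, tuple(np.round(sol.x, 12)), sol))
    if not candidates:
        raise RuntimeError(f"{family}: all optimisation starts failed")
    # lowest RSS wins; ties within 1e-12 broken by parameter lexicographic order
    rss_min = min(c[0] for c in candidates)
    rss, _, sol = min((c for c in candidates if c[0] <= rss_min + 1e-12),
                      key=lambda c: c[1])
    kwargs = dict(zip(fields, sol.x[1:]))
    kwargs.update(fixed)
    params, note = _build_params_kw(family, float(sol.x[0]), kwargs)
    tol = 1e-6
    names = ("s0",) + fields
    at_bound = {
        name: bool(sol.x[i] - lo[i] <= tol * (hi[i] - lo[i])
                   or hi[i] - sol.x[i] <= tol * (hi[i] - lo[i]))
        for i, name in enumerate(names)
    }
    at_bound.update({name: False for name in fixed})
    converged = bool(sol.status > 0 and np.isfinite(rss))
    return FitResult(params=params, rss=rss, converged=converged,
                     n_iter=int(sol.nfev), at_bound=at_bound, note=note)


def fit_ivim_segmented(decay: SignalDecay, config: FitConfig | None = None) -> FitResult:
    """Two-step IVIM: D from the high-b mono-exponential tail (b >= b_split),
    then f and D* with D held fixed on the full (subset) range.

    Falls back to the joint fit when fewer than 3 b-values lie above the
    split point.
    """
    config = config or FitConfig()
    sub = decay.restrict(config.b_subsets.get("IVIM"))
    b, s = sub.b, sub.s
    high = b >= config.b_split
    if high.sum() < 3:
        warnings.warn("too few b-values above b_split; falling back to joint IVIM fit")
        return _fit_nls(decay, "IVIM", replace(config, ivim_strategy="joint"))

    lo_f, hi_f = config.bounds["f"]
    lo_ds, hi_ds = config.bounds["dstar"]
    s0_est = float(s.max())

    slope, intercept = _loglinear(b[high], s[high])
    d_fix = float(np.clip(-slope * 1e3, *config.bounds["d"]))
    # initial f from the perfusion excess of the b=0 intercept
    f0 = float(np.clip(1.0 - np.exp(intercept) / s0_est, lo_f + 1e-6, hi_f - 1e-6))
    theta = np.array([s0_est, f0, 15.0])

    # alternate: (f, D*, S0) with D fixed, then D on the perfusion-subtracted
    # tail; the perfusion contamination of the high-b log-linear slope decays
    # geometrically over the passes
    sol = None
    for _ in range(3):
        def resid(th, d_fix=d_fix):
            s0, f, dstar = th
            return s0 * (f * np.exp(-b * dstar * 1e-3)
                         + (1.0 - f) * np.exp(-b * d_fix * 1e-3)) - s

        sol = least_squares(
            resid, x0=np.clip(theta, [0.05 * s0_est, lo_f, max(lo_ds, d_fix * (1 + 1e-6))],
                              [3.0 * s0_est, hi_f, hi_ds]),
            bounds=([0.05 * s0_est, lo_f, max(lo_ds, d_fix * (1 + 1e-6))],
                    [3.0 * s0_est, hi_f, hi_ds]),
            method="trf", xtol=config.tol, ftol=config.tol, gtol=config.tol,
            max_nfev=config.max_iter,
        )
        theta = sol.x
        s0_i, f_i, dstar_i = theta
        perf = s0_i * f_i * np.exp(-b[high] * dstar_i * 1e-3)
        tail = np.maximum(s[high] - perf, 1e-12 * s0_est)
        slope, _ = _loglinear(b[high], tail)
        d_fix = float(np.clip(-slope * 1e3, *config.bounds["d"]))

    s0, f, dstar = sol.x
    params = M.IVIMParams(s0=float(s0), d=d_fix, dstar=float(dstar), f=float(f))
    rss = float(2.0 * sol.cost)
    at_bound = {
        "d": d_fix in config.bounds["d"],
        "f": bool(f - lo_f <= 1e-6 or hi_f - f <= 1e-6),
        "dstar": bool(hi_ds - dstar <= 1e-4),
    }
    return FitResult(params=params, rss=rss, converged=bool(sol.status > 0),
                     n_iter=int(sol.nfev), at_bound=at_bound)


def fit_ivim_dki_segmented(decay: SignalDecay, config: FitConfig | None = None) -> FitResult:
    """Two-step hybrid fit: tissue (D, K) from the perfusion-free range
    b >= b_split, then (S0, f, Dp) with the tissue decay fixed.

    Decoupling the kurtosis curvature from the perfusion fraction removes
    the K ~ 0 collapse mode of the joint 5-parameter fit under noise.
    Iterated with perfusion subtraction like the segmented IVIM fit.
    """
    config = config or FitConfig()
    sub = decay.restrict(config.b_subsets.get("IVIM_DKI"))
    b, s = sub.b, sub.s
    high = b >= config.b_split
    if high.sum() < 4:
        return _fit_nls(decay, "IVIM_DKI", replace(config, ivim_strategy="joint"))
    lo_f, hi_f = config.bounds["f"]
    lo_dp, hi_dp = config.bounds["dp"]
    lo_d, hi_d = config.bounds["d"]
    lo_k, hi_k = config.bounds["k"]
    s0_est = float(s.max())

    tissue = s.copy()
    d_fix, k_fix = 1.0, 0.7
    theta2 = np.array([s0_est, 0.15, 20.0])
    sol = None
    for _ in range(3):
        def resid_t(th):
            s0t, d, k = th
            bd = b[high] * d * 1e-3
            return s0t * np.exp(-bd + bd * bd * k / 6.0) - tissue[high]

        sol_t = least_squares(
            resid_t, x0=[s0_est, d_fix, k_fix],
            bounds=([0.05 * s0_est, lo_d, lo_k], [3.0 * s0_est, hi_d, hi_k]),
            method="trf", xtol=config.tol, ftol=config.tol, gtol=config.tol,
            max_nfev=config.max_iter)
        _, d_fix, k_fix = sol_t.x

        def resid_p(th, d=d_fix, k=k_fix):
            s0, f, dp = th
            bd = b * d * 1e-3
            return s0 * (f * np.exp(-b * dp * 1e-3)
                         + (1 - f) * np.exp(-bd + bd * bd * k / 6.0)) - s

        sol = least_squares(
            resid_p, x0=np.clip(theta2,
                                [0.05 * s0_est, lo_f, max(lo_dp, d_fix * (1 + 1e-6))],
                                [3.0 * s0_est, hi_f, hi_dp]),
            bounds=([0.05 * s0_est, lo_f, max(lo_dp, d_fix * (1 + 1e-6))],
                    [3.0 * s0_est, hi_f, hi_dp]),
            method="trf", xtol=config.tol, ftol=config.tol, gtol=config.tol,
            max_nfev=config.max_iter)
        theta2 = sol.x
        s0_i, f_i, dp_i = theta2
        tissue = s - s0_i * f_i * np.exp(-b * dp_i * 1e-3)
        tissue = np.maximum(tissue, 1e-12 * s0_est)

    s0, f, dp = sol.x
    params = M.IVIMDKIParams(s0=float(s0), d=float(d_fix), dp=float(dp),
                             f=float(f), k=float(k_fix))
    rss = float(2.0 * sol.cost)
    at_bound = {
        "d": bool(abs(d_fix - lo_d) < 1e-9 or abs(d_fix - hi_d) < 1e-9),
        "k": bool(abs(k_fix - lo_k) < 1e-9 or abs(k_fix - hi_k) < 1e-9),
        "f": bool(f - lo_f <= 1e-6 or hi_f - f <= 1e-6),
        "dp": bool(hi_dp - dp <= 1e-4),
    }
    return FitResult(params=params, rss=rss,
                     converged=bool(sol.status > 0 and sol_t.status > 0),
                     n_iter=int(sol.nfev + sol_t.nfev), at_bound=at_bound)


def fit_all_models(decay: SignalDecay, config: FitConfig | None = None) -> MultiModelFit:
    """Fit the seven families, producing the named 18-metric vector.

    Families whose required b-range or parameter count is not supported by
    the scheme are skipped with an explanatory note (their metrics are NaN);
    a non-convergent family is flagged the same way rather than silently
    returning values.
    """
    config = config or FitConfig()
    results, notes = {}, {}
    has_high_b = decay.scheme.supports_non_gaussian()
    for family in M.FAMILIES:
        if family in _HIGH_B_FAMILIES and not has_high_b:
            results[family] = None
            notes[family] = "scheme lacks b >= 2000 s/mm²"
            continue
        try:
            res = fit_model(decay, family, config)
        except ValueError as exc:
            results[family] = None
            notes[family] = str(exc)
            continue
        results[family] = res
        if not res.converged:
            notes[family] = "did not converge"
    return MultiModelFit(results=results, notes=notes)


def roi_aggregate(voxel_metrics, reducer=np.mean) -> dict:
    """Aggregate voxel-level 18-metric vectors over an ROI.

    ``voxel_metrics`` is a sequence of metric dicts (NaN = non-converged
    voxel).  Each metric is reduced over its converged voxels only; the
    per-metric voxel count used is reported alongside.
    """
    items = list(voxel_metrics)
    if not items:
        raise ValueError("empty ROI")
    keys = set(items[0])
    for it in items[1:]:
        if set(it) != keys:
            raise ValueError("all voxel vectors must share the same metrics")
    out, n_used = {}, {}
    for key in keys:
        vals = np.asarray([it[key] for it in items], dtype=float)
        ok = np.isfinite(vals)
        n_used[key] = int(ok.sum())
        out[key] = float(reducer(vals[ok])) if ok.any() else np.nan
    return {"metrics": out, "n_voxels": n_used}
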