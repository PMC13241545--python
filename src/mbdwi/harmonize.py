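"""ComBat batch harmonization and the cross-vendor validation workflow.

Scanner vendors imprint additive and multiplicative (location/scale)
effects on quantitative diffusion metrics.  ComBat models each feature as

    x_gij = alpha_g + X_j beta_g + gamma_gi + delta_gi * eps_gij

(feature g, batch i, sample j) and removes the batch location ``gamma``
and scale ``delta`` while preserving the biological covariates ``X``
(here: pathology group and zone).  With the parametric empirical-Bayes
option the per-feature batch estimates are shrunk toward their across-
feature prior (normal prior for gamma, inverse-gamma for delta²), which
stabilises small batches; ``eb=False`` gives plain per-feature
location/scale alignment (exactly idempotent).

No reference batch is designated: both vendors are shrunk toward the
pooled mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import METRICS
from .stats import decision_curve, prepare_design, roc_metrics
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "HarmonizationSpec", "combat_harmonize", "cross_vendor_consistency_check",
    "external_validate",
]


@dataclass(frozen=True)
class HarmonizationSpec:
    """Configuration of a ComBat run.

    ``covariates`` are biological columns whose signal must survive
    harmonization (binary/numeric, e.g. csPCa status and the TZ
    indicator); ``eb`` toggles parametric empirical-Bayes shrinkage.
    """

    batch_col: str = "vendor"
    covariates: tuple = ("cspca",)
    metrics: tuple = tuple(METRICS)
    eb: bool = True
    # pooled residual-variance divisor: "pooled" divides by N (the reference
    # ComBat convention) and is idempotent only to O(1/N); "unbiased" divides
    # by N - rank(design), making the no-EB, no-covariate pass exactly
    # idempotent
    sigma_df: str = "pooled"

    def __post_init__(self):
        if self.sigma_df not in ("pooled", "unbiased"):
            raise ValueError("sigma_df must be 'pooled' or 'unbiased'")


def _design_matrix(table: pd.DataFrame, spec: HarmonizationSpec):
    batches = np.sort(table[spec.batch_col].astype(str).unique())
    if len(batches) < 2:
        return batches, None, None
    B = np.stack([(table[spec.batch_col].astype(str) == b).to_numpy(float)
                  for b in batches], axis=1)
    C_cols = list(spec.covariates)
    C = table[C_cols].astype(float).to_numpy() if C_cols else np.empty((len(table), 0))
    Z = np.concatenate([B, C], axis=1)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify the offending covariates for the error message
        bad = []
        base = np.linalg.matrix_rank(B)
        for j, col in enumerate(C_cols):
            sub = np.concatenate([B, C[:, : j + 1]], axis=1)
            r = np.linalg.matrix_rank(sub)
            if r <= base:
                bad.append(col)
            base = r
        raise ValueError(f"singular harmonization design; collinear columns: {bad or C_cols}")
    return batches, B, Z


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return float((2 * s2 + m * m) / s2)


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return float((m * s2 + m ** 3) / s2)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-6, max_iter=500):
    """Iterative EB solution for one batch (features vectorised)."""
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ssq = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(ssq, n, a, b)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_harmonize(table: pd.DataFrame, spec: HarmonizationSpec | None = None,
                     return_estimates: bool = False):
    """Remove batch location/scale effects from the metric columns.

    A single-batch table is returned unchanged.  Each batch must contain
    at least 2 observations.  Output units equal input units; biological
    covariate effects are estimated on the pooled data and restored after
    adjustment.  With ``return_estimates=True`` a ``(table, audit)`` pair
    is returned, where the audit maps each batch to its estimated
    (gamma*, delta*) per metric.
    """
    spec = spec or HarmonizationSpec()
    metrics = list(spec.metrics)
    for m in metrics:
        if m not in table.columns:
            raise KeyError(f"metric column {m!r} not in table")
    batches, B, Z = _design_matrix(table, spec)
    out = table.copy()
    if B is None:
        log.info("single batch: harmonization is the identity")
        return (out, {}) if return_estimates else out
    sizes = B.sum(axis=0)
    if np.any(sizes < 2):
        raise ValueError("every batch needs at least 2 observations")

    X = out[metrics].to_numpy(float).T          # G x N
    n_batch = len(batches)
    beta, *_ = np.linalg.lstsq(Z, X.T, rcond=None)   # (I+P) x G
    grand = (sizes / sizes.sum()) @ beta[:n_batch]   # weighted grand mean, per feature
    resid = X.T - Z @ beta
    denom = len(table) if spec.sigma_df == "pooled" else len(table) - Z.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / denom
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))

    cov_effect = Z[:, n_batch:] @ beta[n_batch:]     # N x G biological signal
    stand_mean = grand[None, :] + cov_effect
    Zdata = ((X.T - stand_mean) / sigma[None, :]).T  # G x N standardized

    audit = {}
    adjusted = Zdata.copy()
    for i, b in enumerate(batches):
        mask = B[:, i] == 1
        z_b = Zdata[:, mask]
        g_hat = z_b.mean(axis=1)
        d_hat = z_b.var(axis=1, ddof=1)
        if spec.eb and len(metrics) > 1:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, bp = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _it_sol(z_b, g_hat, d_hat, g_bar, t2, a, bp)
        else:
            g_star, d_star = g_hat, d_hat
        d_star = np.maximum(d_star, 1e-300)
        adjusted[:, mask] = (z_b - g_star[:, None]) / np.sqrt(d_star)[:, None]
        audit[str(b)] = pd.DataFrame(
            {"gamma_star": g_star, "delta_star": np.sqrt(d_star)}, index=metrics)

    restored = (adjusted.T * sigma[None, :] + stand_mean).T
    out.loc[:, metrics] = restored.T
    return (out, audit) if return_estimates else out


def cross_vendor_consistency_check(primary: pd.DataFrame, validation: pd.DataFrame,
                                   metrics=tuple(METRICS),
                                   group_col: str = "cspca") -> pd.DataFrame:
    """Mann-Whitney comparison of each metric across vendors within each
    pathology group (run after harmonization).

    A metric is consistent when no pathology group shows a significant
    vendor difference (min p > 0.05).  Empty groups are skipped with a
    log entry.
    """
    rows = []
    groups = np.sort(pd.concat([primary[group_col], validation[group_col]]).unique())
    for m in metrics:
        ps = {}
        for g in groups:
            a = primary.loc[primary[group_col] == g, m].dropna()
            b = validation.loc[validation[group_col] == g, m].dropna()
            if len(a) == 0 or len(b) == 0:
                log.warning("consistency check: group %r empty for %s; skipped", g, m)
                continue
            _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            ps[f"p_group{g}"] = float(p)
        row = {"metric": m, **ps}
        row["min_p"] = min(ps.values()) if ps else np.nan
        row["consistent"] = bool(row["min_p"] > 0.05) if ps else False
        rows.append(row)
    return pd.DataFrame(rows)


def external_validate(models: dict, external: pd.DataFrame,
                      outcome: str = "cspca", n_boot: int = 2000,
                      seed: int = 0) -> dict:
    """Apply frozen training models to an external cohort: no refitting,
    thresholds as trained.  Returns per-model evaluations and the decision
    curves."""
    table = prepare_design(external)
    y = table[outcome].to_numpy()
    evals, scores = {}, {}
    for name, model in models.items():
        s = model.predict(table)
        scores[name] = s
        evals[name] = roc_metrics(s, y, threshold=model.threshold,
                                  n_boot=n_boot, seed=seed)
    dca = decision_curve(scores, y)
    return {"evals": evals, "scores": scores, "decision_curve": dca}
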