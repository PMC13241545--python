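"""Inter-reader agreement gating.

Each diffusion metric is measured independently by two readers; a metric
enters the statistical pipeline only when its inter-reader intraclass
correlation coefficient reaches the reliability threshold (default 0.80,
stricter than the conventional 0.75).  The implemented variant is
ICC(2,1): two-way random effects, absolute agreement, single rater,
computed from the classical mean-squares decomposition

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)

with n subjects (lesions) and k = 2 raters.  Retained metrics are the
average of the two readers' measurements.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["icc_two_way", "icc_table", "filter_by_icc", "average_readers"]

log = logging.getLogger(__name__)


def icc_two_way(ratings: np.ndarray, form: str = "ICC2") -> float:
    """Two-way random-effects ICC of an (n subjects x k raters) matrix.

    ``form`` selects single-rater absolute agreement ("ICC2", the default)
    or average-of-k-raters absolute agreement ("ICC2k").
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n subjects x k raters) matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise ValueError("zero total variance: ICC undefined")

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC2k":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise ValueError("degenerate variance decomposition: ICC undefined")
    return float((msr - mse) / denom)


def icc_table(pairs: pd.DataFrame, form: str = "ICC2") -> pd.DataFrame:
    """Per-metric ICC from a long reader-pair table.

    ``pairs`` columns: lesion_id, metric, reader1, reader2 (both readers
    present for every lesion-metric).
    """
    rows = []
    for metric, grp in pairs.groupby("metric", sort=True):
        ratings = grp[["reader1", "reader2"]].to_numpy()
        rows.append({"metric": metric, "icc": icc_two_way(ratings, form=form),
                     "n_lesions": len(grp)})
    return pd.DataFrame(rows)


def filter_by_icc(icc: pd.DataFrame, threshold: float = 0.80,
                  metrics: list | None = None) -> list:
    """Metrics passing the reliability gate; exclusions are logged.

    ``metrics`` optionally restricts/reorders the candidate set (for
    example to the 18 diffusion metrics, leaving morphology aside).
    """
    table = icc.set_index("metric")["icc"]
    candidates = list(metrics) if metrics is not None else list(table.index)
    retained = []
    for m in candidates:
        value = table[m]
        if value >= threshold:
            retained.append(m)
            log.info("reliability gate: retained %s (ICC=%.3f >= %.2f)", m, value, threshold)
        else:
            log.warning("reliability gate: excluded %s (ICC=%.3f < %.2f)", m, value, threshold)
    return retained


def average_readers(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-lesion table of reader-averaged measurements (wide format)."""
    if pairs[["reader1", "reader2"]].isna().any().any():
        raise ValueError("missing reader measurement")
    mean = pairs.assign(value=(pairs["reader1"] + pairs["reader2"]) / 2.0)
    wide = mean.pivot(index="lesion_id", columns="metric", values="value")
    return wide.reset_index().rename_axis(None, axis=1)
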