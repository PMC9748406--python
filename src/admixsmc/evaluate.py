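"""Accuracy metrics for admixture-time recovery experiments.

Operates on the experiment tables produced by
:func:`admixsmc.simulate.run_experiment_grid` (tab-separated on disk):
columns ``time_true_years``, ``ratio``, ``rep``, ``time_est_years``,
``loglik``, ``converged``.  All error metrics are reported in kya.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "rmse",
    "error_by_time_bin",
    "regression_line",
    "read_table",
    "write_table",
    "TIME_BIN_EDGES_KYA",
]

# right-closed bins: (0, 20], (20, 40], (40, 60], (60, 80], (80, 100+]
TIME_BIN_EDGES_KYA = (20.0, 40.0, 60.0, 80.0)
TIME_BIN_LABELS = ("<=20", "20-40", "40-60", "60-80", "80-100")


def _select(table: pd.DataFrame, filter=None, include_nonconverged=False) -> pd.DataFrame:
    df = table
    if filter is not None:
        df = df[df.apply(filter, axis=1)] if callable(filter) else df[filter]
    if not include_nonconverged and "converged" in df.columns:
        df = df[df["converged"].astype(bool)]
    df = df.dropna(subset=["time_est_years"])
    return df


def rmse(table: pd.DataFrame, filter=None, include_nonconverged: bool = False) -> float:
    """Root-mean-square error of estimated vs true admixture time, in kya.

    Parameters
    ----------
    table : DataFrame
        Experiment table with ``time_true_years`` and ``time_est_years``.
    filter : callable or boolean mask, optional
        Row predicate applied before the metric.
    include_nonconverged : bool
        Keep rows whose EM did not reach the convergence tolerance
        (failed fits with NaN estimates are always dropped).
    """
    df = _select(table, filter, include_nonconverged)
    if df.empty:
        raise ValueError("no rows left after filtering")
    err_kya = (df["time_est_years"] - df["time_true_years"]) / 1000.0
    return float(np.sqrt(np.mean(np.square(err_kya))))


def error_by_time_bin(
    table: pd.DataFrame, include_nonconverged: bool = False
) -> pd.DataFrame:
    """Signed-error summaries in five true-time bins.

    Bins by the *true* admixture time with right-closed edges at 20, 40, 60
    and 80 kya (so exactly 40 kya falls in "20-40"); errors are
    (estimate - truth) in kya.  Returns one row per bin with count, mean,
    median and quartiles; empty bins keep count 0.
    """
    if table.empty:
        raise ValueError("empty experiment table")
    df = _select(table, None, include_nonconverged)
    true_kya = df["time_true_years"] / 1000.0
    err = (df["time_est_years"] - df["time_true_years"]) / 1000.0
    edges = (-np.inf, *TIME_BIN_EDGES_KYA, np.inf)
    bins = pd.cut(true_kya, bins=edges, labels=TIME_BIN_LABELS, right=True)
    rows = []
    for label in TIME_BIN_LABELS:
        e = err[bins == label]
        rows.append(
            {
                "bin": label,
                "count": int(e.size),
                "mean": float(e.mean()) if e.size else np.nan,
                "median": float(e.median()) if e.size else np.nan,
                "q1": float(e.quantile(0.25)) if e.size else np.nan,
                "q3": float(e.quantile(0.75)) if e.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def regression_line(
    table: pd.DataFrame, include_nonconverged: bool = False
) -> tuple[float, float]:
    """Ordinary least squares of estimated on true time (kya scale).

    Returns (slope, intercept).  Requires at least two distinct truths.
    """
    df = _select(table, None, include_nonconverged)
    x = df["time_true_years"].to_numpy() / 1000.0
    y = df["time_est_years"].to_numpy() / 1000.0
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct true times for a regression")
    res = _sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
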