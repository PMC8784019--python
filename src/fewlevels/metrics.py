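"""Monte Carlo evaluation metrics over tidy replicate records.

The unit of analysis is a long-format :class:`pandas.DataFrame` of replicate
records, one row per (scenario, replicate, model, parameter), with columns

    n_obs, n_levels, rep, model, parameter, estimate, ci_low, ci_high,
    truth, singular, converged

Variance-component records carry NaN interval endpoints (no per-replicate
CI is formed for them); coverage is computed only over records with finite
intervals.  Non-converged fits are excluded from summaries and counted in
an ``n_excluded`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "coverage",
    "relative_rmse",
    "bias_and_mean",
    "quantile_interval",
    "singular_proportion",
    "summarize",
]

#: grouping keys identifying one summary cell
CELL_KEYS = ["n_obs", "n_levels", "model", "parameter"]


def _require_nonempty(records: pd.DataFrame, what: str) -> None:
    if len(records) == 0:
        raise ValueError(f"{what} is undefined for an empty set of records")


def coverage(records: pd.DataFrame) -> float:
    """Fraction of replicates whose CI contains the truth (endpoints covered).

    Records with NaN interval endpoints are dropped first; infinite
    endpoints participate normally (an interval of (-inf, inf) always
    covers).
    """
    _require_nonempty(records, "coverage")
    with_ci = records.dropna(subset=["ci_low", "ci_high"])
    _require_nonempty(with_ci, "coverage (no records with intervals)")
    hit = (with_ci["ci_low"] <= with_ci["truth"]) & (with_ci["truth"] <= with_ci["ci_high"])
    return float(hit.mean())


def relative_rmse(records: pd.DataFrame) -> float:
    """Root-mean-square error of the estimates, divided by |truth|.

    Normalising by the absolute true value puts the strong-slope and
    weak-slope panels on a comparable scale.
    """
    _require_nonempty(records, "relative RMSE")
    truth = records["truth"].to_numpy()
    if np.any(truth == 0):
        raise ValueError("relative RMSE undefined at truth = 0; use absolute RMSE")
    rmse = float(np.sqrt(np.mean((records["estimate"].to_numpy() - truth) ** 2)))
    return rmse / float(np.abs(truth[0]))


def bias_and_mean(records: pd.DataFrame) -> tuple[float, float]:
    """(mean estimate, bias) where bias = mean estimate - truth."""
    _require_nonempty(records, "bias")
    mean = float(records["estimate"].mean())
    return mean, mean - float(records["truth"].iloc[0])


def quantile_interval(values, lo: float = 0.025, hi: float = 0.975) -> tuple[float, float]:
    """Empirical (lo, hi) quantiles by linear interpolation of order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quantile interval is undefined for an empty sample")
    if not (0 <= lo < hi <= 1):
        raise ValueError("quantile levels must satisfy 0 <= lo < hi <= 1")
    q_lo, q_hi = np.quantile(values, [lo, hi], method="linear")
    return float(q_lo), float(q_hi)


def singular_proportion(records: pd.DataFrame) -> float:
    """Fraction of (LMM) replicates flagged as singular fits."""
    _require_nonempty(records, "singular proportion")
    return float(records["singular"].mean())


def _summarize_cell(cell: pd.DataFrame) -> dict:
    """Metrics for one (scenario, model, parameter[, stratum]) group."""
    has_ci = cell.dropna(subset=["ci_low", "ci_high"])
    truth = float(cell["truth"].iloc[0])
    mean_est, bias = bias_and_mean(cell)
    q_lo, q_hi = quantile_interval(cell["estimate"].to_numpy())
    return {
        "n_reps": int(len(cell)),
        "coverage": coverage(cell) if len(has_ci) else np.nan,
        "relative_rmse": relative_rmse(cell) if truth != 0 else np.nan,
        "bias": bias,
        "mean_estimate": mean_est,
        "q025": q_lo,
        "q975": q_hi,
        "singular_proportion": singular_proportion(cell),
        "single_rep_flag": len(cell) == 1,
    }


def summarize(records: pd.DataFrame, stratify_by_singular: bool = False) -> pd.DataFrame:
    """Aggregate replicate records into per-cell scenario summaries.

    One output row per (n_obs, n_levels, model, parameter) and, when
    ``stratify_by_singular`` is set, additionally per singular-fit stratum.
    Strata with no records are omitted; strata with exactly one record are
    kept but flagged (``single_rep_flag``), since a single 0/1 outcome is
    not a meaningful mean.  Non-converged fits are excluded and tallied in
    ``n_excluded``.
    """
    _require_nonempty(records, "summary")
    keys = CELL_KEYS + (["singular"] if stratify_by_singular else [])
    usable = records[records["converged"]]
    excluded = (
        records[~records["converged"]].groupby(keys, observed=True).size().rename("n_excluded")
    )
    rows = []
    for key, cell in usable.groupby(keys, observed=True, sort=True):
        row = dict(zip(keys, key))
        row.update(_summarize_cell(cell))
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.merge(excluded.reset_index(), on=keys, how="left")
    out["n_excluded"] = out["n_excluded"].fillna(0).astype(int)
    return out
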