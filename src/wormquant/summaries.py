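"""Boxplot-style descriptive summaries shared across pipelines.

Figure convention: boxes span the 25th/75th percentiles with the median as
the central line; whiskers are the minimum and maximum. Quantiles use
linear interpolation between order statistics (numpy's default), which is
stated in output headers so any downstream stats package can reproduce
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["boxplot_stats", "group_summary", "QUANTILE_RULE"]

QUANTILE_RULE = "linear interpolation between order statistics"


def boxplot_stats(values) -> dict:
    """n, mean, min, q25, median, q75, max of a non-empty value list."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(v.size),
        "mean": float(np.mean(v)),
        "min": float(np.min(v)),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "max": float(np.max(v)),
    }


def group_summary(df: pd.DataFrame, value_col: str, group_col: str = "condition") -> pd.DataFrame:
    """One boxplot-statistics row per group, groups in sorted label order."""
    if df.empty:
        raise ValueError("cannot summarize an empty table")
    rows = []
    for cond, grp in df.groupby(group_col, sort=True):
        rows.append({group_col: cond, **boxplot_stats(grp[value_col].to_numpy())})
    return pd.DataFrame(rows)
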