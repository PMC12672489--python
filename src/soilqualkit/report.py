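"""Pattern-level summary reports joining soil quality with stand metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .sqi import SQIResult

__all__ = ["RunReport", "join_report", "pearson_matrix"]


@dataclass
class RunReport:
    """Per-pattern mean/sd/n of SQI and stand metrics, with provenance."""

    table: pd.DataFrame
    audit: str = ""
    version: str = __version__
    config: dict = field(default_factory=dict)
    seed: int | None = None
    unmatched_plots: list[str] = field(default_factory=list)


_STAND_COLS = ("cv_d", "gini_d_standard", "gini_d_paper", "fb", "npp", "pbs")


def join_report(
    sqi_by_plot: pd.DataFrame,
    stands: pd.DataFrame,
    audit: str = "",
    config: dict | None = None,
    seed: int | None = None,
) -> RunReport:
    """Aggregate plot-level SQI and stand metrics to one row per pattern.

    ``sqi_by_plot`` needs columns plot_id, pattern_id, sqi; ``stands`` is the
    per-plot frame from `soilqualkit.stand.summarize_stands`.  Plots present
    on only one side are reported in ``unmatched_plots`` and flagged by n
    mismatches, never dropped silently.
    """
    for col in ("plot_id", "pattern_id", "sqi"):
        if col not in sqi_by_plot.columns:
            raise ValueError(f"sqi table missing column {col!r}")
    merged = sqi_by_plot.merge(
        stands.drop(columns=["pattern_id"], errors="ignore"),
        on="plot_id", how="outer", indicator=True,
    )
    unmatched = sorted(merged.loc[merged["_merge"] != "both", "plot_id"].astype(str))
    if (merged["_merge"] == "both").sum() == 0:
        raise ValueError("no overlapping plots between SQI and stand tables")

    def agg(g: pd.DataFrame) -> pd.Series:
        out: dict[str, float] = {}
        sqi = g["sqi"].dropna()
        out["sqi_mean"] = sqi.mean()
        out["sqi_sd"] = sqi.std(ddof=1) if len(sqi) > 1 else 0.0
        out["sqi_n"] = len(sqi)
        out["si"] = sqi.max() / sqi.min() if len(sqi) >= 2 else np.nan
        for col in _STAND_COLS:
            if col in g.columns:
                vals = g[col].dropna()
                out[f"{col}_mean"] = vals.mean()
                out[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
                out[f"{col}_n"] = len(vals)
        out["n_mismatch"] = float((g["_merge"] != "both").any())
        return pd.Series(out)

    table = (
        merged.groupby("pattern_id", dropna=False, sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return RunReport(
        table=table, audit=audit, config=dict(config or {}), seed=seed,
        unmatched_plots=unmatched,
    )


def pearson_matrix(
    df: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values (t-transform, n-2 df).

    Constant columns yield NaN entries (flagged with a warning), never a
    silent zero.
    """
    cols = list(columns) if columns is not None else list(df.columns)
    if len(df) < 3:
        raise ValueError("Pearson matrix needs at least 3 paired observations")
    constant = [c for c in cols if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s) have undefined correlations: {constant}")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in constant or b in constant:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(df[a], df[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    for c in constant:
        r.loc[c, c] = np.nan
    return r, p


def sqi_by_plot_frame(result: SQIResult, plots: pd.Series, patterns: pd.Series) -> pd.DataFrame:
    """Plot-level SQI table (mean over a plot's samples) ready for joining."""
    df = pd.DataFrame(
        {
            "plot_id": plots.reindex(result.sqi.index),
            "pattern_id": patterns.reindex(result.sqi.index),
            "sqi": result.sqi,
        }
    )
    return (
        df.groupby(["plot_id", "pattern_id"], as_index=False)["sqi"].mean()
    )
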