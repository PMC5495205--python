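"""BestKeeper-style descriptive dispersion and index correlation on raw Cq.

BestKeeper judges candidates directly on the quantification-cycle scale:
per-gene descriptive dispersion (mean absolute deviation from the mean Cq,
the original tool's "SD [+/- Cq]" convention, or sample SD by config) and
the Pearson correlation of each gene's Cq with the BestKeeper index — the
per-sample geometric mean of all candidates' Cq.  Ranking is by ascending
dispersion; genes with dispersion above 1 cycle are flagged as inconsistent
(rule of thumb of the original tool) but stay in the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .cq_io import CqTable

__all__ = [
    "BestKeeperResult",
    "bestkeeper_describe",
    "bestkeeper_index",
    "bestkeeper_correlate",
    "bestkeeper_analysis",
]

DISPERSION_FLAG_CYCLES = 1.0

Metric = Literal["mad", "sd"]


@dataclass
class BestKeeperResult:
    stats: pd.DataFrame  # per gene: geo_mean_cq .. cv_percent
    index: pd.Series  # per-sample geometric mean Cq
    correlation: dict[str, tuple[float, float]]  # gene -> (pearson r, p)
    ranks: dict[str, float]  # ascending dispersion, average-rank ties
    metric: str = "mad"
    inconsistent: list[str] = field(default_factory=list)  # dispersion > 1 cycle


def bestkeeper_describe(table: CqTable, metric: Metric = "mad") -> pd.DataFrame:
    """Per-gene descriptive statistics of the collapsed Cq.

    Columns: geo_mean_cq, arith_mean_cq, min_cq, max_cq, dispersion,
    cv_percent (= 100 * dispersion / arith_mean_cq).
    """
    if not table.is_complete():
        raise ValueError("BestKeeper needs a complete Cq table")
    if metric not in ("mad", "sd"):
        raise ValueError(f"unknown dispersion metric {metric!r}")
    v = table.values
    arith = v.mean(axis=1)
    if metric == "mad":
        disp = np.abs(v - arith[:, None]).mean(axis=1)
    else:
        disp = v.std(axis=1, ddof=1)
    df = pd.DataFrame(
        {
            "geo_mean_cq": stats.gmean(v, axis=1),
            "arith_mean_cq": arith,
            "min_cq": v.min(axis=1),
            "max_cq": v.max(axis=1),
            "dispersion": disp,
            "cv_percent": 100.0 * disp / arith,
        },
        index=table.genes,
    )
    df.index.name = "gene"
    return df


def bestkeeper_index(table: CqTable) -> pd.Series:
    """BestKeeper index: per-sample geometric mean of Cq across genes."""
    if not table.is_complete():
        raise ValueError("BestKeeper needs a complete Cq table")
    return pd.Series(
        stats.gmean(table.values, axis=0), index=table.sample_ids, name="bk_index"
    )


def bestkeeper_correlate(
    table: CqTable, index: pd.Series
) -> dict[str, tuple[float, float]]:
    """Pearson r (and two-sided p, t transform with n-2 df) of each gene vs
    the index.  A constant gene has undefined r and is reported as (nan, nan).
    """
    if table.n_samples < 3:
        raise ValueError("need >= 3 samples for index correlation")
    idx = index.to_numpy()
    out: dict[str, tuple[float, float]] = {}
    for gi, gene in enumerate(table.genes):
        v = table.values[gi]
        if np.ptp(v) == 0 or np.ptp(idx) == 0:
            out[gene] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(v, idx)
        out[gene] = (float(r), float(p))
    return out


def bestkeeper_analysis(table: CqTable, metric: Metric = "mad") -> BestKeeperResult:
    """Full BestKeeper pass: descriptives, index, correlations, ranks."""
    desc = bestkeeper_describe(table, metric)
    index = bestkeeper_index(table)
    corr = bestkeeper_correlate(table, index)
    ranks = stats.rankdata(desc["dispersion"].to_numpy(), method="average")
    return BestKeeperResult(
        stats=desc,
        index=index,
        correlation=corr,
        ranks={g: float(r) for g, r in zip(table.genes, ranks)},
        metric=metric,
        inconsistent=[
            g for g, d in zip(table.genes, desc["dispersion"]) if d > DISPERSION_FLAG_CYCLES
        ],
    )
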