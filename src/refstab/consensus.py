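"""Comprehensive (RefFinder-style) consensus ranking.

Each stability algorithm contributes a rank per gene (ties as average
ranks, e.g. geNorm's tied final pair enters as 1.5/1.5); the consensus
score is the geometric mean of the per-method ranks, weighting methods
equally.  The final order sorts genes by ascending geometric-mean rank,
breaking exact ties lexicographically for deterministic output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConsensusResult", "aggregate", "heatmap_table"]


@dataclass
class ConsensusResult:
    method_ranks: pd.DataFrame  # genes x methods
    geo_mean_rank: dict[str, float]
    final_order: list[str]
    methods_used: list[str]


def aggregate(method_ranks: dict[str, dict[str, float]]) -> ConsensusResult:
    """Geometric-mean consensus over per-method rank mappings.

    ``method_ranks`` maps method name -> (gene -> rank).  All supplied
    methods must rank the identical gene universe; methods a run could not
    produce (e.g. NormFinder on 2 genes) are simply absent and recorded via
    ``methods_used``.
    """
    if len(method_ranks) < 2:
        raise ValueError("need ranks from >= 2 methods")
    methods = list(method_ranks)
    universe = set(method_ranks[methods[0]])
    for m in methods[1:]:
        other = set(method_ranks[m])
        if other != universe:
            diff = sorted(universe.symmetric_difference(other))
            raise ValueError(f"gene sets differ between methods: {diff}")

    genes = sorted(universe)
    table = pd.DataFrame(
        {m: [method_ranks[m][g] for g in genes] for m in methods}, index=genes
    )
    geo = stats.gmean(table.to_numpy(), axis=1)
    geo_map = {g: float(v) for g, v in zip(genes, geo)}
    final_order = sorted(genes, key=lambda g: (geo_map[g], g))
    return ConsensusResult(
        method_ranks=table,
        geo_mean_rank=geo_map,
        final_order=final_order,
        methods_used=methods,
    )


def heatmap_table(result: ConsensusResult) -> pd.DataFrame:
    """Genes (rows, consensus order) x methods matrix of ranks for rendering."""
    return result.method_ranks.loc[result.final_order]


def consensus_frame(result: ConsensusResult) -> pd.DataFrame:
    """Flat output table: per-method ranks, geomean and final rank."""
    df = heatmap_table(result).copy()
    df.columns = [f"{m}_rank" for m in df.columns]
    df["geomean_rank"] = [result.geo_mean_rank[g] for g in df.index]
    df["final_rank"] = np.arange(1, len(df) + 1)
    df.index.name = "gene"
    return df
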