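"""Comparative Delta-Ct stability: mean SD of pairwise Cq differences.

For every pair of candidate genes, take the per-sample Cq difference
(delta-Ct) and its standard deviation across all samples (n-1 denominator,
groups pooled); a gene's stability is the mean of these SDs over all its
partners.  Because per-sample loading effects add the same constant to
every gene's Cq in a sample, they cancel exactly in the differences.

On raw Cq this statistic coincides exactly with the geNorm M value computed
on E=1 log2 quantities: log2-quantity differences equal negated Cq
differences up to per-gene constants, which SD ignores.  The two modules
therefore serve as mutual oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cq_io import CqTable

__all__ = ["DeltaCtResult", "deltact_stability"]


@dataclass
class DeltaCtResult:
    pair_sd: pd.DataFrame  # symmetric, zero diagonal, cycles
    stability: dict[str, float]  # gene -> mean SD over partners
    ranks: dict[str, float]  # ascending, average-rank ties


def deltact_stability(table: CqTable) -> DeltaCtResult:
    """Comparative delta-Ct stability on the raw collapsed Cq matrix."""
    if not table.is_complete():
        raise ValueError("delta-Ct needs a complete Cq table")
    if table.n_genes < 2:
        raise ValueError("need >= 2 genes")
    if table.n_samples < 3:
        raise ValueError("need >= 3 samples")
    v = table.values
    k = table.n_genes
    sd = np.zeros((k, k))
    for i in range(k):
        diffs = v[i][None, :] - v
        sd[i] = diffs.std(axis=1, ddof=1)
    np.fill_diagonal(sd, 0.0)
    mask = ~np.eye(k, dtype=bool)
    stab = np.array([sd[i][mask[i]].mean() for i in range(k)])
    ranks = rankdata(stab, method="average")
    return DeltaCtResult(
        pair_sd=pd.DataFrame(sd, index=table.genes, columns=table.genes),
        stability={g: float(s) for g, s in zip(table.genes, stab)},
        ranks={g: float(r) for g, r in zip(table.genes, ranks)},
    )
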