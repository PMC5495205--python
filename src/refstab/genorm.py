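"""geNorm: M values, stepwise exclusion, normalization factors and V_n/n+1.

The stability measure M of a gene is the mean, over all other candidates,
of the standard deviation across samples of the pairwise log2 expression
ratio.  A perfectly co-regulated (or perfectly stable) pair has M = 0.
Ranking proceeds by stepwise exclusion: repeatedly drop the gene with the
highest recomputed M until two genes remain; those two cannot be ordered by
the method and share the top rank.

The normalization factor NF_n for a sample is the geometric mean of the
relative quantities of the n most stable genes.  The pairwise variation
V_n/n+1 = SD over samples of log2(NF_n / NF_{n+1}) measures what adding the
(n+1)-th gene changes; the smallest n with V below a threshold (0.15 by
convention) is the recommended number of reference genes.

All standard deviations use the n-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantities import ExpressionMatrix

__all__ = [
    "GenormResult",
    "m_values",
    "stepwise_ranking",
    "stability_order",
    "normalization_factors",
    "pairwise_variation",
    "optimal_n",
    "genorm_analysis",
    "DEFAULT_V_THRESHOLD",
    "DEFAULT_M_CUTOFF",
]

logger = logging.getLogger(__name__)

DEFAULT_V_THRESHOLD = 0.15
DEFAULT_M_CUTOFF = 1.5  # genes with full-panel M above this are flagged

UNDETERMINED = "undetermined"


def _m_from_matrix(values: np.ndarray) -> np.ndarray:
    """M_j = mean over k != j of SD_samples(value_j - value_k), ddof=1."""
    k, n = values.shape
    if n < 2:
        raise ValueError("need >= 2 samples for pairwise SDs")
    if k < 2:
        raise ValueError("need >= 2 genes")
    sds = np.empty((k, k))
    for j in range(k):
        diffs = values[j][None, :] - values
        sds[j] = diffs.std(axis=1, ddof=1)
    np.fill_diagonal(sds, np.nan)
    if k == 2:
        # a single partner each; both genes share SD of the one ratio
        return np.array([sds[0, 1], sds[1, 0]])
    return np.nanmean(sds, axis=1)


def m_values(expr: ExpressionMatrix) -> dict[str, float]:
    """Full-panel geNorm M per gene (log2 units)."""
    m = _m_from_matrix(expr.values)
    return {g: float(v) for g, v in zip(expr.genes, m)}


@dataclass(frozen=True)
class GenormRanking:
    exclusion_order: tuple[str, ...]  # least stable first, as removed
    final_pair: tuple[str, str]  # tied most stable pair, name-sorted
    ranks: dict[str, float]  # final pair share rank 1.5


def stepwise_ranking(expr: ExpressionMatrix) -> GenormRanking:
    """Stepwise-exclusion ranking; ties in max M broken by gene name."""
    if expr.n_genes < 3:
        raise ValueError("stepwise ranking needs >= 3 genes")
    genes = list(expr.genes)
    values = expr.values.copy()
    excluded: list[str] = []
    while len(genes) > 2:
        m = _m_from_matrix(values)
        worst = float(np.max(m))
        candidates = [g for g, v in zip(genes, m) if v == worst]
        if len(candidates) > 1:
            logger.info("geNorm tie at M=%.6g among %s; removing %s",
                        worst, candidates, sorted(candidates)[0])
        drop = sorted(candidates)[0]
        i = genes.index(drop)
        excluded.append(drop)
        genes.pop(i)
        values = np.delete(values, i, axis=0)
    final_pair = tuple(sorted(genes))
    k = expr.n_genes
    ranks: dict[str, float] = {g: 1.5 for g in final_pair}
    for pos, g in enumerate(excluded):  # first removed = least stable = rank K
        ranks[g] = float(k - pos)
    return GenormRanking(tuple(excluded), final_pair, ranks)  # type: ignore[arg-type]


def stability_order(ranking: GenormRanking) -> list[str]:
    """Genes from most to least stable (final pair first, name-sorted)."""
    return list(ranking.final_pair) + list(reversed(ranking.exclusion_order))


def normalization_factors(
    expr: ExpressionMatrix, ranking: GenormRanking
) -> pd.DataFrame:
    """NF_n per sample for n = 2..K, geometric mean of top-n quantities.

    Rows indexed by n; columns are sample ids.  Geometric mean of 2^value
    equals 2^(arithmetic mean of values).
    """
    order = stability_order(ranking)
    idx = [expr.genes.index(g) for g in order]
    vals = expr.values[idx]
    rows = {}
    for n in range(2, len(order) + 1):
        rows[n] = np.exp2(vals[:n].mean(axis=0))
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)


def pairwise_variation(nf: pd.DataFrame) -> dict[int, float]:
    """V_n/n+1 = SD over samples of log2(NF_n / NF_{n+1}), keyed by n."""
    ns = sorted(nf.index)
    out: dict[int, float] = {}
    for n in ns[:-1]:
        ratio = np.log2(nf.loc[n].to_numpy() / nf.loc[n + 1].to_numpy())
        out[n] = float(np.std(ratio, ddof=1))
    return out


def optimal_n(
    v_values: dict[int, float], threshold: float = DEFAULT_V_THRESHOLD
) -> int | str:
    """Smallest n with V_n/n+1 < threshold, or "undetermined".

    An undetermined result is advisory: no small set suffices, use all
    candidate genes.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not v_values:
        raise ValueError("empty V-value mapping")
    for n in sorted(v_values):
        if v_values[n] < threshold:
            return n
    return UNDETERMINED


@dataclass
class GenormResult:
    m_values: dict[str, float]
    exclusion_order: tuple[str, ...]
    final_pair: tuple[str, str]
    ranks: dict[str, float]
    nf: pd.DataFrame
    v_values: dict[int, float]
    optimal_n: int | str
    threshold: float = DEFAULT_V_THRESHOLD
    m_cutoff: float = DEFAULT_M_CUTOFF
    flagged: list[str] = field(default_factory=list)  # genes with M >= m_cutoff


def genorm_analysis(
    expr: ExpressionMatrix,
    threshold: float = DEFAULT_V_THRESHOLD,
    m_cutoff: float = DEFAULT_M_CUTOFF,
) -> GenormResult:
    """Full geNorm pipeline: M, stepwise ranks, NF_n, V values, optimal n."""
    m = m_values(expr)
    ranking = stepwise_ranking(expr)
    nf = normalization_factors(expr, ranking)
    v = pairwise_variation(nf)
    n_opt = optimal_n(v, threshold) if v else UNDETERMINED
    flagged = [g for g, val in m.items() if val >= m_cutoff]
    return GenormResult(
        m_values=m,
        exclusion_order=ranking.exclusion_order,
        final_pair=ranking.final_pair,
        ranks=ranking.ranks,
        nf=nf,
        v_values=v,
        optimal_n=n_opt,
        threshold=threshold,
        m_cutoff=m_cutoff,
        flagged=flagged,
    )
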