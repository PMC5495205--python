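"""Model-based stability estimation (NormFinder-style variance decomposition).

The model: log2 expression y_igj of gene i in group g, sample j decomposes
into gene level + sample loading + group-specific bias a_ig + noise with
gene/group variance sigma^2_ig.  A stable reference gene has both small
intragroup variance and small systematic bias between groups; the stability
value rho combines the two so that genes can be ranked on a single axis.

Procedure (K genes, G groups, n_g samples in group g):

1. Sample centering: d_igj = y_igj - mean over genes of y_.gj.  This removes
   per-sample loading exactly but couples genes, hence the correction below.
2. Per gene/group mean m_ig and sample variance s^2_ig (n-1 denominator).
3. Intragroup variance, corrected for centering:
   sigma2_ig = max(0, (K/(K-2)) * (s^2_ig - (1/K^2) * sum_i' s^2_i'g)).
4. Intergroup: bias a_ig = m_ig - mean_g(m_ig);
   tau2_i = max(0, var_g(a_ig) - mean_g(sigma2_ig / n_g))  (G-1 denominator);
   shrunken bias  a~_ig = a_ig * tau2_i / (tau2_i + sigma2_ig / n_g).
5. Stability: rho_i = mean over groups of
   ( |a~_ig| + sqrt( (tau2_i * sigma2_ig/n_g) / (tau2_i + sigma2_ig/n_g) ) ).

With a single group there is no bias term and rho_i = sqrt(sigma2_ig).
Lower rho = more stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .quantities import ExpressionMatrix

__all__ = ["NormFinderResult", "normfinder_stability"]


@dataclass
class NormFinderResult:
    stability: dict[str, float]  # gene -> rho, log2 units
    intragroup_var: dict[tuple[str, str], float]  # (gene, group) -> sigma2 hat
    group_bias: dict[tuple[str, str], float]  # (gene, group) -> shrunken bias
    intergroup_var: dict[str, float]  # gene -> tau2 hat
    ranks: dict[str, float]  # ascending rho, average ranks on ties
    grouped: bool = True


def _group_index(groups: list[str]) -> tuple[list[str], list[np.ndarray]]:
    names = list(dict.fromkeys(groups))
    arr = np.asarray(groups)
    return names, [np.flatnonzero(arr == g) for g in names]


def normfinder_stability(
    expr: ExpressionMatrix, grouped: bool = True
) -> NormFinderResult:
    """Rank genes by model-based stability rho (lower = more stable).

    ``grouped=False`` ignores group labels: all samples form one group and
    rho reduces to the per-gene intragroup SD estimate.
    """
    y = expr.values
    k = expr.n_genes
    if k < 3:
        raise ValueError("need >= 3 genes (sample-centering correction undefined)")

    groups = expr.groups if grouped else ["all"] * expr.n_samples
    gnames, gidx = _group_index(groups)
    for g, idx in zip(gnames, gidx):
        if idx.size < 2:
            raise ValueError(f"group {g!r} has a single sample; need >= 2")

    # Step 1: remove per-sample loading
    d = y - y.mean(axis=0, keepdims=True)

    n_g = np.array([idx.size for idx in gidx], dtype=float)
    m_ig = np.column_stack([d[:, idx].mean(axis=1) for idx in gidx])
    s2_ig = np.column_stack([d[:, idx].var(axis=1, ddof=1) for idx in gidx])

    # Step 3: undo the variance distortion introduced by centering
    colsum = s2_ig.sum(axis=0, keepdims=True)
    sigma2 = np.maximum(0.0, (k / (k - 2)) * (s2_ig - colsum / k**2))

    G = len(gnames)
    if G == 1:
        rho = np.sqrt(sigma2[:, 0])
        tau2 = np.zeros(k)
        bias = np.zeros((k, 1))
    else:
        # Step 4
        a_ig = m_ig - m_ig.mean(axis=1, keepdims=True)
        var_a = a_ig.var(axis=1, ddof=1)
        tau2 = np.maximum(0.0, var_a - (sigma2 / n_g[None, :]).mean(axis=1))
        denom = tau2[:, None] + sigma2 / n_g[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(denom > 0, tau2[:, None] / denom, 0.0)
        bias = a_ig * shrink
        # Step 5
        with np.errstate(invalid="ignore", divide="ignore"):
            post_var = np.where(
                denom > 0, tau2[:, None] * (sigma2 / n_g[None, :]) / denom, 0.0
            )
        rho = (np.abs(bias) + np.sqrt(post_var)).mean(axis=1)

    ranks = rankdata(rho, method="average")
    return NormFinderResult(
        stability={g: float(r) for g, r in zip(expr.genes, rho)},
        intragroup_var={
            (gene, grp): float(sigma2[i, j])
            for i, gene in enumerate(expr.genes)
            for j, grp in enumerate(gnames)
        },
        group_bias={
            (gene, grp): float(bias[i, j]) if G > 1 else 0.0
            for i, gene in enumerate(expr.genes)
            for j, grp in enumerate(gnames)
        },
        intergroup_var={g: float(t) for g, t in zip(expr.genes, tau2)},
        ranks={g: float(r) for g, r in zip(expr.genes, ranks)},
        grouped=grouped,
    )
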