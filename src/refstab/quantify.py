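"""2^-ddCq relative quantification and Mann-Whitney U validation.

Fold change of a target gene is computed against the mean Cq of a chosen
reference-gene set (arithmetic mean of reference Cq = geometric mean of
reference quantities at E = 1), centred on a calibrator condition whose
mean log2 fold is 0 by construction:

    dCq(sample)  = Cq_target - mean(Cq over references)
    ddCq(sample) = dCq(sample) - mean(dCq over calibrator samples)
    fold(sample) = 2^(-ddCq)

Validation against external per-replicate fold estimates (e.g. RNA-seq)
uses the Mann-Whitney U test: exact two-sided p by full enumeration of all
C(n1+n2, n1) group assignments when n1+n2 <= 16 (average ranks for ties),
otherwise the normal approximation with tie correction and 0.5 continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, tiecorrect

from .cq_io import CqTable

__all__ = ["RQResult", "MWUResult", "ddcq", "mwu_test", "compare_to_external"]

EXACT_LIMIT = 16  # n1 + n2 above this switches mode 'auto' to the normal approx


@dataclass
class RQResult:
    target: str
    reference_set: list[str]
    calibrator_group: str
    per_sample_fold: pd.Series  # indexed by sample_id
    group_summary: pd.DataFrame  # group -> mean_fold, sd_fold, n
    groups: pd.Series  # sample_id -> group


@dataclass(frozen=True)
class MWUResult:
    u_statistic: float
    z_value: float | None
    p_value: float
    method: Literal["exact", "normal_approx"]
    n1: int
    n2: int
    degenerate: bool = False

    def significance(self) -> str:
        """Annotation per the usual 0.05 / 0.01 conventions."""
        if self.p_value < 0.01:
            return "p<0.01"
        if self.p_value < 0.05:
            return "p<0.05"
        return "p>0.05"


def ddcq(
    table: CqTable,
    target: str,
    reference_set: Sequence[str],
    calibrator_group: str,
) -> RQResult:
    """Relative quantification of ``target`` by the 2^-ddCq method."""
    reference_set = list(reference_set)
    if not reference_set:
        raise ValueError("reference_set is empty")
    if target in reference_set:
        raise ValueError(f"target {target!r} cannot be its own reference")
    for g in [target, *reference_set]:
        if g not in table.genes:
            raise ValueError(f"gene {g!r} not in table")
    groups = np.asarray(table.groups)
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")

    t_idx = table.genes.index(target)
    r_idx = [table.genes.index(g) for g in reference_set]
    involved = table.values[[t_idx, *r_idx]]
    if np.isnan(involved).any():
        raise ValueError("missing Cq among target/reference genes")

    dcq = table.values[t_idx] - table.values[r_idx].mean(axis=0)
    calib = groups == calibrator_group
    ddcq_vals = dcq - dcq[calib].mean()
    fold = np.exp2(-ddcq_vals)

    sample_ids = table.sample_ids
    per_sample = pd.Series(fold, index=sample_ids, name="fold")
    grp = pd.Series(groups, index=sample_ids, name="group")
    summary = (
        pd.DataFrame({"group": groups, "fold": fold})
        .groupby("group", sort=False)["fold"]
        .agg(mean_fold="mean", sd_fold=lambda v: v.std(ddof=1), n="count")
    )
    return RQResult(
        target=target,
        reference_set=reference_set,
        calibrator_group=calibrator_group,
        per_sample_fold=per_sample,
        group_summary=summary,
        groups=grp,
    )


def _u_from_ranks(pooled: np.ndarray, n1: int) -> float:
    """U for the first group, from rank sums with average ranks."""
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mwu_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "normal"] = "auto",
) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates every C(n1+n2, n1) assignment of the pooled values
    (ties handled by average ranks throughout); ``normal`` uses the
    tie-corrected normal approximation with 0.5 continuity correction;
    ``auto`` picks exact when n1 + n2 <= 16.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return MWUResult(n1 * n2 / 2.0, None, 1.0, "exact", n1, n2, degenerate=True)

    u_obs = _u_from_ranks(pooled, n1)
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_LIMIT else "normal"

    if mode == "exact":
        ranks = rankdata(pooled)
        total = comb(n1 + n2, n1)
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        offset = n1 * (n1 + 1) / 2.0
        for combo in combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return MWUResult(u_obs, None, hits / total, "exact", n1, n2)

    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    mu = n1 * n2 / 2.0
    tie = tiecorrect(rankdata(pooled))
    sigma = sqrt(tie * n1 * n2 * (n1 + n2 + 1) / 12.0)
    if sigma == 0:
        return MWUResult(u_obs, None, 1.0, "normal_approx", n1, n2, degenerate=True)
    z = (abs(u_obs - mu) - 0.5) / sigma
    z = max(z, 0.0)
    p = min(1.0, 2.0 * norm.sf(z))
    return MWUResult(u_obs, float(z), float(p), "normal_approx", n1, n2)


def compare_to_external(
    rq: RQResult,
    external_folds: dict[str, Sequence[float]],
    contrast_group: str,
    mode: Literal["auto", "exact", "normal"] = "auto",
) -> MWUResult:
    """Mann-Whitney comparison of qPCR per-replicate folds in one group
    against external (e.g. RNA-seq) per-replicate folds for the same group.
    """
    if contrast_group not in external_folds:
        raise ValueError(f"no external folds for group {contrast_group!r}")
    qpcr = rq.per_sample_fold[rq.groups == contrast_group]
    if qpcr.empty:
        raise ValueError(f"no qPCR samples in group {contrast_group!r}")
    return mwu_test(qpcr.to_numpy(), list(external_folds[contrast_group]), mode)
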