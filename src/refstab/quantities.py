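"""Cq to log2 relative quantity conversion.

geNorm and NormFinder work on relative quantities, not raw Cq.  Each gene is
referenced to its own minimum Cq (its most expressed sample has quantity 1,
log2 quantity 0); with amplification efficiency E the quantity per cycle is
(1 + E), so

    value(gene, sample) = (Cq_min(gene) - Cq(gene, sample)) * log2(1 + E_gene).

The per-gene reference constant cancels in every downstream dispersion
statistic; min-referencing merely keeps the numbers small and the scale
interpretable.  All downstream M and V statistics are in log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq_io import CqTable

__all__ = ["ExpressionMatrix", "to_expression"]


@dataclass
class ExpressionMatrix:
    """Log2 relative quantities, genes x samples; per-gene max is 0."""

    genes: list[str]
    samples: list[tuple[str, str]]
    values: np.ndarray  # log2 quantities
    scale_note: str = "E=1 for all genes (classic 2^dCq)"

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def groups(self) -> list[str]:
        return [g for _, g in self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.sample_ids)

    def quantities(self) -> np.ndarray:
        """Antilog (2^value) relative quantities."""
        return np.exp2(self.values)

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.genes.index(g) for g in keep]
        return ExpressionMatrix(
            genes=list(keep),
            samples=list(self.samples),
            values=self.values[idx],
            scale_note=self.scale_note,
        )


def to_expression(table: CqTable, use_efficiency: bool = False) -> ExpressionMatrix:
    """Convert a complete Cq table to log2 relative quantities.

    With ``use_efficiency=False`` every gene doubles per cycle (E = 1) and
    the value is simply Cq_min - Cq.  With ``use_efficiency=True`` per-gene
    efficiencies must be present on the table (as fractions, 1.0 = 100%).
    """
    if not table.is_complete():
        raise ValueError(
            "Cq table has missing values; run require_complete() first"
        )
    if use_efficiency:
        if table.efficiencies is None:
            raise ValueError("use_efficiency=True but table has no efficiencies")
        missing = [g for g in table.genes if g not in table.efficiencies]
        if missing:
            raise ValueError(f"no efficiency for genes: {missing}")
        factors = np.array([np.log2(1.0 + table.efficiencies[g]) for g in table.genes])
        note = "per-gene efficiencies from standard curves"
    else:
        factors = np.ones(table.n_genes)
        note = "E=1 for all genes (classic 2^dCq)"

    dcq = table.values.min(axis=1, keepdims=True) - table.values
    return ExpressionMatrix(
        genes=list(table.genes),
        samples=list(table.samples),
        values=dcq * factors[:, None],
        scale_note=note,
    )
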