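"""Static figure helpers (matplotlib, Agg-safe): Cq box plots, V bars,
consensus bars.  Data outputs are the CSVs; these are convenience renders.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .consensus import ConsensusResult
from .cq_io import CqTable

__all__ = ["cq_boxplot", "v_bar_chart", "consensus_bar_chart"]


def cq_boxplot(table: CqTable, path: str | Path) -> None:
    """Per-gene distribution of collapsed Cq (whiskers at min/max)."""
    fig, ax = plt.subplots(figsize=(max(6, table.n_genes * 0.7), 4))
    data = [table.values[i][~(table.values[i] != table.values[i])] for i in range(table.n_genes)]
    ax.boxplot(data, tick_labels=table.genes, whis=(0, 100))
    ax.set_ylabel("Cq (cycles)")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def v_bar_chart(v_values: dict[int, float], threshold: float, path: str | Path) -> None:
    """Pairwise variation V_n/n+1 with the decision threshold."""
    ns = sorted(v_values)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar([f"V{n}/{n + 1}" for n in ns], [v_values[n] for n in ns], color="#4878a8")
    ax.axhline(threshold, color="crimson", ls="--", label=f"threshold {threshold}")
    ax.set_ylabel("pairwise variation (log2 units)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def consensus_bar_chart(result: ConsensusResult, path: str | Path) -> None:
    """Geometric-mean rank per gene, best (lowest) first."""
    order = result.final_order
    fig, ax = plt.subplots(figsize=(max(6, len(order) * 0.7), 4))
    ax.bar(order, [result.geo_mean_rank[g] for g in order], color="#6aa66a")
    ax.set_ylabel("geometric mean of method ranks")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
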