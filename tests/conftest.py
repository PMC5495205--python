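import numpy as np
import pytest

from refstab.cq_io import CqTable, collapse_replicates
from refstab.quantities import to_expression
from refstab.simulate import generate, fungal_dev_config


def make_table(values, groups=None, genes=None, efficiencies=None) -> CqTable:
    """Build a CqTable from a genes x samples array with minimal boilerplate."""
    values = np.asarray(values, dtype=float)
    k, n = values.shape
    genes = genes or [f"G{i + 1}" for i in range(k)]
    groups = groups or ["all"] * n
    samples = [(f"S{j + 1}", groups[j]) for j in range(n)]
    return CqTable(genes=list(genes), samples=samples, values=values,
                   efficiencies=efficiencies)


def random_table(rng, n_genes, n_samples, n_groups=1) -> CqTable:
    """Random complete Cq table, baselines 12-34 cycles, noise ~1 cycle."""
    baselines = rng.uniform(12, 34, size=n_genes)
    values = baselines[:, None] + rng.normal(0, 1.0, size=(n_genes, n_samples))
    groups = [f"grp{j % n_groups}" for j in range(n_samples)]
    return make_table(values, groups=groups)


@pytest.fixture(scope="session")
def fungal_dev_dataset():
    """Collapsed fungal-dev table (13 candidates + 2 GOIs) and ground truth."""
    records, truth = generate(fungal_dev_config(seed=11))
    return collapse_replicates(records), truth


@pytest.fixture(scope="session")
def fungal_dev_candidates(fungal_dev_dataset):
    """Only the 13 candidate reference genes, plus their expression matrix."""
    table, truth = fungal_dev_dataset
    candidates = [g for g in table.genes if g not in ("CDC25", "CHI1")]
    sub = table.subset_genes(candidates)
    return sub, to_expression(sub), truth
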