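"""Synthetic Cq data generator with exported ground truth.

Because published stability studies rarely deposit raw quantification
cycles, the generator emulates the experimental design directly: candidate
genes with chosen baseline Cq, biological noise and stage-specific
expression shifts, measured over groups (developmental stages) x biological
replicates x technical replicates, plus ten-fold dilution series for
standard-curve work.

Generative model for the Cq of gene i, group g, biological sample j,
technical replicate r:

    Cq_igjr = baseline_i + delta_ig + b_gj + eps_igj + eta_igjr

where b_gj ~ N(0, sigma_sample^2) is a loading effect shared by every gene
in the biological sample (RNA input / RT yield), eps_igj ~ N(0,
sigma_bio_i^2) is gene-specific biological noise, and eta_igjr ~ N(0,
sigma_tech^2) is well-to-well technical noise.  Noise is Gaussian on the
Cq (log2 abundance) scale — the implicit assumption of all four stability
algorithms.  Genes of interest carry known per-group log2 folds (a fold of
f lowers Cq by log2 f at perfect efficiency), giving a ground truth for
recovery tests of the 2^-ddCq pipeline.

The ``fungal_dev_config`` preset mirrors a 13-candidate, 4-stage, 3x3
replicate fungal development study with baselines spread over ~10-30
cycles; see docs/methods.md for the parameter rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cq_io import RawCqRecord
from .efficiency import DilutionSeries, slope_for_efficiency

__all__ = [
    "GeneSpec",
    "GroupSpec",
    "GoiSpec",
    "SimConfig",
    "SimTruth",
    "generate",
    "generate_dilution",
    "fungal_dev_config",
    "FUNGAL_DEV_GENES",
    "FUNGAL_DEV_GROUPS",
]


@dataclass(frozen=True)
class GeneSpec:
    name: str
    baseline_cq: float  # cycles
    sigma_bio: float = 0.0  # cycles, biological replicate SD
    group_shifts: Mapping[str, float] = field(default_factory=dict)  # group -> cycles


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_bio: int = 3


@dataclass(frozen=True)
class GoiSpec:
    """Gene of interest with known per-group log2 fold vs the first group."""

    name: str
    baseline_cq: float
    log2_fold: Mapping[str, float]  # group -> true log2 fold change
    sigma_bio: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    genes: tuple[GeneSpec, ...]
    groups: tuple[GroupSpec, ...]
    n_tech: int = 3
    sigma_sample: float = 0.0  # cycles, shared loading-effect SD
    sigma_tech: float = 0.0  # cycles, well-to-well SD
    gois: tuple[GoiSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes] + [g.name for g in self.gois]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        if self.n_tech < 1 or any(g.n_bio < 1 for g in self.groups):
            raise ValueError("replicate counts must be >= 1")
        if self.sigma_sample < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be >= 0")
        if any(g.sigma_bio < 0 for g in self.genes):
            raise ValueError("sigma_bio must be >= 0")


@dataclass
class SimTruth:
    """Ground truth derived deterministically from the config."""

    sigma_bio: dict[str, float]
    group_shifts: dict[str, dict[str, float]]  # gene -> group -> cycles
    instability: dict[str, float]  # |shift deviation| mean + sigma_bio
    goi_fold: dict[str, dict[str, float]]  # goi -> group -> true fold (linear)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


def _truth(config: SimConfig) -> SimTruth:
    group_names = [g.name for g in config.groups]
    shifts = {
        g.name: {grp: float(g.group_shifts.get(grp, 0.0)) for grp in group_names}
        for g in config.genes
    }
    instab = {}
    for g in config.genes:
        d = np.array([shifts[g.name][grp] for grp in group_names])
        instab[g.name] = float(np.abs(d - d.mean()).mean() + g.sigma_bio)
    goi_fold = {
        goi.name: {grp: float(2.0 ** goi.log2_fold.get(grp, 0.0)) for grp in group_names}
        for goi in config.gois
    }
    return SimTruth(
        sigma_bio={g.name: float(g.sigma_bio) for g in config.genes},
        group_shifts=shifts,
        instability=instab,
        goi_fold=goi_fold,
    )


def generate(config: SimConfig) -> tuple[list[RawCqRecord], SimTruth]:
    """Draw a full well-level Cq dataset; bit-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    records: list[RawCqRecord] = []
    all_genes: list[tuple[str, float, float, Mapping[str, float]]] = [
        (g.name, g.baseline_cq, g.sigma_bio, dict(g.group_shifts))
        for g in config.genes
    ]
    for goi in config.gois:
        # fold f in group g lowers Cq by log2(f) relative to the first group
        shifts = {
            grp.name: -goi.log2_fold.get(grp.name, 0.0) for grp in config.groups
        }
        all_genes.append((goi.name, goi.baseline_cq, goi.sigma_bio, shifts))

    for grp in config.groups:
        for j in range(1, grp.n_bio + 1):
            sample_id = f"{grp.name}_{j}"
            # noise terms are always drawn (scale 0 yields 0.0) so that runs
            # differing only in one sigma share the remaining random numbers
            b = rng.normal(0.0, config.sigma_sample)
            for name, baseline, sigma_bio, shifts in all_genes:
                eps = rng.normal(0.0, sigma_bio)
                mean_cq = baseline + shifts.get(grp.name, 0.0) + b + eps
                for r in range(1, config.n_tech + 1):
                    eta = rng.normal(0.0, config.sigma_tech)
                    records.append(
                        RawCqRecord(
                            sample_id=sample_id,
                            group=grp.name,
                            gene=name,
                            replicate=r,
                            cq=float(mean_cq + eta),
                        )
                    )
    return records, _truth(config)


def generate_dilution(
    gene: str,
    efficiency_percent: float,
    intercept: float,
    decades: int = 5,
    sigma: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Ten-fold dilution series: cq = intercept - log10_amount / log10(1+E).

    ``intercept`` is the Cq at log10_amount = 0; points run from 0 down to
    -(decades-1) decades, i.e. a ``decades``-point ten-fold series.
    """
    if decades < 3:
        raise ValueError("need >= 3 decades")
    slope = slope_for_efficiency(efficiency_percent)  # cycles per decade, < 0
    rng = np.random.default_rng(seed)
    pts = []
    for d in range(decades):
        x = -float(d)
        noise = rng.normal(0.0, sigma)
        pts.append((x, intercept + slope * x + noise))
    return DilutionSeries(gene=gene, points=tuple(pts))


# --- the study-design preset -------------------------------------------------

#: Developmental stages, first one doubling as the ddCq calibrator.
FUNGAL_DEV_GROUPS = (
    GroupSpec("conidia", 3),
    GroupSpec("germ_tubes", 3),
    GroupSpec("short_hyphae", 3),
    GroupSpec("elongated_hyphae", 3),
)

#: 13 candidates: two designed ultra-stable genes (ACT1, 18S), a graded
#: middle field, and increasingly stage-shifted unstable genes ending at
#: HISTH4.  Baselines span ~10-30 cycles (rRNAs abundant, enzymes scarce).
FUNGAL_DEV_GENES = (
    GeneSpec("ACT1", 20.0, 0.05),
    GeneSpec("18S", 10.5, 0.05),
    GeneSpec("28S", 12.0, 0.25),
    GeneSpec("EF1", 19.0, 0.25),
    GeneSpec("LSM1", 24.0, 0.28),
    GeneSpec("ALG9", 25.0, 0.30, {"short_hyphae": 0.2}),
    GeneSpec("ACTN1", 22.0, 0.30),
    GeneSpec("TBCE", 23.0, 0.32),
    GeneSpec("DMA2", 26.0, 0.35, {"elongated_hyphae": 0.3}),
    GeneSpec("HPRT", 27.0, 0.40, {"elongated_hyphae": 0.4}),
    GeneSpec(
        "GAPDH", 21.0, 0.45,
        {"germ_tubes": 0.3, "short_hyphae": 0.5, "elongated_hyphae": 0.8},
    ),
    GeneSpec(
        "LDHA", 30.0, 0.50,
        {"germ_tubes": 0.4, "short_hyphae": 0.7, "elongated_hyphae": 1.0},
    ),
    GeneSpec(
        "HISTH4", 18.0, 0.55,
        {"germ_tubes": 0.8, "short_hyphae": 1.2, "elongated_hyphae": 1.8},
    ),
)

FUNGAL_DEV_GOIS = (
    GoiSpec(
        "CDC25", 26.0,
        {"germ_tubes": 1.0, "short_hyphae": 2.0, "elongated_hyphae": 3.0},
        sigma_bio=0.15,
    ),
    GoiSpec(
        "CHI1", 24.0,
        {"germ_tubes": -1.0, "short_hyphae": -1.5, "elongated_hyphae": -2.0},
        sigma_bio=0.15,
    ),
)


def fungal_dev_config(seed: int = 0, with_gois: bool = True) -> SimConfig:
    """Preset emulating a 13-gene, 4-stage, 3 bio x 3 tech replicate study."""
    return SimConfig(
        genes=FUNGAL_DEV_GENES,
        groups=FUNGAL_DEV_GROUPS,
        n_tech=3,
        sigma_sample=0.15,
        sigma_tech=0.10,
        gois=FUNGAL_DEV_GOIS if with_gois else (),
        seed=seed,
    )


#: Table of per-assay efficiencies used for synthetic dilution series,
#: spanning a realistic 98-110% window.
FUNGAL_DEV_EFFICIENCIES = {
    "18S": 108.7, "28S": 104.0, "ACT1": 107.8, "ALG9": 107.7, "ACTN1": 98.2,
    "EF1": 98.7, "GAPDH": 101.4, "HISTH4": 109.7, "HPRT": 100.7, "LDHA": 100.3,
    "TBCE": 100.6, "LSM1": 108.0, "DMA2": 103.1, "CDC25": 101.2, "CHI1": 104.5,
}
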