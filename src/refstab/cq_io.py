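"""Cq table data model, CSV readers/writers, replicate collapsing and QC.

A qPCR experiment yields one quantification cycle (Cq) per well; wells are
technical replicates of a biological sample measured for one gene.  This
module turns well-level records into the complete gene x sample matrix the
stability algorithms operate on, flagging (never silently dropping)
discordant technical replicates.

Long CSV layout (canonical): ``sample_id,group,gene,replicate,cq``.
Wide CSV layout (convenience): ``sample_id,group,<gene1>,...,<geneK>``
with one row per sample and implicit replicate 1.  "NA" or an empty cell
is a missing Cq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawCqRecord",
    "CqTable",
    "QcFlag",
    "read_cq",
    "write_cq",
    "collapse_replicates",
    "summarize",
    "require_complete",
    "CQ_MAX",
]

#: Accepted Cq window in cycles; values outside (0, CQ_MAX] are rejected.
CQ_MAX = 45.0

Layout = Literal["long", "wide"]


@dataclass(frozen=True)
class RawCqRecord:
    """One well: a technical replicate of (sample, gene)."""

    sample_id: str
    group: str
    gene: str
    replicate: int
    cq: float | None  # cycles; None = no amplification / missing

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")
        if self.cq is not None:
            if not math.isfinite(self.cq) or not (0.0 < self.cq <= CQ_MAX):
                raise ValueError(
                    f"cq must be finite and in (0, {CQ_MAX}], got {self.cq!r} "
                    f"for ({self.sample_id}, {self.gene}, rep {self.replicate})"
                )


@dataclass(frozen=True)
class QcFlag:
    sample_id: str
    gene: str
    reason: str


@dataclass
class CqTable:
    """Replicate-collapsed Cq matrix with group labels.

    ``values`` is genes x samples (cycles), NaN marking missing cells.
    ``efficiencies`` optionally maps gene -> amplification efficiency E as a
    fraction of perfect doubling (1.0 = 100%).
    """

    genes: list[str]
    samples: list[tuple[str, str]]  # (sample_id, group), ordered
    values: np.ndarray
    efficiencies: dict[str, float] | None = None
    qc_flags: list[QcFlag] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        if len({s for s, _ in self.samples}) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if any(not g for _, g in self.samples):
            raise ValueError("every sample needs a non-empty group label")
        if len(self.samples) < 2:
            raise ValueError("need at least 2 samples")

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

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples DataFrame (columns = sample ids)."""
        return pd.DataFrame(self.values, index=self.genes, columns=self.sample_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def subset_genes(self, keep: Sequence[str]) -> "CqTable":
        idx = [self.genes.index(g) for g in keep]
        eff = None
        if self.efficiencies is not None:
            eff = {g: self.efficiencies[g] for g in keep if g in self.efficiencies}
        return CqTable(
            genes=list(keep),
            samples=list(self.samples),
            values=self.values[idx],
            efficiencies=eff,
            qc_flags=list(self.qc_flags),
        )


def _parse_cq_cell(raw: object, where: str) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    if isinstance(raw, str):
        txt = raw.strip()
        if txt == "" or txt.upper() == "NA":
            return None
        raw = txt
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric cq value {raw!r} at {where}") from None


def read_cq(path: str | Path, layout: Layout = "long") -> list[RawCqRecord]:
    """Read well-level Cq records from a CSV file.

    Duplicate (sample_id, gene, replicate) triples are rejected with the
    offending row numbers; non-numeric Cq cells are rejected.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    records: list[RawCqRecord] = []
    if layout == "long":
        expected = ["sample_id", "group", "gene", "replicate", "cq"]
        if list(df.columns) != expected:
            raise ValueError(
                f"long layout expects header {expected}, got {list(df.columns)}"
            )
        for i, row in enumerate(df.itertuples(index=False), start=2):
            records.append(
                RawCqRecord(
                    sample_id=row.sample_id,
                    group=row.group,
                    gene=row.gene,
                    replicate=int(row.replicate),
                    cq=_parse_cq_cell(row.cq, f"{path.name}:{i}"),
                )
            )
    else:
        cols = list(df.columns)
        if cols[:2] != ["sample_id", "group"] or len(cols) < 3:
            raise ValueError(
                "wide layout expects header sample_id,group,<gene1>,...,<geneK>"
            )
        gene_cols = cols[2:]
        for i, row in enumerate(df.itertuples(index=False), start=2):
            for j, gene in enumerate(gene_cols):
                records.append(
                    RawCqRecord(
                        sample_id=row.sample_id,
                        group=row.group,
                        gene=gene,
                        replicate=1,
                        cq=_parse_cq_cell(row[2 + j], f"{path.name}:{i}:{gene}"),
                    )
                )

    seen: dict[tuple[str, str, int], int] = {}
    dups: list[str] = []
    for n, rec in enumerate(records, start=2):
        key = (rec.sample_id, rec.gene, rec.replicate)
        if key in seen:
            dups.append(f"{key} at rows {seen[key]} and {n}")
        else:
            seen[key] = n
    if dups:
        raise ValueError("duplicate (sample, gene, replicate): " + "; ".join(dups))
    return records


def write_cq(table: CqTable, path: str | Path, layout: Layout = "long") -> None:
    """Write a collapsed table back to CSV (replicate = 1 in long layout).

    Uses full-precision ``repr`` floats so that a write/read round trip
    reproduces the collapsed values bit-exactly.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")

    def fmt(v: float) -> str:
        return "NA" if np.isnan(v) else repr(float(v))

    lines: list[str] = []
    if layout == "long":
        lines.append("sample_id,group,gene,replicate,cq")
        for gi, gene in enumerate(table.genes):
            for si, (sid, grp) in enumerate(table.samples):
                lines.append(f"{sid},{grp},{gene},1,{fmt(table.values[gi, si])}")
    else:
        lines.append("sample_id,group," + ",".join(table.genes))
        for si, (sid, grp) in enumerate(table.samples):
            cells = ",".join(fmt(table.values[gi, si]) for gi in range(table.n_genes))
            lines.append(f"{sid},{grp},{cells}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def collapse_replicates(
    records: Iterable[RawCqRecord],
    max_spread: float = 0.5,
    efficiencies: dict[str, float] | None = None,
) -> CqTable:
    """Collapse technical replicates to their arithmetic mean Cq.

    The arithmetic mean on the Cq (log) scale equals the geometric mean on
    the quantity scale.  A (sample, gene) whose replicate range exceeds
    ``max_spread`` cycles is kept but flagged; a cell with no non-missing
    replicate is missing (NaN).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to collapse")
    if max_spread <= 0:
        raise ValueError("max_spread must be > 0")

    genes: list[str] = []
    samples: list[tuple[str, str]] = []
    group_of: dict[str, str] = {}
    for rec in records:
        if rec.gene not in genes:
            genes.append(rec.gene)
        if rec.sample_id not in group_of:
            group_of[rec.sample_id] = rec.group
            samples.append((rec.sample_id, rec.group))
        elif group_of[rec.sample_id] != rec.group:
            raise ValueError(
                f"sample {rec.sample_id!r} appears with conflicting groups "
                f"{group_of[rec.sample_id]!r} and {rec.group!r}"
            )

    reps: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        if rec.cq is not None:
            reps.setdefault((rec.sample_id, rec.gene), []).append(rec.cq)

    values = np.full((len(genes), len(samples)), np.nan)
    flags: list[QcFlag] = []
    for gi, gene in enumerate(genes):
        for si, (sid, _) in enumerate(samples):
            cqs = reps.get((sid, gene))
            if not cqs:
                continue
            values[gi, si] = float(np.mean(cqs))
            spread = max(cqs) - min(cqs)
            if spread > max_spread:
                flags.append(
                    QcFlag(sid, gene, f"replicate spread {spread:.3g} > {max_spread:g}")
                )
    return CqTable(genes, samples, values, efficiencies=efficiencies, qc_flags=flags)


def summarize(table: CqTable) -> pd.DataFrame:
    """Per-gene order statistics of the collapsed Cq (box-plot numbers).

    Returns a DataFrame indexed by gene with columns
    ``n, min, q25, median, q75, max``; a gene with no observed values has
    n = 0 and NaN statistics.
    """
    rows = []
    for gi, gene in enumerate(table.genes):
        v = table.values[gi]
        v = v[~np.isnan(v)]
        if v.size == 0:
            rows.append((gene, 0, *([np.nan] * 5)))
        else:
            rows.append(
                (
                    gene,
                    int(v.size),
                    float(v.min()),
                    float(np.percentile(v, 25)),
                    float(np.median(v)),
                    float(np.percentile(v, 75)),
                    float(v.max()),
                )
            )
    return pd.DataFrame(
        rows, columns=["gene", "n", "min", "q25", "median", "q75", "max"]
    ).set_index("gene")


def require_complete(
    table: CqTable, policy: Literal["error", "drop_samples"] = "error"
) -> CqTable:
    """Enforce a complete matrix: fail, or drop samples with any missing gene.

    The four stability algorithms all assume a complete gene x sample
    matrix; missing Cq is never imputed.
    """
    missing = np.argwhere(np.isnan(table.values))
    if missing.size == 0:
        return table
    cells = [(table.genes[gi], table.samples[si][0]) for gi, si in missing]
    if policy == "error":
        listed = ", ".join(f"({g} in {s})" for g, s in cells)
        raise ValueError(f"missing Cq values: {listed}")
    if policy != "drop_samples":
        raise ValueError(f"unknown policy {policy!r}")
    bad_samples = {s for _, s in cells}
    keep = [si for si, (sid, _) in enumerate(table.samples) if sid not in bad_samples]
    if len(keep) < 2:
        raise ValueError(
            f"dropping incomplete samples {sorted(bad_samples)} leaves "
            f"fewer than 2 samples"
        )
    dropped = [QcFlag(s, "*", "sample dropped: missing Cq") for s in sorted(bad_samples)]
    return CqTable(
        genes=list(table.genes),
        samples=[table.samples[i] for i in keep],
        values=table.values[:, keep],
        efficiencies=table.efficiencies,
        qc_flags=list(table.qc_flags) + dropped,
    )


def write_qc_flags(table: CqTable, path: str | Path) -> None:
    """QC flags as CSV ``sample_id,gene,reason``."""
    lines = ["sample_id,gene,reason"]
    for f in table.qc_flags:
        reason = f.reason.replace(",", ";")
        lines.append(f"{f.sample_id},{f.gene},{reason}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
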