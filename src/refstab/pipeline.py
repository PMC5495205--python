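"""End-to-end orchestration: Cq file -> stability report, RQ report.

Ties the modules together in the order a study runs them: read and collapse
Cq wells, enforce completeness, convert to relative quantities, run the
four stability algorithms, aggregate a consensus, decide the optimal
reference-gene count, and (separately) quantify genes of interest against
the chosen reference set.  Every artefact is written as CSV/JSON under an
output directory so reruns with the same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import __version__
from .bestkeeper import bestkeeper_analysis
from .consensus import aggregate, consensus_frame, heatmap_table
from .cq_io import CqTable, collapse_replicates, read_cq, require_complete, summarize, write_qc_flags
from .deltact import deltact_stability
from .genorm import DEFAULT_M_CUTOFF, DEFAULT_V_THRESHOLD, genorm_analysis
from .normfinder import normfinder_stability
from .quantify import compare_to_external, ddcq
from .quantities import to_expression

__all__ = ["RunConfig", "StabilityReport", "run_stability", "run_quantify", "load_table"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    input_path: str | Path
    layout: Literal["long", "wide"] = "long"
    use_efficiency: bool = False
    efficiencies: dict[str, float] | None = None
    max_spread: float = 0.5
    missing_policy: Literal["error", "drop_samples"] = "drop_samples"
    genorm_threshold: float = DEFAULT_V_THRESHOLD
    genorm_m_cutoff: float = DEFAULT_M_CUTOFF
    bestkeeper_metric: Literal["mad", "sd"] = "mad"
    normfinder_grouped: bool = True
    out_dir: str | Path = "results"
    # quantification block
    target: str | None = None
    references: list[str] = field(default_factory=list)
    calibrator_group: str | None = None
    contrast_reference: str | None = None  # optional unstable reference for contrast
    external_folds_path: str | Path | None = None


@dataclass
class StabilityReport:
    table: CqTable
    genorm: object
    normfinder: object | None
    bestkeeper: object
    deltact: object
    consensus: object
    summary: dict


def load_table(config: RunConfig) -> CqTable:
    records = read_cq(config.input_path, config.layout)
    table = collapse_replicates(
        records, max_spread=config.max_spread, efficiencies=config.efficiencies
    )
    return require_complete(table, policy=config.missing_policy)


def run_stability(config: RunConfig) -> StabilityReport:
    """Run all available stability methods and write the consolidated report.

    With fewer than 3 genes only geNorm-M/delta-Ct are computable; the
    consensus then aggregates the available methods and a warning is logged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        table = load_table(config)
        expr = to_expression(table, use_efficiency=config.use_efficiency)
    except Exception as e:
        raise RuntimeError(f"stage cq_io/quantities failed: {e}") from e

    summarize(table).to_csv(out / "cq_summary.csv")
    write_qc_flags(table, out / "qc_flags.csv")

    method_ranks: dict[str, dict[str, float]] = {}

    try:
        dct = deltact_stability(table)
    except Exception as e:
        raise RuntimeError(f"stage deltact failed: {e}") from e
    method_ranks["deltact"] = dct.ranks
    pd.DataFrame(
        {"deltact_mean_sd": dct.stability, "deltact_rank": dct.ranks}
    ).rename_axis("gene").to_csv(out / "deltact.csv")

    try:
        bk = bestkeeper_analysis(table, metric=config.bestkeeper_metric)
    except Exception as e:
        raise RuntimeError(f"stage bestkeeper failed: {e}") from e
    method_ranks["bestkeeper"] = bk.ranks
    bk_out = bk.stats.copy()
    bk_out["pearson_r"] = [bk.correlation[g][0] for g in bk_out.index]
    bk_out["p_value"] = [bk.correlation[g][1] for g in bk_out.index]
    bk_out["bestkeeper_rank"] = [bk.ranks[g] for g in bk_out.index]
    bk_out.to_csv(out / "bestkeeper.csv")

    gn = None
    nf_res = None
    if table.n_genes >= 3:
        try:
            gn = genorm_analysis(
                expr, threshold=config.genorm_threshold, m_cutoff=config.genorm_m_cutoff
            )
        except Exception as e:
            raise RuntimeError(f"stage genorm failed: {e}") from e
        method_ranks["genorm"] = gn.ranks
        pd.DataFrame(
            {"m_value": gn.m_values, "genorm_rank": gn.ranks}
        ).rename_axis("gene").to_csv(out / "genorm.csv")
        pd.Series(gn.v_values, name="v_value").rename_axis("n").to_csv(
            out / "genorm_v.csv"
        )
        try:
            nf_res = normfinder_stability(expr, grouped=config.normfinder_grouped)
            method_ranks["normfinder"] = nf_res.ranks
            pd.DataFrame(
                {
                    "normfinder_stability": nf_res.stability,
                    "normfinder_rank": nf_res.ranks,
                }
            ).rename_axis("gene").to_csv(out / "normfinder.csv")
        except ValueError as e:
            logger.warning("normfinder skipped: %s", e)
    else:
        logger.warning(
            "only %d genes: geNorm stepwise/NormFinder skipped, "
            "consensus uses available methods", table.n_genes,
        )

    try:
        cons = aggregate(method_ranks)
    except Exception as e:
        raise RuntimeError(f"stage consensus failed: {e}") from e
    consensus_frame(cons).to_csv(out / "consensus.csv")
    heatmap_table(cons).to_csv(out / "rank_heatmap.csv")

    n_opt = gn.optimal_n if gn is not None else "undetermined"
    n_rec = n_opt if isinstance(n_opt, int) else table.n_genes
    summary = {
        "schema_version": SCHEMA_VERSION,
        "refstab_version": __version__,
        "n_genes": table.n_genes,
        "n_samples": table.n_samples,
        "methods_used": cons.methods_used,
        "optimal_n": n_opt,
        "recommended_set": cons.final_order[:n_rec],
        "genorm_threshold": config.genorm_threshold,
        "genorm_m_cutoff": config.genorm_m_cutoff,
        "genorm_flagged": gn.flagged if gn is not None else [],
        "bestkeeper_metric": config.bestkeeper_metric,
        "normfinder_grouped": config.normfinder_grouped,
        "final_order": cons.final_order,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n", encoding="utf-8"
    )
    return StabilityReport(table, gn, nf_res, bk, dct, cons, summary)


def _read_external_folds(path: str | Path) -> dict[str, list[float]]:
    df = pd.read_csv(path)
    expected = ["group", "replicate", "fold"]
    if list(df.columns) != expected:
        raise ValueError(f"external folds CSV expects header {expected}")
    return {
        str(g): sub["fold"].astype(float).tolist()
        for g, sub in df.groupby("group", sort=False)
    }


def run_quantify(config: RunConfig) -> dict:
    """2^-ddCq quantification (optionally contrasted against an unstable
    reference) plus optional Mann-Whitney validation against external folds.
    """
    if not config.target or not config.references or not config.calibrator_group:
        raise ValueError("quantify needs target, references and calibrator_group")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_table(config)

    rq = ddcq(table, config.target, config.references, config.calibrator_group)
    folds = pd.DataFrame(
        {"group": rq.groups, "fold": rq.per_sample_fold}
    ).rename_axis("sample_id")
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "target": config.target,
        "references": list(config.references),
        "calibrator_group": config.calibrator_group,
    }

    if config.contrast_reference:
        rq_bad = ddcq(
            table, config.target, [config.contrast_reference], config.calibrator_group
        )
        folds["fold_contrast_ref"] = rq_bad.per_sample_fold
        rq_bad.group_summary.to_csv(out / f"{config.target}_contrast_summary.csv")
        report["contrast_reference"] = config.contrast_reference

    folds.to_csv(out / f"{config.target}_folds.csv")
    rq.group_summary.to_csv(out / f"{config.target}_summary.csv")

    if config.external_folds_path:
        ext = _read_external_folds(config.external_folds_path)
        rows = []
        for grp in ext:
            if grp == config.calibrator_group:
                continue
            res = compare_to_external(rq, ext, grp)
            rows.append(
                {
                    "group": grp, "u": res.u_statistic, "z": res.z_value,
                    "p_value": res.p_value, "method": res.method,
                    "significance": res.significance(),
                }
            )
        pd.DataFrame(rows).to_csv(out / f"{config.target}_validation.csv", index=False)
        report["validation_groups"] = [r["group"] for r in rows]

    (out / f"{config.target}_rq.json").write_text(
        json.dumps(report, indent=2) + "\n", encoding="utf-8"
    )
    return report
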