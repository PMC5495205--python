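"""Rank candidate reference genes by the four stability algorithms.

Runs geNorm, NormFinder, BestKeeper and comparative delta-Ct on the
simulated candidate panel (the two genes of interest are excluded from the
candidate set) and aggregates a geometric-mean consensus ranking.

Reads <out>/sim/cq_long.csv; writes <out>/stability/ (per-method CSVs,
consensus table, rank heat-map table, figures, summary.json).
"""

import argparse
import json
from pathlib import Path

from refstab.bestkeeper import bestkeeper_analysis
from refstab.consensus import aggregate, consensus_frame, heatmap_table
from refstab.cq_io import collapse_replicates, read_cq, summarize
from refstab.deltact import deltact_stability
from refstab.genorm import genorm_analysis
from refstab.normfinder import normfinder_stability
from refstab.plots import consensus_bar_chart, cq_boxplot, v_bar_chart
from refstab.quantities import to_expression

GOI = {"CDC25", "CHI1"}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out / "stability"
    out.mkdir(parents=True, exist_ok=True)

    table = collapse_replicates(read_cq(args.out / "sim" / "cq_long.csv", "long"))
    candidates = table.subset_genes([g for g in table.genes if g not in GOI])
    expr = to_expression(candidates)

    summarize(candidates).to_csv(out / "cq_summary.csv")
    cq_boxplot(candidates, out / "cq_distribution.png")

    gn = genorm_analysis(expr)
    nf = normfinder_stability(expr)
    bk = bestkeeper_analysis(candidates)
    dct = deltact_stability(candidates)
    cons = aggregate(
        {"genorm": gn.ranks, "normfinder": nf.ranks,
         "bestkeeper": bk.ranks, "deltact": dct.ranks}
    )

    import pandas as pd

    pd.DataFrame({"m_value": gn.m_values, "genorm_rank": gn.ranks}).rename_axis(
        "gene"
    ).to_csv(out / "genorm.csv")
    pd.DataFrame(
        {"normfinder_stability": nf.stability, "normfinder_rank": nf.ranks}
    ).rename_axis("gene").to_csv(out / "normfinder.csv")
    bk.stats.assign(bestkeeper_rank=[bk.ranks[g] for g in bk.stats.index]).to_csv(
        out / "bestkeeper.csv"
    )
    pd.DataFrame(
        {"deltact_mean_sd": dct.stability, "deltact_rank": dct.ranks}
    ).rename_axis("gene").to_csv(out / "deltact.csv")
    consensus_frame(cons).to_csv(out / "consensus.csv")
    heatmap_table(cons).to_csv(out / "rank_heatmap.csv")
    consensus_bar_chart(cons, out / "consensus_ranking.png")
    v_bar_chart(gn.v_values, gn.threshold, out / "pairwise_variation.png")

    summary = {
        "final_order": cons.final_order,
        "top2": cons.final_order[:2],
        "max_m": max(gn.m_values.values()),
        "genes_above_m_cutoff": gn.flagged,
        "v_values": {str(k): v for k, v in gn.v_values.items()},
        "optimal_n": gn.optimal_n,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print("consensus ranking (most -> least stable):")
    print("  " + ", ".join(cons.final_order))
    print(f"all geNorm M values below 1.5: {max(gn.m_values.values()):.3f} max, "
          f"flagged: {gn.flagged or 'none'}")
    print(f"V2/3 = {gn.v_values[2]:.3f}, V3/4 = {gn.v_values[3]:.3f} "
          f"-> optimal number of reference genes = {gn.optimal_n}")


if __name__ == "__main__":
    main()
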