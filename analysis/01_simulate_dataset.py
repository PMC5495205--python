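"""Generate the synthetic qPCR study dataset.

Emulates a 13-candidate reference-gene screen across four fungal
developmental stages (conidia, germ tubes, short hyphae, elongated hyphae),
3 biological x 3 technical replicates, plus two genes of interest with
known fold changes and ten-fold dilution series for every assay.

Writes under <out>/sim/: cq_long.csv (well-level Cq), truth.json (the
generative ground truth), dilution.csv (standard-curve points).
"""

import argparse
from pathlib import Path

from refstab.simulate import (
    FUNGAL_DEV_EFFICIENCIES,
    generate,
    generate_dilution,
    fungal_dev_config,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out / "sim"
    out.mkdir(parents=True, exist_ok=True)

    config = fungal_dev_config(seed=args.seed)
    records, truth = generate(config)
    rows = ["sample_id,group,gene,replicate,cq"] + [
        f"{r.sample_id},{r.group},{r.gene},{r.replicate},{r.cq!r}" for r in records
    ]
    (out / "cq_long.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    truth.to_json(out / "truth.json")

    dil = ["gene,log10_amount,cq"]
    for i, (gene, eff) in enumerate(FUNGAL_DEV_EFFICIENCIES.items()):
        series = generate_dilution(
            gene, eff, intercept=30.0, decades=5, sigma=0.05,
            seed=args.seed * 1000 + i,
        )
        dil += [f"{gene},{float(x)!r},{float(cq)!r}" for x, cq in series.points]
    (out / "dilution.csv").write_text("\n".join(dil) + "\n", encoding="utf-8")

    cqs = [r.cq for r in records]
    print(f"wrote {len(records)} wells for {len(config.genes)} candidates "
          f"+ {len(config.gois)} targets across {len(config.groups)} stages")
    print(f"Cq range: {min(cqs):.2f}-{max(cqs):.2f} cycles")
    print(f"outputs in {out}/")


if __name__ == "__main__":
    main()
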