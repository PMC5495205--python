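"""Amplification-efficiency QC from the simulated dilution series.

Fits each assay's standard curve (Cq vs log10 input), converts slopes to
efficiencies, and gates assays on R^2 >= 0.99 and a 90-110% window —
the usual prerequisites before any stability analysis is trusted.

Reads <out>/sim/dilution.csv; writes <out>/efficiency/.
"""

import argparse
import json
from pathlib import Path

from refstab.efficiency import (
    fit_standard_curve,
    gate_assays,
    read_dilution_csv,
    write_fits_csv,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out / "efficiency"
    out.mkdir(parents=True, exist_ok=True)

    series = read_dilution_csv(args.out / "sim" / "dilution.csv")
    fits = [fit_standard_curve(s) for s in series]
    write_fits_csv(fits, out / "efficiency.csv")
    passed = gate_assays(fits)
    (out / "passed.json").write_text(json.dumps({"passed": passed}, indent=2) + "\n")

    effs = [f.efficiency_percent for f in fits]
    print(f"{len(passed)}/{len(fits)} assays pass "
          f"(efficiencies {min(effs):.1f}-{max(effs):.1f}%, "
          f"min R^2 {min(f.r_squared for f in fits):.4f})")
    for f in fits:
        if not f.acceptable:
            print(f"  excluded: {f.gene} ({f.reason})")


if __name__ == "__main__":
    main()
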