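"""Amplification-efficiency estimation from serial-dilution standard curves.

A ten-fold dilution series of template gives Cq as a linear function of
log10(input amount); the slope determines the per-cycle amplification
efficiency E = 10^(-1/slope) - 1 (slope -3.3219 corresponds to perfect
doubling, E = 100%).  Assays are gated on slope sign, linearity (R^2) and
an efficiency window before their genes enter downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyFit",
    "fit_standard_curve",
    "gate_assays",
    "read_dilution_csv",
    "write_fits_csv",
    "slope_for_efficiency",
    "DEFAULT_R2_MIN",
    "DEFAULT_EFF_LO",
    "DEFAULT_EFF_HI",
]

DEFAULT_R2_MIN = 0.99
DEFAULT_EFF_LO = 90.0  # percent
DEFAULT_EFF_HI = 110.0  # percent


@dataclass(frozen=True)
class DilutionSeries:
    """Standard-curve points for one assay: (log10 input amount, Cq)."""

    gene: str
    points: tuple[tuple[float, float], ...]  # (log10_amount in decades, cq cycles)

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError(f"{self.gene}: need >= 3 dilution points")
        if len({round(x, 12) for x, _ in self.points}) < 3:
            raise ValueError(f"{self.gene}: need >= 3 distinct log10 amounts")


@dataclass(frozen=True)
class EfficiencyFit:
    gene: str
    slope: float  # cycles per decade
    intercept: float  # cycles at log10_amount = 0
    r_squared: float
    efficiency_percent: float  # 100 * (10^(-1/slope) - 1); NaN if slope >= 0
    acceptable: bool
    reason: str = ""


def slope_for_efficiency(efficiency_percent: float) -> float:
    """Inverse of the slope->efficiency formula: slope = -1/log10(1 + E)."""
    if efficiency_percent <= 0:
        raise ValueError("efficiency must be > 0%")
    return -1.0 / np.log10(1.0 + efficiency_percent / 100.0)


def fit_standard_curve(
    series: DilutionSeries,
    r2_min: float = DEFAULT_R2_MIN,
    eff_lo: float = DEFAULT_EFF_LO,
    eff_hi: float = DEFAULT_EFF_HI,
) -> EfficiencyFit:
    """OLS of Cq on log10 amount; replicated Cq at a point are averaged first."""
    pts = pd.DataFrame(series.points, columns=["x", "cq"])
    pts = pts.groupby("x", as_index=False)["cq"].mean()
    x = pts["x"].to_numpy()
    y = pts["cq"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError(f"{series.gene}: degenerate dilution range")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    if slope >= 0:
        return EfficiencyFit(
            series.gene, slope, float(res.intercept), r2,
            float("nan"), False, "non-amplifying slope",
        )
    eff = float(100.0 * (10.0 ** (-1.0 / slope) - 1.0))
    ok = r2 >= r2_min and eff_lo <= eff <= eff_hi
    reason = "" if ok else (
        f"R^2 {r2:.4f} < {r2_min}" if r2 < r2_min
        else f"efficiency {eff:.1f}% outside [{eff_lo}, {eff_hi}]%"
    )
    return EfficiencyFit(series.gene, slope, float(res.intercept), r2, eff, ok, reason)


def gate_assays(
    fits: Sequence[EfficiencyFit],
    r2_min: float = DEFAULT_R2_MIN,
    eff_lo: float = DEFAULT_EFF_LO,
    eff_hi: float = DEFAULT_EFF_HI,
) -> list[str]:
    """Genes whose fits pass the thresholds, in input order."""
    if not fits:
        raise ValueError("no fits supplied")
    if eff_lo > eff_hi:
        raise ValueError(f"empty efficiency window [{eff_lo}, {eff_hi}]")
    passed = []
    for f in fits:
        if (
            f.slope < 0
            and f.r_squared >= r2_min
            and eff_lo <= f.efficiency_percent <= eff_hi
        ):
            passed.append(f.gene)
    return passed


def read_dilution_csv(path: str | Path) -> list[DilutionSeries]:
    """Read ``gene,log10_amount,cq`` into one series per gene (input order)."""
    df = pd.read_csv(path)
    expected = ["gene", "log10_amount", "cq"]
    if list(df.columns) != expected:
        raise ValueError(f"dilution CSV expects header {expected}, got {list(df.columns)}")
    out = []
    for gene in df["gene"].drop_duplicates():
        sub = df[df["gene"] == gene]
        pts = tuple(zip(sub["log10_amount"].astype(float), sub["cq"].astype(float)))
        out.append(DilutionSeries(gene=str(gene), points=pts))
    return out


def write_fits_csv(fits: Sequence[EfficiencyFit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": f.gene,
                "slope": f.slope,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "efficiency_percent": f.efficiency_percent,
                "acceptable": f.acceptable,
            }
            for f in fits
        ]
    ).to_csv(path, index=False)
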