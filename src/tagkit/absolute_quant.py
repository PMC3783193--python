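"""Quant-peptide absolute quantification.

A heavy-lysine internal standard (default 500 fmol) is spiked into the
tryptic digest of a CoIP eluate; the light/heavy peak-volume ratio gives
the amount of bait-derived Quant peptide in the eluate, and — given the
number of input cells and an assumed CoIP recovery (default 50%) — the
bait copy number per cell:

    copies/cell = fmol * 1e-15 * N_A / (n_cells * yield)

Reported copy numbers are rounded to one significant figure (the raw
value is always retained); calibration series can be checked for
linearity over the working range by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from math import floor, log10

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TagkitError

AVOGADRO = 6.02214076e23


@dataclass
class QuantMeasurement:
    light_volume: float
    heavy_volume: float
    spike_fmol: float = 500.0
    n_cells: int = 40_000_000
    coip_yield: float = 0.5

    def __post_init__(self) -> None:
        if self.light_volume < 0 or self.heavy_volume < 0:
            raise TagkitError("peak volumes must be >= 0")
        if not 0 < self.coip_yield <= 1:
            raise TagkitError("CoIP yield must be in (0, 1]")
        if self.n_cells < 1:
            raise TagkitError("n_cells must be >= 1")
        if self.spike_fmol <= 0:
            raise TagkitError("spike amount must be positive")


@dataclass
class CalibrationSeries:
    """(concentration, peak volume) pairs, concentrations strictly
    increasing."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise TagkitError("calibration needs >= 2 points")
        conc = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise TagkitError("concentrations must be strictly increasing (no duplicates)")


def eluate_fmol(m: QuantMeasurement) -> float:
    """Amount of light (bait-derived) Quant peptide in the eluate."""
    if m.heavy_volume == 0:
        raise TagkitError("no internal standard detected (heavy peak volume is 0)")
    return (m.light_volume / m.heavy_volume) * m.spike_fmol


def round_to_sig(x: float, sig: int = 1, mode: str = "half_up") -> float:
    """Round to ``sig`` significant figures; ``mode`` is 'half_up'
    (default) or 'half_even'."""
    if x == 0:
        return 0.0
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_HALF_EVEN
    exponent = floor(log10(abs(x)))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(x)).quantize(quantum, rounding=rounding))


@dataclass(frozen=True)
class CopyNumber:
    raw: float
    reported: float


def copies_per_cell(
    fmol: float,
    n_cells: int,
    coip_yield: float = 0.5,
    sig_figures: int = 1,
    rounding: str = "half_up",
) -> CopyNumber:
    """Bait copies per cell from the eluate amount; reported value is
    rounded to one significant figure by default."""
    if fmol < 0:
        raise TagkitError("fmol must be >= 0")
    if not 0 < coip_yield <= 1:
        raise TagkitError("CoIP yield must be in (0, 1]")
    if n_cells < 1:
        raise TagkitError("n_cells must be >= 1")
    raw = fmol * 1e-15 * AVOGADRO / (n_cells * coip_yield)
    return CopyNumber(raw=raw, reported=round_to_sig(raw, sig_figures, rounding))


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    linear_range: bool


def check_linearity(series: CalibrationSeries, r2_threshold: float = 0.99) -> LinearityResult:
    """Ordinary least squares of peak volume on concentration; the
    series is flagged linear when r^2 meets the threshold."""
    if len(series.points) < 3:
        raise TagkitError("r^2 needs >= 3 calibration points")
    conc = np.array([c for c, _ in series.points], dtype=float)
    vol = np.array([v for _, v in series.points], dtype=float)
    fit = stats.linregress(conc, vol)
    r2 = float(fit.rvalue**2)
    return LinearityResult(float(fit.slope), float(fit.intercept), r2, r2 >= r2_threshold)


def process_measurements(
    measurements: pd.DataFrame,
    coip_yield: float = 0.5,
    sig_figures: int = 1,
    rounding: str = "half_up",
) -> pd.DataFrame:
    """Replicate-level table -> per-protein summary.

    Input columns: protein, replicate, light_volume, heavy_volume,
    spike_fmol, n_cells. The eluate amount is computed per replicate and
    reported as mean +/- sample SD; copy numbers derive from the mean.
    """
    required = {"protein", "replicate", "light_volume", "heavy_volume", "spike_fmol", "n_cells"}
    missing = required - set(measurements.columns)
    if missing:
        raise TagkitError(f"measurement table lacks columns {sorted(missing)}")
    rows = []
    for protein, grp in measurements.groupby("protein", sort=True):
        fmols = [
            eluate_fmol(
                QuantMeasurement(
                    light_volume=r.light_volume,
                    heavy_volume=r.heavy_volume,
                    spike_fmol=r.spike_fmol,
                    n_cells=int(r.n_cells),
                    coip_yield=coip_yield,
                )
            )
            for r in grp.itertuples()
        ]
        n_cells = int(grp["n_cells"].iloc[0])
        mean_fmol = float(np.mean(fmols))
        cn = copies_per_cell(mean_fmol, n_cells, coip_yield, sig_figures, rounding)
        rows.append(
            {
                "protein": protein,
                "n_replicates": len(fmols),
                "fmol_mean": mean_fmol,
                "fmol_sd": float(np.std(fmols, ddof=1)) if len(fmols) > 1 else 0.0,
                "copies_raw": cn.raw,
                "copies_reported": cn.reported,
            }
        )
    return pd.DataFrame(rows)
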