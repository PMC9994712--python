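"""GC-FID quantification of PHA monomers as weight percent of cell dry weight.

External-standard calibration converts integrated peak areas to monomer
masses; results are expressed per monomer and in total as percent of the
freeze-dried pellet mass, with volumetric titers derived from culture CDW.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONOMERS",
    "CalibrationStandard",
    "Calibration",
    "PHAQuantResult",
    "fit_calibration",
    "quantify_sample",
    "summarize_experiments",
]

#: Monomer labels with shipped external standards (3-hydroxybutyrate,
#: -hexanoate, -octanoate, -decanoate methyl esters). Other labels are
#: accepted pass-through when the user supplies a calibration.
MONOMERS = ("3HB", "3HHx", "3HO", "3HD")


@dataclass(frozen=True)
class CalibrationStandard:
    """External-standard points for one monomer: (amount mg, peak area)."""

    monomer: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("calibration needs at least 2 points")
        amounts = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise ValueError("calibration amounts must be strictly increasing")
        if any(p[1] < 0 for p in self.points):
            raise ValueError("peak areas must be non-negative")


@dataclass(frozen=True)
class Calibration:
    monomer: str
    slope: float  # area per mg
    intercept: float
    r_squared: float

    def amount_mg(self, area: float) -> float:
        return (area - self.intercept) / self.slope


def fit_calibration(std: CalibrationStandard,
                    through_origin: bool = True) -> Calibration:
    """Least-squares line area = slope·amount (+ intercept).

    Through-origin mode (the default) suits single- or few-point external
    standards; R² is computed against the uncentered total sum of squares in
    that mode.  A non-positive fitted slope is a calibration failure.
    """
    x = np.array([p[0] for p in std.points], dtype=float)
    y = np.array([p[1] for p in std.points], dtype=float)
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        ss_res = float(np.sum((y - slope * x) ** 2))
        ss_tot = float(np.sum(y ** 2))
    else:
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    if slope <= 0:
        raise ValueError(f"calibration failure for {std.monomer}: "
                         f"non-positive slope {slope:.4g}")
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return Calibration(std.monomer, float(slope), float(intercept), r2)


@dataclass(frozen=True)
class PHAQuantResult:
    """Per-monomer and total PHA content of one sample.

    ``total_percent`` is the sum of the monomer percents;
    ``volumetric = total_percent/100 × cdw`` when CDW (g/L) is known.
    """

    sample_id: str
    percents: Mapping[str, float]  # monomer -> % of CDW
    cdw: float | None = None  # g/L
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def total_percent(self) -> float:
        return float(sum(self.percents.values()))

    @property
    def volumetric(self) -> float | None:
        if self.cdw is None:
            return None
        return self.total_percent / 100.0 * self.cdw

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.percents.values()):
            raise ValueError("monomer percents must be >= 0")
        if not 0 <= self.total_percent <= 100:
            raise ValueError(
                f"total percent {self.total_percent:.3g} outside [0, 100]")


def quantify_sample(areas: Mapping[str, float],
                    calibrations: Mapping[str, Calibration],
                    pellet_mass_mg: float,
                    cdw_g_per_L: float | None = None, *,
                    sample_id: str = "") -> PHAQuantResult:
    """Convert peak areas to monomer weight percents of the pellet mass.

    Every monomer with a nonzero area needs a calibration; a missing one is
    an error naming the monomer.  Zero-area monomers contribute 0%.
    """
    if pellet_mass_mg <= 0:
        raise ValueError("pellet mass must be > 0")
    percents: dict[str, float] = {}
    for monomer, area in areas.items():
        if area == 0:
            percents[monomer] = 0.0
            continue
        cal = calibrations.get(monomer)
        if cal is None:
            raise KeyError(f"no calibration for monomer {monomer!r}")
        mg = cal.amount_mg(area)
        percents[monomer] = max(mg, 0.0) / pellet_mass_mg * 100.0
    return PHAQuantResult(sample_id=sample_id, percents=percents, cdw=cdw_g_per_L)


def summarize_experiments(results: pd.DataFrame,
                          group_cols: Sequence[str] = ("strain", "substrate"),
                          value_cols: Sequence[str] | None = None,
                          level_cols: Sequence[str] = ("experiment", "biological",
                                                       "technical")) -> pd.DataFrame:
    """Production-summary table with hierarchical replicate averaging.

    Replicate structure is respected by averaging the innermost level first
    (technical → biological → experiment); the reported SD is the sample SD
    across the outermost level present, matching designs where variability is
    quoted between independent experiments.  Levels absent from the frame are
    skipped.  For balanced designs the hierarchical mean equals the flat mean.
    """
    if value_cols is None:
        value_cols = [c for c in results.columns
                      if c not in set(group_cols) | set(level_cols)
                      and pd.api.types.is_numeric_dtype(results[c])]
    levels = [c for c in level_cols if c in results.columns]
    frame = results.copy()
    # collapse inner replicate levels one at a time, innermost first
    while len(levels) > 1:
        keep = list(group_cols) + levels[:-1]
        frame = (frame.groupby(keep, dropna=False)[list(value_cols)]
                 .mean().reset_index())
        levels = levels[:-1]
    grouped = frame.groupby(list(group_cols), dropna=False)[list(value_cols)]
    summary = grouped.agg(["mean", "std", "count"])
    summary.columns = [f"{v}_{stat}" for v, stat in summary.columns]
    return summary.reset_index()
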