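"""Phenotype-microarray (Biolog PM1) kinetic analysis.

Parses 96-well kinetic absorbance data, subtracts the no-carbon control
well, averages replicate plates, classifies substrate utilization at
configurable net-absorbance cutoffs, and exports substrate × timepoint
heatmaps.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WELLS_96",
    "KineticPlate",
    "PhenotypeCall",
    "pm1_layout",
    "read_plate_csv",
    "write_plate_csv",
    "subtract_background",
    "average_plates",
    "classify_substrates",
    "count_metabolized",
    "export_heatmap",
]

#: Standard 96-well ids, row-major (A1..A12, B1..B12, ..., H12).
WELLS_96 = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))

DEFAULT_CUTOFFS = (0.15, 0.30, 1.00)


def pm1_layout() -> dict[str, str]:
    """Well → substrate map for the standard PM1 plate (A1 = no-carbon)."""
    ref = importlib.resources.files("phascreen.data") / "pm1_layout.csv"
    frame = pd.read_csv(str(ref))
    return dict(zip(frame["well"], frame["substrate"]))


@dataclass
class KineticPlate:
    """Time-resolved 96-well absorbance matrix.

    ``data`` holds one column per well on a shared time grid; ``layout``
    maps wells to substrate names and ``control_well`` names the no-carbon
    background well.
    """

    times: np.ndarray
    data: pd.DataFrame  # columns = well ids, rows aligned with times
    layout: Mapping[str, str]
    control_well: str = "A1"
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.data) != self.times.size:
            raise ValueError("data rows must match the time grid")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ValueError("duplicate well ids in plate data")
        if self.control_well not in self.data.columns:
            raise ValueError(f"control well {self.control_well!r} not in plate")
        if self.control_well not in self.layout:
            raise ValueError(f"control well {self.control_well!r} not in layout")

    @property
    def wells(self) -> list[str]:
        return list(self.data.columns)

    def well_series(self, well: str) -> np.ndarray:
        return self.data[well].to_numpy(dtype=float)


def read_plate_csv(path: str | Path, layout: Mapping[str, str] | None = None,
                   control_well: str = "A1") -> KineticPlate:
    """Read a kinetic plate CSV (``time_h`` column followed by well columns)."""
    frame = pd.read_csv(path)
    if "time_h" not in frame.columns:
        raise ValueError(f"{path}: missing 'time_h' column")
    times = frame.pop("time_h").to_numpy(dtype=float)
    if layout is None:
        layout = {w: w for w in frame.columns}
    return KineticPlate(times=times, data=frame, layout=layout,
                        control_well=control_well)


def write_plate_csv(plate: KineticPlate, path: str | Path) -> Path:
    path = Path(path)
    out = plate.data.copy()
    out.insert(0, "time_h", plate.times)
    out.to_csv(path, index=False)
    return path


def _check_same_grid(a: KineticPlate, b: KineticPlate) -> None:
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("plates have mismatched time grids")


def subtract_background(plate: KineticPlate) -> KineticPlate:
    """Subtract the no-carbon control series from every well, per timepoint.

    The control well becomes identically zero in the result.
    """
    control = plate.data[plate.control_well]
    net = plate.data.sub(control, axis=0)
    return replace(plate, data=net, background_subtracted=True)


def average_plates(plates: Sequence[KineticPlate]) -> KineticPlate:
    """Pointwise mean of replicate plates with identical layouts and grids."""
    if not plates:
        raise ValueError("no plates to average")
    first = plates[0]
    for other in plates[1:]:
        _check_same_grid(first, other)
        if dict(other.layout) != dict(first.layout):
            raise ValueError("plates have mismatched layouts")
        if list(other.data.columns) != list(first.data.columns):
            raise ValueError("plates have mismatched well columns")
    mean = sum(p.data for p in plates) / len(plates)
    return replace(first, data=mean)


@dataclass(frozen=True)
class PhenotypeCall:
    """Per-substrate utilization call at each cutoff."""

    substrate: str
    well: str
    max_net_abs: float
    metabolized_at: dict = field(default_factory=dict)


def classify_substrates(plate: KineticPlate,
                        cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
                        endpoint_only: bool = False) -> list[PhenotypeCall]:
    """Call substrate utilization from a background-subtracted plate.

    A substrate is metabolized at cutoff ``c`` iff the maximum net absorbance
    over all timepoints strictly exceeds ``c`` (the final timepoint only,
    when ``endpoint_only`` is set).  The control well itself is excluded.
    """
    if not plate.background_subtracted:
        raise ValueError("plate must be background-subtracted before calling "
                         "(apply subtract_background first)")
    cutoffs = sorted(float(c) for c in cutoffs)
    calls = []
    for well in plate.wells:
        if well == plate.control_well:
            continue
        series = plate.well_series(well)
        value = float(series[-1]) if endpoint_only else float(np.max(series))
        calls.append(PhenotypeCall(
            substrate=plate.layout.get(well, well),
            well=well,
            max_net_abs=value,
            metabolized_at={c: value > c for c in cutoffs},
        ))
    return calls


def count_metabolized(calls: Sequence[PhenotypeCall]) -> dict[float, int]:
    """Substrate counts per cutoff; monotone non-increasing in the cutoff."""
    if not calls:
        return {}
    cutoffs = sorted(calls[0].metabolized_at)
    return {c: sum(call.metabolized_at[c] for call in calls) for c in cutoffs}


def calls_to_frame(calls: Sequence[PhenotypeCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        row = {"well": call.well, "substrate": call.substrate,
               "max_net_abs": call.max_net_abs}
        row.update({f"metabolized_at_{c:g}": v
                    for c, v in call.metabolized_at.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def export_heatmap(plate: KineticPlate,
                   substrates: Sequence[str] | None = None,
                   timepoints: Sequence[float] | None = None,
                   out_csv: str | Path | None = None,
                   out_png: str | Path | None = None) -> pd.DataFrame:
    """Substrate × timepoint matrix of net absorbance, optionally rendered.

    Row order follows the requested substrate order.  Unknown substrate names
    raise an error listing valid ones.  Negative net values are retained in
    the matrix; color scaling in the rendered figure floors at zero.
    """
    by_substrate = {plate.layout.get(w, w): w for w in plate.wells
                    if w != plate.control_well}
    if substrates is None:
        substrates = list(by_substrate)
    for s in substrates:
        if s not in by_substrate:
            raise KeyError(f"unknown substrate {s!r}; valid: {sorted(by_substrate)}")
    if timepoints is None:
        timepoints = list(plate.times)
    t_idx = []
    for tp in timepoints:
        matches = np.flatnonzero(np.isclose(plate.times, tp))
        if matches.size == 0:
            raise KeyError(f"timepoint {tp} h not on the plate's grid")
        t_idx.append(int(matches[0]))
    matrix = pd.DataFrame(
        [[plate.well_series(by_substrate[s])[i] for i in t_idx] for s in substrates],
        index=pd.Index(substrates, name="substrate"),
        columns=[f"{plate.times[i]:g}h" for i in t_idx],
    )
    if out_csv is not None:
        matrix.to_csv(out_csv)
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * len(t_idx) + 2), max(3, 0.25 * len(substrates) + 1)))
        im = ax.imshow(np.maximum(matrix.to_numpy(), 0.0), aspect="auto",
                       cmap="viridis")
        ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45)
        ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="net Abs590 (AU)")
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return matrix
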