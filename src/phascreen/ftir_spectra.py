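"""Whole-cell FTIR spectral analysis for PHA screening.

Implements spectral I/O, amide-I anchored normalization, linear baseline
correction, band integration with per-region chord ("individual") baselines,
carbonyl-ester peak localization, the carbonyl-to-amide-I (CA1) area ratio,
and scl/mcl-PHA classification from the carbonyl peak position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "BandRegion",
    "InstrumentProfile",
    "CA1Result",
    "CARY",
    "HTS_XT",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "normalize_spectrum",
    "baseline_correct_linear",
    "integrate_band",
    "find_carbonyl_peak",
    "compute_ca1",
    "classify_pha",
    "aggregate_ca1",
    "get_profile",
]

#: Minimum number of grid points for a valid spectrum.
MIN_POINTS = 8

#: Default scl/mcl class boundary for the carbonyl-ester peak position, the
#: midpoint between the scl (~1728 cm-1) and mcl (~1738 cm-1) peak positions.
SCL_MCL_BOUNDARY = 1733.0


class SpectrumParseError(ValueError):
    """Raised when a spectral file cannot be parsed."""


@dataclass(frozen=True)
class BandRegion:
    """Integration region ``[lo, hi]`` in cm⁻¹ for a named spectral band."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band region {self.name!r}: lo must be < hi "
                             f"(got {self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class InstrumentProfile:
    """Band-region and normalization conventions for one FTIR system.

    Attributes
    ----------
    name : str
        Instrument label (``cary``, ``hts_xt``, or custom).
    carbonyl_region, amide1_region : BandRegion
        Integration regions for the carbonyl-ester and amide I bands.
    norm_anchor : float
        Wavenumber (cm⁻¹) of the normalization anchor point.
    norm_target : float
        Target absorbance (AU) at the anchor after normalization.
    """

    name: str
    carbonyl_region: BandRegion
    amide1_region: BandRegion
    norm_anchor: float = 1650.0
    norm_target: float = 0.5

    def __post_init__(self) -> None:
        c, a = self.carbonyl_region, self.amide1_region
        if max(c.lo, a.lo) < min(c.hi, a.hi):
            raise ValueError("carbonyl and amide I regions must not overlap")
        if not (a.lo <= self.norm_anchor <= a.hi):
            raise ValueError("normalization anchor must lie inside the amide I region")


#: ATR-FTIR band conventions (spectral range 650–4000 cm⁻¹).
CARY = InstrumentProfile(
    name="cary",
    carbonyl_region=BandRegion("carbonyl_ester", 1705.0, 1763.0),
    amide1_region=BandRegion("amide_I", 1580.0, 1705.0),
)

#: High-throughput transmission unit band conventions (400–4000 cm⁻¹, 6 cm⁻¹ resolution).
HTS_XT = InstrumentProfile(
    name="hts_xt",
    carbonyl_region=BandRegion("carbonyl_ester", 1710.0, 1772.0),
    amide1_region=BandRegion("amide_I", 1600.0, 1710.0),
)

_PROFILES = {"cary": CARY, "hts_xt": HTS_XT}


def get_profile(name: str) -> InstrumentProfile:
    """Look up a built-in instrument profile by name."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown instrument profile {name!r}; "
                       f"available: {sorted(_PROFILES)}") from None


@dataclass
class Spectrum:
    """A wavenumber-indexed absorbance trace from one FTIR measurement.

    Wavenumbers are stored on a strictly increasing grid; files stored in
    descending order are reversed at the I/O boundary.
    """

    wavenumbers: np.ndarray
    absorbances: np.ndarray
    instrument: str = "other"
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbances.ndim != 1:
            raise ValueError("wavenumbers and absorbances must be 1-D")
        if self.wavenumbers.shape != self.absorbances.shape:
            raise ValueError("wavenumbers and absorbances must have equal length")
        if self.wavenumbers.size < MIN_POINTS:
            raise ValueError(f"spectrum needs at least {MIN_POINTS} points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def value_at(self, nu: float) -> float:
        """Absorbance at ``nu`` by linear interpolation between grid points."""
        lo, hi = self.wavenumbers[0], self.wavenumbers[-1]
        if not (lo <= nu <= hi):
            raise ValueError(f"wavenumber {nu} outside grid span [{lo}, {hi}]")
        return float(np.interp(nu, self.wavenumbers, self.absorbances))

    def with_absorbances(self, values: np.ndarray) -> "Spectrum":
        return replace(self, absorbances=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# I/O

CSV_HEADER = "wavenumber_cm-1,absorbance"


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a two-column spectral CSV (ascending wavenumber grid)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(CSV_HEADER + "\n")
        for nu, a in zip(spectrum.wavenumbers, spectrum.absorbances):
            fh.write(f"{float(nu)!r},{float(a)!r}\n")
    return path


def _parse_two_column_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    nus: list[float] = []
    avs: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if lineno == 1 and not _is_numeric(parts[0]):
                continue  # header
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}, line {lineno}: expected two comma-separated columns")
            try:
                nus.append(float(parts[0]))
                avs.append(float(parts[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"{path}, line {lineno}: non-numeric value in {line!r}") from None
    return np.asarray(nus), np.asarray(avs)


def _is_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _parse_jcamp_xydata(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader for AFFN ``(X++(Y..Y))`` XYDATA blocks."""
    xfactor = yfactor = 1.0
    deltax = None
    in_data = False
    nus: list[float] = []
    avs: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "DELTAX":
                    deltax = float(value)
                elif key == "XYDATA":
                    if "X++" not in value.replace(" ", ""):
                        raise SpectrumParseError(
                            f"{path}, line {lineno}: unsupported XYDATA form {value!r}")
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if not in_data:
                continue
            tokens = line.replace(",", " ").split()
            if any(not _is_numeric(t) for t in tokens):
                raise SpectrumParseError(
                    f"{path}, line {lineno}: compressed JCAMP data not supported")
            x0 = float(tokens[0]) * xfactor
            ys = [float(t) * yfactor for t in tokens[1:]]
            if deltax is None and len(ys) > 1:
                raise SpectrumParseError(
                    f"{path}, line {lineno}: DELTAX required for multi-Y lines")
            step = deltax if deltax is not None else 0.0
            for i, y in enumerate(ys):
                nus.append(x0 + i * step * xfactor if deltax is not None else x0)
                avs.append(y)
    if not nus:
        raise SpectrumParseError(f"{path}: no XYDATA block found")
    return np.asarray(nus), np.asarray(avs)


def read_spectrum(path: str | Path, format: str | None = None, *,
                  instrument: str = "other",
                  sample_id: str | None = None) -> Spectrum:
    """Read a spectrum from a two-column CSV or a JCAMP-DX (XYDATA) file.

    Descending grids are reversed to the internal ascending convention.
    Duplicate or otherwise non-monotone wavenumbers are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        nus, avs = _parse_two_column_csv(path)
    elif format == "jcamp":
        nus, avs = _parse_jcamp_xydata(path)
    else:
        raise ValueError(f"unknown spectral format {format!r}")
    if nus.size < MIN_POINTS:
        raise SpectrumParseError(f"{path}: fewer than {MIN_POINTS} data points")
    d = np.diff(nus)
    if np.all(d < 0):
        nus, avs = nus[::-1], avs[::-1]
    elif not np.all(d > 0):
        bad = int(np.flatnonzero(np.diff(nus) <= 0)[0]) + 2
        raise SpectrumParseError(
            f"{path}, data row {bad}: wavenumbers not strictly monotone "
            "(duplicate or out-of-order grid value)")
    return Spectrum(nus, avs, instrument=instrument,
                    sample_id=sample_id if sample_id is not None else path.stem)


# ---------------------------------------------------------------------------
# Preprocessing


def normalize_spectrum(s: Spectrum, profile: InstrumentProfile) -> Spectrum:
    """Scale so the interpolated absorbance at the anchor equals the target.

    Raises
    ------
    ValueError
        If the anchor absorbance is not strictly positive (blank/degenerate
        sample that cannot be normalized).
    """
    anchor_value = s.value_at(profile.norm_anchor)
    if anchor_value <= 0:
        raise ValueError(
            f"cannot normalize {s.sample_id!r}: absorbance at "
            f"{profile.norm_anchor} cm-1 is {anchor_value:.4g} (must be > 0)")
    return s.with_absorbances(s.absorbances * (profile.norm_target / anchor_value))


def baseline_correct_linear(s: Spectrum) -> Spectrum:
    """Subtract the straight line through the first and last grid points."""
    nu, a = s.wavenumbers, s.absorbances
    slope = (a[-1] - a[0]) / (nu[-1] - nu[0])
    baseline = a[0] + slope * (nu - nu[0])
    return s.with_absorbances(a - baseline)


# ---------------------------------------------------------------------------
# Band integration and peak finding


def _region_grid(s: Spectrum, region: BandRegion) -> tuple[np.ndarray, np.ndarray]:
    """Grid restricted to the region, augmented with interpolated endpoints."""
    lo, hi = region.lo, region.hi
    if lo < s.wavenumbers[0] or hi > s.wavenumbers[-1]:
        raise ValueError(
            f"region {region.name!r} [{lo}, {hi}] outside grid span "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]")
    inside = (s.wavenumbers > lo) & (s.wavenumbers < hi)
    x = np.concatenate(([lo], s.wavenumbers[inside], [hi]))
    y = np.concatenate(([s.value_at(lo)], s.absorbances[inside], [s.value_at(hi)]))
    return x, y


def _chord(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Straight line joining the first and last points of (x, y)."""
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    return y[0] + slope * (x - x[0])


def integrate_band(s: Spectrum, region: BandRegion) -> float:
    """Band area above the endpoint chord ("individual baseline" integral).

    A chord is drawn from ``(lo, A(lo))`` to ``(hi, A(hi))`` using linearly
    interpolated endpoint values; the trapezoidal integral of the signal
    minus the chord is returned, floored at zero.  Adding any global affine
    function of wavenumber leaves the result unchanged.
    """
    x, y = _region_grid(s, region)
    area = float(np.trapezoid(y - _chord(x, y), x))
    return max(area, 0.0)


def find_carbonyl_peak(s: Spectrum, region: BandRegion, *,
                       smooth_window: int = 9, polyorder: int = 2,
                       min_prominence: float = 0.005) -> float | None:
    """Locate the band maximum inside ``region`` on the chord-subtracted signal.

    The chord-subtracted signal is smoothed with a Savitzky–Golay filter
    (``smooth_window`` points, quadratic) and the wavenumber of its maximum is
    returned, provided the smoothed height reaches ``min_prominence`` AU;
    otherwise ``None``.
    """
    x, y = _region_grid(s, region)
    net = y - _chord(x, y)
    if smooth_window > net.size:
        raise ValueError(
            f"smooth_window ({smooth_window}) exceeds points in region ({net.size})")
    window = smooth_window if smooth_window % 2 == 1 else smooth_window - 1
    window = max(window, polyorder + 1 + (polyorder % 2))
    smoothed = savgol_filter(net, window, polyorder) if window > polyorder else net
    i = int(np.argmax(smoothed))
    if smoothed[i] < min_prominence:
        return None
    return float(x[i])


def classify_pha(peak: float | None, boundary: float = SCL_MCL_BOUNDARY) -> str:
    """Classify the PHA side-chain length class from the carbonyl peak position.

    Returns ``"none"`` when no peak was found, ``"scl"`` for peaks at or below
    the boundary, ``"mcl"`` above it.
    """
    if peak is None:
        return "none"
    return "scl" if peak <= boundary else "mcl"


@dataclass(frozen=True)
class CA1Result:
    """Carbonyl-to-amide-I band area ratio and derived classification."""

    sample_id: str
    carbonyl_area: float
    amide1_area: float
    ca1_ratio: float
    carbonyl_peak: float | None
    pha_class: str
    instrument: str = "other"
    metadata: dict = field(default_factory=dict, compare=False)


def compute_ca1(s: Spectrum, profile: InstrumentProfile, *,
                smooth_window: int = 9, polyorder: int = 2,
                min_prominence: float = 0.005,
                class_boundary: float = SCL_MCL_BOUNDARY) -> CA1Result:
    """Full per-spectrum pipeline: normalize, baseline-correct, integrate, classify.

    Operates on the *raw* spectrum, applying in order: anchor normalization,
    global linear baseline correction, chord-baselined integration of the
    carbonyl-ester and amide I regions, carbonyl peak localization, and
    scl/mcl classification.  The amide I area must be strictly positive
    (otherwise there is no protein signal and the sample is invalid).
    """
    normalized = normalize_spectrum(s, profile)
    corrected = baseline_correct_linear(normalized)
    carbonyl_area = integrate_band(corrected, profile.carbonyl_region)
    amide1_area = integrate_band(corrected, profile.amide1_region)
    if amide1_area <= 0:
        raise ValueError(
            f"sample {s.sample_id!r}: amide I area is {amide1_area:.4g}; "
            "no protein signal, cannot form CA1 ratio")
    peak = find_carbonyl_peak(corrected, profile.carbonyl_region,
                              smooth_window=smooth_window, polyorder=polyorder,
                              min_prominence=min_prominence)
    return CA1Result(
        sample_id=s.sample_id,
        carbonyl_area=carbonyl_area,
        amide1_area=amide1_area,
        ca1_ratio=carbonyl_area / amide1_area,
        carbonyl_peak=peak,
        pha_class=classify_pha(peak, class_boundary),
        instrument=profile.name,
        metadata=dict(s.metadata),
    )


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_ca1(results: Iterable[CA1Result],
                  groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Summarize CA1 ratios per group (substrate, condition, ...).

    Parameters
    ----------
    results
        Per-measurement CA1 results.
    groups
        Optional map from ``sample_id`` to group label; when omitted, the
        ``substrate`` metadata key is used, falling back to the sample id.

    Returns
    -------
    DataFrame indexed by group with columns ``n``, ``mean``, ``sd``,
    ``median``, ``q1``, ``q3``, ``fence_lo``, ``fence_hi``.  The sample SD
    (``ddof=1``) is reported as missing for singleton groups, not as 0.
    """
    results = list(results)
    if not results:
        raise ValueError("no CA1 results to aggregate")

    def group_of(r: CA1Result) -> str:
        if groups is not None:
            return groups.get(r.sample_id, r.sample_id)
        return str(r.metadata.get("substrate", r.sample_id))

    frame = pd.DataFrame({
        "group": [group_of(r) for r in results],
        "ca1": [r.ca1_ratio for r in results],
    })
    rows = []
    for name, sub in frame.groupby("group", sort=True):
        x = sub["ca1"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        rows.append({
            "group": name,
            "n": x.size,
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else math.nan,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "fence_lo": float(q1 - 1.5 * iqr),
            "fence_hi": float(q3 + 1.5 * iqr),
        })
    return pd.DataFrame(rows).set_index("group")


def results_to_frame(results: Sequence[CA1Result]) -> pd.DataFrame:
    """Tidy per-measurement table of CA1 results."""
    return pd.DataFrame([{
        "sample_id": r.sample_id,
        "substrate": r.metadata.get("substrate", ""),
        "instrument": r.instrument,
        "carbonyl_area": r.carbonyl_area,
        "amide1_area": r.amide1_area,
        "ca1_ratio": r.ca1_ratio,
        "carbonyl_peak_cm1": r.carbonyl_peak,
        "pha_class": r.pha_class,
    } for r in results])
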