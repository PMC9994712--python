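"""Seeded synthetic fixtures: FTIR spectra, growth curves, kinetic plates.

Every generator is a pure function of its arguments including the seed, so
downstream analyses can be tested against known ground truth without any
instrument files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biolog_phenotype import WELLS_96, KineticPlate
from .ftir_spectra import Spectrum
from .growth_kinetics import GrowthCurve

__all__ = [
    "BandSpec",
    "SimConfig",
    "WellKinetics",
    "PlateSimConfig",
    "generate_spectrum",
    "generate_growth_curve",
    "generate_biolog_plate",
    "gaussian_band",
    "write_manifest",
]

FWHM_FACTOR = 4.0 * np.log(2.0)  # exponent factor so fwhm is the full width at half max


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorption band: center (cm⁻¹), height (AU), FWHM (cm⁻¹)."""

    center: float
    height: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("band height must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be > 0")

    @property
    def area(self) -> float:
        """Closed-form area under the band: height·fwhm·√(π / 4 ln 2)."""
        return self.height * self.fwhm * float(np.sqrt(np.pi / FWHM_FACTOR))


@dataclass(frozen=True)
class SimConfig:
    """Spectral simulation grid, baseline and noise settings."""

    seed: int = 0
    wavenumber_range: tuple[float, float] = (900.0, 4000.0)
    grid_step: float = 2.0
    noise_sd: float = 0.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.wavenumber_range
        if not lo < hi:
            raise ValueError("wavenumber_range must satisfy lo < hi")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def grid(self) -> np.ndarray:
        lo, hi = self.wavenumber_range
        n = int(np.floor((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)


def gaussian_band(nu: np.ndarray, band: BandSpec) -> np.ndarray:
    """Evaluate one Gaussian band on a wavenumber grid."""
    return band.height * np.exp(-FWHM_FACTOR * ((nu - band.center) / band.fwhm) ** 2)


def generate_spectrum(bands: Sequence[BandSpec], cfg: SimConfig, *,
                      sample_id: str = "synthetic",
                      instrument: str = "other") -> Spectrum:
    """Sum of Gaussian bands on an affine baseline with additive noise.

    value(ν) = offset + slope·ν + Σ height·exp(−4 ln2 (ν−center)²/fwhm²) + ε,
    ε ~ N(0, noise_sd²), drawn from a generator seeded by ``cfg.seed`` so
    identical configs give identical spectra.
    """
    nu = cfg.grid()
    lo, hi = cfg.wavenumber_range
    for b in bands:
        if not (lo <= b.center <= hi):
            raise ValueError(f"band center {b.center} outside range [{lo}, {hi}]")
    values = cfg.baseline_offset + cfg.baseline_slope * nu
    for b in bands:
        values = values + gaussian_band(nu, b)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        values = values + rng.normal(0.0, cfg.noise_sd, size=nu.size)
    return Spectrum(nu, values, instrument=instrument, sample_id=sample_id,
                    metadata={"synthetic": True})


def logistic_od(t: np.ndarray, K: float, N0: float, r: float,
                lag_h: float = 0.0) -> np.ndarray:
    """Lagged logistic trajectory; holds at N0 until ``lag_h``."""
    te = np.maximum(np.asarray(t, dtype=float) - lag_h, 0.0)
    e = np.exp(r * te)
    return K * N0 * e / (K + N0 * (e - 1.0))


def generate_growth_curve(K: float, N0: float, r: float, lag_h: float = 0.0,
                          t_end: float = 48.0, step: float = 0.25,
                          noise_sd: float = 0.0, seed: int = 0, *,
                          well: str = "", substrate: str = "",
                          replicate: int = 0) -> GrowthCurve:
    """Logistic OD600 time series with lag and additive Gaussian noise."""
    if not 0 < N0 < K:
        raise ValueError("require 0 < N0 < K")
    if r <= 0:
        raise ValueError("growth rate r must be > 0")
    if step <= 0:
        raise ValueError("time step must be > 0")
    t = np.arange(0.0, t_end + step / 2, step)
    od = logistic_od(t, K, N0, r, lag_h)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=t.size)
    return GrowthCurve(times=t, od=od, well=well, substrate=substrate,
                       replicate=replicate)


@dataclass(frozen=True)
class WellKinetics:
    """Formazan accumulation parameters for one well.

    ``amplitude`` is the net signal reached at the end of the run (so the
    background-subtracted maximum equals the amplitude exactly at zero
    noise); ``rate`` (h⁻¹) and ``midpoint_h`` shape the sigmoid rise.
    """

    amplitude: float
    rate: float = 0.12
    midpoint_h: float = 36.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class PlateSimConfig:
    seed: int = 0
    t_end: float = 96.0
    step: float = 4.0
    noise_sd: float = 0.0
    background_offset: float = 0.05
    background_slope: float = 0.0005  # AU per hour of shared drift

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + self.step / 2, self.step)


def _rise(t: np.ndarray, wk: WellKinetics, t_end: float) -> np.ndarray:
    """Sigmoid rise rescaled to start at 0 and reach 1 at ``t_end``."""
    s = 1.0 / (1.0 + np.exp(-wk.rate * (t - wk.midpoint_h)))
    s0 = 1.0 / (1.0 + np.exp(wk.rate * wk.midpoint_h))
    s1 = 1.0 / (1.0 + np.exp(-wk.rate * (t_end - wk.midpoint_h)))
    return (s - s0) / (s1 - s0)


def generate_biolog_plate(per_well_params: Mapping[str, WellKinetics],
                          control_well: str = "A1",
                          cfg: PlateSimConfig = PlateSimConfig(),
                          layout: Mapping[str, str] | None = None) -> KineticPlate:
    """96-well kinetic plate: shared background plus per-well formazan rise.

    The control well carries the background trace only.  Wells absent from
    ``per_well_params`` default to zero amplitude.  Output is deterministic
    for a given config seed.
    """
    wells = list(per_well_params)
    if len(set(wells)) != len(wells):
        raise ValueError("duplicate well ids in per_well_params")
    unknown = set(wells) - set(WELLS_96)
    if unknown:
        raise ValueError(f"unknown well ids: {sorted(unknown)}")
    if control_well in per_well_params and per_well_params[control_well].amplitude > 0:
        raise ValueError("the no-carbon control well must have zero amplitude")
    t = cfg.times()
    background = cfg.background_offset + cfg.background_slope * t
    rng = np.random.default_rng(cfg.seed)
    columns = {}
    for well in WELLS_96:
        series = background.copy()
        wk = per_well_params.get(well)
        if wk is not None and wk.amplitude > 0 and well != control_well:
            series = series + wk.amplitude * _rise(t, wk, cfg.t_end)
        if cfg.noise_sd > 0 and well != control_well:
            series = series + rng.normal(0.0, cfg.noise_sd, size=t.size)
        columns[well] = series
    data = pd.DataFrame(columns)
    if layout is None:
        layout = {w: ("No carbon" if w == control_well else w) for w in WELLS_96}
    return KineticPlate(times=t, data=data, layout=layout,
                        control_well=control_well)


def write_manifest(params: Mapping, path: str | Path) -> Path:
    """Serialize true simulation parameters to JSON for recovery tests."""
    path = Path(path)

    def default(obj):
        if isinstance(obj, (BandSpec, SimConfig, WellKinetics, PlateSimConfig)):
            return asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"cannot serialize {type(obj)}")

    path.write_text(json.dumps(params, indent=2, sort_keys=True, default=default))
    return path
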