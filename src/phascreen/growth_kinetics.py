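"""Growth-curve metrics from 96-well OD600 kinetics.

Derives four per-well metrics from each curve — maximum specific growth rate
(``gr``, the maximum of d ln(OD)/dt), the time at which it occurs (``t_gr``),
the area under the raw OD curve (``auc``), and the smoothing residual
(``mse``) — then flags outlier wells by box-plot fences and compares substrate
groups against control wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "GrowthCurve",
    "GrowthMetrics",
    "ComparisonRecord",
    "fit_growth_curve",
    "detect_outliers",
    "compare_to_control",
]

MIN_POINTS_FOR_FIT = 10
OUTLIER_FIELDS = ("gr", "t_gr", "mse", "auc")


@dataclass
class GrowthCurve:
    """An OD600 time series for one well."""

    times: np.ndarray
    od: np.ndarray
    well: str = ""
    substrate: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be equal-length 1-D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od values must be finite")


@dataclass
class GrowthMetrics:
    """Derived metrics for one growth curve.

    ``flagged`` marks curves where smoothing was degenerate (all-equal OD);
    ``outlier`` is filled in by :func:`detect_outliers`.
    """

    gr: float
    t_gr: float
    auc: float
    mse: float
    well: str = ""
    substrate: str = ""
    replicate: int = 0
    flagged: bool = False
    outlier: bool = field(default=False, compare=False)


def _spline_smoother(t: np.ndarray, y: np.ndarray):
    """GCV smoothing spline; returns callables for value and derivative."""
    spl = make_smoothing_spline(t, y)
    return spl, spl.derivative()


def _gp_smoother(t: np.ndarray, y: np.ndarray):
    """RBF Gaussian-process smoother (slower; closer to GP-based fitters)."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=np.ptp(t) / 4, length_scale_bounds=(1e-2, 1e3))
              + WhiteKernel(1e-3, (1e-8, 1e1)))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(t[:, None], y)

    def value(x):
        return gp.predict(np.atleast_1d(x)[:, None])

    dt = np.min(np.diff(t)) / 4

    def deriv(x):
        x = np.atleast_1d(x)
        return (value(x + dt) - value(x - dt)) / (2 * dt)

    return value, deriv


def fit_growth_curve(gc: GrowthCurve, *, floor: float = 0.01,
                     smoother: str = "spline",
                     log_auc: bool = False) -> GrowthMetrics:
    """Fit a smooth trend to log-OD and extract gr, t_gr, AUC and MSE.

    The curve is log-transformed with a floor (``ln(max(od, floor))``) and
    smoothed; ``gr`` is the maximum of the smoothed derivative over the
    observed span and ``t_gr`` its argmax.  ``mse`` is the mean squared
    residual on the log scale.  ``auc`` is the trapezoidal integral of raw
    OD over the full span (of log-OD when ``log_auc`` is set).

    Degenerate input (all-equal OD) yields ``gr = 0`` with ``flagged=True``
    rather than an error.
    """
    if gc.times.size < MIN_POINTS_FOR_FIT:
        raise ValueError(
            f"need at least {MIN_POINTS_FOR_FIT} time points, got {gc.times.size}")
    t = gc.times
    y = np.log(np.maximum(gc.od, floor))
    auc = float(np.trapezoid(y if log_auc else gc.od, t))

    if np.allclose(y, y[0]):
        return GrowthMetrics(gr=0.0, t_gr=float(t[0]), auc=auc, mse=0.0,
                             well=gc.well, substrate=gc.substrate,
                             replicate=gc.replicate, flagged=True)

    if smoother == "spline":
        value, deriv = _spline_smoother(t, y)
    elif smoother == "gp":
        value, deriv = _gp_smoother(t, y)
    else:
        raise ValueError(f"unknown smoother {smoother!r} (use 'spline' or 'gp')")

    fine = np.linspace(t[0], t[-1], max(4 * t.size, 200))
    dy = np.asarray(deriv(fine))
    i = int(np.argmax(dy))
    mse = float(np.mean((y - np.asarray(value(t))) ** 2))
    return GrowthMetrics(gr=float(dy[i]), t_gr=float(fine[i]), auc=auc, mse=mse,
                         well=gc.well, substrate=gc.substrate,
                         replicate=gc.replicate)


def _fences(x: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def detect_outliers(metrics: Sequence[GrowthMetrics],
                    fields: Iterable[str] = OUTLIER_FIELDS) -> list[bool]:
    """Flag curves whose metrics fall outside 1.5×IQR box-plot fences.

    Quartiles use linear interpolation.  A curve is an outlier if *any* of
    the requested metric fields falls outside that field's fences.  With
    fewer than 4 curves no flags are raised (a warning is emitted).  The
    ``outlier`` attribute of each metric is updated in place and the flag
    list returned.
    """
    metrics = list(metrics)
    if len(metrics) < 4:
        warnings.warn("fewer than 4 curves: outlier detection skipped",
                      stacklevel=2)
        for m in metrics:
            m.outlier = False
        return [False] * len(metrics)
    flags = np.zeros(len(metrics), dtype=bool)
    for name in fields:
        x = np.array([getattr(m, name) for m in metrics], dtype=float)
        lo, hi = _fences(x)
        flags |= (x < lo) | (x > hi)
    for m, f in zip(metrics, flags):
        m.outlier = bool(f)
    return flags.tolist()


@dataclass(frozen=True)
class ComparisonRecord:
    """Group-vs-control comparison on one metric field."""

    metric_field: str
    group_mean: float
    group_sd: float | None
    control_mean: float
    control_sd: float | None
    outside_band: bool | None  # group mean outside control mean ± 2 SD
    p_value: float | None  # two-sided Welch t-test


def compare_to_control(group: Sequence[GrowthMetrics],
                       control: Sequence[GrowthMetrics],
                       metric_field: str = "gr") -> ComparisonRecord:
    """Compare a substrate group with control wells on one metric.

    Reports mean ± sample SD for both, a ±2 SD band test (a group mean
    exactly on the boundary counts as *inside*), and a two-sided Welch
    t-test p-value.  With a single control well the band test and t-test
    are unavailable (``None``).
    """
    if not group or not control:
        raise ValueError("group and control must both be non-empty")
    g = np.array([getattr(m, metric_field) for m in group], dtype=float)
    c = np.array([getattr(m, metric_field) for m in control], dtype=float)
    g_mean, c_mean = float(np.mean(g)), float(np.mean(c))
    g_sd = float(np.std(g, ddof=1)) if g.size > 1 else None
    c_sd = float(np.std(c, ddof=1)) if c.size > 1 else None
    if c_sd is None:
        return ComparisonRecord(metric_field, g_mean, g_sd, c_mean, c_sd,
                                outside_band=None, p_value=None)
    # round-off guard so a mean exactly on the boundary counts as inside
    tol = 1e-9 * max(abs(c_mean), c_sd, 1e-9)
    outside = abs(g_mean - c_mean) > 2 * c_sd + tol
    if g.size > 1 and (np.std(g) > 0 or np.std(c) > 0):
        p = float(stats.ttest_ind(g, c, equal_var=False).pvalue)
    elif np.allclose(g_mean, c_mean):
        p = 1.0
    else:
        p = None
    return ComparisonRecord(metric_field, g_mean, g_sd, c_mean, c_sd,
                            outside_band=bool(outside), p_value=p)
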