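"""Data conditioning for turnover modelling.

The protocol's inputs rarely arrive analysis-ready: fluorescence traces
carry frame noise and autofluorescence background, and mRNA time courses
are sampled far more sparsely than the imaging (e.g. every 2 h vs every
2 min).  This module provides the conditioning steps applied before any
fitting:

* :func:`moving_average` — small-window walking-average smoothing,
* :func:`subtract_background` — control (autofluorescence) subtraction,
* :func:`align_time_zero` — shifting the clock so both mRNA and protein
  share time zero at the start of protein observation,
* :func:`spline_interpolate` — natural cubic-spline densification of the
  mRNA profile onto a uniform minute grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import TimeSeries

__all__ = [
    "GridSpec",
    "moving_average",
    "subtract_background",
    "align_time_zero",
    "spline_interpolate",
]


@dataclass(frozen=True)
class GridSpec:
    """A uniform evaluation grid: ``[t_start, t_end]`` hours at ``dt_min`` minutes.

    The implied point count is ``n = (t_end - t_start) * 60 / dt_min + 1``
    and must be an integer (t = t_start included).  A 48 h span at 2 min
    yields 1,441 points.
    """

    t_start: float
    t_end: float
    dt_min: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not self.dt_min > 0:
            raise ValueError("dt_min must be positive")
        span_min = (self.t_end - self.t_start) * 60.0
        n = span_min / self.dt_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"span of {span_min:g} min is not a multiple of dt={self.dt_min:g} min"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.t_end - self.t_start) * 60.0 / self.dt_min)) + 1

    def times(self) -> np.ndarray:
        """Grid times in hours, endpoints exact."""
        return np.linspace(self.t_start, self.t_end, self.n_points)


def moving_average(series: TimeSeries, window: int) -> TimeSeries:
    """Centred walking average with an odd window; edges use a truncated window.

    At the boundaries the window is truncated to the available points (no
    padding, no fabricated data), so initiation and plateau levels are
    preserved as far as possible.  Times are unchanged.  ``window=1`` is
    the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    smoothed = (
        pd.Series(series.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return TimeSeries(series.times.copy(), smoothed, raw=series.raw)


def subtract_background(
    sample: TimeSeries, control: TimeSeries
) -> tuple[TimeSeries, int]:
    """Pointwise ``sample - control`` (autofluorescence removal).

    The control is linearly interpolated onto the sample grid when the two
    grids differ; the control must cover the sample's time range.  Negative
    differences are clipped to zero and the number of clipped points is
    returned alongside the corrected series.
    """
    if sample.times.size == control.times.size and np.allclose(
        sample.times, control.times
    ):
        ctrl_vals = control.values
    else:
        if control.times[0] > sample.times[0] or control.times[-1] < sample.times[-1]:
            raise ValueError(
                "control does not cover the sample's time range and cannot "
                "be interpolated onto it"
            )
        ctrl_vals = np.interp(sample.times, control.times, control.values)
    diff = sample.values - ctrl_vals
    n_clipped = int(np.count_nonzero(diff < 0))
    return TimeSeries(sample.times.copy(), np.clip(diff, 0.0, None)), n_clipped


def align_time_zero(series: TimeSeries, t0: float) -> TimeSeries:
    """Shift the time axis so that ``t0`` maps to zero; values unchanged.

    Used to synchronise the mRNA clock (hours after egg laying) with the
    start of protein observation (e.g. embryonic stage 15 at about 11 h
    20 min for Collagen IV).
    """
    return TimeSeries(series.times - t0, series.values.copy(), raw=series.raw)


def spline_interpolate(series: TimeSeries, grid: GridSpec) -> TimeSeries:
    """Natural cubic interpolating spline evaluated on a uniform grid.

    The spline passes through every input node exactly; no extrapolation is
    performed, so the grid must lie within the sampled range.  Negative
    interpolated values (possible between sparse nodes) are clipped to zero
    with a warning, since abundances are non-negative by construction.
    """
    if len(series) < 4:
        raise ValueError("cubic spline interpolation needs at least 4 points")
    tol = 1e-9
    if grid.t_start < series.t_start - tol or grid.t_end > series.t_end + tol:
        raise ValueError(
            f"grid [{grid.t_start}, {grid.t_end}] h extends beyond the data "
            f"range [{series.t_start}, {series.t_end}] h; no extrapolation"
        )
    spline = CubicSpline(series.times, series.values, bc_type="natural")
    tgrid = np.clip(grid.times(), series.t_start, series.t_end)
    vals = spline(tgrid)
    n_neg = int(np.count_nonzero(vals < 0))
    if n_neg:
        warnings.warn(
            f"clipped {n_neg} negative interpolated values to 0", stacklevel=2
        )
        vals = np.clip(vals, 0.0, None)
    return TimeSeries(grid.times(), vals)
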