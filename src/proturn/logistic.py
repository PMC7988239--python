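"""Four-parameter logistic (4PL) fitting of protein expression traces.

Protein expression from initiation to homeostasis is expected to be
sigmoid.  Following common dose-response practice, each replicate is
fitted with the decadic 4PL form (time playing the role of the dose axis)::

    P(t) = Bottom + Span / (1 + 10**((logEC50 - t) * HillSlope))

whose parameters map onto the natural logistic parameterisation as
``K = Span``, ``t_i = logEC50`` and ``r = HillSlope * ln(10)``
(:func:`convert_params`).  ``Bottom`` is the starting value — residual
autofluorescence for imaging data — and is expected to be close to zero.

No R-squared cut-off is enforced: fit quality is reported
(:func:`goodness_report`) and should also be judged visually against the
expected sigmoid shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .core import LogisticParams, TimeSeries

__all__ = ["FourPLFit", "fit_logistic4", "convert_params", "goodness_report",
           "GoodnessReport"]

LN10 = math.log(10.0)

#: a Bottom offset above this fraction of Span is flagged as a background
#: concern in goodness reports.
BACKGROUND_FRACTION = 0.10


@dataclass
class FourPLFit:
    """Raw dose-response-style fit output, before conversion to (K, t_i, r)."""

    bottom: float
    span: float
    log_ec50: float
    hill_slope: float
    r_squared: Optional[float] = None
    converged: bool = True
    message: str = field(default="", repr=False)


def eval_logistic4(fit: FourPLFit, t) -> np.ndarray:
    """Evaluate the decadic 4PL curve at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    return fit.bottom + fit.span * expit(LN10 * fit.hill_slope * (t - fit.log_ec50))


def _4pl_model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    bottom, span, log_ec50, hill = theta
    return bottom + span * expit(LN10 * hill * (t - log_ec50))


def _default_init(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Self-starting heuristic: range-based Bottom/Span, half-rise midpoint,
    slope from the decadic width of the 10-90% rise interval."""
    bottom = float(np.min(y))
    span = float(np.max(y) - np.min(y))
    levels = bottom + np.array([0.1, 0.5, 0.9]) * span

    def first_crossing(level: float) -> float:
        above = y >= level
        idx = np.argmax(above)
        if idx == 0:
            return float(t[0])
        t0, t1 = t[idx - 1], t[idx]
        y0, y1 = y[idx - 1], y[idx]
        if y1 == y0:
            return float(t1)
        return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))

    t10, t50, t90 = (first_crossing(lv) for lv in levels)
    width = max(t90 - t10, (t[-1] - t[0]) / max(len(t) - 1, 1))
    hill = 4.0 / width
    return np.array([bottom, span, t50, hill])


def fit_logistic4(
    series: TimeSeries, init: Optional[FourPLFit] = None
) -> FourPLFit:
    """Least-squares 4PL fit of a protein trace.

    Uses damped (Levenberg-Marquardt) least squares with a
    data-driven initialisation unless ``init`` is supplied; parameter and
    cost tolerances are 1e-10 with at most 1,000 function evaluations.
    Non-convergence yields a flagged result (``converged=False``) rather
    than an exception; a flat (degenerate) series is an error.

    ``r_squared = 1 - SS_res / SS_tot`` is attached to the result.
    """
    t = series.times
    y = series.values
    if len(series) < 5:
        raise ValueError("logistic fitting needs at least 5 points")
    rng_y = float(np.max(y) - np.min(y))
    if rng_y <= 0 or rng_y < 1e-12 * max(abs(float(np.max(y))), 1.0):
        raise ValueError("degenerate (flat) series: no rise to fit")

    if init is not None:
        theta0 = np.array([init.bottom, init.span, init.log_ec50, init.hill_slope])
    else:
        theta0 = _default_init(t, y)

    res = least_squares(
        lambda th: _4pl_model(th, t) - y,
        theta0,
        method="lm",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=1000,
    )
    bottom, span, log_ec50, hill = res.x
    # a negative span with a negative slope is the same curve mirrored;
    # normalise to span > 0 where possible
    if span < 0 and hill < 0:
        bottom, span = bottom + span, -span
        hill = -hill
    ss_res = float(np.sum((_4pl_model(np.array([bottom, span, log_ec50, hill]), t) - y) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FourPLFit(
        bottom=float(bottom),
        span=float(span),
        log_ec50=float(log_ec50),
        hill_slope=float(hill),
        r_squared=max(min(r2, 1.0), 0.0) if math.isfinite(r2) else None,
        converged=bool(res.success),
        message=str(res.message),
    )


def convert_params(fit: FourPLFit) -> LogisticParams:
    """Map 4PL output to the natural logistic parameters.

    ``K = Span``; ``t_i = logEC50``; ``r = HillSlope * ln(10)`` — the
    decadic Hill slope times ln 10 gives the intrinsic rate of increase in
    1/h.  ``bottom`` and ``r_squared`` are carried through unchanged.  A
    non-positive Hill slope (non-increasing curve) violates the model
    assumptions and is an error, as is an unconverged fit.
    """
    if not fit.converged:
        raise ValueError("cannot convert an unconverged fit; inspect diagnostics")
    if fit.hill_slope <= 0:
        raise ValueError(
            f"HillSlope must be positive for rising expression, got {fit.hill_slope}"
        )
    return LogisticParams(
        K=fit.span,
        t_i=fit.log_ec50,
        r=fit.hill_slope * LN10,
        bottom=fit.bottom,
        r_squared=fit.r_squared,
    )


@dataclass
class GoodnessReport:
    """Per-replicate and aggregate fit-quality summary."""

    r_squared: list
    mean_r_squared: float
    converged: list
    all_converged: bool
    bottom_to_span: list
    background_flagged: list  # Bottom > BACKGROUND_FRACTION of Span


def goodness_report(fits: Sequence[FourPLFit]) -> GoodnessReport:
    """Summarise fit quality across replicates.

    Reports per-replicate and mean R², convergence flags, and the Bottom
    magnitude relative to Span; a Bottom above 10% of Span is flagged as a
    background concern (the starting offset should be close to zero).
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    r2 = [f.r_squared for f in fits]
    finite_r2 = [v for v in r2 if v is not None]
    ratios = [abs(f.bottom) / abs(f.span) if f.span else float("inf") for f in fits]
    return GoodnessReport(
        r_squared=r2,
        mean_r_squared=float(np.mean(finite_r2)) if finite_r2 else float("nan"),
        converged=[f.converged for f in fits],
        all_converged=all(f.converged for f in fits),
        bottom_to_span=ratios,
        background_flagged=[rat > BACKGROUND_FRACTION for rat in ratios],
    )
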