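"""Model-validity diagnostics for turnover estimates.

The modelling rests on assumptions that real data may violate: a simple
single-peak-then-plateau mRNA profile, a logistic protein rise, and
internal consistency between the anterograde and retrograde fits.  This
module implements the corresponding checks:

* :func:`mrna_shape_check` — peak counting and plateau detection on the
  mRNA profile (multiple peaks suggest time-dependent synthesis rates);
* :func:`mann_whitney_two_tailed` — the rank test used to compare
  anterograde vs retrograde rate distributions (significance level 0.01);
* :func:`ci_variability_check` — regression confidence intervals must be
  much smaller than the biological variability between replicates;
* :func:`suitability_report` — the combined verdict.

The thresholds for "single peak", "plateau" and "much smaller" are
declared heuristics (the protocol's checks are visual) and are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .core import TimeSeries, TurnoverEstimate

__all__ = [
    "mann_whitney_two_tailed",
    "ci_variability_check",
    "mrna_shape_check",
    "suitability_report",
    "CiVariabilityResult",
    "ShapeCheck",
    "SuitabilityReport",
]

#: default significance level for the anterograde-vs-retrograde comparison
ALPHA = 0.01
#: peaks must be at least this fraction of the profile's range prominent
PEAK_PROMINENCE_FRACTION = 0.10
#: fraction of the window inspected for the plateau
PLATEAU_TAIL_FRACTION = 0.10
#: plateau requires mean |slope| below this fraction of range per hour
PLATEAU_SLOPE_FRACTION = 0.02
#: heuristic floor on the mean logistic R-squared for "protein is logistic"
LOGISTIC_R2_FLOOR = 0.95


def mann_whitney_two_tailed(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test between two rate samples.

    Returns ``(U, p)`` where ``U`` is the statistic of the first sample.
    The exact null distribution (full enumeration over rank assignments) is
    used for small samples (combined n <= 20) without ties; otherwise the
    normal approximation with tie correction and continuity correction.
    Symmetric in its arguments for the p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CiVariabilityResult:
    """Ratio of regression CI half-width to between-replicate spread."""

    sp_ratio: float
    dp_ratio: float
    sp_ok: bool
    dp_ok: bool

    @property
    def ok(self) -> bool:
        return self.sp_ok and self.dp_ok


def _ci_ratio(values: np.ndarray, half_widths: np.ndarray) -> float:
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    med_hw = float(np.median(half_widths))
    if iqr <= 0:
        return 0.0 if med_hw == 0 else float("inf")
    return med_hw / iqr


def ci_variability_check(
    estimates: Sequence[TurnoverEstimate],
) -> CiVariabilityResult:
    """Compare regression CIs with the biological variability across replicates.

    For each parameter the ratio of the median CI half-width to the
    interquartile range of the point estimates is computed; a ratio at or
    above 1 means the regression uncertainty is as large as the biological
    spread, which indicates the modelling is failing for these data.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 replicates with confidence intervals")
    sp = np.array([e.Sp for e in estimates])
    dp = np.array([e.Dp for e in estimates])
    sp_hw = np.array([(e.Sp_ci_high - e.Sp_ci_low) / 2.0 for e in estimates])
    dp_hw = np.array([(e.Dp_ci_high - e.Dp_ci_low) / 2.0 for e in estimates])
    sp_ratio = _ci_ratio(sp, sp_hw)
    dp_ratio = _ci_ratio(dp, dp_hw)
    return CiVariabilityResult(
        sp_ratio=sp_ratio,
        dp_ratio=dp_ratio,
        sp_ok=sp_ratio < 1.0,
        dp_ok=dp_ratio < 1.0,
    )


@dataclass
class ShapeCheck:
    """mRNA profile suitability: interior peak count and plateau flag."""

    n_peaks: int
    plateau_reached: bool

    @property
    def ok(self) -> bool:
        return self.n_peaks <= 1 and self.plateau_reached


def mrna_shape_check(
    mrna: TimeSeries,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
    tail_fraction: float = PLATEAU_TAIL_FRACTION,
    slope_fraction: float = PLATEAU_SLOPE_FRACTION,
) -> ShapeCheck:
    """Screen an mRNA profile for model suitability.

    Counts interior local maxima with prominence at least
    ``prominence_fraction`` of the profile's range, and declares a plateau
    when the mean absolute slope over the final ``tail_fraction`` of the
    window is below ``slope_fraction`` of the range per hour.  A single
    peak followed by a plateau (or a monotone saturating rise) is the
    suitable shape; multiple peaks suggest multiple or time-dependent
    synthesis rates.  Invariant to positive rescaling of the value axis.
    """
    v = mrna.values
    t = mrna.times
    rng = float(np.max(v) - np.min(v))
    if rng <= 0:
        return ShapeCheck(n_peaks=0, plateau_reached=True)
    peaks, _ = find_peaks(v, prominence=prominence_fraction * rng)
    n_tail = max(2, int(np.ceil(tail_fraction * v.size)))
    slopes = np.diff(v[-n_tail:]) / np.diff(t[-n_tail:])
    plateau = bool(np.mean(np.abs(slopes)) < slope_fraction * rng)
    return ShapeCheck(n_peaks=int(peaks.size), plateau_reached=plateau)


@dataclass
class SuitabilityReport:
    """Combined verdict over the protocol's three warning signs."""

    n_mrna_peaks: int
    plateau_reached: bool
    protein_logistic_ok: bool
    consistency_p_value: Optional[float]
    ci_vs_variability_ok: Optional[bool]
    verdict: str = "suitable"
    reasons: list = field(default_factory=list)


def suitability_report(
    shape: ShapeCheck,
    mean_r_squared: Optional[float] = None,
    consistency_p_value: Optional[float] = None,
    ci_check: Optional[CiVariabilityResult] = None,
    alpha: float = ALPHA,
    r2_floor: float = LOGISTIC_R2_FLOOR,
) -> SuitabilityReport:
    """Aggregate the individual checks into a suitability verdict.

    Any failed component downgrades the verdict to at least "warning"; two
    or more failures yield "unsuitable".  Components not supplied (None)
    are not counted either way.  The verdict is monotone: adding a failed
    check can never upgrade it.
    """
    reasons: list[str] = []
    if shape.n_peaks > 1:
        reasons.append(
            f"mRNA profile has {shape.n_peaks} peaks; a single peak followed "
            "by a plateau is required"
        )
    if not shape.plateau_reached:
        reasons.append("mRNA profile does not reach a plateau (no homeostasis)")
    protein_ok = True
    if mean_r_squared is not None:
        protein_ok = mean_r_squared >= r2_floor
        if not protein_ok:
            reasons.append(
                f"mean logistic R² = {mean_r_squared:.3f} below {r2_floor}; "
                "protein may not follow a logistic trend"
            )
    if consistency_p_value is not None and consistency_p_value <= alpha:
        reasons.append(
            f"anterograde and retrograde rates differ significantly "
            f"(p = {consistency_p_value:.3g} <= {alpha})"
        )
    if ci_check is not None and not ci_check.ok:
        reasons.append(
            "regression confidence intervals are not much smaller than the "
            f"between-replicate variability (Sp ratio {ci_check.sp_ratio:.2g}, "
            f"Dp ratio {ci_check.dp_ratio:.2g})"
        )
    verdict = "suitable" if not reasons else ("warning" if len(reasons) == 1 else "unsuitable")
    return SuitabilityReport(
        n_mrna_peaks=shape.n_peaks,
        plateau_reached=shape.plateau_reached,
        protein_logistic_ok=protein_ok,
        consistency_p_value=consistency_p_value,
        ci_vs_variability_ok=None if ci_check is None else ci_check.ok,
        verdict=verdict,
        reasons=reasons,
    )
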