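"""Aggregation-inhibition kinetics from thioflavin-S time courses.

Heparin-induced Tau filament formation is monitored by ThS fluorescence
(ex 440 / em 520 nm).  Each well's time course is fitted with the
empirical exponential-growth form

    Y(t) = Y0 + A * exp(t / t_const)

with A < 0 and t_const < 0 for an approach to plateau, so the fitted
``Y0`` is the plateau fluorescence.  Percent inhibition of assembly is
computed from plateaus relative to an untreated control and the ThS
background, and the IC50 is read off a straight-line fit of percent
inhibition against log10 of compound concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError, NoDoseResponseError, ValidationError

__all__ = [
    "AggregationTimeCourse",
    "KineticFit",
    "InhibitionCurve",
    "DissolutionTrend",
    "fit_exp_plateau",
    "inhibition_percent",
    "estimate_ic50",
    "dissolution_trend",
]


@dataclass(frozen=True)
class AggregationTimeCourse:
    """ThS fluorescence versus time for one well."""

    well_id: str
    compound_id: str
    compound_conc: float  # µM
    tau_conc: float  # µM
    times: np.ndarray  # min
    intensity: np.ndarray  # a.u.

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or t.size < 8:
            raise ValidationError("time course needs >= 8 points")
        if y.shape != t.shape:
            raise ValidationError("times and intensity lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValidationError("intensities must be finite and non-negative")


@dataclass(frozen=True)
class KineticFit:
    """Exponential-plateau fit; ``Y0`` is the plateau by convention."""

    well_id: str
    Y0: float
    A: float
    t_const: float  # min; negative for growth to plateau
    rss: float
    converged: bool
    degenerate: bool = False

    @property
    def plateau(self) -> float:
        return self.Y0

    @property
    def time_zero(self) -> float:
        """Model value at t=0 (Y0 + A); the baseline of a control well."""
        return self.Y0 + self.A


@dataclass(frozen=True)
class InhibitionCurve:
    """Dose-inhibition curve and its log-linear IC50."""

    compound_id: str
    concentrations: np.ndarray  # µM
    inhibition_pct: np.ndarray
    ic50: float  # µM
    slope: float  # % per decade
    intercept: float  # % at 1 µM
    r_squared: float
    n_points: int
    n_saturated: int = 0
    ic50_literal: float = float("nan")  # 10**slope variant, for comparison
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class DissolutionTrend:
    """Trend of a preformed-filament time course under treatment."""

    slope: float  # a.u./min
    drop_pct: float  # relative decrease over the record, %
    classification: str  # "dissolving" | "stable"
    p_value: float


def _model(t, y0, a, tc):
    return y0 + a * np.exp(t / tc)


def fit_exp_plateau(
    tc: AggregationTimeCourse,
    init: tuple[float, float, float] | None = None,
    max_nfev: int = 500,
) -> KineticFit:
    """Levenberg-Marquardt fit of ``Y0 + A*exp(t/t_const)``.

    Default initialisation: Y0 = last observation, A = first - last,
    t_const = -(time span)/3.  A constant signal short-circuits to a
    degenerate fit (Y0 = that constant, A = 0).  Non-convergence is
    reported on the result, not raised, so panel processing can skip
    bad wells explicitly.
    """
    t, y = tc.times, tc.intensity
    if np.ptp(y) == 0.0:
        return KineticFit(tc.well_id, float(y[0]), 0.0, float("nan"), 0.0,
                          converged=True, degenerate=True)
    if init is None:
        span = float(t[-1] - t[0])
        init = (float(y[-1]), float(y[0] - y[-1]), -span / 3.0)
    try:
        popt, _ = optimize.curve_fit(
            _model, t, y, p0=init, method="lm",
            maxfev=max_nfev, xtol=1e-10, ftol=1e-10,
        )
    except RuntimeError:
        return KineticFit(tc.well_id, float("nan"), float("nan"), float("nan"),
                          float("inf"), converged=False)
    rss = float(np.sum((y - _model(t, *popt)) ** 2))
    return KineticFit(tc.well_id, float(popt[0]), float(popt[1]), float(popt[2]),
                      rss, converged=bool(np.all(np.isfinite(popt))))


def inhibition_percent(plateau_treated, plateau_control, baseline):
    """Percent inhibition of assembly from plateau fluorescences.

    ``100 * (control - treated) / (control - baseline)``, capped at 100
    (a treated plateau cannot report less aggregate than none).  The
    baseline is the ThS signal without filaments (control time-zero
    intercept by default in the pipeline).  Affine-invariant: shifting
    all three inputs by a constant leaves the result unchanged.
    """
    if not plateau_control > baseline:
        raise ValidationError("control plateau must exceed baseline")
    treated = np.asarray(plateau_treated, dtype=float)
    pct = 100.0 * (plateau_control - treated) / (plateau_control - baseline)
    pct = np.minimum(pct, 100.0)
    return float(pct) if pct.ndim == 0 else pct


def estimate_ic50(
    concentrations,
    inhibition_pct,
    compound_id: str = "",
    saturation_pct: float = 100.0,
) -> InhibitionCurve:
    """Half-maximal inhibitory concentration from a dose panel.

    Straight-line fit of percent inhibition against log10(concentration)
    over the sub-saturating points (those capped at 100% are excluded:
    the dose law is linear-then-plateau, and plateau points would bias
    the slope).  The IC50 is the concentration whose fitted inhibition
    equals 50%: ``10**((50 - intercept)/slope)``.  The historical
    literal variant ``10**slope`` is recorded alongside for comparison
    but never used.
    """
    conc = np.asarray(concentrations, dtype=float)
    inh = np.asarray(inhibition_pct, dtype=float)
    if conc.shape != inh.shape or conc.ndim != 1:
        raise ValidationError("concentrations and inhibition must be equal-length 1-D")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive")
    finite = np.isfinite(inh)
    sub = finite & (inh < saturation_pct - 1e-9)
    n_saturated = int(np.sum(finite & ~sub))
    if np.sum(sub) < 3:
        if n_saturated and np.sum(sub) == 0:
            raise FitError(f"{compound_id}: all points saturated at 100% inhibition")
        raise FitError(f"{compound_id}: fewer than 3 usable dose points")
    x = np.log10(conc[sub])
    y = inh[sub]
    if np.ptp(y) == 0.0:
        raise NoDoseResponseError(f"{compound_id}: inhibition identical at all doses")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise NoDoseResponseError(f"{compound_id}: inhibition does not increase with dose")
    ic50 = 10.0 ** ((50.0 - res.intercept) / res.slope)
    flags = []
    if not (y.min() < 50.0 < y.max()):
        flags.append("extrapolated")
    return InhibitionCurve(
        compound_id=compound_id,
        concentrations=conc[sub],
        inhibition_pct=y,
        ic50=float(ic50),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(np.sum(sub)),
        n_saturated=n_saturated,
        ic50_literal=float(10.0**res.slope),
        flags=tuple(flags),
    )


def dissolution_trend(tc: AggregationTimeCourse, alpha: float = 0.05) -> DissolutionTrend:
    """Classify a preformed-filament record as dissolving or stable.

    The overall slope is taken from an OLS line of intensity on time and
    the relative drop from its fitted endpoints; the dissolving call
    uses a sign test on successive differences at level ``alpha``
    (robust to the heavy plate-reader tails a t-test would mishandle).
    """
    t, y = tc.times, tc.intensity
    res = stats.linregress(t, y)
    y_start = res.intercept + res.slope * t[0]
    y_end = res.intercept + res.slope * t[-1]
    drop = 100.0 * (y_start - y_end) / y_start if y_start != 0 else 0.0
    diffs = np.diff(y)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        p = 1.0
    else:
        n_neg = int(np.sum(nonzero < 0))
        p = stats.binomtest(n_neg, nonzero.size, 0.5, alternative="greater").pvalue
    dissolving = res.slope < 0 and p < alpha
    return DissolutionTrend(
        slope=float(res.slope),
        drop_pct=float(drop),
        classification="dissolving" if dissolving else "stable",
        p_value=float(p),
    )
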