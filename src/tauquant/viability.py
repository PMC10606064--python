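"""MTT viability normalisation and median-effect (Chou-Talalay) IC50.

Viability is the blank-corrected absorbance of treated wells relative
to untreated wells.  The median-effect equation linearises a
dose-effect curve as

    log10(fa/fu) = m * log10(D) - m * log10(Dm)

with ``fa = 1 - viability`` the affected fraction, ``fu = viability``
the unaffected fraction, ``m`` the sigmoidicity and ``Dm`` the
median-effect dose, which is the IC50 by definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, NoDoseResponseError, ValidationError

__all__ = [
    "DoseResponse",
    "MedianEffectFit",
    "normalize_plate",
    "fit_median_effect",
]


@dataclass(frozen=True)
class DoseResponse:
    """Viability fractions at increasing doses for one compound/cell line."""

    compound_id: str
    cell_line: str
    doses: np.ndarray  # µM
    viability: np.ndarray  # fraction of untreated
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "viability", v)
        if d.ndim != 1 or d.size < 3:
            raise ValidationError("dose-response needs >= 3 doses")
        if v.shape != d.shape:
            raise ValidationError("doses and viability lengths differ")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValidationError("doses must be positive and strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValidationError("viability must be finite")


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect line: slope m and median-effect dose Dm (= IC50)."""

    compound_id: str
    cell_line: str
    m: float
    Dm: float  # µM
    r_squared: float
    n_points: int
    n_excluded: int = 0
    Dm_se: float = float("nan")
    flags: tuple[str, ...] = field(default_factory=tuple)


def normalize_plate(
    doses,
    treated_absorbance,
    untreated_absorbance,
    blank: float = 0.0,
    compound_id: str = "",
    cell_line: str = "",
) -> DoseResponse:
    """Blank-correct and normalise raw MTT absorbances.

    ``treated_absorbance`` holds one sequence of replicate wells per
    dose; replicates are averaged before the ratio is formed:
    ``viability = (mean treated - blank)/(mean untreated - blank)``,
    clipped to [0, 1.5] with values above 1 flagged (growth
    stimulation).
    """
    untreated = np.asarray(untreated_absorbance, dtype=float)
    if untreated.size < 1:
        raise ValidationError("at least one untreated well is required")
    u = float(untreated.mean())
    if u <= blank:
        raise ValidationError("untreated absorbance must exceed the blank")
    means = np.array([np.mean(np.asarray(w, dtype=float)) for w in treated_absorbance])
    if means.size != len(np.asarray(doses)):
        raise ValidationError("one replicate group per dose is required")
    if blank > min(means.min(), u):
        raise ValidationError("blank exceeds a sample absorbance")
    viability = (means - blank) / (u - blank)
    flags = ("stimulation",) if np.any(viability > 1.0) else ()
    viability = np.clip(viability, 0.0, 1.5)
    return DoseResponse(compound_id, cell_line, np.asarray(doses, dtype=float),
                        viability, flags)


def fit_median_effect(dr: DoseResponse) -> MedianEffectFit:
    """Fit the median-effect line and return (m, Dm).

    Points with viability at or beyond the ends of (0, 1) carry no
    information on the log-ratio scale and are excluded with a count
    (stimulated wells are excluded, not clipped, because clipping would
    fabricate dynamic range).  ``Dm = 10**(-intercept/m)``; its standard
    error comes from the coefficient covariance by the delta method.
    """
    v = dr.viability
    usable = (v > 0.0) & (v < 1.0)
    n_excluded = int(np.sum(~usable))
    if np.sum(usable) < 3:
        raise FitError(
            f"{dr.compound_id}/{dr.cell_line}: insufficient dynamic range "
            f"({n_excluded} points at 0 or >= 1 excluded)"
        )
    d = dr.doses[usable]
    fa = 1.0 - v[usable]
    fu = v[usable]
    x = np.log10(d)
    y = np.log10(fa / fu)
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise NoDoseResponseError(
            f"{dr.compound_id}/{dr.cell_line}: effect does not increase with dose"
        )
    m = float(res.slope)
    b = float(res.intercept)
    Dm = 10.0 ** (-b / m)
    # var(log10 Dm) by delta method; linregress lacks coef covariance,
    # so use the standard OLS expressions (cov(m,b) = -xbar*var(m)).
    n = x.size
    var_m = res.stderr**2
    var_b = res.intercept_stderr**2
    cov_mb = -float(x.mean()) * var_m
    g_m = b / m**2  # d(-b/m)/dm
    g_b = -1.0 / m
    var_log_dm = g_m**2 * var_m + g_b**2 * var_b + 2 * g_m * g_b * cov_mb
    Dm_se = Dm * math.log(10.0) * math.sqrt(max(var_log_dm, 0.0))
    return MedianEffectFit(
        compound_id=dr.compound_id,
        cell_line=dr.cell_line,
        m=m,
        Dm=float(Dm),
        r_squared=float(res.rvalue**2),
        n_points=int(n),
        n_excluded=n_excluded,
        Dm_se=float(Dm_se),
        flags=dr.flags,
    )
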