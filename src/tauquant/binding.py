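"""Ligand-protein binding analysis by intrinsic-fluorescence quenching.

Tau protein carries five tyrosines and no tryptophan; its intrinsic
emission (ex 275 nm, em 303 nm) is quenched when a ligand binds near a
Tyr residue.  A titration of protein with increasing quencher
concentration [Q] therefore encodes the binding equilibrium.

Two models are provided:

* the regular Stern-Volmer relation ``F0/F = 1 + K*[Q]``, valid when
  every fluorophore is accessible to the quencher, and
* the modified (Lehrer) form for a two-population fluorophore system in
  which only a fraction ``f_a`` of the initial fluorescence is
  accessible::

      F = f_a*F0 / (1 + K*[Q]) + (1 - f_a)*F0

  which linearises to ``F0/dF = 1/(f_a*K*[Q]) + 1/f_a`` where
  ``dF = F0 - F``.  A straight-line fit of ``F0/dF`` against ``1/[Q]``
  yields ``f_a = 1/intercept`` and ``K = intercept/slope``; the
  dissociation constant is ``K_D = 1/K = slope/intercept``.

Measured intensities are first corrected for the inner-filter effect,
``F = F_obs * exp((A_ex + A_em)/2)``, when absorbances at the excitation
and emission wavelengths are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NonPhysicalFitError, NoQuenchError, ValidationError

__all__ = [
    "TitrationSeries",
    "QuenchFit",
    "RegularSVFit",
    "SternVolmerPoints",
    "inner_filter_correct",
    "stern_volmer_points",
    "fit_modified_stern_volmer",
    "fit_regular_stern_volmer",
]

#: modified Stern-Volmer fits with a lower r-squared are flagged as
#: nonlinear (binding parameters should not be trusted below this).
DEFAULT_R2_FLAG = 0.95


@dataclass(frozen=True)
class TitrationSeries:
    """One compound-versus-protein fluorescence titration.

    The first concentration must be 0 (the ligand-free reference that
    defines F0).  ``A_ex``/``A_em`` are sample absorbances at the
    excitation and emission wavelengths; when absent the inner-filter
    correction is skipped and downstream fits are flagged
    ``uncorrected``.
    """

    compound_id: str
    quencher_conc: np.ndarray  # M
    F_obs: np.ndarray  # a.u. at the emission maximum
    A_ex: np.ndarray | None = None
    A_em: np.ndarray | None = None
    protein_conc: float = 5e-6  # M

    def __post_init__(self):
        q = np.asarray(self.quencher_conc, dtype=float)
        f = np.asarray(self.F_obs, dtype=float)
        object.__setattr__(self, "quencher_conc", q)
        object.__setattr__(self, "F_obs", f)
        if q.ndim != 1 or q.size < 4:
            raise ValidationError("titration needs >= 4 concentration points")
        if f.shape != q.shape:
            raise ValidationError("quencher_conc and F_obs lengths differ")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if q[0] != 0.0:
            raise ValidationError("titration must include a [Q]=0 reference point first")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("intensities must be finite and positive")
        for name in ("A_ex", "A_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                object.__setattr__(self, name, a)
                if a.shape != q.shape:
                    raise ValidationError(f"{name} length differs from concentrations")
                if np.any(a < 0):
                    raise ValidationError(f"{name} contains negative absorbances")

    @property
    def has_absorbances(self) -> bool:
        return self.A_ex is not None and self.A_em is not None


@dataclass(frozen=True)
class QuenchFit:
    """Modified Stern-Volmer fit result.

    ``intercept``/``slope`` are the coefficients of the F0/dF vs 1/[Q]
    line; ``f_a = 1/intercept``, ``K = intercept/slope`` (M^-1) and
    ``K_D = slope/intercept`` (M), so ``K * K_D == 1`` exactly.
    Standard errors are propagated from the OLS coefficient covariance
    by the delta method.
    """

    compound_id: str
    f_a: float
    K: float  # M^-1
    K_D: float  # M
    intercept: float
    slope: float
    r_squared: float
    n_points: int
    n_dropped: int = 0
    f_a_se: float = float("nan")
    K_D_se: float = float("nan")
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class RegularSVFit:
    """Regular Stern-Volmer diagnostic fit of F0/F vs [Q].

    Reported with the intercept both free and fixed at its theoretical
    value of 1; a poor ``r_squared_free`` signals heterogeneous
    fluorophore accessibility (the modified model is then required).
    """

    compound_id: str
    K_free: float
    intercept_free: float
    r_squared_free: float
    K_fixed: float
    r_squared_fixed: float
    n_points: int


@dataclass(frozen=True)
class SternVolmerPoints:
    """Transformed titration: abscissae 1/[Q], ordinates F0/dF."""

    inv_conc: np.ndarray
    f0_over_df: np.ndarray
    n_dropped: int
    corrected: bool


def inner_filter_correct(F_obs, A_ex, A_em):
    """Correct observed fluorescence for the inner-filter effect.

    Returns ``F_obs * exp((A_ex + A_em)/2)``.  Accepts scalars or
    arrays; absorbances must be non-negative and intensities positive.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(F_obs <= 0):
        raise ValidationError("observed fluorescence must be positive")
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValidationError("absorbances must be non-negative")
    out = F_obs * np.exp((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def _corrected_intensities(series: TitrationSeries) -> tuple[np.ndarray, bool]:
    if series.has_absorbances:
        return inner_filter_correct(series.F_obs, series.A_ex, series.A_em), True
    return series.F_obs.copy(), False


def stern_volmer_points(series: TitrationSeries) -> SternVolmerPoints:
    """Transform a titration to modified Stern-Volmer coordinates.

    F0 is the (inner-filter corrected) intensity of the [Q]=0 point,
    which is excluded from the output; points with dF <= 0 (no apparent
    quench, typically noise at low [Q]) are dropped and counted.
    """
    F, corrected = _corrected_intensities(series)
    F0 = F[0]
    q = series.quencher_conc[1:]
    dF = F0 - F[1:]
    usable = dF > 0
    n_dropped = int(np.sum(~usable))
    if np.sum(usable) < 3:
        raise NoQuenchError(
            f"{series.compound_id}: fewer than 3 points with positive quench "
            f"({n_dropped} dropped) - no quench signal to fit"
        )
    return SternVolmerPoints(
        inv_conc=1.0 / q[usable],
        f0_over_df=F0 / dF[usable],
        n_dropped=n_dropped,
        corrected=corrected,
    )


def _ols_with_cov(x: np.ndarray, y: np.ndarray):
    """Unweighted straight-line fit returning (slope, intercept, cov, r2)."""
    coef, cov = np.polyfit(x, y, 1, cov="unscaled" if x.size <= 3 else True)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, cov, max(0.0, min(1.0, r2))


def fit_modified_stern_volmer(
    series: TitrationSeries, r2_flag: float = DEFAULT_R2_FLAG
) -> QuenchFit:
    """Fit the two-population quench model on its linearised form.

    Ordinary least squares of F0/dF on 1/[Q] (the graphical procedure;
    unweighted, so the reciprocal transform inflates low-[Q] variance -
    acceptable for the smooth titrations this assay produces).

    Raises :class:`NonPhysicalFitError` when slope or intercept is not
    positive; an accessible fraction above 1 is flagged, not rejected.
    """
    pts = stern_volmer_points(series)
    slope, intercept, cov, r2 = _ols_with_cov(pts.inv_conc, pts.f0_over_df)
    if intercept <= 0 or slope <= 0:
        raise NonPhysicalFitError(
            f"{series.compound_id}: non-physical fit "
            f"(slope={slope:.3g}, intercept={intercept:.3g}); wrong model or sign of quench"
        )
    f_a = 1.0 / intercept
    K = intercept / slope
    K_D = slope / intercept

    var_s, var_i = float(cov[0, 0]), float(cov[1, 1])
    cov_si = float(cov[0, 1])
    f_a_se = math.sqrt(var_i) / intercept**2
    # K_D = s/i: grad = (1/i, -s/i^2)
    var_kd = (
        var_s / intercept**2
        + (slope**2 / intercept**4) * var_i
        - 2.0 * (slope / intercept**3) * cov_si
    )
    K_D_se = math.sqrt(max(var_kd, 0.0))

    flags = []
    if not pts.corrected:
        flags.append("uncorrected")
    if f_a > 1.0:
        flags.append("f_a>1")
    if r2 < r2_flag:
        flags.append("nonlinear")
    return QuenchFit(
        compound_id=series.compound_id,
        f_a=f_a,
        K=K,
        K_D=K_D,
        intercept=intercept,
        slope=slope,
        r_squared=r2,
        n_points=int(pts.inv_conc.size),
        n_dropped=pts.n_dropped,
        f_a_se=f_a_se,
        K_D_se=K_D_se,
        flags=tuple(flags),
    )


def fit_regular_stern_volmer(series: TitrationSeries) -> RegularSVFit:
    """Fit ``F0/F = 1 + K*[Q]`` as the linearity diagnostic.

    With heterogeneous fluorophore accessibility this plot curves and
    its r-squared drops below that of the modified model.
    """
    F, _ = _corrected_intensities(series)
    F0 = F[0]
    q = series.quencher_conc[1:]
    y = F0 / F[1:]
    if np.allclose(y, 1.0, rtol=0, atol=1e-12):
        raise NoQuenchError(f"{series.compound_id}: F0/F constant at 1 - no quench")
    slope, intercept, _, r2 = _ols_with_cov(q, y)
    if slope <= 0:
        raise NoQuenchError(
            f"{series.compound_id}: non-positive Stern-Volmer slope - no quench"
        )
    # intercept fixed at 1: K = sum((y-1)*q) / sum(q^2)
    k_fixed = float(np.sum((y - 1.0) * q) / np.sum(q**2))
    resid = y - (1.0 + k_fixed * q)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_fixed = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return RegularSVFit(
        compound_id=series.compound_id,
        K_free=slope,
        intercept_free=intercept,
        r_squared_free=r2,
        K_fixed=k_fixed,
        r_squared_fixed=max(0.0, min(1.0, r2_fixed)),
        n_points=int(q.size),
    )
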