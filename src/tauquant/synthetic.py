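"""Synthetic instrument-output generator for every assay in the pipeline.

Each generator draws from the statistical model the corresponding
analysis stage assumes, with assay-realistic defaults (geometry, time
grids, plate layouts), so the full pipeline is testable without any
instrument.  All generators are deterministic given their truth object
(every truth carries a mandatory seed; there is no global random
state); setting the noise parameter to zero yields the exact model
curves.

What is emulated -- and what is not: fluorescence noise is
multiplicative Gaussian (plate-reader noise is approximately
proportional at working intensities); there is no photobleaching,
drift, well-edge effect, or mechanistic nucleation-elongation
aggregation model.  The aggregation dose law is the empirical
linear-then-plateau form: percent inhibition grows linearly with
compound concentration, reaching 50% at ``half_inhibition_conc`` and
saturating at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw
from scipy import ndimage

from .binding import TitrationSeries
from .errors import ValidationError
from .imaging import CellImage
from .kinetics import AggregationTimeCourse
from .migration import Track
from .viability import DoseResponse

__all__ = [
    "QuenchTruth",
    "AggregationTruth",
    "MotilityTruth",
    "ImageTruth",
    "SyntheticCellImage",
    "simulate_titration",
    "simulate_ths_timecourse",
    "simulate_viability",
    "simulate_tracks",
    "simulate_cell_image",
    "DEFAULT_THS_TIMES",
    "DEFAULT_TITRATION_CONCS",
]

#: ThS reads every 15 min for 8.75 h -> 36 points.
DEFAULT_THS_TIMES = np.arange(0.0, 8.75 * 60.0 + 1.0, 15.0)

#: Titration grid, 0-100 µM in molar units.
DEFAULT_TITRATION_CONCS = np.array(
    [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 50.0, 100.0]
) * 1e-6

#: Tau molar extinction coefficient (M^-1 cm^-1) near the excitation
#: wavelength; emission-side protein absorbance is negligible.
TAU_EPS_EX = 7700.0
TAU_EPS_EM = 0.0


# --------------------------------------------------------------------------
# fluorescence titrations

@dataclass(frozen=True)
class QuenchTruth:
    """Ground truth for a two-population quench titration.

    ``f_a`` is the accessible fraction of the initial fluorescence, K
    the association constant (so K_D = 1/K).  Compound extinction
    coefficients make the sample absorbance - and hence the
    inner-filter attenuation - grow linearly with quencher
    concentration.
    """

    f_a: float
    K: float  # M^-1
    F0_total: float = 1.0e6  # a.u.
    protein_conc: float = 5e-6  # M
    eps_ex_compound: float = 0.0  # M^-1 cm^-1 at excitation
    eps_em_compound: float = 0.0  # M^-1 cm^-1 at emission
    eps_ex_protein: float = TAU_EPS_EX
    eps_em_protein: float = TAU_EPS_EM
    path_length: float = 1.0  # cm
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.f_a <= 1.0:
            raise ValidationError("f_a must be in (0, 1]")
        if self.K <= 0 or self.F0_total <= 0:
            raise ValidationError("K and F0_total must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")


def simulate_titration(
    truth: QuenchTruth,
    concentrations=DEFAULT_TITRATION_CONCS,
    compound_id: str = "synthetic",
) -> TitrationSeries:
    """Simulate one titration with inner-filter attenuation and noise.

    True intensity ``F([Q]) = f_a*F0/(1 + K[Q]) + (1-f_a)*F0``;
    absorbances ``A_ex = eps_ex,protein*l*C_protein + eps_ex,compound*l*[Q]``
    (same at emission); the observed signal is attenuated by
    ``exp(-(A_ex+A_em)/2)`` - the exact inverse of the analysis-side
    correction - then multiplied by seeded Gaussian noise of the given CV.
    """
    q = np.asarray(concentrations, dtype=float)
    if np.any(q < 0):
        raise ValidationError("concentrations must be non-negative")
    if np.any(np.diff(q) <= 0):
        raise ValidationError("concentrations must be strictly increasing (no duplicates)")
    f0a = truth.f_a * truth.F0_total
    f0b = (1.0 - truth.f_a) * truth.F0_total
    F = f0a / (1.0 + truth.K * q) + f0b
    l = truth.path_length
    a_ex = truth.eps_ex_protein * l * truth.protein_conc + truth.eps_ex_compound * l * q
    a_em = truth.eps_em_protein * l * truth.protein_conc + truth.eps_em_compound * l * q
    f_obs = F * np.exp(-(a_ex + a_em) / 2.0)
    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed)
        f_obs = f_obs * rng.normal(1.0, truth.noise_cv, size=f_obs.shape)
    return TitrationSeries(
        compound_id=compound_id,
        quencher_conc=q,
        F_obs=f_obs,
        A_ex=a_ex,
        A_em=a_em,
        protein_conc=truth.protein_conc,
    )


# --------------------------------------------------------------------------
# ThS aggregation time courses

@dataclass(frozen=True)
class AggregationTruth:
    """Ground truth for the ThS aggregation-inhibition panel.

    Percent inhibition of the plateau grows linearly with compound
    concentration, reaching 50% at ``half_inhibition_conc`` and capped
    at 100% (full suppression of filament formation); the time course
    approaches its plateau exponentially with time constant
    ``tau_rise``.
    """

    plateau_control: float = 1000.0  # a.u.
    baseline: float = 100.0  # a.u. (ThS background)
    tau_rise: float = 110.0  # min; untreated signal levels off by ~8 h
    half_inhibition_conc: float = 17.3  # µM
    tau_conc: float = 2.0  # µM
    full_inhibition_ratio: float = float("nan")  # ligand/Tau ratio at 100%
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not self.plateau_control > self.baseline >= 0:
            raise ValidationError("need plateau_control > baseline >= 0")
        if self.tau_rise <= 0 or self.half_inhibition_conc <= 0:
            raise ValidationError("tau_rise and half_inhibition_conc must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if np.isnan(self.full_inhibition_ratio):
            # saturation is implied by the linear law: 100% at twice the
            # half-inhibition concentration.
            object.__setattr__(
                self, "full_inhibition_ratio",
                2.0 * self.half_inhibition_conc / self.tau_conc,
            )

    def inhibition_at(self, conc: float) -> float:
        return min(100.0, 50.0 * conc / self.half_inhibition_conc)

    def plateau_at(self, conc: float) -> float:
        inh = self.inhibition_at(conc)
        return self.baseline + (self.plateau_control - self.baseline) * (1 - inh / 100.0)


def simulate_ths_timecourse(
    truth: AggregationTruth,
    compound_conc: float,
    times=DEFAULT_THS_TIMES,
    well_id: str = "w0",
    compound_id: str = "synthetic",
) -> AggregationTimeCourse:
    """One ThS well: exponential approach to a dose-dependent plateau."""
    if compound_conc < 0:
        raise ValidationError("compound concentration must be non-negative")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be non-negative and increasing")
    plateau = truth.plateau_at(compound_conc)
    y = plateau - (plateau - truth.baseline) * np.exp(-t / truth.tau_rise)
    if truth.noise_cv > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([truth.seed, int(round(compound_conc * 1e6))])
        )
        y = y * rng.normal(1.0, truth.noise_cv, size=y.shape)
        y = np.clip(y, 0.0, None)
    return AggregationTimeCourse(
        well_id=well_id,
        compound_id=compound_id,
        compound_conc=float(compound_conc),
        tau_conc=truth.tau_conc,
        times=t,
        intensity=y,
    )


# --------------------------------------------------------------------------
# MTT viability

def simulate_viability(
    m: float,
    Dm: float,
    doses,
    noise_cv: float = 0.0,
    seed: int = 0,
    compound_id: str = "synthetic",
    cell_line: str = "synthetic",
) -> DoseResponse:
    """Median-effect dose-response: viability = 1 - 1/(1 + (Dm/D)^-m).

    Equivalently the affected fraction is ``fa(D) = 1/(1 + (Dm/D)^m)``
    so viability is exactly 0.5 at D = Dm.  Noise is additive Gaussian
    with sd ``noise_cv`` on the viability fraction, clipped to [0, 1].
    """
    if m <= 0 or Dm <= 0:
        raise ValidationError("m and Dm must be positive")
    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("doses must be positive")
    fa = 1.0 / (1.0 + (Dm / d) ** m)
    v = 1.0 - fa
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        v = np.clip(v + rng.normal(0.0, noise_cv, size=v.shape), 0.0, 1.0)
    return DoseResponse(compound_id, cell_line, d, v)


# --------------------------------------------------------------------------
# migration tracks

@dataclass(frozen=True)
class MotilityTruth:
    """Persistent-random-walk ground truth for migration tracks.

    Direction decorrelates exponentially with ``persistence_time``;
    step length is ``mean_speed * dt`` exactly when ``step_cv`` is 0,
    otherwise gamma-distributed with that coefficient of variation.
    """

    mean_speed: float = 0.5  # µm/min
    persistence_time: float = 60.0  # min
    n_frames: int = 61
    total_time: float = 600.0  # min
    step_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.total_time <= 0:
            raise ValidationError("total_time must be positive")
        if self.mean_speed < 0 or self.persistence_time <= 0 or self.step_cv < 0:
            raise ValidationError("speed/persistence/step_cv out of range")


def simulate_tracks(truth: MotilityTruth, n_cells: int) -> list[Track]:
    """Sample persistent-random-walk tracks at uniform frame intervals.

    The heading angle performs a Brownian walk with per-step standard
    deviation ``sqrt(2*dt/persistence_time)``, giving the directional
    autocorrelation ``exp(-t/persistence_time)``; an infinite
    persistence time yields straight-line motion.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(truth.seed)
    dt = truth.total_time / (truth.n_frames - 1)
    sigma = np.sqrt(2.0 * dt / truth.persistence_time) if np.isfinite(
        truth.persistence_time
    ) else 0.0
    times = np.linspace(0.0, truth.total_time, truth.n_frames)
    n_steps = truth.n_frames - 1
    tracks = []
    for i in range(n_cells):
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        theta = theta0 + sigma * np.concatenate(
            [[0.0], np.cumsum(rng.standard_normal(n_steps - 1))]
        ) if n_steps > 0 else np.array([])
        if truth.step_cv > 0 and truth.mean_speed > 0:
            shape = 1.0 / truth.step_cv**2
            lengths = rng.gamma(shape, truth.mean_speed * dt / shape, size=n_steps)
        else:
            lengths = np.full(n_steps, truth.mean_speed * dt)
        dx = lengths * np.cos(theta)
        dy = lengths * np.sin(theta)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        tracks.append(Track(track_id=f"cell{i:03d}", times=times, x=x, y=y))
    return tracks


# --------------------------------------------------------------------------
# two-channel cell images

@dataclass(frozen=True)
class ImageTruth:
    """Ground truth for a synthetic single-cell two-channel image.

    The cell is a centred disk occupying ``cell_mask_fraction`` of the
    frame; the tubulin channel carries a filament-like foreground
    covering exactly ``mt_coverage_of_cell`` of the cell-mask pixels.
    """

    width: int = 512
    height: int = 512
    cell_mask_fraction: float = 0.25
    mt_coverage_of_cell: float = 0.39
    fg_intensity: float = 200.0
    bg_intensity: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValidationError("image must be at least 64x64")
        if not 0.0 < self.mt_coverage_of_cell <= 1.0:
            raise ValidationError("mt_coverage_of_cell must be in (0, 1]")
        if not 0.0 < self.cell_mask_fraction < 1.0:
            raise ValidationError("cell_mask_fraction must be in (0, 1)")
        if self.fg_intensity <= self.bg_intensity:
            raise ValidationError("fg_intensity must exceed bg_intensity")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticCellImage:
    """Generated image plus its ground-truth masks."""

    image: CellImage
    cell_mask: np.ndarray
    mt_mask: np.ndarray
    truth: ImageTruth


def simulate_cell_image(truth: ImageTruth) -> SyntheticCellImage:
    """Render a single-cell two-channel image with exact coverage.

    Random chords of the cell disk are drawn and blurred into a
    filament-likeness score; the top-k scoring pixels inside the cell
    (k = round(coverage * cell area)) become the microtubule
    foreground, so the ground-truth coverage is exact by construction.
    """
    rng = np.random.default_rng(truth.seed)
    h, w = truth.height, truth.width
    radius = np.sqrt(truth.cell_mask_fraction * w * h / np.pi)
    cy, cx = h / 2.0, w / 2.0
    if radius >= min(cx, cy):
        raise ValidationError("cell_mask_fraction too large: disk does not fit the frame")
    rr, cc = draw.disk((cy, cx), radius, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    cell_area = int(mask.sum())
    k = int(round(truth.mt_coverage_of_cell * cell_area))
    if k < 1:
        raise ValidationError(
            "coverage not achievable at this resolution: fewer than one foreground pixel"
        )

    if k == cell_area:
        mt_mask = mask.copy()
    else:
        score = np.zeros((h, w), dtype=float)
        n_lines = max(40, int(cell_area / 150))
        for _ in range(n_lines):
            ang = rng.uniform(0.0, 2.0 * np.pi, size=2)
            r0 = (int(round(cy + radius * np.sin(ang[0]))),
                  int(round(cx + radius * np.cos(ang[0]))))
            r1 = (int(round(cy + radius * np.sin(ang[1]))),
                  int(round(cx + radius * np.cos(ang[1]))))
            lr, lc = draw.line(r0[0], r0[1], r1[0], r1[1])
            keep = (lr >= 0) & (lr < h) & (lc >= 0) & (lc < w)
            score[lr[keep], lc[keep]] += 1.0
        score = ndimage.gaussian_filter(score, sigma=1.5)
        score += rng.uniform(0.0, 1e-9, size=score.shape)  # deterministic tie-break
        flat = np.where(mask.ravel())[0]
        order = np.argsort(score.ravel()[flat])[::-1]
        chosen = flat[order[:k]]
        mt_mask = np.zeros(h * w, dtype=bool)
        mt_mask[chosen] = True
        mt_mask = mt_mask.reshape(h, w)

    contrast = truth.fg_intensity - truth.bg_intensity
    tubulin = truth.bg_intensity + contrast * mt_mask.astype(float)
    actin = truth.bg_intensity + contrast * mask.astype(float)
    if truth.noise_sd > 0:
        tubulin = tubulin + rng.normal(0.0, truth.noise_sd, size=tubulin.shape)
        actin = actin + rng.normal(0.0, truth.noise_sd, size=actin.shape)
        tubulin = np.clip(tubulin, 0.0, None)
        actin = np.clip(actin, 0.0, None)
    img = CellImage(tubulin_channel=tubulin, actin_channel=actin)
    return SyntheticCellImage(image=img, cell_mask=mask, mt_mask=mt_mask, truth=truth)
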