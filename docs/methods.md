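# Methods

`tauquant` re-implements, as a tested pipeline, the quantitative workflow
used to characterise small-molecule Tau-binding compounds: fluorescence-
quenching binding analysis, thioflavin-S (ThS) aggregation-inhibition
kinetics, MTT viability dose-response, cell-migration track analytics, and
microtubule surface-fraction image quantification. Raw instrument output is
emulated by a first-class synthetic-data module so that every stage is
testable end to end.

## Binding by fluorescence quenching

Tau's intrinsic fluorescence comes from tyrosines (no tryptophan); ligand
binding near a Tyr quenches it. For a titration with quencher concentration
[Q], the two-population (Lehrer) model assumes only a fraction f_a of the
initial fluorescence F0 is accessible:

    F([Q]) = f_a·F0 / (1 + K·[Q]) + (1 − f_a)·F0

which linearises to F0/ΔF = 1/(f_a·K·[Q]) + 1/f_a with ΔF = F0 − F. The fit
is ordinary least squares of F0/ΔF on 1/[Q] — the graphical procedure the
assay community uses — giving f_a = 1/intercept, K = intercept/slope and
K_D = slope/intercept, so K·K_D = 1 holds exactly on every fit. A direct
nonlinear fit of the hyperbola is *not* the production path; it exists only
as a brute-force grid oracle in the test suite.

Numerical notes:

* The OLS is unweighted. The reciprocal transform inflates the variance of
  low-[Q] points (small ΔF), which is why single noisy titrations can carry
  large K_D spread; the estimator-sanity test documents a median K_D bias
  within 10% at 2% signal CV over 1000 replicates.
* Points with ΔF ≤ 0 are dropped with a count, never clipped — clipping
  would bias the intercept. Fewer than 3 usable points raises a "no quench"
  error.
* Inner-filter correction F = F_obs·exp((A_ex + A_em)/2) is applied when
  absorbance columns are present; otherwise the fit is flagged
  `uncorrected`. The generator applies the exact inverse attenuation with
  A(ex/em) = ε_protein·l·C_protein + ε_compound·l·[Q], so the correction
  round-trips to machine precision.
* A fitted intercept or slope ≤ 0 is a non-physical fit and raises; f_a > 1
  is flagged, not raised. Modified-plot linearity below r² = 0.95 (the
  configurable default) is flagged `nonlinear`, mirroring how compounds
  with curved modified plots are excluded from parameter reporting.
* Standard errors of f_a and K_D come from the OLS coefficient covariance
  by the delta method.

## ThS aggregation kinetics and IC50

Heparin-induced Tau assembly monitored by ThS (ex 440/em 520 nm) is fitted
per well with the empirical exponential form Y(t) = Y0 + A·exp(t/t),
A < 0, t < 0, so Y0 is the plateau. Levenberg–Marquardt with
initialisation Y0 = last value, A = first − last, t = −span/3; cap 500
function evaluations, tolerances 1e−10. A constant signal short-circuits
to a degenerate fit; non-convergence is reported on the result so panels
can skip bad wells explicitly.

Percent inhibition compares plateaus against the untreated control with an
explicit ThS background: 100·(control − treated)/(control − baseline),
capped at 100. The baseline defaults to the control fit's time-zero
intercept (model value at t = 0); it is affine-invariant by construction.

The IC50 is read from an OLS line of percent inhibition on log10
concentration, as the concentration whose fitted inhibition equals 50%.
Two deliberate choices:

* **Saturated points are excluded.** The dose law is linear until full
  inhibition then flat; plateau points carry no slope information and bias
  the line.
* **Panels bracket the half-max.** The underlying dose law is linear in
  concentration, so a straight line in log10(conc) is only locally valid;
  with doses spread geometrically over a decade the log-linear readout is
  biased by 20–35%. The pipeline therefore designs IC50 panels at ratios
  0.80–1.20 of the suspected half-max (6 doses plus control), where the
  residual bias is ≈ 0.9% — comfortably inside the 2% recovery target and
  the way a bench scientist refines an IC50 after a range-finding screen.
  `bracketing_concentrations()` encodes this design.

The historical variant "IC50 = 10^slope" is recorded on each result as
`ic50_literal` for comparison but never used: it is dimensionally
inconsistent and does not reproduce the half-maximal concentration.

Filament-dissolution records (preformed filaments under treatment) are
classified dissolving/stable by the OLS slope sign plus a sign test on
successive differences at α = 0.05 — robust to heavy-tailed reader noise.

## Viability (median-effect / Chou–Talalay)

Viability is the blank-corrected treated/untreated absorbance ratio
(replicates averaged first, values clipped to [0, 1.5] with > 1 flagged as
stimulation). The median-effect equation

    log10(fa/fu) = m·log10(D) − m·log10(Dm),  fa = 1 − viability

is fitted by OLS; Dm = 10^(−intercept/m) is the IC50 by definition.
Viabilities at 0 or ≥ 1 carry no information on the log-ratio scale and
are excluded with a count (clipping would fabricate dynamic range); fewer
than 3 usable points is an "insufficient dynamic range" error. Dm standard
error is delta-method propagated; no 4-parameter logistic alternative is
fitted.

## Migration metrics

Per track: total distance (sum of step lengths), distance to origin (net
first→last translocation), velocity = total distance / nominal experiment
time (600 min by default, even when sampling is coarser), and directional
persistence = distance to origin / total distance. A track shorter than
the nominal window uses its own elapsed time and is flagged `short_track`;
zero-length tracks get persistence 0 with a `degenerate` flag so group
means stay defined. Metrics are rigid-motion invariant, and subsampling
can only shorten the path, hence never lowers persistence.

Group summaries report mean ± SEM and n per metric, percent change versus
a reference group, and a two-sided Mann–Whitney rank-sum p-value — the
nonparametric comparison appropriate for skewed speed distributions.

## Imaging

The cell outline is an Otsu binarisation of the actin channel with hole
filling and largest-connected-component selection (single-cell contract).
The microtubule mask is a second Otsu threshold computed on tubulin
intensities *restricted to the cell mask*; the readout is
100·mt_area/cell_area. Otsu uses a 256-bin histogram (8-bit-like behaviour
for float inputs via min–max binning); a local circular-ROI variant
(`local_radius`) and a constant background subtraction (default off) are
exposed as options. A tubulin channel that is constant inside the cell is
resolved against the whole-frame histogram so unlabelled and fully
labelled cells give 0% and 100% respectively.

## Synthetic data: what it emulates, what it does not

Generators draw from exactly the models above, with assay-realistic
defaults: titrations 0–100 µM against 5 µM protein; ThS reads every 15 min
for 8.75 h (36 points) at 2 µM Tau; viability plates as 2-fold dose
series; tracks as persistent random walks sampled 61 frames over 600 min
(heading diffusion sets the directional autocorrelation e^(−t/P), step
lengths exact or gamma-distributed with CV 0.3); images as a centred disk
cell with filament-like tubulin foreground covering an exact pixel count.
Seeds are mandatory fields; there is no global random state, and noise = 0
returns the exact model curves.

Noise is multiplicative Gaussian with CV 2% for fluorescence (plate-reader
noise is approximately proportional at working intensities; the true
instrument CV is unknown, so it is a parameter), additive for viability
fractions and image intensities. Not emulated: photobleaching, drift,
well-edge effects, mechanistic nucleation–elongation aggregation kinetics,
multi-cell fields, uneven illumination. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
model, not robustness to instrument artefacts outside it.

## Problem sizes and determinism

Recovery tests run at the assay's native sizes (36-point time courses,
7-dose plates, 80-track groups, one 512² image); replicate calibrations
use 200–1000 seeded repeats of the cheap fits. The full suite and the
acceptance script each complete in well under a minute on one core. All
pipeline outputs are byte-identical for identical (config, seed); the
report's provenance block carries the seed and a hash of every
numerics-affecting configuration field.

## Known limitations

* The unweighted reciprocal-space binding fit is noise-sensitive at low
  [Q]; weighted or direct nonlinear fitting would be more efficient but is
  deliberately not the production path.
* The log-linear IC50 readout assumes the panel brackets the half-max; on
  wide range-finding panels it is biased (see above).
* The imaging stage quantifies one cell per frame and does not segment
  touching cells or correct flat-field.
* Percent-change comparisons use group means; no mixed-effects structure
  across fields or experiments is modelled.
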