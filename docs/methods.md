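# Methods

This note documents the models implemented by `dualfov`, the defaults and
why they were chosen, what the synthetic trial does and does not emulate,
and the numerical conventions a user should know before trusting or
extending the results.

## Radiometry

A spectral sample is one four-frame sequence recorded in acquisition
order: upwelling dark, upwelling target, downwelling target, downwelling
dark. Dark frames are paired strictly within their sequence (same channel,
grid, and integration time) and never interpolated across sequences.
Relative reflectance is

R(λ) = K · [(C_up − C_up,dark)/(t_up·g_up)] / [(C_down − C_down,dark)/(t_down·g_down)],

where `t` are integration times and `g` fiber throughputs, taken
proportional to fiber cross-sectional area: `g_down/g_up = (d_down/d_up)²
= (600/400)² = 2.25` by default, overridable when a calibrated throughput
ratio is known. Any fixed geometry difference between the cosine
fore-optic and the bare target fiber is folded into the single system
constant `K` (default 1.0). This is deliberate: *relative* reflectance
supports ratio-based indices and regression models without absolute
calibration, and no component of the analysis depends on the value of
`K`. The generator uses `K = 1` internally, which is what makes the
noise-free round trip exact.

Conventions that matter downstream:

- **Negative net counts are preserved, not clamped.** Clamping would bias
  low-signal bands (deep absorption under heavy overcast) upward once
  sequences are averaged. Bands below −3·σ_dark are flagged.
- Bands whose net downwelling signal is ≤ 1 count (configurable) are set
  to missing and flagged `low_irradiance`; a sequence failing the floor on
  every band is rejected as degenerate.
- Bands outside 400–900 nm are flagged `edge` (noisy detector margins)
  and trimmed during preprocessing.
- Sequence QC fails on any saturated frame, out-of-range integration
  times, negative net irradiance on more than 10% of bands, or a median
  reflectance above 2.0 (a cheap screen for swapped/duplicated channels).

## Preprocessing

Committed order, pinned by a regression test: (1) linear interpolation of
the native ~1.33 nm grid onto integer nanometres (no extrapolation beyond
the native span, so 340–1020 nm); (2) Savitzky–Golay smoothing with a
2nd-order polynomial and a 5-point window — 5 nm on the 1 nm grid — with
edges handled by a polynomial fit on the truncated window; (3) aggregation
to 5 nm block means centred on multiples of 5 nm over 400–900 nm (101
bands); (4) arithmetic plot means over all QC-passing sequences of a plot,
both measurement passes pooled. Linear (not spline) interpolation is used
because the 1.33→1 nm upsampling is mild and linearity cannot ring near
the red edge. Swapping smoothing and aggregation changes the result, which
is why the order is pinned.

Missing bands propagate as NaN through interpolation and smoothing; a 5 nm
window with some missing members averages the rest and is flagged
`partial`.

No preprocessing step reads the sky-condition label; a test shuffles the
labels and asserts identical output.

## NDSI screen

`NDSI(i, j) = (R_i − R_j)/(R_i + R_j)` in canonical order `band_i <
band_j` (swapping bands negates the index; the fit quality is unchanged).
For each of the 101·100/2 = 5050 pairs, measured population is regressed
on the index by ordinary least squares and pairs are ranked by r²,
descending, ties broken lexicographically. Ranking by |r| would give the
same order; r² was chosen for comparability with the PLSR reporting, since
the original analysis does not name its ranking statistic. Pairs whose
denominator underflows on a plot yield a missing value there; a pair
missing on more than 20% of plots is excluded from ranking. A pair with
zero index variance is reported with r² = 0 and flagged degenerate.

The scan is invariant to any common rescaling of all spectra — the same
scale-freedom that underlies illumination invariance.

## PLSR ensemble

PLS1 regression (NIPALS, mean-centering only, no unit-variance scaling of
bands — reflectances share units, and scaling would inflate noisy edge
bands) maps spectra to population. The resampling topology is:

1. per iteration *t* (seeded by `(seed, t)`, so any iteration is
   reproducible in isolation): draw a random 25% validation hold-out;
2. split the remaining pool 75/25 into calibration and cross-validation
   sets; choose the component count `k` in 1..15 as the argmin of CV RMSE,
   ties to the smallest `k` (exact-fit plateaus in noise-free data resolve
   to the most parsimonious model);
3. refit at `k` on the whole pool and predict the hold-out.

An alternative reading of the procedure — one fixed validation set with
100 calibration/cross-validation shuffles of the remainder — is available
as `topology="fixed-validation"` and is never silently mixed with the
default.

Component selection evaluates all truncations from a single maximal fit:
NIPALS components are computed sequentially, so the k-component model
equals the 15-component fit truncated to its first k latent directions
(verified against separate fits to 1e−8). With maximal components PLSR
reproduces OLS predictions, which the test suite checks against an
independent normal-equations oracle.

Reported metrics: R² is the squared Pearson correlation of predicted vs.
measured (the two vectors are regressed on each other), *not*
1 − SS_res/SS_tot; with a mean offset the two differ, and RMSE (population
units) is reported alongside precisely to catch such offsets. Calibration
and cross-validation metrics are per-iteration means with SDs; validation
is reported both ways — per-iteration means, and the regression of the
per-sample averaged hold-out predictions on the measured values
(`validation_aggregated`, the headline number). Samples never held out
across all iterations (possible at few iterations) are reported missing
with a warning.

Missing spectral entries are mean-imputed within the training fold and the
imputation is recorded on the model.

## Synthetic trial

The generator exists so the full pipeline can be exercised and its claims
tested without any field data. What it emulates:

- **Illumination.** A smooth solar-like irradiance shape (Planck curve at
  5800 K, normalised). Sunny: full brightness, ≤1% temporal jitter.
  Cloudy: per-sequence brightness drawn from 10–50% of clear sky
  (scattered-to-full cloud), 5% jitter. Brightness and jitter multiply
  both channels and therefore cancel exactly in the reflectance ratio —
  the in-silico form of the instrument's core design property. An optional
  `nir_divergence` perturbs the *downwelling* channel only (up-weighting
  bands beyond ~750 nm by a configurable few percent under cloud), leaking
  a mild near-infrared condition signature into retrieved reflectance; it
  is off by default.
- **Canopy.** Linear soil/vegetation mixture. The vegetation endmember is
  an analytic curve (Gaussian green peak at 550 nm, logistic red edge,
  NIR plateau), the soil endmember a gentle ramp — parametric stand-ins,
  not spectral-library measurements. Vegetation cover follows
  `f = 1 − exp(−(c_stage·p)^k)` with per-plant area `c_stage` growing
  with development stage (defaults 0.008/0.012/0.020/0.030 for
  V_C/V_1/V_2/V_3 per plant·m⁻², k = 1): linear at low density, saturating
  as foliage overlaps — which is what produces underestimation at high V3
  populations in downstream models.
- **Heterogeneity.** (a) Per-sequence cover jitter with stage-dependent
  CV (0.90/0.75/0.35/0.18 for V_C..V_3): the ~0.13 m-radius footprint
  contains only a handful of small seedlings at early stages (Poisson
  counting in a ~0.05 m² disc gives relative SDs near 1 at V_1 densities),
  while V_3 foliage integrates the footprint. Averaging 26 sequences per
  plot reduces but does not remove this, and it is the mechanism that
  makes early-stage predictions worse — the stage ordering in the
  recovery tests emerges from it rather than being asserted. (b) Per-plot
  establishment patchiness (3% cover SD). (c) Per-plot soil brightness
  variation (5% SD) plus a tillage brightness factor (conventional till
  1.15 vs no-till 1.0), which is what makes pooling across treatments
  costly. (d) Narrow rows boost effective cover ((0.76/rs)^0.25), since
  the same population is spread more evenly.
- **Sensor.** Uniform 1.33 nm grid over 340–1022 nm (513 points — an
  idealisation of the instrument's 1.33 nm FWHM resolution), dark level
  180 counts with 4-count read noise, Poisson shot noise, 16-bit full
  well. Integration times are drawn per sequence (13–15 ms upwelling,
  4–6 ms downwelling); if a channel would saturate, its integration time
  is redrawn once from the lower half of the range, after which counts are
  clipped and the frame flagged (QC drops it).
- **Trial design.** 2 replicates × 4 stages × 2 row spacings × 2 tillages
  × 2 cultivars × 14 seeding rates (3.7·k, k = 1..14, plants × 10⁴ ha⁻¹) =
  224 physical plots, 896 plot records; 13 samples per row × 2 center rows
  = 26 sequences per record. Measured population = seeding rate × a
  per-plot emergence draw (mean 0.85, SD 0.08, truncated to (0, 1]) —
  emergence is an invented nuisance parameter, surfaced in config, and
  never treated as ground truth by tests. The sky-condition schedule
  mirrors the canonical calendar: replicate 1 sunny at V_1, replicate 2
  sunny at V_3, overcast otherwise.

Everything is a pure function of (parameters, seed); per-record and
per-sequence draws are keyed by their indices, so generation order cannot
change results.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: radiative-transfer canopy structure and
BRDF, wavelength-dependent atmospheric (diffuse/direct) geometry beyond
the optional NIR perturbation, detector nonlinearity and stray light,
wavelength miscalibration, and any spectral richness beyond a
two-endmember mixture. The last point matters for method comparisons: the
synthetic spectral manifold is nearly rank-2, so a single well-chosen
band-pair index captures almost all usable signal and the advantage of
full-spectrum PLSR over the best NDSI is small here (it is structural on
data whose response spans several spectral directions, which is how the
multi-band comparison test is built). For the same reason the identity of
the top-ranked NDSI pairs depends on the invented endmember shapes, and
the green/red-edge pair (565, 710) — tracked throughout as the reference
pair — ranks mid-field on default synthetic data rather than in the top
ten.

## Study driver

Datasets are analysed at three canonical granularities: treatment level
({stage × row spacing × tillage × replicate} = 32 groups, cultivars
pooled — the factorisation that matches the printed count; using cultivar
instead of replicate also reaches 32 and can be requested explicitly),
stage level (4), and pooled (1). Each group gets the PLSR ensemble, the
NDSI scan with its top-10 pairs, and a univariate model on the reference
pair. Stages measured under opposite conditions in the two replicates are
cross-validated in both directions (train sunny → test cloudy and vice
versa), training wholly on one side with internal resampling.

The residual condition check — a two-sided permutation test (999 seeded
shuffles) on the cloudy-minus-sunny difference of mean residuals — is an
addition of this package, formalising a visual residual inspection as a
reportable statistic. It reports only; nothing gates on it.

Reports are deterministic given the config: canonical JSON rendering of
two runs with the same seed is byte-identical. Timestamps live only in a
sidecar file.

## Problem sizes in tests and the acceptance script

The test suite exercises the full default trial (896 plots, 26 sequences
each) once per session for the recovery and cross-condition checks, with
100-iteration ensembles at stage level; the whole-study determinism check
uses a structurally complete but reduced study (2 stages, 7 seeding
rates, 2 sequences per plot, 8 iterations) — determinism is
size-independent, and the reduced study keeps the suite quick. The
acceptance script runs the full default study at 100 iterations. These
sizes are the package's chosen trade-off between statistical stability of
the reported quantities and a test suite that runs in minutes.

## Known limitations

- `K` absorbs all un-modelled field-of-view geometry; absolute
  reflectance is out of scope.
- The emergence model links seeding rate to measured population by a
  single truncated-normal draw; real emergence varies spatially within
  plots.
- Integration-time redraw-once saturation handling is a simplification of
  an instrument's adaptive exposure logic.
- The NDSI/PLSR comparison and top-pair identities on synthetic data
  reflect the two-endmember mixture (see above), not field spectra.
- GPS/plot-assignment is reduced to trusted plot labels plus an optional
  nearest-centroid assigner with a 0.15 m rejection radius.
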