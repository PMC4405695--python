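# Methods

This note documents the models, estimators, and numerical choices in
vesitrack, what the synthetic-data generator does and does not
emulate, and the known limitations.  No empirical claim here goes
beyond what the test suite and `scripts/acceptance.py` compute.

## Trajectory model

Simulated vesicle tracks come in two motion classes.

**Confined** tracks are 2-D Brownian motion (diffusion coefficient
`D`, default 0.05 µm²/s) inside a disc of radius `R` about the start
point, with hard specular (billiard) reflection at the boundary.
Reflection was chosen over a harmonic (Ornstein–Uhlenbeck) restoring
force because it makes the true occupied region exactly the disc, so
the estimator target is the closed form πR² rather than a
model-dependent occupancy quantile.  The stationary distribution is
uniform on the disc, giving two useful identities: the long-lag MSD
plateau is E‖x₁−x₂‖² = R², and the maximal distance from the centre
approaches R, so the minimal-enclosing-circle area approaches πR²
from below.

**Directed** tracks move at constant speed (default 0.5 µm/s) along a
fixed axis whose heading flips 180° at Poisson rate ρ (a telegraph
velocity process).  Exact 180° reversals match the 1-D character of
the downstream statistic, which projects displacements onto the
track's first principal axis.

Both classes support pausing as an alternating renewal process:
pause onsets at Poisson rate (per second of moving time), pause
durations exponential.  A pause suppresses true displacement but not
localization noise, so pause detection is exercised against realistic
jitter.  All event times are drawn in continuous time and integrated
exactly within each frame interval; the sampled positions are the
only observables.  Consequently an excursion or reversal pair shorter
than one frame can be invisible — a property of every frame-based
estimator on real data, deliberately not corrected in the generator.

Independent Gaussian localization noise (default sd 0.02 µm, a
typical vesicle localization precision; the imaging system this
emulates does not pin the value) is added per frame per coordinate.

## Motion statistics

* **MSD** is time-averaged over all ordered observation pairs at each
  integer frame lag; gapped tracks contribute only existing pairs.
* **Classification**: α = least-squares slope of log MSD vs. log lag
  over lags 1..min(10, n/3).  Defaults α_confined = 0.7,
  α_linear = 1.3, minimum 20 points; the thresholds are symmetric
  about the diffusive value 1 and give ≥90% correct assignment on the
  labelled synthetic suite (free diffusion lands in the unclassified
  band by design).  A zero-variance track is confined by convention
  with α = 0.
* **Confinement area** is the area of the minimal enclosing circle,
  computed by a randomised incremental (Welzl move-to-front)
  algorithm, expected linear time, shuffled deterministically.
  Containment tests use relative slack 1e−12 so support points
  re-test as inside.  The implementation is verified exactly against
  brute-force enumeration of all pair/triple candidate circles.  A
  2σ-ellipse summary was considered and rejected: the circle matches
  how confinement zones are drawn and compared in this assay family.
* **Mean speed** = mean over consecutive observed pairs of Euclidean
  displacement / elapsed time; gaps use the actual elapsed time.
* **Pauses**: a pause is a maximal run of steps with instantaneous
  speed strictly below 0.1 µm/s; the rate counts onsets over the full
  first-to-last-frame duration.  Whether the natural denominator is
  full or non-paused duration is ambiguous in this assay family; full
  duration is used and the choice is visible in the report.
* **Direction changes**: the first principal axis is estimated from
  all positions (paused ones carry information about where the track
  lives); consecutive displacements are projected onto it; paused
  steps and exact-zero projections are discarded; sign changes
  between successive retained projections are counted.  Counting any
  sign flip (rather than only positive→negative) keeps the statistic
  invariant under the inherent sign ambiguity of a principal axis.
* **Group comparison**: two-sided Wilcoxon rank-sum on the per-track
  metric (track metrics are far from normal), with means, SEs and
  fold change reported for effect-size context.

### Sampling-rate choice in the reversal-recovery experiment

A frame-based counter can only see an odd number of reversals between
consecutive samples; the expected relative loss is
1 − (1 − e^(−2ρΔ))/(2ρΔ) ≈ ρΔ.  At the live-vesicle cadence Δ = 2 s
and ρ = 0.1/s this is ~18%, an intrinsic property of the sampled
statistic rather than an estimator defect.  The recovery experiment
therefore samples at Δ = 0.2 s (ρΔ ≤ 0.02), where the discretisation
loss (≤2%) is well below the 3-standard-error resolution of 200
replicate tracks, so unbiasedness of the counting itself is what is
tested.  The confinement-area recovery is run noise-free: with 500
frames the circle radius is an extreme-value statistic, and even
0.02 µm noise inflates the area of an R = 0.2 µm track by tens of
percent (max of ~500 radial noise draws), which would test the noise
model, not the estimator.

## Detection and linking

Detection finds 8-neighbourhood local maxima above a threshold; a
connected plateau of equal maxima up to 3×3 pixels is one peak at its
centroid, larger plateaus are flat background.  Sub-pixel refinement
uses three-point Gaussian (log-parabola) interpolation per axis on
locally background-subtracted intensities (background = minimum of
the surrounding 5×5 window).  The classical 3×3 intensity-weighted
centroid was measured at 0.11–0.35 px worst-case bias for PSF σ of
0.7–1.5 px — a well-documented limitation — and is kept only as the
fallback for degenerate windows; the log-parabola is exact for a
Gaussian spot (<0.004 px bias noise-free, ~0.04 px rms at SNR ≈ 60).
Maxima closer than `min_separation` pixels keep only the brighter.

Linking is greedy nearest-neighbour: candidate links between open
track ends and next-frame spots are sorted globally by distance and
accepted subject to a gate of `max_disp` µm per elapsed frame, with
up to `max_gap` missing frames bridged.  This is an explicit
simplification relative to global assignment (LAP) trackers; it is
exact when trajectories are separated by more than the per-frame
search radius, which the recovery experiments guarantee and real
usage should check.  No merge/split handling, no motion-model
(Kalman) prediction.

## Single-molecule metrics

* **Microtubule length**: per-filament skeletonization, then the sum
  over adjacent skeleton pixel pairs of 1 (axial) or √2 (diagonal)
  pixel steps.  This chain-code estimator is exact for axial and 45°
  lines but overestimates arbitrary-angle straight digital lines by
  up to +8.2% (at 22.5°; ~+5% averaged over angles) — the classical
  chain-code length bias.  Corrected-weight estimators exist but
  break the exact hand-countable step identities, so the plain
  weights are kept and the bias is documented; the density recovery
  below absorbs it within its 10% band.
* **Motors per µm** = mean per-frame count of detections falling on
  the 1-px-dilated microtubule mask, divided by total length.  The
  dilation absorbs localization error; per-frame averaging (rather
  than unique-motor counting) is used and stated, since the two
  differ when motors turn over.
* **Moving motors**: mean speed > 0.12 µm/s AND net start-to-end
  displacement > 0.2 µm AND duration > 0.9 s, all strict.  Net
  displacement (not path length) is the default "distance" reading
  so diffusive jitter cannot qualify; a path-length variant is
  available behind a flag.  The percentage denominator keeps every
  track regardless of duration, which is what makes a large
  short-lived immobile pool dilute the moving percentage.
* **Lifespan** = (last − first frame) × frame interval; the median
  and the fraction beyond a configurable cutoff are reported.

The motor-field generator places straight filaments of exact summed
length and decorates them with a stationary birth–death spot
population (initial count Poisson with mean density × length, births
at the equilibrium rate, exponential lifetimes), so the expected
per-frame count equals density × length at every frame.  An optional
hard-core minimum separation (arc length at birth) makes every
emitter optically resolvable; the density-recovery experiment uses
0.5 µm because two emitters inside one PSF merge into a single peak
for any detector (expected loss ≈ 2·r_merge·density, ~16% at
0.3 motors/µm) — with resolvable spots the experiment grades
detection and counting fidelity, which is what it is for.  Filament
crossings can still superpose spots from different filaments; this
is left in as realistic behaviour.

## Golgi scoring and colocalization

Segmentation is threshold (Otsu or fixed) → 8-connected components →
area filter, labels renumbered by descending area.  Background is the
median intensity outside all cell masks (robust, parameter-free).
Objects are assigned to cells by majority pixel overlap, ties to the
lower cell id.  The per-cell score is the background-subtracted
Golgi intensity in objects with area strictly above the threshold,
divided by the total over that cell's objects — the
intensity-weighted ("fraction of staining") reading; an area-weighted
variant is behind a flag.  The normalised score divides by the
cell's mean background-subtracted marker intensity; because the exact
normalisation arithmetic used by published pipelines varies, the raw
fraction is always reported alongside.  Cells without objects and
unassigned objects are counted in a QC report rather than silently
dropped.  Scores are invariant to Golgi-channel gain and scale
inversely with marker gain.  Condition comparison is Welch's t-test
(per-cell scores; unequal variances are the norm between intact and
fragmented populations).

Pearson colocalization is computed over mask-object pixels, pooled
and per object; zero-variance channels yield a missing value rather
than a number.

Rendered ground truth records the *achieved* pixel-quantised object
area, not the requested one: a disc of requested area A is rasterised
to the nearest achievable pixel set and every downstream exactness
check compares against what was actually rendered.

## Binding fits

One-site saturation S(L) = B·L/(K_D + L), unweighted nonlinear least
squares (`scipy.optimize.curve_fit`), K_D initialised at the
concentration nearest half-maximal signal, B at the maximal signal,
K_D bounded to (1e−4, 1e4) µM.  The ligand-depletion-free hyperbola
matches standard pull-down analysis; a quadratic depletion-aware
variant (requires the receptor concentration) is available for
bead-bound assays at sub-µM K_D.  Optional 1/σ² weighting is exposed
but off by default.  A fit is *flagged* (never silently returned)
when the optimiser fails, K_D sticks at a bound, or K_D lands far
outside the sampled concentration range (>100× the maximum or <1% of
the minimum) — the signature of data that do not constrain
saturation.  Standard errors come from the covariance of the fit;
K_D shift ratios propagate them to first order (delta method).  The
noisy recovery experiments titrate each concentration in duplicate
(12 points), as binding assays routinely do; with only 6 points the
nominal ±2 SE interval covers at ~88% for degrees-of-freedom reasons
alone.

## Pipeline, configuration, determinism

Every parameter has a default in one validated configuration tree;
unknown keys are rejected by name.  Named presets carry the assay
constants: vesicle frame interval 2 s, streaming TIRF 0.041 s, pause
threshold 0.1 µm/s, moving-motor thresholds 0.12 µm/s / 0.2 µm /
0.9 s, Golgi area thresholds 4.11 µm² (siRNA-rescue) and 2.74 µm²
(nocodazole).  A pipeline run executes its stages in order, logs
in/out counts per stage (tracks rejected, objects discarded), and
writes a manifest (parameters, seed, version, counts, runtimes)
sufficient to regenerate every output.  All randomness flows from
one integer seed through `numpy.random.SeedSequence` spawning;
rerunning a config byte-identically reproduces every CSV.

## Verification experiments and problem sizes

`scripts/acceptance.py` (and the mirrored acceptance tests) run:
minimal-circle vs. brute force on 1000 random sets of ≤25 points;
confinement-area recovery at R ∈ {0.2, 0.5, 1.0} µm × 100 tracks of
500 frames; reversal-rate recovery at ρ ∈ {0.02, 0.05, 0.1}/s × 200
tracks of 500 frames at 5 Hz; classification on 200 + 200 labelled
tracks; the moving-classifier boundary table; motor-density recovery
at 0.1 and 0.3 /µm × 100 rendered fields; Golgi exactness on
noise-free renders at both presets plus a 30 + 30 cell population
comparison; 100-seed colocalization null; 100-seed K_D recovery,
coverage, and 10-fold shift; and a byte-level determinism check.
These sizes keep each experiment's Monte-Carlo error comfortably
inside the tolerance it tests while the whole script runs in well
under a minute on one core.

## What the generator does not emulate

Gaussian noise only — no Poisson shot noise, EMCCD gain chains, or
photobleaching.  No 3-D trajectories or image stacks; 2-D inputs are
assumed throughout.  Straight filaments only; curved microtubules
would interact with the chain-code length bias differently.  Passing
the recovery suite therefore demonstrates correctness of the
estimators under the stated models, not robustness to every
instrument effect in real microscopy; on real data the documented
knobs (thresholds, gates, dilation radius) are the interface for
adapting to those effects.
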