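# Methods

This note records the models, conventions, and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Track motility analysis

**Model.** A trajectory is an ordered sequence of 2D positions (µm) at a
fixed frame interval `dt` (s). Frames must be consecutive; tracks with
gaps are rejected rather than interpolated, because a time-averaged MSD
over unevenly spaced points silently mixes lag times. Tracks shorter than
`min_frames` (default 25) are excluded from population statistics.

**MSD estimator.** The time-averaged MSD uses all overlapping ordered
pairs: `MSD(k·dt) = mean over i of |r(i+k) − r(i)|²` for integer lags
`k = 1 … floor(max_lag_fraction·(n−1))`. The overlapping estimator
maximizes pairs per lag; `max_lag_fraction` defaults to 0.25 because
long-lag estimates average few pairs and are dominated by noise. For
tracks so short that this yields fewer than the 2 lags a line fit needs,
the fraction is widened just enough to provide them.

**Exponent fit.** Unweighted OLS of `ln MSD` on `ln Δt`; the slope is the
anomalous-diffusion exponent α and the intercept C is reported in natural
log. Zero-valued MSD lags are dropped before fitting (their logarithm is
undefined); a track with fewer than 2 usable lags — e.g. a motionless
particle — is flagged degenerate and classified non-processive, as the
limiting case of confinement. Weighted fits (by pair count) were
considered and rejected: the unweighted fit is the field's convention for
this classification, and the class boundaries, not the variance of α̂,
carry the scientific meaning.

**Classification.** α > 1.45 → processive; 1 ≤ α ≤ 1.45 → diffusive
(both boundaries inclusive); α < 1 → non-processive. The thresholds are
exposed in `ClassifierConfig` but default to these values. One known
consequence, verified by simulation: the sampling distribution of α̂ for a
finite Brownian track is centred on 1 — exactly the lower diffusive
boundary — so individual Brownian tracks split roughly evenly between
diffusive and non-processive by estimation noise (mean α̂ ≈ 0.97,
sd ≈ 0.16 at 100 frames). Population mean α is recovered accurately; the
per-track label for a borderline diffusive particle is intrinsically
noisy. Directed and confined motion sit far from their boundaries and
classify essentially perfectly.

**Phase segmentation.** The active/passive segmentation slides a window of
`phase_window` frames (default 10) along the track, computes the local
log-log MSD slope within the window (lags 1 … window/2), and marks the
window active when that slope exceeds `phase_alpha_active` (default 1.45,
reusing the track-level threshold so "active" means "locally processive").
Each frame takes the majority vote of the windows covering it (ties go to
passive), and state runs shorter than `min_phase_frames` (default 3) are
absorbed into their neighbours, shortest first. Phases therefore tile the
track and alternate states. Tracks shorter than the window collapse to a
single phase carrying the whole-track classification. This is the
simplest segmentation consistent with the exponent-based track classes; a
hidden-Markov state model would give soft boundaries but introduces a
likelihood model the rest of the analysis does not need. The window length
sets the resolution limit: runs shorter than ~one window cannot be
resolved and are absorbed into the surrounding phase.

**Run length.** The net Euclidean displacement between an active phase's
first and last positions — transport distance, not path length. Path
length grows without bound with localization noise at fixed true motion,
whereas net displacement is noise-robust and matches the interpretation of
long runs (> 2 µm) as sustained motor-driven transport. Population run
lengths are pooled into half-open 1-µm bins [0,1), [1,2), …

## Synthetic trajectories

Brownian steps are i.i.d. Gaussian per axis with variance `2·D·dt`
(MSD = 4·D·Δt in 2D, α = 1). Ballistic motion advances `v·dt` along a
fixed heading (MSD = (v·Δt)², α = 2). Confined motion is Brownian
reflected radially at a circle of radius R about the start; the reflection
`r → |2R − r|` is iterated so steps larger than the circle fold back
inside. Switching motion is a two-state per-frame Markov chain — active =
ballistic with a heading redrawn at each passive→active transition,
passive = Brownian — with the initial state drawn from the chain's
stationary distribution. Localization noise is additive i.i.d. Gaussian
per coordinate on top of the true path, which is retained as ground truth.

Defaults emulate retrograde endosome transport in cultured cells: active
speed 0.5 µm/s, passive D 0.01 µm²/s, localization noise sd 0.02 µm, and
per-frame switch probabilities of 0.005 (mean dwell ≈ 200 frames). The
dwell default is deliberately long relative to the 10-frame segmentation
window — the rolling-window segmenter cannot resolve runs shorter than its
window, so the generator's standard conditions keep phases in the regime
the method is designed for; shorter-dwell populations can be generated
explicitly and will show the stated resolution limit. All draws for one
generator call flow from a single seeded generator, so identical
(parameters, seed) reproduce identical output bytewise.

What the generator does *not* emulate: photophysics (blinking, bleaching),
3D motion projected to 2D, motion blur, heterogeneous per-track noise, or
tracking/linking errors. Passing tests therefore demonstrate correctness
of the analysis on clean kinematics, not robustness to detector artefacts.

## Image quantification

**Maximum-entropy threshold.** Kapur's criterion over a 256-bin histogram
spanning the observed min–max range (the ImageJ convention for non-8-bit
data): choose the split maximizing the summed Shannon entropies of the
background and foreground distributions. Ties break toward the lowest
threshold. The returned value is the upper edge of the last background
bin, so the foreground mask is `data > threshold`. A constant image has no
histogram to split and raises a degenerate-input error rather than
returning an arbitrary value. Numerical note: mathematically tied splits
(e.g. across empty bins) can be ordered either way by floating-point
round-off; the implementation's choice always attains the exhaustive
maximum to ~1e-15.

**Particle morphometry.** Supra-threshold connected components
(8-neighbour default, matching common particle-analysis defaults;
4-neighbour available), with components below `min_area_px` discarded and
labels renumbered consecutively. Areas are pixel counts × pixel_size²;
centroids in µm with pixel centres at integer coordinates, x = column ×
pixel_size. Touching organelles are not split (no watershed); confocal and
EM images share the code path and differ only in pixel_size.

**Colocalization.** Pearson's r on raw intensities; thresholded Manders
M1 = Σ(A | A > thrA, B > thrB) / Σ(A | A > thrA) and symmetrically M2,
which keeps both in [0,1] by construction (classic Manders is the
thr = 0 special case). The pipeline thresholds each channel with the
maximum-entropy criterion, then computes the PCC over the union of the two
supra-threshold masks by default — correlation over joint background
inflates r — with a whole-frame mode available, and falls back to the
whole frame (recorded in the result) when the masked intensities are
constant, as in noiseless full overlap. Thresholds, pixel counts and the
PCC mode used are recorded in the result. Background inflates raw-
intensity overlap coefficients slightly: for planted colocalized fraction
f, the unrestricted numerator would carry an additive ≈ (1−f)·bg/signal
term; restricting the numerator to the joint supra-threshold set removes
it.

**Radial profiles.** Concentric mode assigns each pixel centre to the
half-open ring containing its distance from the given centre and reports
per-ring integrated intensity over the total in-circle intensity (sums to
1); a per-ring-mean mode is available for parity with plugin conventions
that average rather than integrate. Rim mode computes each pixel's
Euclidean distance to the nearest nucleus pixel via a distance transform —
distance from the *rim*, which differs measurably from centroid distance
for elongated nuclei — excludes the nuclear interior, bins in fixed-width
rings (5 µm typical), and normalizes by total cell-mask intensity
including the nucleus; fractions then sum to ≤ 1, with equality when the
nucleus holds no signal. Pixels beyond the outermost full ring accumulate
into a flagged partial ring rather than being dropped.

## Scalar assays

**CTCF** = integrated density − cell area × mean background, with area in
pixels and background per pixel; negative values (background brighter than
the cell mean) are reported with a warning, never clamped, because they
are diagnostic of a bad background region. **Degradation fractions**
normalize each chase-time intensity to the t = 0 pulse and are scale
invariant. **Fold change** is a plain ratio of summary means with a
positive-control precondition. **pH calibration** fits a straight line of
340/380 ratio on buffer pH over the calibrated range (pH 4–6). The dye's
full response is sigmoidal; over this narrow range a line is the standard
working approximation, and the linearity assumption is recorded here
rather than hidden. The inverse read-out flags (rather than rejects)
values outside the calibrated range, with a 1e-9 tolerance at the
boundaries so round-trip noise is not flagged.

## Problem sizes and tolerances

The test suite and the acceptance script run on simulated populations of
200–1000 tracks of 60–200 frames, 256² images with up to 200 puncta, and
100-seed repeats for noisy-recovery averages — sizes at which every
ensemble statistic is stable to well within its stated tolerance while the
whole suite runs in seconds. Oracle-equivalence checks (MSD vs explicit
double loop, threshold vs exhaustive entropy search) are exact up to
floating-point tie-ordering, as noted above; stochastic recovery checks
use fixed seeds and tolerances stated in each test (5% for ensemble MSD,
0.05 for mean exponents, 10% per run length with a 90% recovery floor,
0.02 per radial bin, 0.05 pH units).

## Known limitations

- The phase segmenter cannot resolve active runs shorter than its window
  (default 10 frames); such runs are absorbed into neighbouring phases.
- Per-track class labels near α = 1 are intrinsically noisy for finite
  tracks (see above); compare populations, not single borderline tracks.
- No particle detection or frame-to-frame linking: trajectories are
  inputs. No 3D analysis anywhere in the package.
- Manders coefficients on raw intensities remain sensitive to residual
  background below threshold; heavy uncorrected background argues for
  background subtraction upstream.
- The pH calibration is linear by construction and should not be
  extrapolated far outside the buffer range; the out-of-range flag marks
  when that is happening.
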