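# Methods

`hectpipe` analyses the functional, structural, and molecular readouts of
engineered cardiac tissues (hECTs): muscle strips self-assembled between
two flexible PDMS posts whose deflection reports twitch force. This note
documents the models behind each stage, the parameters that matter, what
the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Force transduction (mechanics)

The posts are treated as linear cantilever springs: `F = k·δ`, with the
tip deflection δ (µm) referenced to the post position at tissue
fabrication and signed positive toward the tissue midline (contraction).
When the stiffness is not supplied directly it is computed from post
geometry with the Euler–Bernoulli formula `k = 3EI/L³`, `I = πr⁴/4`;
units are normalized so E in MPa and lengths in mm give k in µN/µm. An
optional multiplicative `lever_correction` (default 1) accommodates rigs
where the tissue attaches below the tracked tip; this package takes no
position on whether any specific rig needs it. Developed stress divides
developed force by a circular cross-section `πd²/4` inferred from a
single diameter measurement — an axisymmetry assumption that
overestimates stress for flattened tissues.

## Twitch model and metric extraction

The synthetic twitch waveform is a double-exponential,
`g(t) = (1 − e^{−t/a}) e^{−t/b}` scaled to unit peak, parameterized by
the observable quantities time-to-peak (default 0.20 s) and relaxation
time constant `b` (default 0.35 s); the rise constant `a` is solved from
`t_peak = a·ln(1 + b/a)` by bracketed root finding. Any peak time in
`(0, b)` is representable. A recording is baseline (passive force,
default 20 µN) plus one kernel per beat with per-beat amplitude
`A_i = A(1 + cv·N(0,1))⁺`, optional linear drift, and white Gaussian
measurement noise.

Detection runs on a Savitzky–Golay-smoothed copy (window 51 ms, order 2
at the default 100 Hz sampling): peaks require prominence ≥ 0.3× the
smoothed signal range and ≥ 0.3 s separation (max plausible rate ≈ 3 Hz).
Onset and end are the crossings of baseline + 5% of twitch amplitude on
either side of the peak. The per-twitch baseline is the 10th percentile
of the samples in the flanking inter-twitch windows, which tolerates
incomplete relaxation and referenced-to-fabrication offsets.

Per twitch: DF = smoothed peak − local baseline; ±dF/dt from a
Savitzky–Golay differentiator (same window family); time-to-peak from
onset; RT50/RT90 as the first post-peak crossings of 50%/90% relaxation,
linearly interpolated between samples. Because the kernel's steepest rise
precedes the 5% onset crossing, the +dF/dt search extends backward from
the onset while the smoothed derivative remains positive; without this
the contraction rate is underestimated by several percent. −dF/dt is
stored signed (negative) and reported as magnitude in group tables.

Accuracy on noise-free input: with 2 kHz sampling and short (3-sample)
derivative windows every metric agrees with dense finite differences of
the analytic kernel to better than 1%. The verification uses 0.25 Hz
pacing so twitches relax fully between beats; at 0.5 Hz the previous
twitch's exponential tail biases the inter-twitch baseline by ~0.5% of
the amplitude, which is inherent to the waveform, not to the estimator.

## Rhythm and pacing capture

Spontaneous beat intervals are Gaussian with configurable mean rate
(default 0.39 Hz) and interval coefficient of variation (default 0.14),
floored at 0.2 s as a refractory bound. Beat-rate variability is the
sample (n−1) COV of the inter-beat intervals over the 30-s window,
computed on intervals rather than instantaneous rates (the two agree to
first order; the interval form matches the Poincaré analysis). A 30-s
window at 0.39 Hz holds only ~11 intervals, so the sample COV carries the
usual small-sample downward bias of order 1/(4n); recovery tests
therefore compare the analyzer against the ground-truth finite-sample COV
of the same simulated series, not only against the asymptotic parameter.

Poincaré analysis pairs consecutive intervals and reports
SD1 = SD((PP_{n+1} − PP_n)/√2) and SD2 = SD((PP_{n+1} + PP_n)/√2);
the identity `2(SD1² + SD2²) = Var(diff) + Var(sum)` holds exactly under
the sample convention and is asserted in tests.

1:1 pacing capture is declared when the detected beat count reaches 95%
of `floor(window·f)` and every interval lies within 10% of the pacing
period; both thresholds are configuration. A tissue responding to every
second stimulus fails on both counts. The criterion is deliberately
strict about single long intervals, which is what a dropped stimulus
looks like.

## Force–frequency relationship

Each tissue's developed force is normalized to its own 0.25 Hz value
(tissues without a 0.25 Hz measurement are excluded, with a logged
reason; series truncated by capture loss are retained). The group slope
is ordinary least squares of normalized DF on frequency, pooling all
tissue–frequency points, with a two-sided t-test against zero. Group
slopes are compared through the group×frequency interaction of a pooled
regression; its squared t equals the ANCOVA F for equality of slopes.

The FFR generator draws per-tissue baselines (CV 0.3 around 10 µN) and
applies `E[DF] = base·(1 + slope·(f − 0.25))` with additive relative
noise of SD 0.1 per point. Because normalization divides a tissue's whole
series by its noisy 0.25 Hz value, the residual at the reference
frequency is exactly zero and within-tissue errors are correlated; under
these conditions the pooled OLS inference is slightly conservative
(empirical size of the slope-difference test ~1–2% at nominal 5%, CI
coverage above nominal). Under iid errors the test attains its nominal
size; both regimes are exercised in the tests.

## Fiber orientation and image quantification

Orientation is axial (180°-periodic), reported in degrees in (−90, 90]
measured counterclockwise from the image x-axis with y up, so horizontal
fibers are 0°. Gradients are Gaussian-derivative filters (σ = 1 px);
plain central differences are available by disabling smoothing but show a
systematic ~1.5° bias toward the diagonals on a discrete lattice, which
is why the rotationally symmetric kernel is the default. Per 7×7-pixel
subregion the fiber angle is `½·atan2(Σ2GxGy, Σ(Gx²−Gy²)) + 90°`
(perpendicular to the dominant gradient), weighted by the summed gradient
magnitude; the weakest 10% of blocks (flat regions) are masked and
partial edge blocks dropped rather than padded, avoiding synthetic
gradients.

Summary statistics double the angles, average the unit vectors with
weights, and halve the resultant argument. The circular standard
deviation `CSD = (180/π)·½·√(2(1−r))` runs from 0° (perfect alignment,
r = 1) to `(180/π)·√2/2 ≈ 40.51°` (uniform, r = 0). When r = 0 the mean
angle is undefined (two equal perpendicular axes); the CSD is still
returned. Note that any finite sample of n uniform angles has E[r] ≈
0.89/√n > 0, so an image with ~1000 analysed blocks is expected to read
~40.0° rather than 40.51°.

The texture generator superposes line segments at angles drawn from a von
Mises distribution on doubled angles (κ = `dispersion`; κ = 0 is the
random-orientation limit), rendered with bilinear splatting so
rasterization does not bias gradient directions, then lightly blurred.
It emulates the oriented-texture statistics of collagen micrographs, not
their intensity distribution, fiber curvature, branching, or
out-of-plane structure — so passing recovery tests validate the
orientation operator, not segmentation of real histology.

Particle counting applies a global threshold (Otsu default), 8-connected
component labeling, and a minimum area of 5 px; labeled-cell percentages
divide counts from two channels. The particle generator places
non-overlapping discs with a 2-px moat (so rasterized discs never touch
diagonally) and labels exactly `round(fraction·n)` of them.

## Gene-panel analysis

Counts emulate a targeted nCounter-style panel: negative binomial with
`Var = m + φm²` (default φ = 0.05, i.e. ~22% biological CV), log-normal
per-sample size factors (CV 0.15), baseline means of 1500 (endogenous),
8000 (the five reference genes B2M, EEF1A1, GAPDH, RNPS1, SRP14) and
20000 (TNNT2), and group fold changes patterned on the study's 59-gene
myocardial panel. φ = 0 degenerates to deterministic rounded means, which
the tests use as an exactness anchor.

Normalization is two-stage: each sample is divided by the geometric mean
of its housekeeping counts (rescaled by the global mean of those factors
to stay count-like — the nCounter convention; arithmetic mean available),
then by its normalized TNNT2 value, expressing every gene relative to
cardiac content. Optional background subtraction of user-flagged
negative-control genes is off by default — synthetic data needs none.
Differential expression uses the equal-variance Student t (Welch via
config) with raw p-values primary and Benjamini–Hochberg q-values
alongside. Isoform maturation ratios report both mean-of-per-sample-
ratios (primary) and ratio-of-group-means, because the two diverge
whenever per-sample levels vary and published ratios do not always state
their convention.

PCA is a singular value decomposition of the column-centered (optionally
autoscaled) samples×genes matrix. PLSR is the classic NIPALS PLS2 on
autoscaled blocks: per component, iterate `w ∝ Xᵀu`, `t = Xw`,
`q ∝ Yᵀt`, `u = Yq` to a relative score tolerance of 1e-10 (max 500
iterations), then deflate both blocks by the X-score; the first weight
vector equals the dominant left singular vector of XᵀY, which the tests
exploit as an independent oracle. Correlation loadings are Pearson
correlations of each scaled variable with each score. Predictability is
the leave-one-out cross-validated R² of predicted vs reference Y (the
validation scheme is a package choice; autoscaling is refit within every
fold). Default 2 components — the plotted plane of a correlation-loading
biplot.

## Orchestration and study simulation

`pipeline.run_study` executes mechanics → twitch → rhythm → capture → FFR
per recording, orientation/particle quantification per image, and the
panel chain per count table, then forms day-matched control-normalized
group comparisons (equal-variance t, α = 0.05). All exclusions (no
detectable twitches, too few beats, no 0.25 Hz capture) carry
machine-readable reason codes in the logs and outputs. All randomness
descends from the single study seed; re-running with the same seed
reproduces `summary.json` bit-for-bit.

The default simulated study uses 2 groups (control DF 10 µN; treated
2.1-fold higher), a mild +5%/day maturation trend, a 40% linear DF
decline from 0.25 to 1.0 Hz, and a 30% chance per high-frequency
recording that a control tissue drops to 2:1 capture — qualitative
patterns chosen to exercise every pipeline branch, not quantitative
claims about any real tissue batch.

## Problem sizes and verification scope

Recovery tests run at desk scale: 30-s recordings at 100 Hz (2 kHz only
for the noise-free derivative oracle), 100–200 seeds for detection and
COV recovery, 100 replicates for FFR slope coverage, 600 for test size,
40 panels of 30 samples/group for fold recovery. These sizes put
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

* The twitch kernel has a derivative kink at onset; real force onsets are
  smoother, so real +dF/dt extraction is, if anything, easier than the
  synthetic worst case.
* Gaussian interval and amplitude models omit bigeminy, alternans and
  drift in spontaneous rate; capture failure is deterministic n:1, not
  stochastic dropout.
* The image generators emulate orientation statistics and disc-shaped
  nuclei only; no uneven illumination, debris, or overlapping cells.
* Panel counts ignore probe-level background and cross-hybridization;
  normalization assumes the housekeeping set is truly stable.
* The PLSR predictability R² is leave-one-out and will be optimistic for
  panels much wider than the sample count if components are not also
  selected within folds.
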