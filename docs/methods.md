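# Methods

This note documents the models, estimators, parameter defaults and numerical
choices behind `nucleofid`, and what the synthetic-data tests do and do not
establish about real data.

## Motion model

Chromatin loci are modeled as two-dimensional fractional Brownian motion:
per-axis increments are fractional Gaussian noise with Hurst exponent
H = α/2, scaled so the expected 2-D MSD is exactly 4·D·τ^α, with α the
anomalous exponent (dimensionless, 0 < α ≤ 2; α < 1 subdiffusive) and D the
generalized diffusion coefficient in µm²/min^α. fGn is generated by circulant
embedding: the eigenvalue-weighted FFT of complex white noise yields the
target stationary covariance in its real and imaginary parts independently,
so one transform provides both spatial axes with the exact covariance. If
the embedding is not nonnegative-definite for a given (n, H) the generator
falls back, with a warning, to a Cholesky factorization of the exact
Toeplitz covariance; α = 2 (perfectly correlated increments) is handled as a
straight line with Gaussian velocity. The increment autocovariance and the
MSD power law are verified against their closed forms at 10 000 tracks in
the test suite.

fBM is a stationary-increment, Gaussian, ergodic-in-the-weak-sense model: it
reproduces the power-law MSD and the anticorrelated steps of chromatin at
minute timescales but not active directed transport, confinement plateaus,
or heterogeneity in α.

## Condition presets

The locus probe's motion preset encodes the biology being emulated
(bulk probes always use the bulk preset):

| condition | α | D (µm²/min^α) | note |
|---|---|---|---|
| bulk, active | 0.8 | 2.5×10⁻³ | active ≈ bulk |
| repressed | 0.8 | 1.0×10⁻³ | condensed, less mobile |
| damaged-repressed | 0.8 | 2.5×10⁻³ | damage restores bulk-level mobility |
| damaged-active-late | 0.8 | 4.0×10⁻³ mean | per-track D lognormal, CV 0.6 |

The numbers are simulator inputs chosen to reproduce the orderings and the
heavy-tailed late-damage behavior, not measured values; only their ordering
and the lognormal heterogeneity (which produces the long-lag skew of the
late-damage condition) carry meaning. The lognormal choice itself is a design
decision: the emulated observation is strong per-cell variability with skew
at long lags, and a CV of 0.6 produces that without pathological outliers.

## Synthetic scene and rendering

Each "cell" is a 128×128 px field with one elliptical nucleus
(semi-axes 34×22 px, sigmoid rim of width 2 px), one locus-probe spot and
1–5 bulk-probe spots (uniform), initialized inside 0.7× the nuclear radii
with ≥ 12 px in-channel separation. Positions are kept inside the nucleus by
radial reflection at the boundary — a simplification of specular reflection
that keeps tracks in-frame for the persistence filter; it slightly perturbs
increments only in the rare frames a track reaches the rim. Defaults: pixel
size 0.1 µm/px (typical of a 63× oil objective with a modern camera; the
acquisition protocol does not fix it), frame interval 3 min (the emulated
acquisition cadence), 40 frames.

Spots are isotropic Gaussians (σ = 1.3 px, amplitude 1000 counts) on a
200-count background; the nucleus counterstain is rendered at 2000 counts
(the counterstain is realistically the brightest channel, and rotation
recovery is information-limited if it is dim). Noise is Gaussian read noise
with SD = amplitude/10 (spot SNR 10), optional Poisson shot noise. Rigid
nuclear motion composes per-frame drift and rotation about the nucleus
center; the default constant drift (0.2, −0.15) px/frame and 0.3°/frame are
modest compared with the up-to-3 px / 3° per frame regime the registration
stage is tested under. All generation is bit-reproducible under a seed
(NumPy SeedSequence spawning per cell and track).

Dosimetry helper: fluence = irradiance × duration; 15 J/m²/s for 600 s gives
9000 J/m², i.e. 9 nJ onto a ~1 µm² target.

## Registration

Translation: phase correlation with 1/50-px upsampling. Rotation: polar
resampling of both images about the reference nucleus centroid, 1-D phase
correlation along the angle axis (0.5°/sample, upsampled), restricted to
radii that carry angular structure, followed by a second-moment
principal-axis refinement (the principal axes of the central second moments
rotate exactly with the image and average the noise over every pixel).
Frames are Gaussian-smoothed (σ = 2 px) before correlation; the same blur on
both images leaves shift and angle unbiased. Every frame is registered
directly against frame 0 (no running reference, so errors do not compound),
with two translation↔rotation refinement passes — one pass left translation
residuals above tolerance at cumulative rotations of ~20°, because the
initial translation estimate is rotation-biased.

A near-elliptical nucleus leaves a half-turn rotation alias; within a stack
it is resolved by temporal continuity (the previous frame's angle as prior),
standalone by correlation-scoring both aliases with ties going to the
smaller angle. Perfectly circular content triggers an ambiguity warning and
returns 0°. Angles follow the array convention (x = column, y = row,
positive from +x toward +y); only relative angles enter the analysis.

For quantitative tracks the pipeline corrects detection *coordinates*
through the estimated transforms instead of resampling images, avoiding
interpolation noise; the two routes agree within 5% in ensemble MSD
(asserted in the test suite). Image-space alignment (`align_stack`, spline order 3) is
provided for visualization and for detectors that require aligned frames.

Measured recovery on synthetic nuclei at default noise, random-walk motion
up to 3 px and 3°/frame, 30 frames: ≤ 0.25 px and ≤ 0.5° per frame.

## Detection

Noise calibration: robust (sigma-clipped) background mean and SD, excluding
the Otsu foreground when it is genuinely bright (guarding the pure-noise
case, where an Otsu split would truncate the distribution); a user ROI can
override. Detection: difference-of-Gaussians band-pass with σ_low = σ_PSF
and σ_high = 3σ_PSF; local maxima above a low candidate gate (2 robust SDs
of the band-passed frame) are refined by an iterated Gaussian-weighted
centroid in a window of radius ⌈3σ_PSF⌉ (fixed weights, nothing is fit; a
plain top-hat centroid would have ~0.22 px noise at SNR 10, this has ~0.07).
The reported SNR is a Gaussian-weighted least-squares amplitude estimate at
the refined position divided by the background SD, and a detection is kept
iff SNR ≥ k (default k = 4). In amplitude units this is exactly
"threshold = background mean + k·SD" while referring the comparison to a
matched-filtered statistic, which is what makes recall ≥ 0.95 at spot SNR 5
and < 0.1 false positives per blank 256×256 frame simultaneously achievable
— a raw-pixel threshold cannot do both. Duplicate maxima within 2σ_PSF merge
to the brighter. For locus probes (exactly one tagged site per nucleus) a
brightest-in-nucleus mode bypasses thresholding inside the counterstain
mask.

## Linking and persistence

Frame-to-frame one-to-one assignment, greedy in ascending distance, gated at
`max_link_distance` (default 5 px): at 3-minute intervals chromatin loci
move far less than spot spacing, so greedy equals optimal matching in the
regime the experiment operates in (verified exactly on well-separated
synthetic movies). Detections are canonicalized by position within each
frame, making the output invariant to listing order. No gap closing, merging
or splitting: the full-duration persistence filter makes gap closing moot.
In the pipeline, the single-spot locus channel uses its own 8 px gate —
sized to the largest per-frame steps of the most mobile damage condition —
since with one detection per frame the gate only rejects artifacts. Only
tracks present in every frame survive; an empty survivor set is an explicit
error that downstream stages refuse.

## MSD statistics

Averaging hierarchy: time average over overlapping pairs within a track →
mean over tracks within a cell → mean over cells; SEM over cells, n = cells.
This matches ensemble averaging "from the particle tracks" with n counted in
cells: bulk probes may contribute several tracks per cell, locus probes
exactly one (then n equals the number of tracks). Averaging within the cell
first keeps cells equally weighted regardless of how many bulk tracks they
carry; this choice is deliberate and documented because the alternative
(pooling all tracks) weights cells unevenly.

Lags are reported up to ⅓ of the track length by default (estimator variance
grows steeply beyond; the cap is configurable). The outlier rule is a single
pass: mean and sample SD of MSD at the final reported lag over all candidate
curves (each candidate included), exclusion beyond 3 SDs, never iterated —
so it is order-invariant and, by construction, sample-size sensitive (an
extreme curve among 10 survives, among 21 it does not; both cases are pinned
in tests). Zero SD removes nothing.

Comparisons: two-sided pooled-variance Student's t per lag on per-cell
values, no correction across lags (each time point is reported
independently, as is conventional for MSD curves; a Bonferroni option exists
but is off by default). Zero variance in both groups with equal means is
reported as t = 0, p = 1 with a degeneracy flag. Power-law fits are ordinary
least squares on (log τ, log MSD), requiring ≥ 3 strictly positive points;
α̂ is the slope and D̂ = exp(intercept)/4.

Directionality: signed turning angles between successive displacements
(zero-length displacements skipped and counted), pooled mean resultant
length R, and a Rayleigh uniformity test (Z = nR² with the Zar finite-sample
series; cross-checked against an independent implementation, and its null
rejection rate verified at 5% over 1000 Brownian tracks).

## Pipeline and reproducibility

`run_pipeline` executes generate → register → detect (raw frames, brightest
mode for the locus channel, thresholded detection for bulk) → coordinate
correction → link → persistence → outlier screening → per-cell/ensemble MSD
→ power-law fits → per-lag comparisons, and records a JSON manifest (seed,
all stage parameters, per-stage counts, fits). A config + seed reproduces
the synthetic data bit-for-bit and the analysis deterministically.
`validate_against_truth` reports registration residuals (angle error, and
the displacement error of the estimated map at the nucleus center — the
parameterization-independent way to compare transforms whose rotation
centers differ slightly), track recall/precision, and α/D recovery. For the
heterogeneous late-damage preset, D recovery is judged against the realized
mean of the per-track draws recorded in ground truth: that is the quantity
the ensemble of those cells actually carries.

The packaged study size is 10 cells × 30 frames per condition at 128×128 px
— large enough that α recovers within ±0.1 and D within ±20% per condition,
small enough to run in about 1.5 minutes per study on one CPU. Statistical
power at this size: the repressed-vs-bulk difference (2.5×) is detected at
essentially every lag; identical presets (damaged-repressed vs bulk) show no
significant lags in the packaged runs, though with ~9 uncorrected correlated
tests an occasional false positive lag is expected by construction.

## What passing tests do and do not show

The generator shares its coordinate conventions and PSF model with the
analysis, so recovery tests validate the estimators' correctness and noise
behavior — not robustness to un-modeled properties of real movies:
non-elliptical or deforming nuclei, non-rigid intranuclear flows,
photobleaching, focus drift, aggregates and autofluorescence, z-motion
through the focal plane, or camera artifacts. 3-D motion, photobleaching
kinetics, conversion of MSD to viscoelastic moduli, and motion-model
(Kalman) tracking are out of scope.
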