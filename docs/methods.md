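# Methods

`avcortex` implements a complete analysis chain for asking whether the
"auditory" activity recorded in a visual cortical population is a sensory
signal or a behavioral one, together with a generative model of a recording
session that makes every stage testable by parameter recovery. This note
describes the model, the analysis conventions, the numerical choices, and
what the synthetic benchmark does and does not establish.

## The trial tensor and its decomposition

All trial-based analyses operate on a 5-way array `D[t, v, a, r, c]`: time
bin x video x sound x repeat x channel. Spike trains are binned at 30 ms,
smoothed with a *causal* half-Gaussian (SD 43 ms; only past samples enter
each output bin, so onset responses are never smeared backwards in time)
and z-scored per neuron over the entire continuous session (stimulus and
spontaneous epochs alike) before slicing. Behavioral channels — face
motion-energy PCs resampled by linear interpolation from the camera rate,
and nine eye channels (pupil area and x/y position baselined per trial on
the pre-onset second; signed, unsigned and global eye motion from
bin-to-bin position differences computed after linear blink interpolation;
a blink flag) — are assembled into tensors of identical layout.

The peri-stimulus window spans 4.8 s at 30 ms: 33 bins before onset and
127 after (−0.99 s to +3.81 s). Aligning onset to a bin edge is what makes
the 127-bin post-onset stretch usable as the encoding-model window; a
literal 1.00 s pre-onset margin is not an integer number of 30 ms bins.

For a complete balanced design the tensor decomposes exactly, as in
factorial ANOVA, into

    D = M + V + A + I + E

with `M[t,c]` the grand mean over videos, sounds and repeats, `V[t,v,c]`
and `A[t,a,c]` the video- and sound-related components (factor averages
relative to M), `I[t,v,a,c]` the audiovisual interaction, and `E` the
trial-to-trial residual. Each component sums to zero over its own factor,
so squared norms partition the mean-removed variance. The blank-screen and
silence conditions are ordinary factor levels; their marginal responses
are read relative to the grand average.

## Cross-validated PCA and the shuffle test

Repeats are split into halves by presentation order (1st and 3rd
presentations train, 2nd and 4th test). PCA weights `W` are computed from
the train-half component (no extra centering — marginal components are
zero-mean across stimuli by construction); the per-component *reliable*
variance is the covariance between the train- and test-half projections,

    vhat_k = 1/(n-1) * sum_j (T_jk - mean)(T_jk,test - mean_test),

with projections centered across rows, as the estimator requires. Because
the two halves carry independent noise this is an unbiased estimate of the
repeatable stimulus-related variance; noise-dominated components can come
out slightly negative and are deliberately not clipped.

A component is significant when its `vhat` strictly exceeds the 99th
percentile of a null obtained by re-permuting the joint (video, sound)
labels independently within every repeat, 1,000 times by default. The
dimensionality statistic is the length of the *leading block* of
significant components: components are ordered by explained training
variance, and because every component is tested at the 1% level, isolated
exceedances deep in the noise floor occur at the test's false-positive
rate (roughly one run in five with a few dozen channels) and are not
evidence of a signal subspace with gaps. The raw significance mask and the
count of all significant components are also reported for users who prefer
the unadorned tally. Sign convention for displayed time courses: each component is
flipped so its mean channel weight is non-negative (population sound
responses have positively biased PC1 weights, and singular-vector signs
are otherwise arbitrary). Spectra can be normalized by the summed spectrum
of one component kind or by the sum over video + sound + interaction.

## Decoding

A template-matching decoder: to decode the sound of a test trial, subtract
the train-half mean response to that trial's video, project the residual
N_t x N_c trace onto the top `N_p` sound-PC weights (N_p = 4 for sound,
30 for video in cortex-sized populations), and pick the sound whose
train-half mean projected time course is nearest in Euclidean distance on
the flattened (N_t x N_p) trace. Ties break to the lowest class index for
determinism. The same decoder runs unchanged on behavioral tensors; with
more than `N_p` behavioral channels the same 4-component projection is
applied (the choice of N_p for behavioral decoding is this package's
default, not something the procedure itself fixes). Chance level is
verified by permuting class labels (the implementation permutes the test
trials' true labels against the fixed decoder output, which draws from the
identical null at a fraction of the cost).

## Encoding models

The target `Y` is single-trial sound-plus-noise activity: `D - M - V`
restricted to the 127 post-onset bins, reshaped trial-major and projected
onto the top-4 sound PCs computed from the *full* dataset. Rows follow a
fixed trial-major layout (videos, then sounds, then repeats; time within
trial), with 12 NaN pad rows at each trial's start and end so lagged
filters never straddle trials; pad rows are excluded from fitting and
evaluation.

Three designs: **auditory** — one indicator column per (sound,
peristimulus bin), `N_a x 127` columns (1,524 at the full design), making
the fit equivalent to a train-half repeat average; **behavioral** —
sound-marginalized behavioral channels (each channel's own `D - M - V`) at
12 bin lags each (−3…+8 bins, i.e. −90…+240 ms; twelve 30 ms lags cannot
tile a −100…+200 ms span exactly, so the grid leans toward positive lead,
where behavior precedes spiking), 1,644 columns with 9 eye channels + 128
motion PCs; **full** — their concatenation (3,168 columns). Behavioral
tensors for the encoder are assembled on a window extended 8 bins past the
encoding window so every in-trial lagged value is observed.

Ridge weights are fit on the training half with the penalty chosen from a
9-point logarithmic grid (1e-3…1e5) by 3-fold cross-validation over
contiguous blocks of training trials; predictors and targets are not
re-standardized (channels are already z-scored, and Y is mean-removed by
construction, so no intercept is fit). Trial-average accuracy is the
Pearson correlation between per-sound test-half averages of data and
prediction, pooled over components (a per-component variant is available);
trial-to-trial ("noise") accuracy correlates the residuals after removing
per-sound test means from both. A prediction constant across repeats of a
sound — the auditory model — has identically zero residual, so its noise
correlation is undefined and reported as missing; this is the structural
reason a stimulus-only model cannot explain trial-to-trial fluctuations.
Halves are then swapped and correlations averaged through Fisher's z.
Pixel maps of behavioral weights are the weighted sum of the per-motion-PC
spatial masks using the lag-0 motion weights.

## Movement subspace, overlap, and timing

On the stimulus-free epoch, binned at the camera frame rate, reduced-rank
regression predicts the z-scored population matrix from lagged motion PCs
(21 lags, −10…+10 frames; 128 x 21 = 2,688 columns). The estimator is the
classical one: OLS solution, SVD of the fitted values, truncation to rank
r = 40 (matching the sound-subspace size; configurable); the top right
singular vectors form the orthonormal channel-space basis `C`. A
rank-deficient design is stabilized by a small recorded ridge penalty.

Overlap: project the train- and test-half sound components onto `C`, take
per-dimension test-retest covariances, and divide the sum over the first 4
movement dimensions by the sum of the first 4 sound-PC covariances. The
ratio is not clipped (noise can push it past 1). Significance is assessed
against the 95th percentile of the same ratio for random orthonormal
4-dimensional subspaces (QR of Gaussian draws; the sampling law behind
"random dimensions" is a package choice).

Timing, two ways, both on the spontaneous epoch at the camera rate:
(1) the peak lag of the normalized motion-PC1 x sound-PC1
cross-correlogram over ±2 s (positive = movement precedes); (2) the lag of
the largest-magnitude ridge weight of motion PC1 when predicting sound PC1
from the lagged motion design, with the penalty chosen by 3-fold
contiguous-block cross-validation — spike-count targets are noisy enough
that a weakly regularized solution scatters weight across collinear lags.

## The generative model

A session is defined by a schedule, a ground truth, and a seed; identical
inputs give bit-identical tables.

* **Schedule** — all `n_videos x n_sounds` pairs in one seeded random
  order, repeated `n_repeats` times in blocks (the same sequence each
  repeat); 4 s trials, 2 s inter-trial intervals; a stimulus-free epoch
  (default 600 s, comparable to the recordings being emulated) after the
  last trial. Defaults: 12 x 12 x 4 = 576 trials.
* **Latent** — each sound has a kernel built from 2–4 gamma-shaped bumps
  within ~1 s of onset (silence: zero), scaled by a per-trial lognormal
  gain (SD 0.5) to produce repeat-to-repeat variability. Between and
  during trials a spontaneous component continues: Gaussian noise low-pass
  filtered at ~2 Hz (SD 0.5) plus a smaller broadband term (~10 Hz cutoff,
  SD 0.3) — real face motion carries sharp transients, and without fast
  shared content a tens-of-milliseconds lead would be unidentifiable in
  principle. Higher generative sound rank uses several independent latents
  with their own kernels and loadings.
* **Face motion** — 128 PCs at 40 Hz: loadings on the latent decay
  exponentially from PC1, plus independent smooth noise of slowly decaying
  amplitude.
* **Neurons** — rate = lognormal baseline (median 4 spikes/s) + latent
  drive delayed by the lead time Δ = 30 ms with per-neuron Gaussian
  loadings of positive mean (0.8 ± 0.5 spikes/s per latent unit) + a
  high-rank video code (independent smooth per-(video, neuron) time
  courses, SD 3 spikes/s, blank screen zero) + smooth rate noise, rectified
  at zero. Spikes are an inhomogeneous Poisson process (piecewise-constant
  intensity on a 5 ms grid, uniform jitter within cells). Poisson rather
  than negative-binomial spiking: downstream analyses z-score everything,
  so added dispersion would only rescale channels.
* **Eye** — pupil area (slow drift + a small latent coupling), slow x/y
  position noise at 100 Hz, and rare (~0.1 Hz) 100–300 ms blink dropouts
  that corrupt the eye values and set the blink flag, exercising the
  interpolation path.

The default sound-kernel amplitude (1.0) makes sound-related variance a
small fraction of video-related variance, as in sensory cortex; with it,
sound decoding sits modestly above chance and video decoding near ceiling.
Because every sound influence reaches the neurons through the same latent
that moves the face, the generator's default world is one where "auditory"
cortical activity is behavioral — which is exactly the hypothesis the
analyses are built to detect.

What the generator does *not* emulate: raw video (motion PCs are abstract,
with optional synthetic pixel masks), non-Poisson spiking statistics,
nonlinear or adapting neural responses, eye-position-dependent visual
responses, and any true sound-specific cortical input channel. Passing the
recovery benchmarks therefore shows the estimators are correct and
well-calibrated under the model's assumptions (linear low-rank coupling,
Poisson noise), not that real recordings satisfy those assumptions.

## Problem sizes, tolerances, defaults

* Recovery benchmarks run on scaled sessions chosen to keep the whole
  suite quick at a desk: 24–40 neurons, 4–16 motion PCs, 6 x 6 or 12 x 12
  designs, 60–240 s spontaneous epochs, with the sound-kernel amplitude
  raised to 3.0 (the "high-SNR" regime) where a planted structure is
  being recovered. The full-size defaults (100 neurons, 128 motion PCs,
  600 s) are what `analysis/` drivers and the pipeline use.
* Exactness tolerances: marginalization reconstruction and zero-sum
  constraints at 1e-10; variance partition at 1e-8 (balanced-design
  orthogonality); orthonormality of PCA/RRR bases at 1e-8.
* Statistical tolerances are stated as z-bounds on seeded runs (2–3 SE),
  derandomized so the suite is reproducible.
* Degenerate inputs: zero-spike channels z-score to zeros with a warning;
  a single stimulus level makes the shuffle test vacuously non-significant;
  constant series make the cross-correlogram an error and flat weight
  profiles make the peak delay NaN with a warning; correlations of
  zero-variance matrices are reported missing, and |r| = 1 terms are
  dropped from Fisher averages.

## Known limitations

* Unbalanced designs (missing cells) are rejected rather than reweighted.
* The behavioral-decoder projection dimension and the exact lag grids
  (encoding: −3…+8 bins; RRR: symmetric ±10 frames) are package choices
  where the procedure itself fixes only counts, not placement.
* The shuffle null permutes joint (video, sound) labels per repeat; nulls
  that preserve temporal autocorrelation across trials are out of scope.
* The pipeline's stage seeding derives named sub-seeds from one master
  seed; runs are reproducible per-version but not guaranteed stable across
  numpy generations.
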