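# Methods

This note documents the models, conventions and numerical choices behind
`eegrel`, and what the surrogate-data experiments do and do not show.

## Signal model and preprocessing

Input segments are single-channel EEG amplitude series (µV) with a known
sampling rate; the default, 173.61 Hz with 23.6 s segments, matches the
public Bonn epilepsy collection whose plain-text dialect the readers
support.  23.6 s × 173.61 Hz = 4097.196; the sample count convention is
`floor(duration · fs)` = 4097 samples, which is also the length of the
real recordings.

Preprocessing band-limits each segment to 0–40 Hz with a zero-phase
(forward–backward) Butterworth filter of order 4 — the standard EEG
choice, preserving waveform morphology; the doubled effective order
gives ≥ 40 dB attenuation one octave above the cutoff.  The lower edge
defaults to a literal 0 Hz (pure low-pass); an optional 0.5 Hz high-pass
for drift is available, in which case the δ band's lower edge moves to
0.5 Hz.  Amplitude normalization divides by the segment's greatest
absolute value (per segment, not per recording session), making
max |y| = 1 exactly; it is idempotent, scale-invariant, and undefined on
an all-zero segment (an error, not a silent pass-through).  Filtering
precedes normalization.

## Short-time transform

The spectrogram uses a Gaussian window of 2.9 s — 503 samples at
173.61 Hz under the `round(window_seconds · fs)` convention — with σ =
W/6, so the window is effectively supported within ±3σ.  "40 % overlap"
is read as overlap = 0.40·W, hence hop = round(0.60·W) = 302 samples;
the alternative reading (hop = 0.40·W) is a configuration away
(`overlap_fraction=0.6`).  The DFT length is the next power of two ≥ W
(512 by default), zero-padded, one-sided, power stored as squared
magnitude.  No per-frame detrending is applied by default.  A 23.6 s
segment therefore yields T = 1 + floor((4097 − 503)/302) = 12 frames.

## Rhythm features

Bands: δ [0, 4), θ [4, 8], α [8, 13], β [14, 30] Hz.  Each band carries
`n_filt = 5` triangular filters whose apexes are linearly spaced strictly
inside the band (band divided into `n_filt + 2` equidistant points;
triangle m spans points m..m+2); responses are sampled on the DFT grid
and rescaled to unit peak.  Filter energies pass through
`log(s + ε)` with ε = 1e−10 guarding empty bands, then an orthonormal
DCT-II across the five filters of each band; the first `n_M = 5`
coefficients per rhythm are kept.  "Five cepstral coefficients" is
implemented as five per rhythm (the coefficients are tied to each of
δ, θ, α, β); a config switch reduces to coefficient 0 only.

Observation matrices stack one object (segment) per column in
rhythm-major order — δ block, then θ, α, β; within a block, coefficients
in order, frames time-ordered — a layout that round-trips losslessly and
permutes with the input objects.

## Stochastic relevance

The covariance of the stacked columns (mean-centered across objects, so
the zero-mean model assumption is realized empirically) is
eigendecomposed; when the stacked dimension exceeds the object count M
the M × M Gram matrix is used and eigenvectors are mapped back by
`v = X u / sqrt(M λ)`, exact for the nonzero spectrum.  The retained
count q is the smallest whose cumulative eigenvalue fraction reaches
`var_threshold` (default 0.95).  Relevance is the eigenvalue-weighted
loading magnitude `g = Σ_{k≤q} λ_k |v_k|`; an unweighted `Σ |v_k|`
variant stays behind a flag.  Weights γ_i are per-frame averages of the
per-rhythm slices of g; ranking is by decreasing γ with canonical band
order (δ, θ, α, β) breaking ties.  Scaling the data by c scales every
γ by c², leaving the ranking invariant.

**Reduced feature mode (default for relevance).**  The relevance stage
operates by default on one value per rhythm per frame — cepstral
coefficient 0, i.e. the overall log band energy — matching the model's
p-dimensional short-time rhythm vector.  The rationale is statistical
as well as structural: at 2.9 s windows the narrow δ/θ triangles
average only a handful of spectral degrees of freedom, so the higher
cepstral coefficients (within-band spectral shape) are dominated by
chi-square estimation noise whose log-variance is largest exactly in
the slow bands; summing that noise into the relevance masks genuine
between-object structure.  Classification always uses the full
coefficient block, where the SVM can weight dimensions itself.  The
full block remains available to the relevance stage via
`reduce_coefficients=False`.

Per-class weights fit a separate subspace per class (class-mean
centering) and divide each class's γ vector by its own maximum, so
max γ^(k) = 1 exactly and profiles are comparable across classes.

## Classification

The SVM is the textbook soft-margin maximal-margin machine with
Gaussian kernel `K(x, y) = exp(−‖x−y‖²/(2ς²))`; the quadratic program
is delegated to scikit-learn's SVC (`gamma = 1/(2ς²)`), and multi-class
problems use an explicit one-against-all wrapper (with two classes it
reduces to the plain binary machine, verified by test).  Hyperparameters
(c, ς) are tuned by a global-best particle swarm in log10 space —
defaults 30 particles, 50 iterations, inertia 0.72, cognitive = social
= 1.49, c ∈ [1e−2, 1e3], ς ∈ [1e−2, 1e2] — against validation accuracy
on an inner stratified 70/30 split of the training fold only, so test
labels never influence tuning (a leak-free reading of per-repetition
tuning).  Evaluation is 10 repetitions of stratified 70/30 hold-out;
accuracy uses overall correctness, sensitivity/specificity treat the
pathological (seizure) class as positive, collapsing to
positive-vs-rest in multi-class problems.  Undefined rates (zero
denominators) are reported as NaN with a warning rather than silently
clamped.  Feature scenarios 1–4 add rhythms in decreasing-relevance
order (δ; δ+θ; δ+θ+α; all), with an explicit ranking overridable.

## Relevance rhythm diagrams

The diamond has δ up, θ right, α down, β left.  The reference class is
summarized by per-rhythm mean and sample standard deviation (ddof = 1)
over segment-level weight vectors, with a shaded band of half-width 3σ;
segment-level vectors come from leave-one-out (default) or random-subset
refits of the per-class relevance, since a single class fit yields only
one vector — an interpretation, documented as such.  Diff signs use a
tolerance of 1e−6 to avoid spurious ± on numerically equal means and are
antisymmetric under swapping reference and compared.

## Surrogate data generator

Each segment is a sum over bands of band-limited Gaussian noise plus
broadband white noise (relative sd 0.15) and an optional 60 Hz line
sinusoid (off by default; 60 Hz because the intended noisy-environment
emulation is a 60 Hz mains region).  Two design points matter:

* **Band components are filtered last.**  White noise is first
  amplitude-modulated by a slow lognormal envelope (2nd-order low-pass
  at 0.3 Hz, log-sd = `mod_depth · share`, modulator clipped at ±1.5 sd,
  `mod_depth = 2.5`), then band-filtered with an order-8 zero-phase
  Butterworth and rescaled to its exact power share.  Filtering last
  guarantees band confinement (configured band-power shares are
  recoverable from a Welch periodogram within 15 % relative error);
  clipping keeps waxing-and-waning strong but finite, because an
  unbounded lognormal tail would collapse a segment into one broadband
  burst.
* **Modulation depth scales with band prominence.**  Dominant rhythms
  (posterior α in relaxed wakefulness; δ–θ bursting in seizures) wax and
  wane strongly within a recording, while background bands sit near the
  broadband floor.  This within-segment non-stationarity is what a
  short-time relevance analysis detects; with stationary components all
  log band energies would have nearly scale-free, equal variance and no
  class-dependent ranking could emerge.

Class presets (relative band powers @ amplitude):
normal {δ 0.8, θ 1.0, α 4.0, β 3.0} @ 50 µV (α-dominant with
appreciable wakeful β), ictal {δ 5, θ 4, α 1, β 0.4} @ 150 µV (power
concentrated below 8 Hz at roughly three-fold amplitude), interictal
{δ 2.5, θ 2, α 1.5, β 0.8} @ 80 µV.  The magnitudes are this package's
own calibration of qualitative clinical descriptions and are not fitted
to any recording.

**What the surrogates do not emulate:** 1/f background structure,
spike–wave morphology, ocular/muscle artifacts beyond additive
components, inter-subject variability, or channel topography.
Consequently, passing tests demonstrate that the pipeline's stages
behave as specified and that the relevance machinery recovers planted
spectral structure — not clinical performance on real EEG.

## Experiment sizes and numerical choices

The self-check experiments run at reduced ensemble sizes chosen to keep
estimates stable: per-class Diff-sign runs use 50 segments per class
(the reference collection has 100), the rhythm-recovery runs 40 per
class with a θ-power factor of 3.  The factor is deliberately moderate:
max-abs normalization turns any absolute band-power change into a
composition shift, and a very large factor moves the *other* bands' log
energies more than the boosted band's own, making "which band differs"
ill-posed; factors around 2–3 keep the boosted band's move dominant.
Repeated 70/30 SVM runs use a 12-particle, 20-iteration swarm — the
objective surface on well-separated classes is flat near the optimum,
so the smaller swarm is sufficient there.

Other numerics: eigenvalues are clipped at zero and components below
1e−12 of the leading eigenvalue are treated as null; identical columns
after centering raise a degenerate-covariance error; PSO velocities are
clamped to the (log) box width and positions to the box; confusion
counts are validated non-negative.  All randomness flows through
`numpy.random.default_rng` seeds (dataset seeds spawned via
`SeedSequence`), and identical spec + seed reproduces segments
bit-exactly.

## Known limitations

* Relevance attribution is variance-based; a rhythm can be
  discriminative in ways that do not increase its subspace loading
  (e.g. phase coupling), which this method will not credit.
* The max-abs normalization couples bands: raising one band's power
  lowers every other band's normalized log energy, so per-rhythm
  attributions near the margin should be read qualitatively, as the RRD
  intends.
* The 3σ RRD band relies on leave-one-out refits, which are correlated;
  the band is therefore an internal-consistency region, not a
  calibrated confidence interval.
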