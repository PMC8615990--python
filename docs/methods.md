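# Methods

`erpdecode` implements a complete time-resolved decoding analysis for
two-condition event-related potential (ERP) studies — here the conditions are
the *near* vs *far* framing distance of an environmental scene in a go/no-go
priming task — together with the synthetic data generator used to validate
every stage against known ground truth.

## The decoding model

At every sample `t` of the analysis window a two-class linear discriminant is
fitted to the single-trial channel patterns `x ∈ ℝ^d` (d = number of
channels):

    dval(x) = wᵀx + b,     class = sign(dval),

with near encoded as +1 and far as −1 (`dval = 0` is assigned to +1; this
tie-break is documented and tested but has probability zero for continuous
data). The weights are the regularized Fisher solution

    w = Σ̂⁻¹ (μ₊ − μ₋),     b = −wᵀ(μ₊ + μ₋)/2,
    Σ̂ = (1 − λ) Σ_pooled + λ ν I,

where `Σ_pooled` is the maximum-likelihood pooled within-class covariance,
`ν = tr(Σ_pooled)/d` the mean pooled variance, and `λ ∈ [0, 1]` the shrinkage
intensity. Equal class priors are assumed; the simulator produces balanced
designs. With ~10²  channels and a few hundred training trials `Σ_pooled` is
ill-conditioned or singular, so `λ` defaults to the analytic Ledoit–Wolf
estimate computed per training split on the within-class-centered trials.
`λ = 0` falls back to a pseudo-inverse.

Out-of-sample accuracy is estimated by leave-one-out cross-validation with
one fold per subject (all trials of one subject held out together; training
pools the remaining subjects' trials), or one fold per trial for
single-subject data. Accuracy is averaged across folds per time point; the
fold-wise standard error is reported alongside. Chance level is 50%.

Implementation note: the cross-validation engine precomputes per-fold scatter
matrices and squared trial norms (label-independent sufficient statistics)
and re-derives class means, pooled covariance, Ledoit–Wolf intensity and the
batched linear solve from them. This is algebraically identical to the
per-time-point reference implementation (`fit_lda`/`lda_predict`) — the test
suite asserts exact agreement — and is what makes permutation nulls with
hundreds of full CV re-runs tractable on one core.

## Permutation statistics

The empirical null is built by shuffling the condition labels across the
pooled trial set (trial-to-subject assignment, hence the fold structure,
stays fixed) and re-running the complete cross-validated decoding per
shuffle. A time point is significant when the observed accuracy exceeds both

* the 99th percentile (empirical order statistic, linear interpolation) of
  its per-time-point null, and
* an absolute chance threshold of 60%,

combined with AND; either criterion can be disabled (the type-I calibration
study disables the absolute threshold). Thresholding is pointwise — no
across-time family-wise correction is applied. Contiguous runs of
significant samples become half-open intervals `[start_ms, end_ms)`;
`min_duration_ms` defaults to 0, so isolated 4 ms blips are reported — at
p = 0.01 over ~550 time points roughly five flagged samples are expected by
chance, which is why the recovery tests treat a stray blip as a failed
replicate rather than silently filtering it. The default number of shuffles
at desk scale is 500 (the procedure supports arbitrarily many; the
calibration studies in this repository use 120–300 to keep a full run within
minutes on one core).

For a toy problem the null can be built exhaustively over all distinct label
arrangements, which the tests compare against an independent enumeration.

## Channel-space statistics

Within a significant interval, each channel is averaged per subject and
condition (first across the subject's trials of that condition, then across
the interval's samples) and the far-minus-near contrast is tested per channel
with a two-tailed paired Student t-test across subjects — the subject is the
unit of analysis. `t = mean(d)/(sd(d)/√n)`, `df = n − 1`. Channels with
`p < 0.05` are flagged; tests are uncorrected by default (an optional
Bonferroni flag exists). Identical inputs return `t = 0, p = 1`;
zero-variance differences with nonzero mean raise instead of fabricating an
infinite statistic.

Because all data are common-average referenced, any injected single-polarity
source pattern appears as a *bipolar* (zero-mean) scalp topography: the
injected sign is carried by the channels at the pattern's positive pole. The
recovery tests therefore check the sign at the best-coupled channel and the
correlation of the difference map with the referenced pattern, not the map's
spatial mean (which is zero by construction).

## Source localization (eLORETA)

The distributed inverse is the exact low-resolution electromagnetic
tomography weight iteration for fixed-orientation (scalar) sources on a
supplied lead field `K` (channels × sources):

    w_j ← sqrt( k_jᵀ (K W⁻¹ Kᵀ + αH)⁺ k_j ),   W = diag(w_j),

with `H` the common-average centering matrix and `⁺` the Moore–Penrose
pseudo-inverse, iterated until the maximum relative weight change drops below
`tol = 1e-6` (error on non-convergence). The mapping applied to centered
topographies is `W⁻¹Kᵀ(K W⁻¹Kᵀ + αH)⁺`. `α` defaults to `1e-4` times the
mean eigenvalue of `KKᵀ`. The defining property — zero localization error
for noiseless point sources — is tested exhaustively on the toy head model.
Condition differences are localized as the difference of the two estimates;
by linearity this equals localizing the difference topography, so the choice
is immaterial and signed (not power) maps are reported.

With `α = 0` and a full-column-rank lead field the inverse is exact for any
weights and the iteration converges immediately; the nontrivial weight
dynamics (and the depth-bias compensation they provide) only appear for
`α > 0` or underdetermined source spaces. Very small but nonzero `α`
(below the pseudo-inverse cutoff) can make the stopping rule stall just above
`tol`; use `α = 0` for the exact regime.

Two practical caveats, both visible in the tests: the zero-error guarantee is
a *point-source* property — the scalp projection of a sum of sources can
genuinely resemble a different single source, so multi-source condition
effects need not peak at an injected index — and on noisy grand averages the
peak becomes unstable once the per-channel noise is within an order of
magnitude of the (referenced) signal, because the smooth toy lead field has
strongly correlated columns. The end-to-end localization test therefore uses
single-source effects at a grand-average SNR where the peak is stable, while
the channel-level sign checks run at the default noise level.

## Preprocessing

* **Band-pass**: Butterworth design of the stated order (default 2) applied
  forward and backward (`sosfiltfilt`, odd-reflection padding), i.e. exactly
  zero phase with a squared (4th-order) magnitude response. Filtering is
  applied to the continuous recording before epoching to keep edge
  transients out of the analysis window.
* **Reference**: common average over all channels; no bad-channel handling.
* **Epoching**: one epoch per *go* event from −1500 to +1500 ms around
  target onset (half-open, `round((tmax−tmin)/1000·sfreq)` samples); no-go
  trials never enter the decoder. Events too close to a recording edge are
  dropped with a warning.
* **Baseline**: per-trial, per-channel mean over [−1500, −1200) ms — the
  300 ms preceding prime onset — subtracted.
* **Artifact rejection**: deterministic peak-to-peak criterion (default
  150 µV on any channel) standing in for visual inspection plus ICA-based
  artifact removal, which is out of scope; a hard error is raised if any
  subject drops below `min_epochs` (default 40) surviving trials in either
  condition.

Conventions: 0 ms = target onset; all user-facing times in ms; all windows
half-open `[start, end)`; internal indexing in samples.

## The synthetic-data generator

The generator reproduces the study design being emulated: 30 subjects, 84 go
trials per condition per subject, 128 channels at 250 Hz; each trial is
prime (700 ms) → ISI (500 ms) → target (700 ms) → ITI (2500 ms), with
one no-go trial per four go trials (8 : 32 per block) and epochs of
−1500..+1500 ms around target onset. The desk-scale analyses in the tests
and the acceptance script use 8 subjects × 40 trials × 16 channels, which
preserves every structural property at a fraction of the cost. (A full-scale
30-subject × 128-channel study holds its continuous recordings in memory at
~7 GB as float64; prefer desk-scale configs, or simulate subjects in batches,
on small machines.)

* **Head model**: sensors on a Fibonacci lattice over the upper unit
  hemisphere, sources seeded uniformly in the upper half of a 0.7-radius
  ball, gain `exp(−d²/2·spread²)` with unit column maxima. A parametric
  stand-in for an anatomical BEM head model: any injective smooth lead field
  supports the eLORETA point-source property and realistic spatial mixing.
* **Noise**: per-channel std 9 µV (a realistic single-trial EEG background
  after 1–40 Hz filtering), split by variance into spatially correlated pink
  noise (8 deep noise sources mixed through smooth Gaussian-decay patterns,
  50%), independent per-channel pink noise (30%, spectral slope −1) and
  white noise (20%). Pink noise is synthesized by rFFT spectral shaping.
* **Condition effects**: each effect adds `amplitude · pattern · Hann(t)` to
  far-condition trials only, where `pattern` is the unit-peak channel
  projection of the chosen sources, so the expected far−near difference
  equals the specification exactly and amplitude 0 makes the conditions
  exchangeable by construction. Defaults mirror the reported phenomenology:
  +5 µV on fronto-central sources at −550..−450 ms and −5 µV on posterior
  sources at 600..700 ms. The 5 µV amplitude was chosen (once, as a study
  condition) to put desk-scale peak decoding accuracy in the 0.63–0.70
  range — the regime in which a 60% chance threshold is meaningfully
  exceeded but decoding is far from perfect, as in the kind of study being emulated.
  Between-subject effect variability is a multiplicative per-subject
  scaling (Gaussian, relative SD 0.2, floored at 0.2).
* **Reaction times**: shifted lognormal per condition (near 935 ms, far
  905 ms, SD 140 ms, shift 350 ms) with a subject intercept (SD 60 ms) and a
  subject-specific near−far offset (SD 70 ms), so the across-subject paired
  t-test on ~30 subjects lands near t ≈ 2–3 rather than being driven to
  arbitrary significance by trial counts. Framing distance exists only as
  the binary near/far label.

What the generator does **not** emulate: ocular/cardiac/muscle artifacts
(rejection is exercised with injected amplitude spikes instead), volume
conduction through real anatomy, non-stationary noise, behavioral errors on
go/no-go (all go trials respond), or inter-electrode impedance effects.
Passing tests therefore demonstrate the statistical machinery — calibration
of the permutation test, recovery of injected effects, exactness of the
inverse on its own forward model — not performance on real recordings.

## Numerical choices

* Percentiles of permutation nulls use the linearly interpolated empirical
  order statistic (`numpy.percentile` default).
* The significance comparison is strict (`>`), so an observation tied with
  the threshold is not flagged.
* Shrinkage solves use `numpy.linalg.solve` with a pseudo-inverse fallback
  for singular systems.
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  per-subject streams are spawned from a root `SeedSequence`, so studies are
  bitwise reproducible for a fixed config.

## Known limitations

* Only the diagonal (train-at-t, test-at-t) accuracy curve is computed; no
  temporal generalization matrix.
* Leave-one-subject-out training pools trials across subjects rather than
  averaging per-subject decoders; with strong inter-subject variability the
  pooled covariance may be dominated by between-subject structure.
* The eLORETA implementation is scalar (fixed orientation) and desk-scale;
  it makes no claim about anatomical accuracy on real head geometry.
* The peak-to-peak rejection is a crude stand-in for component-based
  artifact removal and will not catch stereotyped low-amplitude artifacts.
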