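# Methods

## Scope and data model

The package estimates linear forward (encoding) models from continuous
stimulus features to multichannel EEG recorded in runs. A *session* is a
set of runs sharing sampling rate and channel set; all analyses operate
at a 32 Hz analysis rate, chosen to keep 0–750 ms of causal lags at 25
taps while comfortably covering the 0.5–8 Hz band where cortical speech
tracking concentrates. Time is 0-based seconds; sample *i* covers
[i/fs, (i+1)/fs).

## Preprocessing

EEG preprocessing is the standard low-frequency speech-tracking recipe:

- **Band-pass 0.5–8 Hz**, 3rd-order Butterworth. The filter is applied
  forward–backward (`sosfiltfilt`), so it is zero-phase — important
  because any filter phase lag would masquerade as neural response
  latency in the TRF — and the effective magnitude order doubles.
- **Down-sampling to 32 Hz** by polyphase anti-aliased resampling
  (`resample_poly`, `padtype="line"` so constant signals stay constant at
  the edges). Output length is `ceil(n * fs_out / fs_in)`; for
  integer-second runs at commensurate rates this is exact.
- **Re-referencing** to the mean of the two mastoid channels, which are
  then dropped.

Order of operations is not critical (a property test checks variance
agreement within 10% between orders), but the pipeline default is
band-pass → resample → re-reference.

## Acoustic features

- **Broadband envelope**: a gammatone filter bank (4th-order IIR,
  `scipy.signal.gammatone`) on 128 ERB-spaced centers from 80 Hz to
  8 kHz stands in for a gammachirp bank — the downstream band-average is
  insensitive to the chirp term. Bands are weighted by a 60-phon
  equal-loudness contour (sparse ISO-226-style table, log-frequency
  interpolated, 0 dB at 1 kHz), per-band envelopes are magnitudes of the
  analytic signal, and the band average is resampled to 32 Hz with
  anti-aliasing (tiny negative ripple clipped to keep the envelope
  nonnegative). An optional audio pre-low-pass slot (22.05 kHz cutoff)
  exists for provenance; it is a no-op at any input rate ≤ 44.1 kHz.
- **Rectified derivative** (acoustic onsets): `max(diff(env), 0)` with
  one leading zero so envelope and derivative concatenate into the
  2-dim `Env&Dv` regressor.
- **Log-Mel spectrogram**: 25 ms windows, 10 ms hop, 80 Slaney-scale
  triangular mel filters up to 8 kHz, log10 power clamped at
  `max − 8` orders of magnitude then affinely rescaled by `(x+4)/4` —
  the convention of the ASR front end this mirrors — and resampled from
  100 Hz frames to 32 Hz.

## Embedding features and the extractor contract

Deep-network activations enter through the `EmbeddingExtractor`
contract: a deterministic callable mapping an audio segment to per-layer
frame matrices at a native frame rate (e.g. 50 Hz). The package ships
stub extractors only — context-free frame statistics, a past-integrating
(box-average) extractor with a controllable integration horizon, and a
random projection of frame samples — which exercise every property the
pipeline relies on (determinism, frame-count consistency, causality,
context sensitivity) without any pretrained weights.

**Causal sliding-window extraction** steps a window forward in 1/8 s
increments; at each step the extractor sees only audio in
`[t − max_context, t]` and the frames inside the final step are kept, so
frame values never depend on future audio and context restriction is a
single parameter. Two alignment details: the restricted window start is
snapped *up* to the native frame grid (so window-local frames coincide
with the global frame grid; effective context shrinks by < 1 frame), and
frames straddling a step boundary are deferred to the next step, where
the window covers them fully. With a context-free extractor the output
is bit-identical for every context length — the invariant the context
sweep is calibrated against.

**PCA projection**: axes are fit once (scikit-learn PCA, mean-centered,
full SVD) on a held-out corpus and applied by matrix multiplication;
they are never refit on analysis data.

**Word-aligned regressors**: surprisal spikes place each word's
surprisal at the sample nearest its onset (coincident words sum);
word-stretched vectors hold a word's vector over [onset, offset) with
zeros in silence; sub-word token rows are summed into word rows.

**Ablations** (seeded per repetition): within-word shuffling permutes
frame rows inside each word's boundaries and leaves inter-word frames
fixed (the conservative null — only *within-word* order is destroyed);
lexicalization replaces each word's frames by their feature-wise mean
(idempotent); global shuffling permutes all rows. Shuffles commute with
per-frame linear maps such as PCA projection, which is tested.

## The encoder

EEG at time *t* is modeled from stimulus at *t − τ*, τ = 0…750 ms in
1/32 s steps: a stimulus impulse appears in lagged columns shifted later
in time, and samples shifted past the run start are zero-padded (on
z-scored data, zero is the mean, so padding is neutral). Runs never
share design rows.

Ridge is solved in closed form on the normal equations; inside the
cross-validation loop one eigendecomposition of X'X per rotation serves
the whole penalty grid. The split scheme generalizes the 18/1/1
rotation: test = run *i*, tuning = run *i−1* (mod *n*), train = rest,
for any *n* ≥ 3; each run serves exactly once as test and once as
tuning. Training runs are z-scored with pooled statistics; held-out runs
are z-scored within themselves (`norm_heldout="self"`, the documented
default; `"train-stats"` is available). Zero-variance columns are left
at zero with a warning. The penalty maximizes the arithmetic mean of
per-channel tuning-run correlations; ties take the smaller penalty.
A constant prediction scores r = 0 with a warning.

Accuracies are per-channel Pearson r per held-out run, Fisher-averaged
over runs (arctanh → mean → tanh, never the arithmetic mean of r);
scalp-average accuracy is the channel mean of the Fisher means.
Rotation-averaged weights are rescaled back through the train z-scoring
(`w · sd_y / sd_x`) so they estimate the physical convolution kernels —
that is what the kernel-recovery benchmark correlates against truth.

Single-lag profiles run the full nested CV independently per lag (the
whole penalty grid is reused per lag). Whether overlapping sliding
windows are recomputed or cached is irrelevant for deterministic
extractors; the implementation recomputes.

## Union models and variance partitioning

Unions are column-wise concatenations fit jointly with one penalty.
Electrode-wise unique contributions are pseudo-correlations
`sqrt(max(r_union² − r_subset², 0))` — negative partitions (possible
under overfitting) are zeroed *only* here. Pairwise shared/unique
percentages follow
`shared = 100 (r_A² + r_B² − r_U²) / r_U²`,
`unique_A = 100 r_A² / r_U² − shared` (and analogously B); the three sum
to 100 algebraically. Negative shared estimates are reported as-is with
a warning. Partitioning operates on Fisher-mean per-channel r (or the
scalp average of those), not per-run r. The layer-depth trend statistic
is each subject's Spearman ρ of scalp-average accuracy against layer
index, tested against zero with a group signed-rank test.

## Group statistics

Signed-rank tests use W⁺ with midranks, no continuity correction, and
the tie-corrected variance; the reported statistic is a signed Z
(positive when the first sample dominates) and p = tails·(1 − Φ(|Z|)).
This convention makes the all-positive case at n = 19 hit its exact
maximum Z = 95/√617.5 = 3.8230. Exact enumeration over sign patterns is
available for n ≤ 12 (and used automatically in pipeline comparisons at
small n, where the normal approximation is not valid). FDR is
Benjamini–Hochberg step-up (Benjamini–Yekutieli by flag), implemented
directly and cross-checked in tests against both statsmodels and a
brute-force step-up. Binomial tails and Spearman ρ delegate to scipy
(`binom.sf`, `spearmanr`).

## The synthetic-session generator

The generator manufactures what the real pipeline consumes, with known
ground truth. Defaults mirror a single-speaker audiobook session: 20
runs × 180 s at 32 Hz; 16 channels by default (128 supported, but 16
keeps full-pipeline tests fast without changing any estimator
property — channel count only scales embarrassingly parallel work).
All randomness flows from one session seed through named substreams
(words, latents, kernels, noise).

- **Word tables**: Poisson onsets at 3 words/s (dead-time-corrected for
  a 2-sample refractory gap so the realized rate matches), log-normal
  durations (median 0.25 s, σ = 0.5 log-units) truncated to prevent
  overlap, i.i.d. log-normal surprisals (median 3, σ = 0.6 log-units —
  the scale of natural-language negative log probabilities in nats).
- **Feature banks**: `envelope_like` is rectified < 8 Hz low-passed
  Gaussian noise (nonnegative, 2-dim); `embedding_like` is smooth
  unit-variance Gaussian latents (10-dim default); with a shared latent
  S, each dimension is √f·S + √(1−f)·unique. `spikes` reuses the
  surprisal-spike regressor.
- **Kernels**: per channel and feature, damped sinusoids
  `exp(−(τ−τ₀)/τ_d)·sin(2πf_k(τ−τ₀))`, zero before a channel-specific
  onset latency τ₀ ∈ [30, 400] ms, decay τ_d ∈ [50, 150] ms,
  oscillation 1.5–6 Hz, random sign — supported entirely on the 0–750 ms
  lag window so the estimator's lag range is complete.
- **EEG**: clean = Σ banks (features ⊛ kernels); i.i.d. Gaussian noise,
  independent across runs, scaled per channel against the realized clean
  variance so var(clean)/var(noise) = SNR exactly in the realized
  session. A perfect model then has accuracy ceiling √(SNR/(1+SNR)).

**Shared-variance design.** For a designed shared fraction f, two banks
mix a common latent as above and EEG is driven by the *sum* of both
banks through identical kernels. Then the union model is complete
(a_i + b_i reconstructs the driving signal exactly), each single bank
explains (1+f)/2 of the predictable variance, and the population shared
fraction is exactly f — so recovery can be scored against 100f without
simulation-calibrated fudge factors.

**What the generator does not emulate**: volume conduction / leadfield
mixing across channels, 1/f and oscillatory EEG background, artifacts,
non-stationarity, and correlated noise across channels. Passing recovery
tests therefore demonstrates correctness of the estimation machinery at
a known SNR, not that real-EEG effect sizes (r ≈ 0.05, two orders of
magnitude below these synthetic ceilings) would be detected; detection
power on real data is governed by run count and duration, which the
session spec mirrors.

## Benchmarks and problem sizes

`lagcoder.benchmarks` fixes the validation suites:

- **Parameter recovery**: 16 channels, 20 runs × 180 s, SNR 4, 2-dim
  envelope-like bank. Checks per-channel accuracy against the 0.894
  ceiling and kernel recovery by correlation.
- **Partition recovery**: 8 runs × 120 s, 8 channels, 5-dim banks,
  f ∈ {0.25, 0.5, 0.75} — a size at which the estimate is limited by
  sampling noise of a few percentage points, well inside the ±10-point
  scoring band.
- **Ablation logic**: 6 runs × 90 s, 6 channels, 5-dim embedding-like
  bank; EEG driven either by the raw frame sequence ("ordered") or by
  its lexicalization. Within-word shuffling must hurt the former and not
  the latter; global shuffling must hurt more than within-word.
- **Type-I calibration**: 2000 null simulations at n = 19.

These sizes are the package's own defaults for fast, stable validation;
all benchmarks accept a `SessionSpec` to run larger.

## Numerical conventions and edge cases

- Fisher averaging clips |r| at 1 − 1e-12 before arctanh.
- Ridge path: `eigh` on X'X (symmetric PSD); single fits use a
  positive-definite solve. Agreement with the closed form and with
  scikit-learn's Ridge is tested to 1e-8.
- Word sample spans use nearest-sample rounding of onsets/offsets,
  matching spike placement.
- Readers reject NaN/Inf everywhere; degenerate statistics (all-zero
  differences, zero union accuracy) raise or return flagged NaN rather
  than silently producing numbers.

## Known limitations

- No pretrained-network adapter is bundled; real embedding time-series
  enter via the array container or a user-supplied extractor satisfying
  the contract.
- Preprocessing covers filtering/resampling/re-referencing only — no
  artifact rejection, ICA or bad-channel interpolation.
- One ridge penalty per model (no banded/grouped penalties per feature
  set within a union).
- The orchestration layer's checkpointing is file-level (per-model
  results keyed on the config hash), not sub-stage.
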