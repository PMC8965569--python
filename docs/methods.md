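# Methods

This note records the models, numerical choices and known limitations of
the package, in the order data flows through it.

## Signal model and preprocessing

An epoch is a channels × samples matrix in µV with a sampling rate,
electrode labels and (subject, block, target) identity. The preprocessing
chain is per-channel mean removal, a 4th-order Butterworth band-pass
(7–80 Hz default), an IIR notch (50 Hz, quality factor 35), and
anti-aliased integer-factor decimation (zero-phase low-pass at 0.8× the
target Nyquist, then stride). All filters are applied forward–backward, so
the chain is zero-phase and window onsets stay stimulus-locked; the
effective attenuation is the squared single-pass response. The filter
family and order are package choices — standard EEG practice with an
easily testable frequency response. The chain order is filter → decimate →
window; windows are half-open `[start, start+len)` with 0-based sample
indexing.

## References and CCA

Reference matrices stack sin/cos pairs of harmonics 1..N_h (N_h = 5 by
default) with the time index starting at 1/F_s — a fixed phase convention;
correlation results are insensitive to it. CCA is solved as the
generalized eigenproblem C_ab C_bb⁻¹ C_ba w = λ C_aa w on centered inputs,
with covariances left unnormalized (K = XXᵀ); canonical correlations are
√λ. Numerical choices:

- **Ridge**: a covariance block whose smallest eigenvalue falls below
  1e−10 × (trace/dim) gets ε·(trace/dim)·I added, ε = 1e−8, with a
  warning. Heavily filtered EEG at short windows can be near-singular;
  well-conditioned inputs are solved exactly (the unit tests hold the
  solver to 1e−8 agreement with an independent whitening-SVD oracle).
- **Signs**: each weight vector is flipped so its largest-magnitude element
  is positive, making projected time courses reproducible.
- **Pairing**: the second set's weights are derived as C_bb⁻¹ C_ba w_a, so
  paired projections correlate positively at exactly the reported
  canonical correlation.
- Eigenvalue ties are broken by the solver's stable ordering; this is
  non-semantic.

## Optimized common templates

Per frequency, subject templates (trial averages, centered per channel) are
jointly projected by one channel-weight vector each, maximizing the sum of
all inter-subject correlations of the projected time courses. The
first-order conditions form one symmetric block generalized eigensystem
B w = λ D w on the stacked weights, where B holds all cross-covariance
blocks Σ_{n₁n₂} (diagonal included, so N identical templates give λ₁ = N)
and D is the block diagonal of self-covariances. Only the leading
eigenvector is kept, giving an optimized template with one row per
subject. A single Lagrange multiplier cannot enforce all N unit
self-correlation constraints simultaneously (the classic MAXVAR
relaxation), so each block is rescaled post hoc to ωₙᵀ Σ_nn ωₙ = 1; the
reported λ₁ is the raw eigenvalue. Template banks include the test
subject's own calibration data by default (`include_target_subject`), as
in a calibration-session workflow; the held-out test trial itself never
enters the bank.

## Recognition

Three per-frequency correlations are combined by the signed-square sum
ρ = Σ sign(ρᵢ)ρᵢ²: the template-projection Pearson correlation ρ₁, the
signal-vs-template canonical correlation ρ₂ and the signal-vs-reference
canonical correlation ρ₃. ρ₁ uses only the leading canonical pair — the
pair that carries the maximized correlation; the published construction
leaves the filter count open and matrices U, V would need a pooling rule,
which is exposed as an option but off by default. One subtlety is
load-bearing: u_k (fit time) and v_k (online) come from two independent
eigensolves whose signs are mutually arbitrary, so the raw PCC can come
out at −|PCC| on a correct-class trial and the signed square then inverts
a near-perfect match. The projection u_kᵀX̂_k is therefore sign-anchored to
the online canonical direction of X̂_k (the weights_b pair of CCA(X, X̂_k)),
which pairs positively with v_kᵀX by construction. This resolves the
convention without discarding information — genuine anti-correlations at
wrong frequencies survive. The spatial filter V is computed online per
test window; U is precomputed at fit time.

## Evaluation

Leave-one-block-out: per held-out block, templates and OCTs are rebuilt
from the remaining blocks only, every held-out trial is cut to the
requested window and classified, and per-subject accuracies pool all
folds. ITR uses the Wolpaw formula with T equal to the analysis window
alone — the convention that uniquely reproduces the published rate table
from its accuracy table; gaze-shift and actuation time are reported
separately by applications that need wall-clock command rates. Accuracies
at or below chance clamp the ITR to zero (the raw formula rebounds below
chance, which is not meaningful throughput); P = 1 is handled by its
limit. Summaries use the sample (n−1) standard deviation, a single value
having std 0 by convention. Paired t-tests are two-tailed with star coding
*** p<0.001, ** p<0.01, * p<0.05; identical vectors give (t=0, p=1, ns)
and a constant nonzero shift gives t = ±∞, p = 0.

## Synthetic cohorts

The generator emulates a six-target (9–14 Hz, 1 Hz steps), six-channel
occipital recording at 256 Hz, the layout of a five-subject,
six-block calibration study. Each trial is

X = g · A_n (e(t) ⊙ S_k) + E,

- **Source** S_k: harmonics h = 1..3 of f_k with amplitudes h^(−γ), γ = 1.
  Phases are stimulus-locked: one population phase per (frequency,
  harmonic), a fixed per-subject offset (sd 0.3 rad, the latency spread
  across heads), and small per-trial phase jitter (sd 0.1 rad) and
  amplitude jitter (sd 10%).
- **Onset envelope** e(t) = 1 − exp(−t/τ), τ = 0.25 s: the evoked
  oscillation builds up over a few hundred ms after flicker onset. The
  envelope is reproducible across trials, so averaged templates capture it
  while a stationary sine reference cannot — its correlation ceiling is
  ≈0.95 at 1 s windows and ≈0.999 at 5 s, which is the realistic origin of
  the template methods' short-window advantage.
- **Mixing** A_n: subject-specific channel × harmonic gains, fixed across
  blocks — the structure the optimized common template exploits (a shared
  stimulus-locked waveform observed through per-subject spatial
  projections).
- **Background** E: per-channel pink (1/f) noise plus subject-specific
  rhythms — two alpha oscillators (individual frequencies in 8–13 Hz) and
  three weaker beta oscillators (13–25 Hz), each a narrowband Gaussian
  process (0.6 Hz spectral width) with a fixed topography, random phase
  and Rayleigh-modulated amplitude per trial. Occipital alpha overlapping
  the stimulus band is the canonical false-positive source for
  reference-based CCA; because it is not stimulus-locked it averages out
  of templates, which is what separates the template methods from the
  baseline in real recordings. The rhythms are narrowband processes rather
  than pure sinusoids deliberately: a pure sinusoid at a wrong target
  frequency matches the sine reference almost perfectly at any SNR,
  whereas a realistic ~1 Hz-wide rhythm decorrelates from a pure sine over
  multi-second windows.
- **SNR**: g is set per trial so that the fundamental's mean channel power
  relative to the total realized background power in f_k ± 0.5 Hz equals
  `snr_db`. The calibration is verified spectrally on the stationary,
  rhythm-free configuration (the onset envelope spreads roughly 1 dB of
  fundamental energy outside the measurement band, and rhythms bias the
  flank-interpolated noise floor).

Everything derives from a single seed; identical configs are bit-identical.

**What the generator does not model**: biophysical forward models and
electrode geometry, eye-blink/EMG artifacts, powerline interference,
non-stationary drowsiness effects, frame-quantized stimulus timing.
Passing tests on these cohorts therefore demonstrate that the methods
exploit the intended structure (shared stimulus-locked waveforms,
subject-specific mixing, non-stimulus-locked background), not performance
on any particular recording system.

**Problem sizes.** The test-suite and reproduction runs use cohorts of 3–4
subjects × 4 blocks with 1.5–2.5 s epochs, and 20 independent cohorts for
the short-window method comparison — large enough for the orderings to be
statistically decisive under a paired bootstrap while keeping a full run
in tens of seconds.

## Known limitations

- The OCT eigensystem is solved densely; for very large montages × subject
  counts (N·N_c ≫ 10³) an iterative eigensolver would be preferable.
- The benchmark MAT reader validates the 4-D (channel, sample, target,
  block) layout and fails loudly on anything else; channel names are not
  stored in those containers and must be supplied by the caller.
- ρ₁'s multi-component pooling (sum of signed-squared PCCs over canonical
  pairs) is exposed but untuned; the default single-pair form is the one
  validated here.
- The t-tests treat per-subject accuracies as paired samples across
  methods; with very few subjects (< 4) their power is limited and the
  bootstrap comparisons in the evaluation harness are the more reliable
  summary.
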