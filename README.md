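# octcca

SSVEP frequency recognition with **optimized common templates** (OCT-CCA),
alongside standard CCA and individual-template CCA (IT-CCA) baselines, a
leave-one-block-out evaluation harness and a synthetic multi-subject SSVEP
generator.

## The problem

A steady-state visual evoked potential (SSVEP) brain–computer interface maps
which of K flickering targets a user is gazing at to a device command, by
detecting the stimulation frequency f_k (and its harmonics) in a short
multichannel EEG window X ∈ ℝ^(N_c×N_p). The workhorse detector is canonical
correlation analysis against harmonic sine–cosine references

Y_k = [sin(2π f_k n); cos(2π f_k n); …; sin(2π N_h f_k n); cos(2π N_h f_k n)],
n = 1/F_s, …, N_p/F_s,

choosing f_target = argmax_k ρ_k where ρ_k is the largest canonical
correlation between X and Y_k. Ideal references carry no real SSVEP features
(subject-specific spatial patterns, harmonic ratios, onset dynamics) and
background alpha rhythms match them spuriously, so accuracy degrades at
short windows. IT-CCA replaces Y_k with the subject's trial-averaged
template M_k; OCT-CCA goes further and pools calibration data from N
subjects.

## The method

For each frequency, subject n's trial-averaged template X̄_{n,k} is projected
by a channel-weight vector ω_n; the weights jointly maximize all
inter-subject correlations of the projected time courses under unit
self-correlation constraints, which leads to the symmetric generalized
eigensystem

Σ_{n₂=1}^N Σ_{n₁n₂} ω_{n₂} = λ Σ_{n₁n₁} ω_{n₁},   Σ_{n₁n₂} = X̄_{n₁,k} X̄_{n₂,k}ᵀ,

solved as one block eigenproblem on the stacked vector [ω_1; …; ω_N]. The
leading eigenvector yields the optimized common template X̂_k ∈ ℝ^(N×N_p)
with rows ω_nᵀ X̄_{n,k}; the leading eigenvalue λ₁ ∈ (0, N] measures
inter-subject consistency (λ₁ = N iff the templates are linearly
dependent). At recognition time three correlations are combined per
frequency:

- ρ₁ = PCC(v_kᵀX, u_kᵀX̂_k), with u_k from CCA(X̂_k, Y_k) at fit time and
  v_k from CCA(X, X̂_k) online,
- ρ₂ = max canonical correlation of (X, X̂_k),
- ρ₃ = max canonical correlation of (X, Y_k),

summed as ρ_k = Σᵢ sign(ρᵢ)ρᵢ², and classified by argmax. Throughput is
summarized by the Wolpaw information transfer rate
ITR = (60/T)·[log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))] bits/min with T the
gaze window.

## Worked example

Simulate a four-subject cohort at 0 dB narrowband SNR (six 9–14 Hz targets,
six occipital channels, 256 Hz), band-pass it and run the leave-one-block-out
sweep:

```python
from octcca import (SimConfig, generate_dataset, bandpass, EvalConfig,
                    leave_one_block_out, itr)

cfg = SimConfig(n_subjects=4, n_blocks=4, duration=2.5, snr_db=0.0, seed=1)
dataset = generate_dataset(cfg).map(lambda e: bandpass(e, 7.0, 80.0))
report = leave_one_block_out(dataset, EvalConfig(window_lengths=(1.0, 2.0)))
print(report.summary().to_string(index=False))
```

```
method  window_s  accuracy_mean  accuracy_std  itr_mean   itr_std
   CCA       1.0      41.666667      7.607258 15.814547  8.381199
   CCA       2.0      63.541667     17.137448 25.883129 16.021983
 ITCCA       1.0      46.875000      6.250000 21.765457  8.158167
 ITCCA       2.0      61.458333     11.474105 22.767391 10.578726
OCTCCA       1.0      56.250000     10.485881 36.278606 15.892189
OCTCCA       2.0      70.833333     22.308859 35.392802 24.522119
```

Per-subject accuracy (%) is the fraction of correctly decoded trials over
all held-out blocks; ITR converts it to bits/min at that window length. At
the 1 s window OCT-CCA decodes 56.3% of six-way trials versus 41.7% for
reference-only CCA — the pooled template advantage is largest exactly where
single-trial evidence is weakest. `report.ttests()` adds paired t-tests
with the usual star coding (***, **, *, ns), and

```python
itr(0.9056, 6, 2.5)   # -> 45.95 bits/min
```

reproduces the throughput of a 90.56%-accurate six-class selection every
2.5 s. A `octcca` console script wraps the same pipeline
(`simulate`, `fit`, `classify`, `evaluate`, `itr`, `report` subcommands).

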