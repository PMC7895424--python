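# seqtag

Neural frequency tagging and representational similarity analysis (RSA) for
statistical-learning experiments, with a synthetic-data generator that makes
the whole pipeline testable end to end.

## The problem

In a statistical-learning (SL) experiment, participants hear or see a
continuous stream of tokens — e.g., twelve syllables at 4 Hz hiding four
tri-syllabic words (word rate 1.33 Hz), or eight fractal images at 2.66 Hz
hiding four pairs (pair rate 1.33 Hz). Transitional probabilities (TPs) are
the only cue to the hidden units: TP = 1.0 inside a unit, ≈ 0.33 at unit
boundaries, and uniform (1/11 or 1/7) in control streams with no structure.
Multichannel recordings (e.g., intracranial EEG) made during exposure let one
ask two questions this package answers:

1. **Which channels entrain to the learned units?** Frequency tagging: if a
   channel segments the stream into words, its activity acquires a 1.33-Hz
   rhythm even though nothing in the stimulus is physically periodic at that
   rate.
2. **What do the responses represent?** RSA over token-evoked spatial
   patterns: do tokens group by TP (unpredictable vs predictable), by ordinal
   position within a unit, or by the identity of the unit they belong to?

## Methods at the core

- **Phase coherence.** Recordings are cut into 10-unit segments (7.5 s; five
  540-syllable blocks give 90 trials) and Fourier transformed. At frequency
  bin *k* with trial phases φᵢ, the tagging statistic is the resultant length
  R = √[(Σᵢ cos φᵢ)² + (Σᵢ sin φᵢ)²], with phase-locking value R/N ∈ [0, 1].
  Significance at the unit and token rates is assessed against surrogates
  that circularly time-shift every trial by an independent uniform offset,
  p = (1 + #{R_surr ≥ R_obs}) / (1 + n_surr), followed by Benjamini–Hochberg
  FDR across channels within subject. Channels are classified *unit-only*
  (significant at 1.33 Hz alone), *unit+token* (both rates), or
  nonresponsive; a cumulative Rayleigh-test analysis estimates how early in
  exposure each channel's unit response emerged.
- **Cross-validated RDMs.** Token-evoked patterns (epoch samples × channels)
  are baseline-corrected, centered on the grand mean, and spatially whitened
  by the inverse square root of a Ledoit–Wolf shrinkage noise covariance.
  The dissimilarity between tokens a and b is the fivefold cross-validated
  correlation distance d(a,b) = 1 − ½[corr(train_a, val_b) +
  corr(train_b, val_a)], which is unbiased by shared noise. RDMs are embedded
  in 2-D by classical (Torgerson) scaling and compared to binary model RDMs
  for the tp / ordinal / identity coding schemes.
- **Resampled category contrasts.** Channels are resampled with replacement
  200 times; per resample, token-mean patterns are correlated pairwise and
  Fisher-transformed. Each token-pair cell's similarity, averaged over
  resamples, enters a two-sided Wilcoxon rank-sum test of within-category vs
  between-category cells; a Friedman test compares the effect across
  electrode sets (unit-only, unit+token, hippocampus).
- **Behavior.** A one-back cover task (detect inserted token repetitions) is
  scored with d′ using a 250–1500 ms response window and 1/(2N) rate
  correction; reaction times are compared across conditions with a paired
  Wilcoxon signed-rank test, and 2AFC recognition against 50% chance.

The synthetic-data module generates streams with exactly these TP structures,
recordings with 1/f noise plus onset-locked entrainment (with a logistic
learning ramp) and scheme-coded spatial patterns, and simulated keypresses —
so every stage has ground truth to recover.

## Worked example

```python
from seqtag.pipeline import RunConfig, run_experiment

config = RunConfig(n_blocks=1, surrogates=200, resamples=50, seed=1,
                   n_unit_plus_token=5, n_unit_only=5,
                   n_hippocampus=4, n_noise=4, out_dir="example_run")
manifest = run_experiment(config)
```

This simulates one 135-s structured and one random block over an 18-channel
synthetic electrode population and prints (via the manifest) the
channel-class counts:

```
structured: {"unit_plus_token": 5, "unit_only": 4, "nonresponsive": 9}
random:     {"nonresponsive": 18}
```

All five simulated early-sensory channels are recovered as unit+token and
4 of 5 higher-order channels as unit-only (one missed at this short, single-
block exposure); the random stream yields no unit-rate channels, the key
structured/random dissociation. The contrast table shows the coding
dissociation across electrode sets (diff = mean within-category minus
between-category Fisher-z similarity):

```
 electrode set    scheme    diff      p
 unit_plus_token  tp        +1.063  2.2e-04
 unit_plus_token  ordinal   +0.717  2.3e-05
 unit_plus_token  identity  +0.085  0.43
 unit_only        tp        +1.129  2.7e-04
 unit_only        ordinal   +1.568  5.0e-10
 unit_only        identity  -0.012  0.96
 hippocampus      tp        -0.173  0.22
 hippocampus      ordinal   -0.224  0.11
 hippocampus      identity  +0.945  3.5e-07
```

Each set's injected geometry (tp, ordinal, identity respectively) produces
its largest and most significant contrast; identity coding appears only in
the hippocampal set. (The tp and ordinal contrasts share token-pair cells by
construction, so each partially reflects the other's geometry; see
`docs/methods.md`.) Simulated behavior shows the reaction-time facilitation
in the structured stream (733 ms vs 1019 ms mean RT on probe hits).

A command-line interface mirrors the library:
`seqtag generate | preprocess | nft | rsa | behavior | run | fixtures`.

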