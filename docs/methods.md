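# Methods

This note documents the models, parameters and numerical choices behind
`seqtag`, what the synthetic-data generator does and does not emulate, and
the known limitations of the statistical procedures it implements.

## Stimulus streams

Structured streams concatenate hidden units (four tri-syllabic "words" over a
12-syllable alphabet, SOA 250 ms; or four fractal "pairs" over an 8-image
alphabet, SOA 375 ms). Units are drawn uniformly with **no immediate unit
repetition** and balanced counts per block (±1). The no-repetition rule is
what makes the empirical between-unit TP equal 1/(n_units − 1) = 1/3; with
repetition allowed it would be 1/4. Within-unit token order is fixed, so
within-unit TPs are exactly 1. Random streams draw each successor uniformly
from the alphabet excluding the current token, giving TP = 1/(A−1) — 1/11
for syllables, 1/7 for fractals — with balanced counts per block.

Both stream types default to five blocks of 540 (auditory) or 360 (visual)
tokens, i.e. 135 s per block, with a 1.5-s on/off ramp. One-back probes
(default 16 per block) are inserted as immediate repetitions at uniformly
chosen positions, with a minimum gap of 3 tokens between probes and none
within the ramp windows — probes at the very edge would be cued by the
amplitude ramp, and piled-up probes would make greedy response assignment
ambiguous. Probe insertion preserves the order and unit parse of all
non-probe tokens; onsets stay on the SOA grid.

The generator draws every random quantity from one seeded
`numpy.random.Generator` per call; identical seeds give bit-identical
outputs.

## Synthetic recordings

Each channel is the sum of:

- **1/f noise**, unit RMS (spectral exponent 1.0 by default). Sampling rate
  is 250 Hz, matching the rate at which such recordings are analyzed, so
  tests skip resampling.
- **A token-evoked response**: a one-cycle raised cosine spanning one SOA at
  each token onset, scaled per channel and token by pattern weights (below).
- **A token-rate sinusoid** (4 or 2.66 Hz) for channels whose
  `ground_truth_class` includes token tracking. Tokens stay on the SOA grid
  even with probes inserted, so a global sinusoid is exactly token-locked.
- **A unit-rate oscillation** for unit-tracking channels in the structured
  condition only: one cosine cycle per unit, phase-locked to each unit's
  actual onset. Locking to onsets rather than to global time matters twice
  over — probe insertions shift the unit rhythm within a block, and block
  start times are not integer periods of 1.33 Hz. Its amplitude follows a
  logistic learning curve in the number of unit exposures (midpoint 45
  exposures, scale 15 by default), emulating entrainment that emerges over
  the first block of exposure.

Default component amplitudes are 0.5× the noise RMS. At the 1.33-Hz analysis
bin of a 7.5-s segment this corresponds to a spectral amplitude ≈ 2.9× the
noise magnitude in that bin, which the surrogate test detects in ≥ 90% of
channels with 18 trials (one block) at 200 surrogates; that is the
documented detection threshold the acceptance checks use.

**Pattern weights.** Channels with a `ground_truth_scheme` share category
centroids in channel space: one centroid per ordinal position (`ordinal`),
per unit (`identity`), or for the low-TP (unit-initial) tokens (`tp`). Each
token adds a fixed scatter (0.3 by default) to its centroid. Two deliberate
choices:

- Under `tp`, the high-TP tokens are *dispersed* (each its own direction,
  norm-matched) rather than clustered. TP coding in the within/between
  contrast sense is the low-TP tokens grouping more tightly than the high-TP
  tokens; giving both categories tight clusters would make the ordinal
  contrast dominate.
- Weights are centered across the token alphabet per channel, so carrying a
  token-discriminating pattern does not by itself create a consistent
  token-rate evoked response; rate tracking is controlled independently by
  `ground_truth_class`. (An ordinal pattern still produces a genuine
  unit-rate component, since position-coded responses repeat every unit —
  which is realistic.)
- In the random condition every token gets an independent stable direction:
  tokens remain perceptually discriminable, but no category structure exists
  to be learned.

**What the generator does not emulate:** realistic ECoG biophysics, line
noise, epileptiform or movement artifacts, inter-subject variability in
electrode coverage, volume conduction between channels (noise is independent
across channels; only the *signal* components are spatially structured), or
rendered audio/images. Passing tests therefore demonstrate that the analysis
recovers the statistical structure it targets under idealized noise, not
that it is robust to every artifact of clinical recordings.

## Frequency tagging

Segments are 10 units (7.5 s, 1875 samples at 250 Hz; frequency resolution
2/15 ≈ 0.133 Hz). In the structured condition each segment starts at the
onset of every 10th unit of a block, so the 1.33-Hz bin is exactly periodic
in the segment even when probes shift later units; random streams are tiled
contiguously from each block start. Five 540-syllable blocks give 90 trials.

The surrogate null circularly shifts every trial by an independent uniform
offset. This is computed in the frequency domain — a shift of *s* samples
rotates the bin-*k* phase by −2πks/N, an exact DFT identity verified against
literal roll-and-FFT in the tests — so 1000 surrogates over hundreds of
channels cost a single matrix product per frequency. The add-one p-value
rule (1 + exceedances)/(1 + n) keeps p > 0, with minimum 1/1001 at 1000
surrogates. BH-FDR is applied across channels within subject, per frequency
of interest; applying it per frequency (rather than jointly) matches the
two-stage electrode-selection logic (select at the unit rate, subtype by the
token rate).

Latency analysis applies the Rayleigh test to the first k = 2..N trial
phases, with BH correction across the tested channels at each k and no
correction across k. Because the cumulative tests are strongly dependent, a
null channel has a ≈ 4% chance of ever crossing the threshold in an all-null
channel set, but the false-latency rate grows when the tested set mixes null
channels with strongly significant ones (they shrink the BH threshold's
denominator harmlessly but rank the null channel lower). The analysis is
therefore intended, and tested, for channel sets already restricted to
responsive channels.

ROI enrichment reports responsive proportions per ROI and pairwise odds
ratios with the Haldane–Anscombe 0.5 correction when a 2×2 cell is zero.
The spatial grouping statistic is a beta-binomial Bayes factor: with x of n
channels whose nearest neighbor shares their type, BF₁₀ compares
P(same) > p₀ (uniform prior on (p₀, 1]) against P(same) = p₀, where p₀ is
the same-type probability implied by the label proportions; natural-log
BF₁₀ is reported.

## High-gamma envelope

Eight constant-Q Morlet kernels (7 cycles) at geometrically spaced centers
70–150 Hz (70.0, 77.9, 86.8, 96.7, 107.7, 120.0, 133.7, 148.9 Hz — the exact
centers are logged in the output metadata); band signals are averaged
*before* the analytic-signal magnitude, and signals are reflect-padded by
one kernel length so filter edges do not wrap. Note 150 Hz requires an input
rate above 300 Hz: the envelope must be extracted from the raw-rate signal
(e.g., 512 Hz) before any downsampling to 250 Hz, and the function refuses
rates that cannot resolve the top band.

## RSA

Epochs span one SOA from token onset, half-open — floor(0.25 s × 250 Hz) =
62 samples per channel — since no response window is canonical and one SOA
captures the full evoked kernel without overlapping the next token's window.
Each channel's epoch mean is subtracted (baseline correction): 1/f activity
is correlated across neighboring epochs, and tokens of the same unit are
*always* temporally adjacent, so without this step same-unit token pairs
inherit spurious similarity from shared slow noise (measured as a strong
false identity-coding bias on pure-noise recordings).

Whitening is spatial: the channel × channel noise covariance is estimated by
Ledoit–Wolf shrinkage (analytic intensity) from residuals around per-token
means pooled over epoch samples, and each trial is multiplied by its inverse
matrix square root after grand-mean (nonspecific response) subtraction.
Residuals around token means — not around the grand mean — define noise;
otherwise the token-specific signal inflates the covariance precisely along
the pattern directions and whitening suppresses the signal it should
preserve.

The cross-validated correlation distance uses stratified fivefold splits
(seeded): per fold, token means are computed separately on the train and
validation partitions and d(a,b) = 1 − ½[corr(train_a, val_b) +
corr(train_b, val_a)], averaged over folds. Symmetrization makes the RDM
exactly symmetric; the diagonal holds cross-validated self-distances and is
not interpreted. Embedding uses classical (Torgerson) scaling — eigenvectors
of the double-centered squared-distance matrix — which is PCA of the implied
configuration and reconciles "MDS" and "PCA" descriptions of the same plot.

Model RDMs are binary (0 within category, 1 between); the identity model
masks all same-position cells, which can never share a unit. Model
comparisons use Spearman correlation over unmasked upper-triangle cells with
a seeded token-relabeling permutation p (1000 permutations).

**Category contrasts.** Cell sets per scheme (triplet inventories):

- tp: within = first–first pairs (low TP); between = second–second plus
  second–third pairs (high TP). Third–third pairs are excluded by default
  and available behind `include_third_third`.
- ordinal: same-position vs cross-position pairs.
- identity: same-unit cross-position vs cross-unit cross-position pairs.

Channels are resampled with replacement 200 times; per resample, token-mean
patterns are correlated pairwise and Fisher-transformed. The test compares
the *cells* of the two sets (each cell averaged over resamples) with a
two-sided Wilcoxon rank-sum; the resampling controls for any single channel
driving the similarity. Treating the 200 resample means themselves as
rank-sum samples is not a valid alternative — they are dependent, and any
stable difference, including frozen noise, then yields vanishingly small p.
The per-resample means are kept for the Friedman test of the
within-minus-between effect across electrode sets (with Bonferroni-adjusted
pairwise follow-ups; two sets fall back to a rank-sum with a note).

**A structural caveat:** the tp and ordinal contrasts share cells — the tp
"within" set *is* ordinal's first-position within cells, and tp's "between"
set contains within-unit second–third pairs — so any geometry that produces
one contrast partially produces the other (for pair inventories the two are
fully confounded, as the two-token unit length forces). The identity
contrast is exactly balanced under any purely position-based geometry. The
recovery tests therefore require the matching scheme to be the largest and
most significant contrast, and strict nullity only for the geometrically
uncoupled combinations.

## Behavior

d′ uses hits within a 250–1500 ms post-probe window, greedy earliest-probe
response assignment, false alarms counted against all non-probe tokens, and
the 1/(2N) correction at rates of exactly 0 or 1 (the correction and the FA
denominator are conventions; both are isolated in one function). RT
comparisons use the paired two-sided Wilcoxon signed-rank Z (normal
approximation, tie-corrected; all-zero differences return Z = 0, p = 1 with
a note); d′ tests are one-sample/paired t-tests; 2AFC scores are tested
against 50% with the signed-rank test. Simulated RT means default to 733 ms
(structured) and 917 ms (random) with 150-ms SD, 10% lapse rate and a
0.005-Hz false-alarm Poisson process, a facilitation effect of the size such
streams typically produce.

## Problem sizes in the tests

The default test run and the acceptance checks use one 540-token block
(18 trials), 100–200 surrogates, 50 resamples and 16–30 channels for the
stochastic calibration and recovery suites, and the full five-block design
(90 trials) where the design arithmetic itself is under test; stream
statistics use ≥ 10,000-token streams. These sizes were chosen so each
property is measured well inside its noise floor while the whole suite stays
fast enough to run habitually.

## Known limitations

- The channel-resampling contrast tests stability across channels, not
  against a noise null; its calibration here relies on the cell-level
  comparison and the epoch baseline correction described above.
- Latency estimates are biased early at high SNR (first significant k is a
  minimum over dependent tests) and undefined for channels that never reach
  significance.
- The Bayes factor's uniform prior on (p₀, 1] is a convenience choice; with
  very small n it is sensitive to that choice.
- Whitening assumes spatially stationary noise across the session; the
  generator satisfies this by construction, real recordings only
  approximately.
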