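"""Neural frequency tagging: phase coherence with surrogate inference.

A continuous recording is reshaped into fixed-duration segments aligned to
unit onsets (10 units, 7.5 s at the 1.33-Hz unit rate) and Fourier
transformed, giving one phase per trial, channel and frequency bin.  The
tagging statistic at a bin is the resultant length of the trial phase
vectors,

    R = sqrt[(sum_N cos phi)^2 + (sum_N sin phi)^2],

whose normalization R/N is the phase-locking value.  Significance at the
frequencies of interest is assessed against surrogate datasets in which every
trial is circularly time-shifted by an independent uniform offset, followed by
Benjamini-Hochberg FDR correction across channels within subject.  Channels
are then classified by which rates they track, and a cumulative Rayleigh-test
analysis estimates how early in exposure each channel's unit-rate response
became significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.special import betaln, betainc
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .recording import ChannelInfo, NeuralRecording
from .streams import TokenStream

__all__ = [
    "TrialTensor",
    "CoherenceResult",
    "ChannelClassification",
    "LatencyResult",
    "CoherenceTagger",
    "segment_trials",
    "phase_at_frequency",
    "coherence_spectrum",
    "surrogate_test",
    "fdr_correct",
    "classify_channels",
    "latency_analysis",
    "roi_enrichment",
    "spatial_grouping_bayes",
]

UNIT_RATE_HZ = 4.0 / 3.0


@dataclass
class TrialTensor:
    """Segmented data: ``values`` is trials x samples-per-segment x channels."""

    values: np.ndarray
    rate_hz: float
    segment_units: int
    segment_duration_s: float
    condition: str
    field_type: str
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x samples x channels")
        expected = int(round(self.segment_duration_s * self.rate_hz))
        if self.values.shape[1] != expected:
            raise ValueError(
                f"samples per segment {self.values.shape[1]} != "
                f"segment_duration_s * rate_hz = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    @property
    def freq_resolution_hz(self) -> float:
        return 1.0 / self.segment_duration_s

    def freqs_hz(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_samples, d=1.0 / self.rate_hz)

    def subset_trials(self, k: int) -> "TrialTensor":
        return TrialTensor(
            values=self.values[:k],
            rate_hz=self.rate_hz,
            segment_units=self.segment_units,
            segment_duration_s=self.segment_duration_s,
            condition=self.condition,
            field_type=self.field_type,
            channels=self.channels,
        )


@dataclass
class CoherenceResult:
    """Per channel x frequency coherence with surrogate/FDR inference.

    ``R`` and ``plv`` span all FFT bins; p-values are computed only at
    ``tested_freqs_hz`` (columns of ``p_raw``/``p_fdr``/``significant``).
    """

    freqs_hz: np.ndarray
    R: np.ndarray
    plv: np.ndarray
    n_trials: int
    channels: list[ChannelInfo]
    condition: str = ""
    field_type: str = "fp"
    tested_freqs_hz: np.ndarray | None = None
    p_raw: np.ndarray | None = None
    p_fdr: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float | None = None

    def freq_index(self, f_hz: float) -> int:
        if self.tested_freqs_hz is None:
            raise ValueError("no tested frequencies recorded")
        hits = np.flatnonzero(np.isclose(self.tested_freqs_hz, f_hz, atol=1e-6))
        if len(hits) != 1:
            raise KeyError(f"frequency {f_hz} Hz was not tested")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table at the tested frequencies."""
        rows = []
        for ci, ch in enumerate(self.channels):
            for fi, f in enumerate(self.tested_freqs_hz):
                bin_idx = int(np.argmin(np.abs(self.freqs_hz - f)))
                rows.append(
                    {
                        "channel": ch.id,
                        "subject": ch.subject,
                        "freq_hz": f,
                        "R": self.R[ci, bin_idx],
                        "plv": self.plv[ci, bin_idx],
                        "p_raw": None if self.p_raw is None else self.p_raw[ci, fi],
                        "p_fdr": None if self.p_fdr is None else self.p_fdr[ci, fi],
                        "significant": (
                            None if self.significant is None else bool(self.significant[ci, fi])
                        ),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ChannelClassification:
    """Channel classes from unit- and token-rate significance flags."""

    channels: list[ChannelInfo]
    classes: list[str]  # nonresponsive | unit_only | unit_plus_token
    token_only: np.ndarray  # channels significant at the token rate alone
    unit_hz: float
    token_hz: float
    field_type: str = "fp"

    def responsive_ids(self, klass: str | None = None) -> list[str]:
        return [
            ch.id
            for ch, c in zip(self.channels, self.classes)
            if (c != "nonresponsive" if klass is None else c == klass)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": [ch.id for ch in self.channels],
                "subject": [ch.subject for ch in self.channels],
                "roi": [ch.roi for ch in self.channels],
                "class": self.classes,
                "token_only": self.token_only.astype(bool),
            }
        )


@dataclass
class LatencyResult:
    """Earliest cumulative-trial count at which each channel is significant."""

    channels: list[ChannelInfo]
    first_significant_trial: np.ndarray  # -1 where never significant
    p_trajectory: np.ndarray  # channels x (n_trials - 1), for k = 2..N
    ks: np.ndarray
    f_hz: float
    alpha: float


def segment_trials(
    recording: NeuralRecording,
    stream: TokenStream,
    segment_units: int = 10,
) -> TrialTensor:
    """Reshape a continuous recording into fixed-duration unit-aligned segments.

    Segments of ``segment_units`` x unit-duration seconds (7.5 s for 10 units
    at 1.33 Hz) are aligned to unit onsets: in the structured condition each
    segment starts at the onset of every ``segment_units``-th unit of a block,
    so the unit rhythm is exactly periodic in the segment even when probe
    insertions shift later units.  Random streams have no unit parse and are
    tiled contiguously from each block start.  A trailing partial segment is
    dropped; five blocks of 540 syllables give 90 ten-word trials.
    """
    unit_len = stream.inventory.unit_length if stream.inventory else None
    if unit_len is None:
        unit_len = 3 if stream.modality == "auditory" else 2
    unit_dur = unit_len * stream.soa_s
    seg_dur = segment_units * unit_dur
    seg_samples = int(round(seg_dur * recording.rate_hz))

    starts_t: list[float] = []
    if stream.condition == "structured" and stream.inventory is not None:
        mask = (stream.position_of == 1) & ~stream.is_probe
        for b in range(stream.n_blocks):
            onsets = stream.onsets_s[mask & (stream.block_of == b)]
            n_units = len(onsets)
            for j in range(0, (n_units // segment_units) * segment_units, segment_units):
                starts_t.append(float(onsets[j]))
    else:
        bounds_t = [stream.onsets_s[i] for i in stream.block_boundaries] + [
            stream.duration_s
        ]
        for b in range(stream.n_blocks):
            t0, t1 = bounds_t[b], bounds_t[b + 1]
            n_seg = int((t1 - t0) // seg_dur)
            starts_t.extend(t0 + j * seg_dur for j in range(n_seg))

    segments = []
    for t0 in starts_t:
        a = int(round(t0 * recording.rate_hz))
        if a + seg_samples <= recording.n_samples:
            segments.append(recording.data[:, a : a + seg_samples].T)
    if not segments:
        raise ValueError(
            f"stream too short: no complete {seg_dur:.3g}-s segment fits in any block"
        )
    return TrialTensor(
        values=np.stack(segments, axis=0),
        rate_hz=recording.rate_hz,
        segment_units=segment_units,
        segment_duration_s=seg_dur,
        condition=stream.condition,
        field_type=recording.field_type,
        channels=recording.channels,
    )


def _bin_index(trials: TrialTensor, f_hz: float, tol: float = 1e-6) -> int:
    k = f_hz * trials.segment_duration_s
    k_int = int(round(k))
    if abs(k - k_int) > tol * trials.segment_duration_s or not (
        0 <= k_int <= trials.n_samples // 2
    ):
        df = trials.freq_resolution_hz
        lo, hi = np.floor(k) * df, np.ceil(k) * df
        raise ValueError(
            f"{f_hz} Hz is not an FFT bin center; nearest bins are "
            f"{lo:.6g} Hz and {hi:.6g} Hz (resolution {df:.6g} Hz)"
        )
    return k_int


def phase_at_frequency(trials: TrialTensor, f_hz: float) -> np.ndarray:
    """Phase angle of the DFT coefficient at ``f_hz`` per trial and channel.

    Uses the cosine convention: a cosine at the bin frequency has phase 0.
    """
    k = _bin_index(trials, f_hz)
    spec = np.fft.rfft(trials.values, axis=1)
    return np.angle(spec[:, k, :])


def coherence_spectrum(trials: TrialTensor) -> CoherenceResult:
    """Resultant length R and phase-locking value R/N at every FFT bin."""
    if trials.n_trials < 2:
        raise ValueError("coherence needs at least 2 trials")
    spec = np.fft.rfft(trials.values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = spec / np.abs(spec)
    unit = np.nan_to_num(unit)
    resultant = np.abs(unit.sum(axis=0))  # bins x channels
    return CoherenceResult(
        freqs_hz=trials.freqs_hz(),
        R=resultant.T,
        plv=resultant.T / trials.n_trials,
        n_trials=trials.n_trials,
        channels=trials.channels,
        condition=trials.condition,
        field_type=trials.field_type,
    )


def surrogate_test(
    trials: TrialTensor,
    freqs: list[float] | tuple[float, ...] = (UNIT_RATE_HZ, 4.0),
    n_surrogates: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CoherenceResult:
    """Surrogate p-values for the coherence at the frequencies of interest.

    Each surrogate circularly time-shifts every trial by an independent
    uniform integer offset before phase extraction.  In the frequency domain a
    shift of s samples rotates the phase at bin k by -2*pi*k*s/N, so surrogate
    resultants are computed from the observed phases directly (exact DFT
    identity).  p = (1 + #{surrogate R >= observed R}) / (1 + n_surrogates),
    so p is never zero; with 1000 surrogates the minimum is 1/1001.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    result = coherence_spectrum(trials)
    n_samp = trials.n_samples
    p_raw = np.empty((trials.n_channels, len(freqs)))
    for fi, f in enumerate(freqs):
        k = _bin_index(trials, f)
        phases = phase_at_frequency(trials, f)  # trials x channels
        vectors = np.exp(1j * phases)
        observed = np.abs(vectors.sum(axis=0))
        shifts = rng.integers(0, n_samp, size=(n_surrogates, trials.n_trials))
        rotations = np.exp(-2j * np.pi * k * shifts / n_samp)
        surrogate_R = np.abs(rotations @ vectors)  # n_surrogates x channels
        exceed = (surrogate_R >= observed[None, :]).sum(axis=0)
        p_raw[:, fi] = (1.0 + exceed) / (1.0 + n_surrogates)
    result.tested_freqs_hz = np.asarray(freqs, dtype=float)
    result.p_raw = p_raw
    return result


def fdr_correct(
    p_raw: np.ndarray, alpha: float = 0.05, subjects: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment, applied within subject.

    Returns (adjusted p, flags).  Columns (frequencies) are corrected
    independently; the correction pools channels of the same subject.
    """
    p_in = np.asarray(p_raw, dtype=float)
    squeeze = p_in.ndim == 1
    p = p_in.reshape(-1, 1) if squeeze else p_in
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if subjects is None:
        subjects = ["all"] * p.shape[0]
    subjects = np.asarray(subjects)
    adj = np.empty_like(p)
    flags = np.zeros(p.shape, dtype=bool)
    for subj in np.unique(subjects):
        rows = subjects == subj
        for col in range(p.shape[1]):
            rej, p_adj, _, _ = multipletests(
                p[rows, col], alpha=alpha, method="fdr_bh"
            )
            adj[rows, col] = p_adj
            flags[rows, col] = rej
    if squeeze:
        return adj[:, 0], flags[:, 0]
    return adj, flags


def apply_fdr(result: CoherenceResult, alpha: float = 0.05) -> CoherenceResult:
    """Fill ``p_fdr``/``significant`` on a surrogate-tested result in place."""
    if result.p_raw is None:
        raise ValueError("run surrogate_test first")
    subjects = [ch.subject for ch in result.channels]
    result.p_fdr, result.significant = fdr_correct(result.p_raw, alpha, subjects)
    result.alpha = alpha
    return result


def classify_channels(
    coh: CoherenceResult,
    unit_hz: float = UNIT_RATE_HZ,
    token_hz: float = 4.0,
) -> ChannelClassification:
    """Classify channels by which presentation rates they track.

    ``unit_only`` channels are significant at the unit (word/pair) rate alone;
    ``unit_plus_token`` at both rates.  Channels significant only at the token
    rate are 'nonresponsive' for unit-level analyses but flagged
    ``token_only``.
    """
    if coh.significant is None:
        raise ValueError("classification requires FDR flags; run apply_fdr first")
    ui, ti = coh.freq_index(unit_hz), coh.freq_index(token_hz)
    sig_unit = coh.significant[:, ui]
    sig_token = coh.significant[:, ti]
    classes = []
    for u, t in zip(sig_unit, sig_token):
        if u and t:
            classes.append("unit_plus_token")
        elif u:
            classes.append("unit_only")
        else:
            classes.append("nonresponsive")
    return ChannelClassification(
        channels=coh.channels,
        classes=classes,
        token_only=np.asarray(sig_token & ~sig_unit),
        unit_hz=unit_hz,
        token_hz=token_hz,
        field_type=coh.field_type,
    )


def latency_analysis(
    trials: TrialTensor,
    f_hz: float = UNIT_RATE_HZ,
    alpha: float = 0.05,
) -> LatencyResult:
    """Time-to-first-significance of the unit-rate phase response.

    For each cumulative trial count k = 2..N the Rayleigh test is applied to
    the first k trial phases of every channel and BH-FDR is applied across
    channels at that k.  The first k whose flag survives is the latency, in
    segments of ``segment_units`` units.
    """
    phases = phase_at_frequency(trials, f_hz)  # trials x channels
    n_trials, n_channels = phases.shape
    if n_trials < 2:
        raise ValueError("latency analysis needs >= 2 trials")
    ks = np.arange(2, n_trials + 1)
    p_traj = np.empty((n_channels, len(ks)))
    for ci in range(n_channels):
        for ki, k in enumerate(ks):
            _, pval = pg.circ_rayleigh(phases[:k, ci])
            p_traj[ci, ki] = pval
    first = np.full(n_channels, -1, dtype=int)
    for ki, k in enumerate(ks):
        _, flags = fdr_correct(p_traj[:, ki], alpha)
        newly = (first == -1) & flags
        first[newly] = k
    return LatencyResult(
        channels=trials.channels,
        first_significant_trial=first,
        p_trajectory=p_traj,
        ks=ks,
        f_hz=f_hz,
        alpha=alpha,
    )


def roi_enrichment(
    classification: ChannelClassification, roi_labels: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Responsive-channel proportion per ROI and pairwise odds ratios.

    The odds ratio of ROI A contributing more responsive channels than ROI B
    is (resp_A/nonresp_A)/(resp_B/nonresp_B), with the Haldane-Anscombe 0.5
    correction added to all cells of a table containing a zero.
    """
    if roi_labels is None:
        roi_labels = [ch.roi for ch in classification.channels]
    responsive = np.array([c != "nonresponsive" for c in classification.classes])
    df = pd.DataFrame({"roi": roi_labels, "responsive": responsive})
    counts = df.groupby("roi")["responsive"].agg(["sum", "count"])
    empty = counts.index[counts["count"] == 0]
    if len(empty):
        warnings.warn(f"excluding empty ROIs: {list(empty)}")
        counts = counts.drop(index=empty)
    if len(counts) < 2:
        raise ValueError("need >= 2 ROIs with at least one channel")
    props = pd.DataFrame(
        {
            "n_channels": counts["count"],
            "n_responsive": counts["sum"],
            "proportion": counts["sum"] / counts["count"],
        }
    )
    rows = []
    for a, b in combinations(props.index, 2):
        ra, na = props.loc[a, "n_responsive"], props.loc[a, "n_channels"]
        rb, nb = props.loc[b, "n_responsive"], props.loc[b, "n_channels"]
        cells = np.array([ra, na - ra, rb, nb - rb], dtype=float)
        if np.any(cells == 0):
            cells = cells + 0.5
        orat = (cells[0] / cells[1]) / (cells[2] / cells[3])
        rows.append({"roi_a": a, "roi_b": b, "odds_ratio": orat})
    return props, pd.DataFrame(rows)


def spatial_grouping_bayes(
    labels: list[str], coords: np.ndarray
) -> tuple[float, dict]:
    """Bayes factor for spatial clustering of two channel types.

    For every channel, the nearest other channel (Euclidean) is found and the
    number of same-type outcomes x of n is scored with a beta-binomial Bayes
    factor BF10 for H1: P(same) > p0 (uniform prior on (p0, 1]) against
    H0: P(same) = p0, where p0 is the same-type probability expected from the
    label proportions alone.  Returns (log BF10, details).
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    types, counts = np.unique(labels, return_counts=True)
    if len(types) != 2:
        raise ValueError(f"expected exactly 2 channel types, got {list(types)}")
    if counts.min() < 2:
        raise ValueError("each type needs >= 2 channels to define a typed neighbor")
    n = len(labels)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    nearest = d2.argmin(axis=1)
    same = labels[nearest] == labels
    x = int(same.sum())
    p0 = float(sum((c / n) * ((c - 1) / (n - 1)) for c in counts))
    # marginal likelihood under H1: uniform prior on (p0, 1]
    log_beta = betaln(x + 1, n - x + 1)
    tail = 1.0 - betainc(x + 1, n - x + 1, p0)
    if tail <= 0:
        log_m1 = -np.inf
    else:
        log_m1 = log_beta + np.log(tail) - np.log(1.0 - p0)
    log_m0 = x * np.log(p0) + (n - x) * np.log(1.0 - p0)
    log_bf10 = log_m1 - log_m0
    return float(log_bf10), {"n": n, "same_type": x, "p0": p0}


class CoherenceTagger(BaseEstimator):
    """Phase-coherence frequency tagger with surrogate + FDR inference.

    A scikit-learn style estimator: ``fit`` takes a :class:`TrialTensor`,
    computes the coherence spectrum, surrogate p-values at the frequencies of
    interest, BH-FDR flags within subject, and a per-channel classification.

    Parameters
    ----------
    freqs : tuple of float
        Frequencies of interest (unit rate first, token rate second).
    n_surrogates : int
        Number of circular-shift surrogates for the null distribution.
    alpha : float
        FDR level for the significance flags.
    random_state : int or None
        Seed for the surrogate shifts.
    """

    def __init__(
        self,
        freqs: tuple[float, float] = (UNIT_RATE_HZ, 4.0),
        n_surrogates: int = 1000,
        alpha: float = 0.05,
        random_state: int | None = 0,
    ):
        self.freqs = freqs
        self.n_surrogates = n_surrogates
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X: TrialTensor, y=None) -> "CoherenceTagger":
        result = surrogate_test(
            X,
            freqs=self.freqs,
            n_surrogates=self.n_surrogates,
            seed=self.random_state if self.random_state is not None else 0,
        )
        apply_fdr(result, alpha=self.alpha)
        self.result_ = result
        self.freqs_hz_ = result.freqs_hz
        self.R_ = result.R
        self.plv_ = result.plv
        self.p_raw_ = result.p_raw
        self.p_fdr_ = result.p_fdr
        self.significant_ = result.significant
        self.classification_ = classify_channels(
            result, unit_hz=self.freqs[0], token_hz=self.freqs[1]
        )
        return self

    def predict(self, X: TrialTensor | None = None) -> list[str]:
        """Per-channel class labels from the fitted flags."""
        if not hasattr(self, "classification_"):
            raise RuntimeError("CoherenceTagger is not fitted")
        return list(self.classification_.classes)
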