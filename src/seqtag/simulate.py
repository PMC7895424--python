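"""Synthetic neural recordings and behavioral responses.

The signal model emulates the phenomenology that the analysis stages are built
to detect, without attempting biophysical realism:

* 1/f ("pink") background noise per channel, unit RMS;
* a per-token evoked response (one-cycle raised cosine over the SOA) whose
  amplitude across channels follows cluster centroids defined by a coding
  scheme (``tp``, ``ordinal`` or ``identity``), so that spatial patterns carry
  recoverable category structure;
* a sinusoid at the token presentation rate for token-responsive channels
  (tokens stay on the SOA grid even when probes are inserted, so a global
  sinusoid is exactly token-locked);
* for unit-responsive channels in the structured condition only, an
  oscillation at the unit (word/pair) rate built as one cosine cycle per unit
  locked to each unit's actual onset — so it follows probe-induced timing
  shifts as an entrained response would — with amplitude following a logistic
  learning curve in the number of unit exposures.

Behavioral responses to one-back probes are modeled as truncated-normal
reaction times with condition-specific means, a lapse probability, and a
Poisson false-alarm process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .recording import ChannelInfo, NeuralRecording
from .streams import TokenStream

__all__ = [
    "ChannelSpec",
    "EffectParams",
    "RTParams",
    "BehavioralRecord",
    "pink_noise",
    "synthesize_recording",
    "simulate_behavior",
]

TOKEN_RATE_HZ = {"auditory": 4.0, "visual": 8.0 / 3.0}
UNIT_RATE_HZ = 4.0 / 3.0


@dataclass
class ChannelSpec(ChannelInfo):
    """Per-channel simulation config: metadata plus signal content.

    ``snr`` scales every injected signal component of this channel relative to
    the unit-RMS noise floor.  ``learn_midpoint_units``/``learn_scale_units``
    override the global logistic learning curve for the unit-rate component.
    """

    snr: float = 1.0
    learn_midpoint_units: float | None = None
    learn_scale_units: float | None = None


@dataclass
class EffectParams:
    """Global effect sizes, as amplitude ratios against unit-RMS noise."""

    token_amp: float = 0.5
    unit_amp: float = 0.5
    pattern_amp: float = 0.5
    #: within-category scatter of token centroids (0 = tokens in a category
    #: are identical, 1 = scatter comparable to between-category separation)
    pattern_scatter: float = 0.3
    #: logistic learning-curve midpoint/scale, in unit (word/pair) exposures
    learn_midpoint_units: float = 45.0
    learn_scale_units: float = 15.0
    noise_exponent: float = 1.0


@dataclass
class RTParams:
    """Reaction-time model for the one-back cover task.

    Defaults emulate the typical facilitation effect: 733 ms mean RT in the
    structured and 917 ms in the random stream.
    """

    mean_structured_s: float = 0.733
    mean_random_s: float = 0.917
    sd_s: float = 0.15
    lapse_rate: float = 0.1
    fa_rate_hz: float = 0.005

    def __post_init__(self) -> None:
        if self.mean_structured_s <= 0 or self.mean_random_s <= 0:
            raise ValueError("RT means must be positive")
        for r in (self.lapse_rate,):
            if not 0 <= r <= 1:
                raise ValueError("lapse_rate must be in [0, 1]")
        if self.fa_rate_hz < 0:
            raise ValueError("fa_rate_hz must be >= 0")


@dataclass
class BehavioralRecord:
    """Keypress timestamps from one participant in one stream."""

    response_times_s: np.ndarray
    condition: str
    participant: str = "P01"

    def __post_init__(self) -> None:
        self.response_times_s = np.sort(np.asarray(self.response_times_s, dtype=float))


def pink_noise(
    n_samples: int, rng: np.random.Generator, exponent: float = 1.0
) -> np.ndarray:
    """1/f^exponent noise with unit RMS, via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    return shaped / shaped.std()


def _raised_cosine(duration_s: float, rate_hz: float) -> np.ndarray:
    """One-cycle raised cosine kernel spanning one SOA; band-limited evoked shape."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def _scheme_categories(stream: TokenStream, scheme: str) -> dict[str, int]:
    """Map each token id to a category index under a coding scheme."""
    inv = stream.inventory
    if inv is None:
        raise ValueError("pattern schemes require a stream with a unit inventory")
    pos = inv.position_of_token()
    unit = inv.unit_of_token()
    unit_index = {u: i for i, u in enumerate(inv.unit_ids)}
    if scheme == "tp":
        # unit-initial tokens are unpredictable (low TP); the rest are high TP
        return {t: (0 if p == 1 else 1) for t, p in pos.items()}
    if scheme == "ordinal":
        return {t: p - 1 for t, p in pos.items()}
    if scheme == "identity":
        return {t: unit_index[unit[t]] for t in inv.token_alphabet}
    raise ValueError(f"unknown scheme {scheme!r}")


def _pattern_weights(
    stream: TokenStream,
    ch_indices: np.ndarray,
    scheme: str,
    params: EffectParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Across-channel evoked amplitude for each token.

    Tokens in a category share a centroid direction plus a fixed per-token
    scatter.  Two special cases: under 'tp' the high-TP category is dispersed
    (each token its own direction) because TP coding manifests as the low-TP
    tokens grouping more tightly than the high-TP tokens; in the random
    condition no category structure can be learned, so every token gets an
    independent direction regardless of scheme.

    Weights are centered across the token alphabet per channel, so carrying a
    token-discriminating pattern does not by itself constitute a consistent
    token-rate evoked response — rate tracking is controlled independently by
    ``ground_truth_class``.  (An ordinal pattern still produces a genuine
    unit-rate component, since position-coded responses repeat every unit.)
    """

    def unit_dir(n: int) -> np.ndarray:
        v = rng.standard_normal(n)
        return v / np.linalg.norm(v) * np.sqrt(n)

    n_ch = len(ch_indices)
    if stream.condition != "structured":
        weights = {
            t: unit_dir(n_ch) + params.pattern_scatter * unit_dir(n_ch)
            for t in stream.token_alphabet
        }
    else:
        cat = _scheme_categories(stream, scheme)
        n_cat = max(cat.values()) + 1
        centroids = np.stack([unit_dir(n_ch) for _ in range(n_cat)])
        weights = {}
        for token, c in cat.items():
            if scheme == "tp" and c == 1:
                # dispersed high-TP tokens, norm matched to the clustered ones
                weights[token] = unit_dir(n_ch) * np.sqrt(1 + params.pattern_scatter**2)
            else:
                weights[token] = centroids[c] + params.pattern_scatter * unit_dir(n_ch)
    mean_w = np.mean(list(weights.values()), axis=0)
    return {t: w - mean_w for t, w in weights.items()}


def synthesize_recording(
    stream: TokenStream,
    channel_spec: list[ChannelSpec],
    params: EffectParams | None = None,
    seed: int | np.random.Generator = 0,
    rate_hz: float = 250.0,
) -> NeuralRecording:
    """Simulate a multichannel recording entrained to a token stream.

    Channels with ``ground_truth_class`` containing ``token`` receive a
    token-rate sinusoid; those containing ``unit`` receive a unit-rate sinusoid
    (structured condition only) with logistic amplitude growth over unit
    exposures.  Channels with a ``ground_truth_scheme`` other than 'none'
    additionally carry evoked responses whose across-channel pattern encodes
    that scheme's category geometry.
    """
    params = params or EffectParams()
    token_rate = TOKEN_RATE_HZ[stream.modality]
    if rate_hz < 2.0 * token_rate:
        raise ValueError(
            f"rate_hz={rate_hz} is below the Nyquist rate for the "
            f"{token_rate:.3g}-Hz token rate"
        )
    rng = np.random.default_rng(seed)
    n_samples = int(round(stream.duration_s * rate_hz))
    t = np.arange(n_samples) / rate_hz
    data = np.empty((len(channel_spec), n_samples))

    # noise floor
    for i in range(len(channel_spec)):
        data[i] = pink_noise(n_samples, rng, params.noise_exponent)

    # shared pattern geometry per scheme group
    scheme_groups: dict[str, np.ndarray] = {}
    for scheme in ("tp", "ordinal", "identity"):
        idx = np.array(
            [i for i, ch in enumerate(channel_spec) if ch.ground_truth_scheme == scheme],
            dtype=int,
        )
        if len(idx):
            scheme_groups[scheme] = idx
    kernel = _raised_cosine(stream.soa_s, rate_hz)
    onset_samples = np.round(stream.onsets_s * rate_hz).astype(int)
    for scheme, idx in scheme_groups.items():
        weights = _pattern_weights(stream, idx, scheme, params, rng)
        snrs = np.array([channel_spec[i].snr for i in idx])
        for tok_i, token in enumerate(stream.tokens):
            s0 = onset_samples[tok_i]
            s1 = min(s0 + len(kernel), n_samples)
            w = weights[token] * snrs * params.pattern_amp
            data[idx, s0:s1] += np.outer(w, kernel[: s1 - s0])

    # rate-locked components
    unit_wave = None
    if stream.condition == "structured" and stream.inventory is not None:
        # one cosine cycle per unit, phase-locked to each unit's onset, so the
        # oscillation follows the actual (probe-shifted) unit rhythm
        unit_dur = stream.inventory.unit_length * stream.soa_s
        unit_onsets = stream.unit_onsets()
        unit_wave = np.zeros(n_samples)
        raw_learning = np.zeros(n_samples)
        for u_idx, t_u in enumerate(unit_onsets):
            s0 = int(round(t_u * rate_hz))
            s1 = min(int(round((t_u + unit_dur) * rate_hz)), n_samples)
            t_rel = (np.arange(s0, s1) / rate_hz) - t_u
            unit_wave[s0:s1] = np.cos(2 * np.pi * UNIT_RATE_HZ * t_rel)
            raw_learning[s0:s1] = u_idx
    for i, ch in enumerate(channel_spec):
        if ch.ground_truth_class in ("token_only", "unit_plus_token"):
            data[i] += ch.snr * params.token_amp * np.cos(2 * np.pi * token_rate * t)
        if (
            ch.ground_truth_class in ("unit_only", "unit_plus_token")
            and unit_wave is not None
        ):
            midpoint = (
                ch.learn_midpoint_units
                if ch.learn_midpoint_units is not None
                else params.learn_midpoint_units
            )
            scale = (
                ch.learn_scale_units
                if ch.learn_scale_units is not None
                else params.learn_scale_units
            )
            learning = 1.0 / (1.0 + np.exp(-(raw_learning - midpoint) / scale))
            data[i] += ch.snr * params.unit_amp * learning * unit_wave

    channels = [
        ChannelInfo(
            id=ch.id,
            subject=ch.subject,
            roi=ch.roi,
            coords=ch.coords,
            ground_truth_class=ch.ground_truth_class,
            ground_truth_scheme=ch.ground_truth_scheme,
        )
        for ch in channel_spec
    ]
    return NeuralRecording(
        data=data,
        rate_hz=rate_hz,
        channels=channels,
        field_type="fp",
        meta={
            "condition": stream.condition,
            "modality": stream.modality,
            "token_rate_hz": token_rate,
            "unit_rate_hz": UNIT_RATE_HZ,
        },
    )


def simulate_behavior(
    stream: TokenStream,
    rt_params: RTParams | None = None,
    seed: int | np.random.Generator = 0,
    participant: str = "P01",
) -> BehavioralRecord:
    """Simulate one-back keypresses for a stream with embedded probes.

    For each probe, a response is produced with probability ``1 - lapse_rate``
    at probe onset plus a reaction time drawn from a normal truncated at zero,
    with the condition's mean.  False alarms arrive as a homogeneous Poisson
    process over the stream duration.
    """
    rt_params = rt_params or RTParams()
    rng = np.random.default_rng(seed)
    mean = (
        rt_params.mean_structured_s
        if stream.condition == "structured"
        else rt_params.mean_random_s
    )
    a = (0.0 - mean) / rt_params.sd_s  # truncate RTs at zero
    responses: list[float] = []
    for idx in stream.repeat_probes:
        if rng.random() < rt_params.lapse_rate:
            continue
        rt = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=rt_params.sd_s, random_state=rng)
        responses.append(float(stream.onsets_s[idx] + rt))
    n_fa = rng.poisson(rt_params.fa_rate_hz * stream.duration_s)
    responses.extend(rng.uniform(0.0, stream.duration_s, size=n_fa).tolist())
    return BehavioralRecord(
        response_times_s=np.array(responses),
        condition=stream.condition,
        participant=participant,
    )
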