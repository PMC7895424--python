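"""Signal conditioning and high-gamma-band (HGB) envelope extraction.

Raw field potentials are downsampled to a common analysis rate with a 60-Hz
notch applied.  The HGB envelope is obtained by filtering with eight
constant-Q Morlet wavelets whose center frequencies are geometrically spaced
between 70 and 150 Hz, averaging the band-filtered signals, and taking the
magnitude of the analytic signal of the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import gcd

import numpy as np
from scipy import signal as sps
from mne.time_frequency import morlet

from .recording import NeuralRecording

__all__ = ["FilterSpec", "condition_signal", "extract_hgb_envelope", "hgb_centers"]


def hgb_centers(
    low_hz: float = 70.0, high_hz: float = 150.0, n: int = 8
) -> np.ndarray:
    """Geometrically spaced band centers in [low, high], inclusive."""
    return np.geomspace(low_hz, high_hz, n)


@dataclass
class FilterSpec:
    """Filtering parameters for conditioning and HGB extraction."""

    notch_hz: float | None = 60.0
    target_rate_hz: float = 250.0
    hgb_centers_hz: np.ndarray = field(default_factory=hgb_centers)
    #: constant-Q factor: number of cycles per Morlet wavelet
    wavelet_q: float = 7.0
    notch_quality: float = 30.0

    def __post_init__(self) -> None:
        c = np.asarray(self.hgb_centers_hz, dtype=float)
        if not np.all(np.diff(c) > 0):
            raise ValueError("hgb centers must be strictly increasing")
        if c[0] < 70.0 - 1e-9 or c[-1] > 150.0 + 1e-9:
            raise ValueError("hgb centers must lie within [70, 150] Hz")
        self.hgb_centers_hz = c


def condition_signal(
    recording: NeuralRecording, spec: FilterSpec | None = None
) -> NeuralRecording:
    """Downsample to the target rate and notch out line noise.

    Resampling uses polyphase filtering; the output length is
    ``ceil(n * target / input)``.  With the input already at the target rate
    and the notch disabled, the data pass through unchanged.
    """
    spec = spec or FilterSpec()
    if recording.rate_hz < spec.target_rate_hz:
        raise ValueError(
            f"input rate {recording.rate_hz} Hz is below the target "
            f"{spec.target_rate_hz} Hz"
        )
    data = recording.data
    rate = recording.rate_hz
    if rate != spec.target_rate_hz:
        up, down = (
            int(round(spec.target_rate_hz * 1000)),
            int(round(rate * 1000)),
        )
        g = gcd(up, down)
        data = sps.resample_poly(data, up // g, down // g, axis=1)
        rate = spec.target_rate_hz
    if spec.notch_hz is not None:
        b, a = sps.iirnotch(spec.notch_hz, spec.notch_quality, fs=rate)
        data = sps.filtfilt(b, a, data, axis=1)
    return replace(
        recording,
        data=data,
        rate_hz=rate,
        channels=[replace(ch) for ch in recording.channels],
        meta={**recording.meta, "conditioned": True, "notch_hz": spec.notch_hz},
    )


def extract_hgb_envelope(
    recording: NeuralRecording, spec: FilterSpec | None = None
) -> NeuralRecording:
    """High-gamma-band envelope of a conditioned field-potential recording.

    Each channel is convolved with the real part of the eight constant-Q
    Morlet kernels; the eight band signals are averaged and the magnitude of
    the analytic (Hilbert) signal of the average is returned.  Signals are
    reflect-padded by one kernel length so filter edges do not wrap.
    """
    spec = spec or FilterSpec()
    if recording.rate_hz < 2.0 * spec.hgb_centers_hz[-1]:
        raise ValueError(
            f"rate {recording.rate_hz} Hz cannot resolve the "
            f"{spec.hgb_centers_hz[-1]:.0f}-Hz band"
        )
    kernels = morlet(recording.rate_hz, spec.hgb_centers_hz, n_cycles=spec.wavelet_q)
    pad = max(len(k) for k in kernels)
    data = np.pad(recording.data, ((0, 0), (pad, pad)), mode="reflect")
    band_mean = np.zeros_like(data)
    for k in kernels:
        kr = np.real(k)
        kr = kr / np.sum(kr**2) ** 0.5  # unit-energy kernel
        band_mean += sps.fftconvolve(data, kr[None, :], mode="same", axes=1)
    band_mean /= len(kernels)
    envelope = np.abs(sps.hilbert(band_mean, axis=1))[:, pad:-pad]
    return replace(
        recording,
        data=envelope,
        channels=[replace(ch) for ch in recording.channels],
        field_type="hgb",
        meta={
            **recording.meta,
            "hgb_centers_hz": list(np.round(spec.hgb_centers_hz, 3)),
            "wavelet_q": spec.wavelet_q,
            "edge_flag_samples": pad,
        },
    )
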