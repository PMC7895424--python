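"""Multichannel recording container with per-channel metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ChannelInfo", "NeuralRecording"]

GROUND_TRUTH_CLASSES = ("none", "token_only", "unit_only", "unit_plus_token")
GROUND_TRUTH_SCHEMES = ("none", "tp", "ordinal", "identity")


@dataclass
class ChannelInfo:
    """Metadata for a single channel.

    ``ground_truth_class``/``ground_truth_scheme`` record the signal content a
    synthetic channel was built with ('none' for real or pure-noise channels).
    """

    id: str
    subject: str = "S01"
    roi: str = "unknown"
    coords: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ground_truth_class: str = "none"
    ground_truth_scheme: str = "none"

    def __post_init__(self) -> None:
        if self.ground_truth_class not in GROUND_TRUTH_CLASSES:
            raise ValueError(f"unknown ground_truth_class {self.ground_truth_class!r}")
        if self.ground_truth_scheme not in GROUND_TRUTH_SCHEMES:
            raise ValueError(f"unknown ground_truth_scheme {self.ground_truth_scheme!r}")
        self.coords = tuple(float(c) for c in self.coords)


@dataclass
class NeuralRecording:
    """Continuous multichannel data: ``data`` is channels x samples.

    ``field_type`` distinguishes the broadband field potential ('fp') from the
    derived high-gamma-band envelope ('hgb').
    """

    data: np.ndarray
    rate_hz: float
    channels: list[ChannelInfo]
    field_type: str = "fp"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} "
                "channel entries"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.field_type not in ("fp", "hgb"):
            raise ValueError("field_type must be 'fp' or 'hgb'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def channel_ids(self) -> list[str]:
        return [ch.id for ch in self.channels]

    def channel_table(self) -> pd.DataFrame:
        rows = []
        for ch in self.channels:
            d = asdict(ch)
            d["x"], d["y"], d["z"] = d.pop("coords")
            rows.append(d)
        return pd.DataFrame(rows)

    def pick(self, channel_ids) -> "NeuralRecording":
        """Sub-recording restricted to the given channel ids, in that order."""
        index = {ch.id: i for i, ch in enumerate(self.channels)}
        missing = [c for c in channel_ids if c not in index]
        if missing:
            raise KeyError(f"unknown channels: {missing}")
        rows = [index[c] for c in channel_ids]
        return replace(
            self,
            data=self.data[rows].copy(),
            channels=[replace(self.channels[i]) for i in rows],
        )

    def save(self, path: str | Path) -> None:
        """Write data as .npy with a JSON channel table sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {
            "rate_hz": self.rate_hz,
            "field_type": self.field_type,
            "channels": [asdict(ch) for ch in self.channels],
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NeuralRecording":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        channels = [ChannelInfo(**c) for c in sidecar["channels"]]
        return cls(
            data=data,
            rate_hz=sidecar["rate_hz"],
            channels=channels,
            field_type=sidecar["field_type"],
            meta=sidecar.get("meta", {}),
        )
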