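"""Core containers: multichannel recordings, channel metadata, frequency bands.

A :class:`SignalSet` is the unit of analysis throughout the package — one
subject's channels × samples matrix plus the sidecar metadata (sampling rate,
channel labels with region tags, subject/group identity, optional spike
annotations).  Band definitions use half-open ``[low, high)`` intervals so a
shared edge frequency belongs to exactly one band (4 Hz is theta, not delta).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelMeta",
    "BandDefinition",
    "SpikeEvent",
    "SignalSet",
    "DEFAULT_BANDS",
    "default_channel_meta",
    "save_signalset",
    "load_signalset",
]


@dataclass(frozen=True)
class ChannelMeta:
    """Label and anatomical tags for one channel (virtual sensor)."""

    label: str
    region: str  # "anterior" | "posterior"
    hemisphere: str = "midline"  # "L" | "R" | "midline"

    def __post_init__(self) -> None:
        if self.region not in ("anterior", "posterior"):
            raise ValueError(
                f"channel {self.label!r}: region must be 'anterior' or "
                f"'posterior', got {self.region!r}"
            )
        if self.hemisphere not in ("L", "R", "midline"):
            raise ValueError(
                f"channel {self.label!r}: hemisphere must be 'L', 'R' or "
                f"'midline', got {self.hemisphere!r}"
            )


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"[{self.low}, {self.high})"
            )

    @property
    def bandwidth(self) -> float:
        return self.high - self.low

    def validate_for(self, sampling_rate: float) -> None:
        """Raise if the band cannot be analyzed at this sampling rate."""
        if self.high >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz reaches the "
                f"Nyquist frequency {sampling_rate / 2} Hz"
            )


#: The six canonical analysis bands (Hz).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
    BandDefinition("ripple", 80.0, 250.0),
)


@dataclass(frozen=True)
class SpikeEvent:
    """An injected (or annotated) transient: onset time, channel, peak amplitude."""

    time: float  # seconds from the start of the recording
    channel: int
    amplitude: float


def default_channel_meta(n_channels: int) -> list[ChannelMeta]:
    """Anterior tags on the first half of channels, posterior on the rest.

    Left/right hemispheres alternate within each region; a lone middle channel
    of an odd split is tagged midline.
    """
    metas: list[ChannelMeta] = []
    n_ant = n_channels // 2
    for i in range(n_channels):
        region = "anterior" if i < n_ant else "posterior"
        hemi = "L" if i % 2 == 0 else "R"
        metas.append(ChannelMeta(label=f"ch{i:02d}", region=region, hemisphere=hemi))
    return metas


@dataclass
class SignalSet:
    """One subject's multichannel recording plus metadata.

    Parameters
    ----------
    data : ndarray of shape (n_channels, n_samples)
        The recording, arbitrary units.
    sampling_rate : float
        Samples per second.
    channels : sequence of ChannelMeta
        One entry per matrix row.
    subject_id, group : str
        Identity used downstream in tidy tables.
    annotations : list of SpikeEvent
        Optional event markers (ground truth for synthetic data).
    """

    data: np.ndarray
    sampling_rate: float
    channels: Sequence[ChannelMeta]
    subject_id: str = "S00"
    group: str = ""
    annotations: list[SpikeEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel metadata length {len(self.channels)} does not match "
                f"matrix rows {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, **changes) -> "SignalSet":
        """Copy of this set with new data (and optional metadata changes)."""
        return replace(self, data=data, **changes)


# ---------------------------------------------------------------------------
# container I/O: HDF5, or CSV matrix with a JSON sidecar
# ---------------------------------------------------------------------------

def _meta_dict(s: SignalSet) -> dict:
    return {
        "sampling_rate": s.sampling_rate,
        "subject_id": s.subject_id,
        "group": s.group,
        "channels": [
            {"label": c.label, "region": c.region, "hemisphere": c.hemisphere}
            for c in s.channels
        ],
        "annotations": [
            {"time": a.time, "channel": a.channel, "amplitude": a.amplitude}
            for a in s.annotations
        ],
    }


def _from_meta(data: np.ndarray, meta: dict) -> SignalSet:
    return SignalSet(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channels=[ChannelMeta(**c) for c in meta["channels"]],
        subject_id=meta.get("subject_id", "S00"),
        group=meta.get("group", ""),
        annotations=[SpikeEvent(**a) for a in meta.get("annotations", [])],
    )


def save_signalset(s: SignalSet, path: str | Path) -> None:
    """Write a SignalSet to ``.h5`` (single file) or ``.csv`` + ``.json`` sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=s.data)
            f.attrs["meta"] = json.dumps(_meta_dict(s))
    elif path.suffix == ".csv":
        np.savetxt(path, s.data, delimiter=",")
        path.with_suffix(".json").write_text(json.dumps(_meta_dict(s), indent=1))
    else:
        raise ValueError(f"unsupported container format: {path.suffix!r}")


def load_signalset(path: str | Path) -> SignalSet:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()]
            meta = json.loads(f.attrs["meta"])
        return _from_meta(data, meta)
    if path.suffix == ".csv":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        meta = json.loads(path.with_suffix(".json").read_text())
        return _from_meta(data, meta)
    raise ValueError(f"unsupported container format: {path.suffix!r}")
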