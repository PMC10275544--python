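"""Synthetic cohorts: coupled band-limited sources with spike-wave transients.

The generator plants a known pairwise correlation structure per frequency band
and lets the whole analysis chain run without any recorded data.  Construction,
per band: draw independent Gaussian sources, restrict each to the band with an
exact spectral mask over the half-open interval ``[low, high)``, normalize to
unit variance, then mix them through the Cholesky factor of the target
correlation matrix.  Because every component of a channel has the same in-band
spectrum, linear filtering downstream preserves the planted correlations, so
the ground truth is directly comparable to the band-filtered correlation
estimates the connectivity stage produces.  Band contributions are summed and
broadband white sensor noise is added at a configurable fraction of the signal
RMS.

Spike-and-slow-wave transients (interictal-discharge-like events) are injected
as a fixed template — a ~70 ms biphasic sharp transient followed by a ~200 ms
slow wave — with ±10 % random jitter in amplitude and width, at Poisson event
counts per window.  Injected events are returned as ground-truth annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signals import (
    DEFAULT_BANDS,
    BandDefinition,
    ChannelMeta,
    SignalSet,
    SpikeEvent,
    default_channel_meta,
)

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "block_coupling",
    "generate_subject",
    "inject_spikes",
    "generate_cohort",
    "generate_scores",
    "default_cohort_spec",
    "WISC_NORMS",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Generative recipe for one cohort group.

    ``coupling`` maps band name -> symmetric matrix of target pairwise
    correlations (zero diagonal, entries in [0, 1)); bands absent from the
    mapping are generated uncoupled.  ``spike_rate`` is the expected number of
    spike-wave events per analysis window (Poisson), ``spike_amplitude`` the
    event peak as a multiple of the background RMS, ``noise_sd`` the white
    sensor-noise SD relative to the composite signal RMS.
    """

    name: str
    n_subjects: int = 15
    coupling: Mapping[str, np.ndarray] = field(default_factory=dict)
    spike_rate: float = 0.0
    spike_amplitude: float = 8.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.spike_amplitude < 0:
            raise ValueError("spike_amplitude must be >= 0")

    def validate_coupling(self, n_channels: int) -> None:
        for band_name, mat in self.coupling.items():
            m = np.asarray(mat, dtype=float)
            if m.shape != (n_channels, n_channels):
                raise ValueError(
                    f"group {self.name!r}, band {band_name!r}: coupling shape "
                    f"{m.shape} != ({n_channels}, {n_channels})"
                )
            if not np.allclose(m, m.T):
                raise ValueError(
                    f"group {self.name!r}, band {band_name!r}: coupling not symmetric"
                )
            if np.any(np.diag(m) != 0):
                raise ValueError(
                    f"group {self.name!r}, band {band_name!r}: diagonal must be zero"
                )
            if np.any(m < 0) or np.any(m >= 1):
                raise ValueError(
                    f"group {self.name!r}, band {band_name!r}: entries must be "
                    "in [0, 1)"
                )


@dataclass
class CohortSpec:
    """Full generative ground truth for a multi-group cohort."""

    groups: Sequence[GroupSpec]
    sampling_rate: float = 1000.0
    duration: float = 30.0
    n_channels: int = 30
    seed: int = 0
    bands: Sequence[BandDefinition] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names in {names}")
        top = max(b.high for b in self.bands)
        if self.sampling_rate < 2 * top:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz below twice the highest "
                f"band edge ({top} Hz)"
            )
        for g in self.groups:
            g.validate_coupling(self.n_channels)


def block_coupling(
    n_channels: int, within: float, cross: float, n_anterior: int | None = None
) -> np.ndarray:
    """Two-block (anterior/posterior) coupling matrix.

    ``within`` is the target correlation inside each region, ``cross`` between
    regions.  Matches the default channel tagging (first half anterior).
    """
    if n_anterior is None:
        n_anterior = n_channels // 2
    region = np.array([0] * n_anterior + [1] * (n_channels - n_anterior))
    same = region[:, None] == region[None, :]
    m = np.where(same, within, cross).astype(float)
    np.fill_diagonal(m, 0.0)
    return m


# ---------------------------------------------------------------------------
# signal construction
# ---------------------------------------------------------------------------

def _bandlimited_sources(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sampling_rate: float,
    band: BandDefinition,
) -> np.ndarray:
    """Independent unit-variance sources, spectrally confined to [low, high)."""
    w = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(w, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    spec[:, ~((freqs >= band.low) & (freqs < band.high))] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _correlation_cholesky(coupling: np.ndarray, label: str) -> np.ndarray:
    c = np.asarray(coupling, dtype=float) + np.eye(coupling.shape[0])
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            f"{label}: target correlation matrix is not positive definite; "
            "the requested pairwise couplings are jointly infeasible"
        ) from e


def generate_subject(
    group_spec: GroupSpec,
    band_defs: Sequence[BandDefinition],
    sampling_rate: float,
    duration: float,
    n_channels: int,
    seed: int | np.random.SeedSequence,
    subject_id: str = "S00",
    channels: Sequence[ChannelMeta] | None = None,
) -> SignalSet:
    """One subject's recording with the group's planted coupling structure.

    Within each band, the expected pairwise correlation of the band-filtered
    channel pair (a, b) equals the corresponding coupling entry.  Deterministic
    in `seed`.  Spikes are injected afterwards when the group's spike_rate > 0.
    """
    group_spec.validate_coupling(n_channels)
    for b in band_defs:
        if sampling_rate < 2 * b.high:
            raise ValueError(
                f"sampling_rate {sampling_rate} Hz below twice band "
                f"{b.name!r} upper edge {b.high} Hz (aliasing)"
            )
    n = int(round(duration * sampling_rate))
    rng = np.random.default_rng(seed)
    data = np.zeros((n_channels, n))
    zero = np.zeros((n_channels, n_channels))
    for band in band_defs:
        sources = _bandlimited_sources(rng, n_channels, n, sampling_rate, band)
        coupling = np.asarray(group_spec.coupling.get(band.name, zero), dtype=float)
        if np.any(coupling):
            chol = _correlation_cholesky(
                coupling, f"group {group_spec.name!r}, band {band.name!r}"
            )
            data += chol @ sources
        else:
            data += sources
    if group_spec.noise_sd > 0:
        rms = float(np.sqrt(np.mean(data**2)))
        data += rng.standard_normal(data.shape) * (group_spec.noise_sd * rms)
    if channels is None:
        channels = default_channel_meta(n_channels)
    out = SignalSet(
        data=data,
        sampling_rate=sampling_rate,
        channels=channels,
        subject_id=subject_id,
        group=group_spec.name,
    )
    if group_spec.spike_rate > 0:
        out, _ = inject_spikes(
            out,
            group_spec.spike_rate,
            group_spec.spike_amplitude,
            seed=rng.integers(2**31),
        )
    return out


# ---------------------------------------------------------------------------
# spike-wave transients
# ---------------------------------------------------------------------------

#: template segment durations in seconds: two sharp lobes then a slow wave
_SPIKE_LOBES = ((0.030, 0.6), (0.040, -1.0), (0.200, 0.45))


def spike_template(sampling_rate: float, width_scale: float = 1.0) -> np.ndarray:
    """Biphasic sharp transient (~70 ms) followed by a slow wave (~200 ms).

    Peak absolute value is 1; scale by the desired amplitude when injecting.
    """
    parts = []
    for dur, amp in _SPIKE_LOBES:
        m = max(2, int(round(dur * width_scale * sampling_rate)))
        parts.append(amp * np.sin(np.linspace(0, np.pi, m, endpoint=False)))
    return np.concatenate(parts)


def inject_spikes(
    signals: SignalSet,
    spike_rate: float,
    spike_amplitude: float,
    seed: int | np.random.SeedSequence,
) -> tuple[SignalSet, list[SpikeEvent]]:
    """Add Poisson(`spike_rate`) spike-wave events to random channels.

    Event amplitude is ``spike_amplitude`` × the pre-injection RMS of the
    target channel, jittered ±10 %; width is jittered ±10 % as well.  Returns
    the modified signals and the injected-event ground truth; a zero rate
    returns the input unchanged with an empty list.
    """
    if spike_rate < 0:
        raise ValueError("spike_rate must be >= 0")
    if spike_amplitude < 0:
        raise ValueError("spike_amplitude must be >= 0")
    if spike_rate == 0:
        return signals, []
    rng = np.random.default_rng(seed)
    data = signals.data.copy()
    fs = signals.sampling_rate
    rms = np.sqrt(np.mean(data**2, axis=1))
    n_events = int(rng.poisson(spike_rate))
    events: list[SpikeEvent] = []
    for _ in range(n_events):
        ch = int(rng.integers(signals.n_channels))
        width = float(rng.uniform(0.9, 1.1))
        amp = spike_amplitude * float(rng.uniform(0.9, 1.1)) * rms[ch]
        tpl = spike_template(fs, width) * amp
        max_start = signals.n_samples - tpl.size
        if max_start <= 0:
            raise ValueError("window too short for the spike template")
        i0 = int(rng.integers(max_start))
        data[ch, i0 : i0 + tpl.size] += tpl
        events.append(SpikeEvent(time=i0 / fs, channel=ch, amplitude=amp))
    out = signals.with_data(data, annotations=list(signals.annotations) + events)
    return out, events


# ---------------------------------------------------------------------------
# cohorts and cognitive scores
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[list[SignalSet], dict]:
    """All subjects of all groups, with a ground-truth record.

    Subject seeds are spawned deterministically from the master seed, so the
    same spec and seed reproduce the cohort bit-identically.
    """
    master = np.random.SeedSequence(spec.seed)
    children = iter(master.spawn(sum(g.n_subjects for g in spec.groups)))
    subjects: list[SignalSet] = []
    truth: dict = {
        "seed": spec.seed,
        "sampling_rate": spec.sampling_rate,
        "duration": spec.duration,
        "n_channels": spec.n_channels,
        "groups": {},
    }
    for g in spec.groups:
        grec: dict = {
            "spike_rate": g.spike_rate,
            "noise_sd": g.noise_sd,
            "coupling": {
                b: np.asarray(m).tolist() for b, m in g.coupling.items()
            },
            "subjects": {},
        }
        for i in range(g.n_subjects):
            sid = f"{g.name}-{i + 1:02d}"
            s = generate_subject(
                g,
                spec.bands,
                spec.sampling_rate,
                spec.duration,
                spec.n_channels,
                seed=next(children),
                subject_id=sid,
            )
            subjects.append(s)
            grec["subjects"][sid] = {
                "spikes": [
                    {"time": a.time, "channel": a.channel, "amplitude": a.amplitude}
                    for a in s.annotations
                ]
            }
        truth["groups"][g.name] = grec
    return subjects, truth


#: Cognitive score norms per group: (mean, SD) for each index.
WISC_NORMS: dict[str, dict[str, tuple[float, float]]] = {
    "IED": {
        "FSIQ": (95.53, 6.37),
        "VCI": (87.53, 10.82),
        "PRI": (105.06, 8.67),
        "WMI": (92.27, 8.79),
        "PSI": (103.67, 12.99),
    },
    "non-IED": {
        "FSIQ": (102.73, 11.49),
        "VCI": (100.00, 14.56),
        "PRI": (108.80, 13.26),
        "WMI": (99.33, 12.27),
        "PSI": (99.20, 10.11),
    },
    "HC": {
        "FSIQ": (111.67, 12.21),
        "VCI": (114.53, 12.42),
        "PRI": (108.87, 12.02),
        "WMI": (105.40, 10.29),
        "PSI": (101.73, 12.03),
    },
}

_GENERIC_NORMS = {k: (100.0, 12.0) for k in ("FSIQ", "VCI", "PRI", "WMI", "PSI")}


def generate_scores(
    group_name: str,
    subject_ids: Sequence[str],
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Synthetic cognitive index scores (FSIQ, VCI, PRI, WMI, PSI) per subject.

    Gaussian around group norms, rounded to integer points and floored at 40
    (standardized scales do not go lower).
    """
    norms = WISC_NORMS.get(group_name, _GENERIC_NORMS)
    rng = np.random.default_rng(seed)
    rows = []
    for sid in subject_ids:
        row = {"subject_id": sid, "group": group_name}
        for key, (mu, sd) in norms.items():
            row[key] = max(40, int(round(rng.normal(mu, sd))))
        rows.append(row)
    return pd.DataFrame(rows)


def default_cohort_spec(
    seed: int = 0,
    n_subjects: int = 15,
    n_channels: int = 30,
    sampling_rate: float = 1000.0,
    duration: float = 30.0,
) -> CohortSpec:
    """The default three-group cohort (IED / non-IED / HC).

    Couplings are anterior/posterior block models.  The healthy-control group
    keeps moderate long-range (cross-region) coupling in every band; the IED
    group loses it in the beta and ripple bands (and gains diffuse theta
    coupling plus ~10 spike-wave events per window); the non-IED group is
    intermediate: reduced ripple cross-region coupling and stronger gamma
    coupling (shorter weighted path lengths).
    """
    nc = n_channels

    def bands(**over: np.ndarray) -> dict[str, np.ndarray]:
        base = {b.name: block_coupling(nc, 0.35, 0.25) for b in DEFAULT_BANDS}
        base.update(over)
        return base

    hc = GroupSpec(name="HC", n_subjects=n_subjects, coupling=bands())
    ied = GroupSpec(
        name="IED",
        n_subjects=n_subjects,
        spike_rate=10.0,
        coupling=bands(
            theta=block_coupling(nc, 0.35, 0.30),
            beta=block_coupling(nc, 0.35, 0.05),
            ripple=block_coupling(nc, 0.45, 0.05),
        ),
    )
    non_ied = GroupSpec(
        name="non-IED",
        n_subjects=n_subjects,
        coupling=bands(
            gamma=block_coupling(nc, 0.45, 0.35),
            ripple=block_coupling(nc, 0.35, 0.12),
        ),
    )
    return CohortSpec(
        groups=[ied, non_ied, hc],
        sampling_rate=sampling_rate,
        duration=duration,
        n_channels=n_channels,
        seed=seed,
    )
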