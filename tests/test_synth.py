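"""Generator contracts: planted correlations, spikes, determinism."""

import numpy as np
import pytest

from bandnet.fc import pairwise_correlation
from bandnet.preprocess import bandpass
from bandnet.signals import DEFAULT_BANDS
from bandnet.synth import (
    CohortSpec,
    GroupSpec,
    block_coupling,
    default_cohort_spec,
    generate_cohort,
    generate_scores,
    generate_subject,
    inject_spikes,
)

THETA = DEFAULT_BANDS[1]


def pair_coupling(r, n=2, bands=DEFAULT_BANDS):
    c = np.zeros((n, n))
    c[0, 1] = c[1, 0] = r
    return {b.name: c for b in bands}


# ------------------------------------------------------------ validation

def test_coupling_entry_at_or_above_one_rejected():
    g = GroupSpec(name="bad", coupling=pair_coupling(1.0))
    with pytest.raises(ValueError, match=r"\[0, 1\)"):
        generate_subject(g, DEFAULT_BANDS, 1000.0, 1.0, 2, seed=0)


def test_sampling_below_band_nyquist_rejected():
    g = GroupSpec(name="g", coupling={})
    with pytest.raises(ValueError, match="aliasing"):
        generate_subject(g, DEFAULT_BANDS, 400.0, 1.0, 2, seed=0)


def test_jointly_infeasible_couplings_rejected():
    # three pairwise correlations of 0.9, -impossible- style: 0.9/0.9/-... use
    # r(0,1)=r(0,2)=0.9 but r(1,2)=0 -> not positive definite
    c = np.array([[0, 0.9, 0.9], [0.9, 0, 0.0], [0.9, 0.0, 0]])
    g = GroupSpec(name="g", coupling={"theta": c})
    with pytest.raises(ValueError, match="positive definite"):
        generate_subject(g, [THETA], 1000.0, 1.0, 3, seed=0)


def test_asymmetric_coupling_rejected():
    c = np.array([[0, 0.5], [0.2, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        GroupSpec(name="g", coupling={"theta": c}).validate_coupling(2)


# ------------------------------------------------- planted correlations

def test_uncoupled_channels_have_near_zero_correlation():
    """No coupling: band-filtered |R| stays at the noise floor (wide bands)."""
    g = GroupSpec(name="g", coupling={}, noise_sd=0.1)
    s = generate_subject(g, DEFAULT_BANDS, 1000.0, 10.0, 6, seed=42)
    for band in DEFAULT_BANDS[-2:]:  # gamma, ripple: widest bands
        r = pairwise_correlation(bandpass(s, band)).R
        off = np.abs(r[np.triu_indices(6, 1)])
        assert off.mean() < 3 / np.sqrt(s.n_samples)


def test_planted_theta_correlation_recovered():
    """Target 0.8 between channels 0 and 1 in theta; 60 s at 1000 Hz."""
    g = GroupSpec(name="g", coupling={"theta": pair_coupling(0.8)["theta"]})
    s = generate_subject(g, DEFAULT_BANDS, 1000.0, 60.0, 2, seed=7)
    r = pairwise_correlation(bandpass(s, THETA)).R[0, 1]
    assert r == pytest.approx(0.8, abs=0.05)


def test_band_separation():
    """Coupling planted only in theta leaves disjoint bands uncorrelated."""
    g = GroupSpec(name="g", coupling={"theta": pair_coupling(0.8)["theta"]})
    s = generate_subject(g, DEFAULT_BANDS, 1000.0, 60.0, 2, seed=11)
    for band in (DEFAULT_BANDS[0], DEFAULT_BANDS[2], DEFAULT_BANDS[3]):
        r = pairwise_correlation(bandpass(s, band)).R[0, 1]
        assert abs(r) < 0.1, f"leakage into {band.name}: R={r:.3f}"


def test_generate_subject_deterministic():
    g = GroupSpec(name="g", coupling=pair_coupling(0.5), spike_rate=5.0)
    a = generate_subject(g, DEFAULT_BANDS, 1000.0, 2.0, 2, seed=3)
    b = generate_subject(g, DEFAULT_BANDS, 1000.0, 2.0, 2, seed=3)
    assert np.array_equal(a.data, b.data)
    assert a.annotations == b.annotations


# ------------------------------------------------------------- spikes

def test_zero_rate_returns_input_unchanged(noise_signals):
    out, events = inject_spikes(noise_signals, 0.0, 8.0, seed=0)
    assert out is noise_signals
    assert events == []


def test_negative_rate_rejected(noise_signals):
    with pytest.raises(ValueError):
        inject_spikes(noise_signals, -1.0, 8.0, seed=0)


def test_poisson_event_count(noise_signals):
    counts = [
        len(inject_spikes(noise_signals, 10.0, 8.0, seed=s)[1]) for s in range(500)
    ]
    assert np.mean(counts) == pytest.approx(10.0, abs=0.5)


def test_spike_amplitude_exceeds_background(noise_signals):
    out, events = inject_spikes(noise_signals, 10.0, 8.0, seed=1)
    assert events
    q999 = np.quantile(np.abs(noise_signals.data), 0.999)
    fs = out.sampling_rate
    for e in events:
        i0 = int(round(e.time * fs))
        seg = np.abs(out.data[e.channel, i0 : i0 + int(0.3 * fs)])
        assert seg.max() > q999


def test_spike_injection_preserves_shape(noise_signals):
    out, _ = inject_spikes(noise_signals, 10.0, 8.0, seed=2)
    assert out.data.shape == noise_signals.data.shape
    assert out.sampling_rate == noise_signals.sampling_rate


# ------------------------------------------------------------- cohorts

def small_spec(seed=0, n_subjects=2):
    groups = [
        GroupSpec(name="IED", n_subjects=n_subjects, spike_rate=10.0,
                  coupling={"theta": block_coupling(4, 0.4, 0.1)}),
        GroupSpec(name="non-IED", n_subjects=n_subjects),
        GroupSpec(name="HC", n_subjects=n_subjects),
    ]
    return CohortSpec(groups=groups, sampling_rate=1000.0, duration=2.0,
                      n_channels=4, seed=seed)


def test_cohort_size_three_groups_of_fifteen():
    spec = CohortSpec(
        groups=[GroupSpec(name=n) for n in ("IED", "non-IED", "HC")],
        sampling_rate=1000.0, duration=0.5, n_channels=2, seed=0,
    )
    subjects, truth = generate_cohort(spec)
    assert len(subjects) == 45
    assert {s.group for s in subjects} == {"IED", "non-IED", "HC"}
    assert set(truth["groups"]) == {"IED", "non-IED", "HC"}


def test_empty_group_contributes_no_subjects():
    spec = small_spec()
    spec.groups[1].n_subjects = 0
    subjects, _ = generate_cohort(spec)
    assert len(subjects) == 4
    assert all(s.group != "non-IED" for s in subjects)


def test_duplicate_group_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        CohortSpec(
            groups=[GroupSpec(name="HC"), GroupSpec(name="HC")],
            n_channels=2, seed=0,
        )


def test_cohort_deterministic():
    a, ta = generate_cohort(small_spec(seed=9))
    b, tb = generate_cohort(small_spec(seed=9))
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.data, sb.data)
    assert ta == tb


def test_ied_group_gets_spike_annotations():
    subjects, truth = generate_cohort(small_spec(seed=5))
    ied = [s for s in subjects if s.group == "IED"]
    assert all(len(s.annotations) > 0 for s in ied)
    hc = [s for s in subjects if s.group == "HC"]
    assert all(len(s.annotations) == 0 for s in hc)


def test_default_cohort_spec_shape():
    spec = default_cohort_spec(seed=1)
    assert [g.name for g in spec.groups] == ["IED", "non-IED", "HC"]
    assert all(g.n_subjects == 15 for g in spec.groups)
    assert spec.sampling_rate == 1000.0 and spec.duration == 30.0
    ied = spec.groups[0]
    assert ied.spike_rate == 10.0
    # long-range ripple coupling ordered HC > non-IED > IED
    def cross(g):
        return g.coupling["ripple"][0, -1]
    assert cross(spec.groups[2]) > cross(spec.groups[1]) > cross(spec.groups[0])


def test_generate_scores_reproducible_and_plausible():
    a = generate_scores("HC", ["HC-01", "HC-02", "HC-03"], seed=4)
    b = generate_scores("HC", ["HC-01", "HC-02", "HC-03"], seed=4)
    assert a.equals(b)
    assert set(a.columns) >= {"subject_id", "FSIQ", "VCI", "PRI", "WMI", "PSI"}
    assert (a[["FSIQ", "VCI", "PRI", "WMI", "PSI"]] > 40).all().all()
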