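"""Weighted topology metrics against brute-force oracles and closed forms."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandnet.fc import ConnectivityResult, ThresholdedNetwork, build_network
from bandnet.graph import (
    WeightedGraph,
    clustering,
    compute_all,
    degree,
    path_length,
    path_length_harmonic,
    strength,
    strength_sum,
)

from _oracles import (
    bf_clustering,
    bf_degree,
    bf_path_length_average,
    bf_strength,
    random_weighted_graph,
)


def complete_graph(n, w=1.0):
    return WeightedGraph(w * (np.ones((n, n)) - np.eye(n)))


# ------------------------------------------------------------ closed forms

@pytest.mark.parametrize("n", [3, 4, 6])
def test_complete_unit_graph_closed_forms(n):
    g = complete_graph(n)
    d, da = degree(g)
    s, sa = strength(g)
    _, la = path_length(g)
    c, ca = clustering(g)
    assert np.all(d == n - 1) and da == n - 1
    assert np.allclose(s, (n - 1) / n) and sa == pytest.approx((n - 1) / n)
    assert la == pytest.approx(1.0)
    assert np.allclose(c, 1.0) and ca == pytest.approx(1.0)


def test_path_graph_degrees():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    d, da = degree(WeightedGraph(w))
    assert list(d) == [1, 2, 1]
    assert da == pytest.approx(4 / 3)


def test_empty_graph_metrics_all_zero():
    g = WeightedGraph(np.zeros((4, 4)))
    assert degree(g)[1] == 0.0
    assert strength(g)[1] == 0.0
    assert path_length(g)[1] == 0.0  # unreachable pairs contribute zero
    assert clustering(g)[1] == 0.0


def test_two_disconnected_nodes_have_zero_average_path():
    g = WeightedGraph(np.zeros((2, 2)))
    _, la = path_length(g)
    assert la == 0.0


def test_triangle_with_weak_edge_routes_through_middle():
    # weights (w12, w23, w13) = (1, 1, 0.25): direct 1->3 costs 4, via 2 costs 2
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    w[0, 2] = w[2, 0] = 0.25
    l, la = path_length(WeightedGraph(w))
    assert l[0, 2] == pytest.approx(2.0)
    assert la == pytest.approx(bf_path_length_average(w), abs=1e-12)


def test_strength_scales_linearly(rng):
    w = random_weighted_graph(rng, 6)
    s1, _ = strength(WeightedGraph(w))
    s2, _ = strength(WeightedGraph(3.0 * w))
    assert np.allclose(s2, 3.0 * s1)


def test_strength_sum_is_n_times_printed_strength(rng):
    w = random_weighted_graph(rng, 5)
    s_printed, _ = strength(WeightedGraph(w))
    s_conv, _ = strength_sum(WeightedGraph(w))
    assert np.allclose(s_conv, 5 * s_printed)


def test_star_graph_has_no_triangles():
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    _, ca = clustering(WeightedGraph(w))
    assert ca == 0.0


def test_triangle_plus_pendant_clustering():
    w = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (0, 2), (2, 3)]:
        w[i, j] = w[j, i] = 1.0
    c, ca = clustering(WeightedGraph(w))
    # pendant node has degree 1 -> C=0; node 2 has degree 3 with one triangle:
    # ordered neighbor pairs (0,1),(1,0) -> 2 / (3*2) = 1/3
    assert c[3] == 0.0
    assert c[0] == pytest.approx(1.0) and c[1] == pytest.approx(1.0)
    assert c[2] == pytest.approx(1 / 3)
    assert ca == pytest.approx(bf_clustering(w)[1], abs=1e-12)


# --------------------------------------------------------------- oracles

def test_metrics_match_bruteforce_on_random_graphs(rng):
    for _ in range(50):
        n = int(rng.integers(2, 9))
        w = random_weighted_graph(rng, n, density=float(rng.uniform(0.2, 0.9)))
        g = WeightedGraph(w)
        d, da = degree(g)
        s, sa = strength(g)
        _, la = path_length(g)
        c, ca = clustering(g)
        d0, da0 = bf_degree(w)
        s0, sa0 = bf_strength(w)
        la0 = bf_path_length_average(w)
        c0, ca0 = bf_clustering(w)
        assert np.allclose(d, d0, atol=1e-10) and abs(da - da0) < 1e-10
        assert np.allclose(s, s0, atol=1e-10) and abs(sa - sa0) < 1e-10
        assert abs(la - la0) < 1e-10
        assert np.allclose(c, c0, atol=1e-10) and abs(ca - ca0) < 1e-10


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_scale_invariances(seed):
    """w -> c*w: degree and clustering unchanged, S_i scaled by c, L_ij by 1/c."""
    r = np.random.default_rng(seed)
    w = random_weighted_graph(r, int(r.integers(3, 8)))
    c = float(r.uniform(0.5, 5.0))
    g1, g2 = WeightedGraph(w), WeightedGraph(c * w)
    assert np.array_equal(degree(g1)[0], degree(g2)[0])
    assert np.allclose(strength(g2)[0], c * strength(g1)[0])
    assert np.allclose(path_length(g2)[1], path_length(g1)[1] / c)
    assert np.allclose(clustering(g2)[0], clustering(g1)[0])


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_permutation_invariance_of_network_metrics(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(3, 8))
    w = random_weighted_graph(r, n)
    perm = r.permutation(n)
    wp = w[np.ix_(perm, perm)]
    for f in (degree, strength, path_length, clustering):
        assert f(WeightedGraph(w))[1] == pytest.approx(
            f(WeightedGraph(wp))[1], abs=1e-12
        )


# ------------------------------------------------------------ compute_all

def test_compute_all_on_thresholded_toy():
    r = np.array([
        [1.0, 0.9, -0.8],
        [0.9, 1.0, 0.1],
        [-0.8, 0.1, 1.0],
    ])
    conn = ConnectivityResult(R=r, K=10)
    net = build_network(conn, alpha=0.05)
    gm = compute_all(net)
    w = np.abs(net.weights)
    assert gm.DA == pytest.approx(bf_degree(w)[1])
    assert gm.SA == pytest.approx(bf_strength(w)[1])
    assert gm.LA == pytest.approx(bf_path_length_average(w))
    assert gm.CA == pytest.approx(bf_clustering(w)[1])


def test_compute_all_uses_magnitudes_for_signed_weights():
    w = np.array([[0, -0.5, 0.5], [-0.5, 0, -0.5], [0.5, -0.5, 0]])
    net = ThresholdedNetwork(weights=w, threshold_R=0.4, alpha=0.05, K=100)
    gm = compute_all(net)
    assert gm.SA > 0 and gm.CA > 0  # negative edges contribute as |w|


def test_isolated_node_dilutes_averages():
    w3 = np.ones((3, 3)) - np.eye(3)
    w4 = np.zeros((4, 4))
    w4[:3, :3] = w3
    m3 = compute_all(WeightedGraph(w3))
    m4 = compute_all(WeightedGraph(w4))
    assert m4.DA < m3.DA and m4.SA < m3.SA and m4.CA < m3.CA
    assert m4.LA == pytest.approx(bf_path_length_average(w4))


def test_empty_network_warns_and_zeroes(caplog):
    net = ThresholdedNetwork(
        weights=np.zeros((3, 3)), threshold_R=0.9, alpha=0.05, K=10
    )
    with caplog.at_level(logging.WARNING, logger="bandnet.graph"):
        gm = compute_all(net)
    assert gm.as_dict() == {"DA": 0.0, "SA": 0.0, "LA": 0.0, "CA": 0.0}
    assert any("empty network" in r.message for r in caplog.records)


def test_harmonic_path_length_penalizes_fragmentation():
    connected = WeightedGraph(np.ones((4, 4)) - np.eye(4))
    frag = np.zeros((4, 4))
    frag[0, 1] = frag[1, 0] = 1.0
    fragmented = WeightedGraph(frag)
    # printed convention: fragmentation lowers LA; harmonic variant does not
    assert path_length(fragmented)[1] < path_length(connected)[1]
    assert path_length_harmonic(fragmented)[1] > path_length_harmonic(connected)[1]


def test_weighted_graph_validation():
    with pytest.raises(ValueError, match="symmetric"):
        WeightedGraph(np.array([[0, 1.0], [0.5, 0]]))
    with pytest.raises(ValueError, match="non-negative"):
        WeightedGraph(np.array([[0, -1.0], [-1.0, 0]]))
    with pytest.raises(ValueError, match="diagonal"):
        WeightedGraph(np.array([[1.0, 0.5], [0.5, 0]]))
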