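"""Weighted graph-topology metrics: degree, strength, path length, clustering.

Definitions (for a weighted undirected graph G with N nodes, weight matrix w,
zero diagonal):

* degree          d_i = number of nonzero edges at node i;  DA = mean(d_i)
* strength        S_i = (1/N) * sum_j w_ij;                 SA = mean(S_i)
* path length     L_ij = shortest-path distance with edge lengths 1/w_ij,
                  with L_ij = 0 when j is unreachable from i or i = j;
                  LA = sum_{i,j} L_ij / (N (N-1))
* clustering      C_i = sum_{j,k} (w_ij w_jk w_ki)^(1/3) / (d_i (d_i - 1))
                  over ordered neighbor pairs (geometric-mean triangle
                  weight); C_i = 0 when d_i < 2;            CA = mean(C_i)

Note the deliberately nonstandard conventions this analysis uses: strength
carries a 1/N prefactor (not the plain sum), and unreachable pairs contribute
zero (not infinity) to the average path length, so fragmenting a network can
*lower* LA.  Standard alternatives are available behind explicit flags
(``strength_sum``, ``path_length_harmonic``).

Metrics operate on non-negative weights: thresholded networks are converted
with |w| (cube roots and inverse lengths are ill-defined for signed weights),
and weights are normalized by their maximum before clustering so C_i is
bounded by 1.  When weights are correlation magnitudes the normalization is a
monotone rescaling bounded below by the edge threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from .fc import ThresholdedNetwork

__all__ = [
    "WeightedGraph",
    "GraphMetrics",
    "degree",
    "strength",
    "strength_sum",
    "path_length",
    "path_length_harmonic",
    "clustering",
    "compute_all",
]

log = logging.getLogger(__name__)


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w
        if not self.labels:
            self.labels = [str(i) for i in range(w.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_network(cls, net: ThresholdedNetwork) -> "WeightedGraph":
        """Magnitude graph of a signed thresholded network."""
        return cls(weights=np.abs(net.weights))


@dataclass
class GraphMetrics:
    """Node-level and network-level topology metrics for one subject × band."""

    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    DA: float
    SA: float
    LA: float
    CA: float
    subject_id: str = ""
    group: str = ""
    band: str = ""

    def as_dict(self) -> dict[str, float]:
        return {"DA": self.DA, "SA": self.SA, "LA": self.LA, "CA": self.CA}


def degree(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    """Edge counts per node and their network average DA."""
    d = np.count_nonzero(graph.weights, axis=1).astype(float)
    return d, float(d.mean()) if d.size else 0.0


def strength(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    """S_i = (1/N) sum_j w_ij (note the 1/N prefactor) and the average SA."""
    n = graph.n_nodes
    s = graph.weights.sum(axis=1) / n
    return s, float(s.mean()) if n else 0.0


def strength_sum(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    """Conventional strength: plain weight sum per node."""
    s = graph.weights.sum(axis=1)
    return s, float(s.mean()) if s.size else 0.0


def _distance_matrix(graph: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path distances with edge lengths 1/w (inf = unreachable)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(graph.weights > 0, 1.0 / graph.weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return _sp_shortest_path(lengths, method="D", directed=False)


def path_length(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    """Distance matrix L_ij and the average LA over ordered node pairs.

    Unreachable pairs and the diagonal contribute 0 (so a totally disconnected
    graph has LA = 0).
    """
    n = graph.n_nodes
    if n < 2:
        return np.zeros((n, n)), 0.0
    dist = _distance_matrix(graph)
    l = np.where(np.isfinite(dist), dist, 0.0)
    np.fill_diagonal(l, 0.0)
    return l, float(l.sum() / (n * (n - 1)))


def path_length_harmonic(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    """Harmonic-mean alternative (global-efficiency style): averages 1/L_ij,
    so unreachable pairs count as 0 efficiency instead of 0 distance."""
    n = graph.n_nodes
    if n < 2:
        return np.zeros((n, n)), 0.0
    dist = _distance_matrix(graph)
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / dist, 0.0)
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum() / (n * (n - 1))
    return dist, float(1.0 / eff) if eff > 0 else 0.0


def clustering(graph: WeightedGraph, normalize: bool = True) -> tuple[np.ndarray, float]:
    """Geometric-mean weighted clustering per node and the average CA.

    C_i sums (w_ij w_jk w_ki)^(1/3) over ordered pairs of distinct neighbors
    and divides by d_i (d_i - 1); nodes with degree < 2 get C_i = 0.  With
    ``normalize`` (default) weights are divided by their maximum first so
    C_i ∈ [0, 1].
    """
    w = graph.weights
    n = graph.n_nodes
    if n == 0:
        return np.zeros(0), 0.0
    wmax = w.max()
    if normalize and wmax > 0:
        w = w / wmax
    cw = np.cbrt(w)
    # (cw^3)_ii sums (w_ij w_jk w_ki)^(1/3) over ordered pairs j != k
    tri = np.diag(cw @ cw @ cw)
    d = np.count_nonzero(graph.weights, axis=1).astype(float)
    denom = d * (d - 1)
    c = np.divide(tri, denom, out=np.zeros(n), where=denom > 0)
    return c, float(c.mean())


def compute_all(net: ThresholdedNetwork | WeightedGraph) -> GraphMetrics:
    """All four metrics of a thresholded network (or magnitude graph).

    Signed networks are converted to magnitude graphs first.  An empty network
    yields all-zero metrics with a logged warning.
    """
    if isinstance(net, ThresholdedNetwork):
        graph = WeightedGraph.from_network(net)
        sid, grp = net.subject_id, net.group
        band = net.band.name if net.band is not None else ""
    else:
        graph, sid, grp, band = net, "", "", ""
    if graph.n_nodes == 0 or not np.any(graph.weights):
        log.warning("empty network for subject=%r band=%r: all metrics 0", sid, band)
        n = graph.n_nodes
        return GraphMetrics(
            degree=np.zeros(n),
            strength=np.zeros(n),
            clustering=np.zeros(n),
            DA=0.0,
            SA=0.0,
            LA=0.0,
            CA=0.0,
            subject_id=sid,
            group=grp,
            band=band,
        )
    d, da = degree(graph)
    s, sa = strength(graph)
    _, la = path_length(graph)
    c, ca = clustering(graph)
    return GraphMetrics(
        degree=d,
        strength=s,
        clustering=c,
        DA=da,
        SA=sa,
        LA=la,
        CA=ca,
        subject_id=sid,
        group=grp,
        band=band,
    )
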