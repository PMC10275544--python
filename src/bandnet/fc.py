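"""Pairwise correlation connectivity and t-statistic edge thresholding.

For a channel pair (a, b) the connectivity is the zero-lag Pearson correlation
R = cov(Xa, Xb) / (S_Xa S_Xb) over the analysis window.  An edge is retained
when its correlation is significant under the t statistic

    Tp = R * sqrt(K - 2) / sqrt(1 - R**2),

compared two-sided against Student's t with K - 2 degrees of freedom, where K
is the number of data points in the window.  Equivalently, |R| must exceed the
critical correlation r* = t_c / sqrt(K - 2 + t_c**2).  Surviving edges keep
the sign of R: positive weights are read as excitatory connections, negative
as inhibitory.

K is not corrected for autocorrelation by default, mirroring common practice
for this statistic; for band-limited signals an optional effective-sample-size
correction (K_eff ≈ 2 × bandwidth × duration) is available via
``effective_samples`` / ``use_effective_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as spstats

from .signals import BandDefinition, ChannelMeta, SignalSet

__all__ = [
    "ConnectivityResult",
    "ThresholdedNetwork",
    "pairwise_correlation",
    "t_statistic",
    "critical_R",
    "effective_samples",
    "build_network",
    "regional_edge_count",
    "edges_dataframe",
    "to_graphml",
]


@dataclass
class ConnectivityResult:
    """Per-band correlation matrix with its effective sample count.

    ``R`` is symmetric with unit diagonal; pairs involving a constant channel
    are undefined and stored as NaN, with the offending channels listed in
    ``excluded_channels``.
    """

    R: np.ndarray
    K: int
    band: BandDefinition | None = None
    subject_id: str = ""
    group: str = ""
    sampling_rate: float | None = None
    excluded_channels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        n = self.R.shape[0]
        if self.R.shape != (n, n):
            raise ValueError("R must be square")
        if self.K < 3:
            raise ValueError("need K >= 3 data points")
        finite = np.isfinite(self.R)
        if np.any(np.abs(self.R[finite]) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(
            np.where(finite, self.R, 0.0), np.where(finite.T, self.R.T, 0.0)
        ):
            raise ValueError("R must be symmetric")


@dataclass
class ThresholdedNetwork:
    """Signed weighted graph of correlations surviving the t threshold.

    Zero entries are absent edges; nonzero entries keep the sign and magnitude
    of R (positive = excitatory, negative = inhibitory) and satisfy
    ``|w| >= threshold_R``.
    """

    weights: np.ndarray
    threshold_R: float
    alpha: float
    K: int
    band: BandDefinition | None = None
    subject_id: str = ""
    group: str = ""

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def pairwise_correlation(
    signals: SignalSet, band: BandDefinition | None = None
) -> ConnectivityResult:
    """Zero-lag Pearson correlation of every channel pair over the window.

    Constant channels cannot be correlated; their pairs are set to NaN and the
    channel indices recorded in ``excluded_channels`` (they are dropped from
    any thresholded network rather than treated as zero-correlation).
    """
    data = signals.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = data.std(axis=1)
    excluded = [int(i) for i in np.flatnonzero(sd == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    if excluded:
        r[excluded, :] = np.nan
        r[:, excluded] = np.nan
    np.fill_diagonal(r, 1.0)
    return ConnectivityResult(
        R=r,
        K=data.shape[1],
        band=band,
        subject_id=signals.subject_id,
        group=signals.group,
        sampling_rate=signals.sampling_rate,
        excluded_channels=excluded,
    )


def t_statistic(R: np.ndarray | float, K: int) -> np.ndarray | float:
    """Tp = R sqrt(K-2) / sqrt(1-R^2); |R| = 1 maps to infinity."""
    r = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(K - 2) / np.sqrt(1.0 - r**2)
        t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    return float(t) if np.isscalar(R) else t


def critical_R(K: int, alpha: float = 0.05) -> float:
    """Minimal |R| whose t statistic is significant two-sided at `alpha`.

    Monotonically decreasing in K: longer windows admit weaker correlations.
    """
    if K < 3:
        raise ValueError("need K >= 3")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    tc = spstats.t.ppf(1 - alpha / 2, df=K - 2)
    return float(tc / np.sqrt(K - 2 + tc**2))


def effective_samples(K: int, sampling_rate: float, band: BandDefinition) -> int:
    """Effective independent sample count of a band-limited window.

    A signal confined to a band of width B carries about 2·B·T independent
    samples over a window of T seconds, i.e. K · 2B / fs of the K recorded
    points.  Floored at 3 so the t statistic stays defined.
    """
    k_eff = int(round(K * 2.0 * band.bandwidth / sampling_rate))
    return max(3, min(K, k_eff))


def build_network(
    conn: ConnectivityResult,
    alpha: float = 0.05,
    use_effective_k: bool = False,
    bonferroni_pairs: bool = False,
) -> ThresholdedNetwork:
    """Threshold a correlation matrix into a signed functional network.

    An edge (i, j) survives iff ``|R_ij| >= critical_R(K, alpha)``; the weight
    keeps the sign and magnitude of R_ij.  ``use_effective_k`` replaces K with
    the band-limited effective sample count; ``bonferroni_pairs`` divides
    alpha by the number of channel pairs first (both off by default).
    """
    n = conn.R.shape[0]
    k = conn.K
    if use_effective_k:
        if conn.band is None or conn.sampling_rate is None:
            raise ValueError("effective-K correction needs band and sampling_rate")
        k = effective_samples(conn.K, conn.sampling_rate, conn.band)
    a = alpha / (n * (n - 1) / 2) if bonferroni_pairs else alpha
    r_crit = critical_R(k, a)
    w = np.where(np.abs(conn.R) >= r_crit, conn.R, 0.0)
    w[~np.isfinite(conn.R)] = 0.0  # excluded (constant-channel) pairs
    np.fill_diagonal(w, 0.0)
    return ThresholdedNetwork(
        weights=w,
        threshold_R=r_crit,
        alpha=a,
        K=k,
        band=conn.band,
        subject_id=conn.subject_id,
        group=conn.group,
    )


def regional_edge_count(
    net: ThresholdedNetwork, channels: Sequence[ChannelMeta]
) -> dict[str, int]:
    """Edge counts by region pair: anterior-anterior / anterior-posterior /
    posterior-posterior.  The three counts sum to the total edge count."""
    if len(channels) != net.n_nodes:
        raise ValueError("channel metadata length does not match network size")
    regions = [c.region for c in channels]
    counts = {
        "anterior-anterior": 0,
        "anterior-posterior": 0,
        "posterior-posterior": 0,
    }
    ii, jj = np.nonzero(np.triu(net.weights, 1))
    for i, j in zip(ii, jj):
        pair = tuple(sorted((regions[i], regions[j])))
        counts[f"{pair[0]}-{pair[1]}"] += 1
    return counts


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def edges_dataframe(conn: ConnectivityResult, net: ThresholdedNetwork):
    """Tidy edge list: source, target, R, retained, sign."""
    import pandas as pd

    n = conn.R.shape[0]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            r = conn.R[i, j]
            retained = bool(net.weights[i, j] != 0)
            rows.append(
                {
                    "source": i,
                    "target": j,
                    "R": r,
                    "retained": retained,
                    "sign": int(np.sign(r)) if retained else 0,
                }
            )
    return pd.DataFrame(rows)


def to_graphml(net: ThresholdedNetwork, path: str | Path) -> None:
    """Write the thresholded network as GraphML (signed edge weights)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    ii, jj = np.nonzero(np.triu(net.weights, 1))
    for i, j in zip(ii, jj):
        g.add_edge(int(i), int(j), weight=float(net.weights[i, j]))
    nx.write_graphml(g, str(path))
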