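"""Functional connectivity graphs from binned spike-count correlations.

Spike trains of active channels are binned (100 ms default), Pearson
correlations are computed for every electrode pair, and an undirected binary
edge is kept when the correlation is significant (two-sided P < alpha from
the exact t-transform of r) AND its absolute value clears the weight
threshold.  Node degree, clustering coefficient and global efficiency of the
resulting graph summarize network integration and segregation.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import numpy as np
from scipy import stats

from .io import QCConfig, Recording, active_channels


@dataclasses.dataclass(frozen=True)
class ConnectivityConfig:
    bin_s: float = 0.1
    alpha: float = 0.05
    weight_threshold: float = 0.35

    def __post_init__(self) -> None:
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.weight_threshold <= 1:
            raise ValueError("weight_threshold must be in [0, 1]")


def binned_counts(
    rec: Recording, bin_s: float, channels: list[int]
) -> np.ndarray:
    """(n_channels, n_bins) spike-count matrix."""
    n_bins = int(math.ceil(rec.duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    edges[-1] = max(edges[-1], rec.duration_s)  # last bin absorbs the remainder
    out = np.empty((len(channels), n_bins))
    for i, ch in enumerate(channels):
        out[i], _ = np.histogram(rec.train(ch), bins=edges)
    return out


def build_graph(
    rec: Recording,
    cfg: ConnectivityConfig | None = None,
    qc: QCConfig | None = None,
) -> nx.Graph:
    """Thresholded significant-correlation graph over active channels.

    Isolated active channels remain as degree-0 nodes; pairs where either
    count vector has zero variance get no edge.  Edge attribute ``r`` stores
    the Pearson correlation.
    """
    cfg = cfg or ConnectivityConfig()
    qc = qc or QCConfig()
    chans = active_channels(rec, qc)
    g = nx.Graph()
    g.add_nodes_from(chans)
    if len(chans) < 2:
        return g
    counts = binned_counts(rec, cfg.bin_s, chans)
    n_bins = counts.shape[1]
    sd = counts.std(axis=1)
    for i in range(len(chans)):
        for j in range(i + 1, len(chans)):
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = float(np.corrcoef(counts[i], counts[j])[0, 1])
            if abs(r) < cfg.weight_threshold:
                continue
            # two-sided p from the exact t-transform with n_bins - 2 d.f.
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n_bins - 2) / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df=n_bins - 2)
            if p < cfg.alpha:
                g.add_edge(chans[i], chans[j], r=r)
    return g


def graph_metrics(g: nx.Graph) -> dict[str, float]:
    """Mean node degree, mean clustering coefficient and global efficiency.

    Global efficiency is the mean over ordered node pairs of the inverse
    shortest-path length; disconnected pairs contribute 0.  With fewer than
    two nodes all three metrics are NaN (missing).
    """
    n = g.number_of_nodes()
    if n < 2:
        return {
            "node_degree": math.nan,
            "clustering_coeff": math.nan,
            "efficiency": math.nan,
        }
    return {
        "node_degree": float(np.mean([d for _, d in g.degree()])),
        "clustering_coeff": float(nx.average_clustering(g)),
        "efficiency": float(nx.global_efficiency(g)),
    }


def edge_list(g: nx.Graph) -> list[tuple[int, int, float]]:
    """(node_i, node_j, r) rows for CSV export."""
    return [(u, v, data.get("r", math.nan)) for u, v, data in g.edges(data=True)]
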