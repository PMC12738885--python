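"""Graph construction and topology: DEG-BRIN, PPI tiers, hubs, baselines.

The DEG-BRIN (brain-region interaction network) has one node per anatomical
region; regions i and j are connected iff their DEG sets (restricted to the
universal cross-region list G) intersect, with edge weight |G_i ∩ G_j| and
self-loop weight |G_i|.  PPI edge lists are thresholded into confidence tiers
(s >= tau, tau in {0.4, 0.7, 0.9} by convention); hubs are nodes in the top
20% of BOTH degree and betweenness centrality.  Random baseline graphs match
node and edge counts.  Adjacencies are symmetrically degree-normalized,
A_hat = D^{-1/2} W D^{-1/2}, for graph convolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dge import RegionDEGSets


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weighted graph with explicit self-loop weights."""

    nodes: list
    weights: np.ndarray  # n x n symmetric, nonnegative; diagonal = self-loops

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node count")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Number of off-diagonal edges (unordered pairs with positive weight)."""
        off = self.weights.copy()
        np.fill_diagonal(off, 0.0)
        return int((off > 0).sum() // 2)

    def edge_list(self) -> pd.DataFrame:
        """Edge rows (node_a, node_b, weight); self-loops as node_a == node_b."""
        rows = []
        for i in range(self.n_nodes):
            if self.weights[i, i] > 0:
                rows.append((self.nodes[i], self.nodes[i], self.weights[i, i]))
            for j in range(i + 1, self.n_nodes):
                if self.weights[i, j] > 0:
                    rows.append((self.nodes[i], self.nodes[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if self.weights[i, j] > 0:
                    g.add_edge(self.nodes[i], self.nodes[j], weight=self.weights[i, j])
        return g

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame, nodes=None) -> "WeightedGraph":
        if nodes is None:
            nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
        nodes = list(nodes)
        pos = {n: i for i, n in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for _, row in edges.iterrows():
            i, j = pos[row["node_a"]], pos[row["node_b"]]
            w[i, j] = w[j, i] = float(row["weight"])
        return cls(nodes=nodes, weights=w)


def build_degbrin(region_sets: RegionDEGSets) -> WeightedGraph:
    """DEG co-occurrence network over brain regions.

    Region DEG sets are first restricted to the universal list G (genes DE in
    >= min_regions regions); W_ij = |G_i ∩ G_j|, W_ii = |G_i|.
    """
    restricted = region_sets.restricted()
    regions = sorted(restricted)
    if len(regions) < 2:
        raise ValueError(f"need >= 2 regions, got {len(regions)}")
    n = len(regions)
    w = np.zeros((n, n))
    for i, ri in enumerate(regions):
        w[i, i] = len(restricted[ri])
        for j in range(i + 1, n):
            w[i, j] = w[j, i] = len(restricted[ri] & restricted[regions[j]])
    return WeightedGraph(nodes=regions, weights=w)


#: STRING-style confidence tiers conventionally reported
PPI_TIERS = (0.4, 0.7, 0.9)


def threshold_ppi(edges: pd.DataFrame, tau: float, nodes=None) -> WeightedGraph:
    """Binary PPI graph keeping pairs with combined score s >= tau (inclusive)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    keep = edges[edges["score"] >= tau]
    if nodes is None:
        nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    nodes = list(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b in zip(keep["gene_a"], keep["gene_b"]):
        if a == b or a not in pos or b not in pos:
            continue
        i, j = pos[a], pos[b]
        w[i, j] = w[j, i] = 1.0
    return WeightedGraph(nodes=nodes, weights=w)


def degree_centrality(g: WeightedGraph) -> pd.Series:
    """Neighbor counts (weights binarized, self-loops ignored)."""
    adj = (g.weights > 0).astype(int)
    np.fill_diagonal(adj, 0)
    return pd.Series(adj.sum(axis=1), index=g.nodes, name="degree")


def betweenness_centrality(g: WeightedGraph) -> pd.Series:
    """Raw Freeman betweenness: sum over unordered pairs s != t (both != v) of
    the fraction of unweighted shortest s-t paths passing through v."""
    cb = nx.betweenness_centrality(g.to_networkx(), normalized=False, weight=None)
    return pd.Series({n: cb[n] for n in g.nodes}, name="betweenness")


def centrality_table(g: WeightedGraph) -> pd.DataFrame:
    return pd.DataFrame(
        {"degree": degree_centrality(g), "betweenness": betweenness_centrality(g)}
    )


def select_hubs(cent: pd.DataFrame, top_fraction: float = 0.2) -> set:
    """Nodes in the top ``top_fraction`` of BOTH degree and betweenness.

    The cut is the empirical (1 - top_fraction) quantile of each metric;
    boundary ties are included.
    """
    if cent.empty:
        raise ValueError("empty centrality table")
    q = 1.0 - top_fraction
    deg_cut = cent["degree"].quantile(q)
    bet_cut = cent["betweenness"].quantile(q)
    mask = (cent["degree"] >= deg_cut) & (cent["betweenness"] >= bet_cut)
    return set(cent.index[mask])


def random_graph_matched(
    n_nodes: int, n_edges: int, self_loop_weights=None, seed: int = 0, nodes=None
) -> WeightedGraph:
    """Uniform random simple graph with exactly ``n_edges`` unit-weight edges.

    Self-loop weights (e.g. those of the DEG-BRIN being ablated) are carried
    over unchanged so that only the off-diagonal topology is randomized.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds maximum {max_edges} for {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    w = np.zeros((n_nodes, n_nodes))
    w[iu[0][chosen], iu[1][chosen]] = 1.0
    w += w.T
    if self_loop_weights is not None:
        np.fill_diagonal(w, np.asarray(self_loop_weights, dtype=float))
    if nodes is None:
        nodes = [f"N{i:02d}" for i in range(n_nodes)]
    elif len(nodes) != n_nodes:
        raise ValueError("nodes must have length n_nodes")
    return WeightedGraph(nodes=list(nodes), weights=w)


def normalize_adjacency(g: WeightedGraph) -> np.ndarray:
    """Symmetric degree normalization A_hat = D^{-1/2} W D^{-1/2}.

    Requires strictly positive row sums (guaranteed when self-loops are
    present); the result is symmetric with spectral radius <= 1.
    """
    w = g.weights
    d = w.sum(axis=1)
    if (d <= 0).any():
        bad = [g.nodes[i] for i in np.flatnonzero(d <= 0)]
        raise ValueError(f"zero row sum for nodes {bad}; add self-loops first")
    dinv = 1.0 / np.sqrt(d)
    return w * dinv[:, None] * dinv[None, :]


def write_edge_list(path, g: WeightedGraph) -> None:
    g.edge_list().to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> WeightedGraph:
    edges = pd.read_csv(path, sep="\t")
    nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    pos = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for _, row in edges.iterrows():
        i, j = pos[row["node_a"]], pos[row["node_b"]]
        w[i, j] = w[j, i] = float(row["weight"])
    return WeightedGraph(nodes=nodes, weights=w)
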