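"""Binary graph analysis of similarity matrices: sparsity thresholding,
small-world indices against degree-preserving nulls, and betweenness hubs.

Metrics follow the binary (unweighted) conventions: Watts–Strogatz nodal
clustering, characteristic path length over reachable pairs, and exact
betweenness centrality.  Small-worldness compares the graph with an ensemble
of null networks of identical size; the default null is Maslov–Sneppen
degree-preserving rewiring (an Erdős–Rényi same-|V|,|E| null is also
available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected simple graph as a 0/1 adjacency matrix plus its sparsity."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops not allowed")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency)
        G.add_nodes_from(range(self.n_nodes))
        return G

    @classmethod
    def from_networkx(cls, G: nx.Graph, sparsity: float) -> "BinaryGraph":
        n = G.number_of_nodes()
        a = nx.to_numpy_array(G, nodelist=range(n), dtype=int)
        return cls(a, sparsity)


@dataclass(frozen=True)
class SmallWorldMetrics:
    Cp: float
    Lp: float
    gamma: float
    lambda_sw: float
    sigma_sw: float
    n_null: int
    null_summaries: dict = field(default_factory=dict)


@dataclass(frozen=True)
class NodalCentrality:
    bc: np.ndarray
    hubs: tuple[int, ...]


def threshold_by_sparsity(weights: np.ndarray, S: float) -> BinaryGraph:
    """Binarize a symmetric weight matrix by keeping the ``round(S * p)``
    strongest off-diagonal edges, ``p = V(V-1)/2``.

    Ties at the cutoff are broken deterministically by lexicographic (i, j)
    order, so the same matrix and sparsity always give the same graph.
    """
    if not 0 < S <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {S}")
    W = np.asarray(weights, dtype=float)
    V = W.shape[0]
    iu, ju = np.triu_indices(V, k=1)
    p = len(iu)
    k = int(round(S * p))
    # stable sort on -weight; equal weights keep (i, j) lexicographic order
    order = np.argsort(-W[iu, ju], kind="stable")
    adj = np.zeros((V, V), dtype=int)
    keep = order[:k]
    adj[iu[keep], ju[keep]] = 1
    return BinaryGraph(adj + adj.T, S)


def clustering_coefficient(G: BinaryGraph) -> tuple[np.ndarray, float]:
    """Watts–Strogatz nodal clustering (triangles over possible triangles;
    degree < 2 contributes 0) and its unweighted mean Cp."""
    cc = nx.clustering(G.to_networkx())
    per_node = np.array([cc[i] for i in range(G.n_nodes)])
    return per_node, float(per_node.mean())


def characteristic_path_length(G: BinaryGraph) -> tuple[float, int]:
    """Mean shortest-path length over reachable ordered node pairs.

    Unreachable pairs are excluded from the mean; their count is returned so
    disconnected graphs are visible to the caller.
    """
    if G.n_edges == 0:
        raise ValueError("graph has no edges")
    g = G.to_networkx()
    n = G.n_nodes
    total = 0.0
    reachable = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                reachable += 1
    excluded = n * (n - 1) - reachable
    return total / reachable, excluded


def rewire_degree_preserving(
    G: BinaryGraph, n_swaps: int | None = None, seed: int | None = None
) -> BinaryGraph:
    """Maslov–Sneppen double-edge-swap randomization.

    Preserves the degree sequence exactly while destroying higher-order
    structure (e.g. clustering).  ``n_swaps`` defaults to ``10 * |E|``.  On
    degenerate graphs where the swap budget cannot be realized the best-effort
    result is returned.
    """
    g = G.to_networkx()
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("need at least two edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * m
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXAlgorithmError:
        pass  # swap budget unreachable on degenerate graphs; best effort
    return BinaryGraph.from_networkx(g, G.sparsity)


def er_null(G: BinaryGraph, seed: int | None = None) -> BinaryGraph:
    """Erdős–Rényi G(n, m) null preserving only node and edge counts."""
    g = nx.gnm_random_graph(G.n_nodes, G.n_edges, seed=seed)
    return BinaryGraph.from_networkx(g, G.sparsity)


def small_world(
    G: BinaryGraph,
    n_null: int = 100,
    n_swaps: int | None = None,
    seed: int | None = None,
    null_model: str = "maslov_sneppen",
) -> SmallWorldMetrics:
    """Small-world indices against a null ensemble.

    gamma = Cp / mean(Cp_null), lambda = Lp / mean(Lp_null),
    sigma = gamma / lambda; sigma > 1 with lambda close to 1 is the
    small-world signature.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    _, Cp = clustering_coefficient(G)
    Lp, _ = characteristic_path_length(G)
    rng = np.random.default_rng(seed)
    cps, lps = [], []
    for _ in range(n_null):
        s = int(rng.integers(0, 2**31 - 1))
        if null_model == "maslov_sneppen":
            H = rewire_degree_preserving(G, n_swaps=n_swaps, seed=s)
        elif null_model == "erdos_renyi":
            H = er_null(G, seed=s)
        else:
            raise ValueError(f"unknown null model: {null_model}")
        _, c = clustering_coefficient(H)
        l, _ = characteristic_path_length(H)
        cps.append(c)
        lps.append(l)
    cp_null, lp_null = float(np.mean(cps)), float(np.mean(lps))
    gamma = Cp / cp_null
    lam = Lp / lp_null
    return SmallWorldMetrics(
        Cp=Cp,
        Lp=Lp,
        gamma=gamma,
        lambda_sw=lam,
        sigma_sw=gamma / lam,
        n_null=n_null,
        null_summaries={
            "Cp_null_mean": cp_null,
            "Cp_null_sd": float(np.std(cps)),
            "Lp_null_mean": lp_null,
            "Lp_null_sd": float(np.std(lps)),
        },
    )


def betweenness_hubs(G: BinaryGraph) -> NodalCentrality:
    """Exact (Brandes) betweenness centrality, unnormalized, with hubs defined
    as nodes whose BC exceeds mean + SD (population SD) over the network."""
    bc_dict = nx.betweenness_centrality(G.to_networkx(), normalized=False)
    bc = np.array([bc_dict[i] for i in range(G.n_nodes)])
    cut = bc.mean() + bc.std(ddof=0)
    hubs = tuple(int(i) for i in np.nonzero(bc > cut)[0])
    return NodalCentrality(bc=bc, hubs=hubs)


def sparsity_sweep(
    weights: np.ndarray,
    sparsities: Sequence[float],
    n_null: int = 100,
    seed: int | None = None,
) -> list[dict]:
    """Compute Cp, Lp, small-world indices, BC and hubs at each sparsity."""
    out = []
    for i, S in enumerate(sparsities):
        G = threshold_by_sparsity(weights, S)
        sw = small_world(G, n_null=n_null, seed=None if seed is None else seed + i)
        cent = betweenness_hubs(G)
        out.append(
            {
                "sparsity": float(S),
                "n_edges": G.n_edges,
                "Cp": sw.Cp,
                "Lp": sw.Lp,
                "gamma": sw.gamma,
                "lambda": sw.lambda_sw,
                "sigma": sw.sigma_sw,
                "bc": cent.bc.tolist(),
                "hubs": list(cent.hubs),
            }
        )
    return out
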