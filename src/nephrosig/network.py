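"""Seed-set subnetwork expansion and Monte Carlo specificity testing.

A set of experimentally implicated proteins (seeds) is expanded over an
evidence-weighted protein-protein interaction graph: edges below an evidence
threshold are dropped, and every non-seed protein adjacent to at least two
distinct seeds is added as an intermediate (a node touching a single seed
cannot connect anything).  The induced subgraph on seeds plus intermediates
is summarized by connectivity metrics of its largest connected component.

Specificity is assessed against a resampling null: random seed sets of the
same size are drawn from the measured-protein universe (not the whole
interactome), expanded identically, and the observed metric is ranked within
the null samples, giving the add-one empirical p-value
(1 + #{null >= observed}) / (1 + n_iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Interactome",
    "SubnetworkResult",
    "NullDistribution",
    "expand_subnetwork",
    "component_metrics",
    "monte_carlo_null",
]

METRIC_NAMES = (
    "n_nodes",
    "n_edges",
    "mean_degree",
    "largest_component_node_count",
    "largest_component_edge_count",
)


class Interactome:
    """Undirected evidence-weighted protein graph.

    Parallel records of the same unordered pair are aggregated by summing
    evidence; self-loops are rejected.  The adjacency structure is kept as a
    dense boolean matrix per evidence threshold (cached), which keeps the
    resampling null fast at the graph sizes used here (thousands of nodes).
    """

    def __init__(self, edges: pd.DataFrame):
        required = {"node_a", "node_b", "evidence"}
        if not required <= set(edges.columns):
            raise ValueError(f"edge list needs columns {sorted(required)}")
        if (edges["node_a"] == edges["node_b"]).any():
            raise ValueError("self-loops are not allowed")
        if (edges["evidence"] <= 0).any():
            raise ValueError("evidence counts must be positive")
        a = edges["node_a"].astype(str)
        b = edges["node_b"].astype(str)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        dedup = (
            pd.DataFrame({"node_a": lo, "node_b": hi, "evidence": edges["evidence"]})
            .groupby(["node_a", "node_b"], as_index=False)["evidence"]
            .sum()
        )
        self.edges = dedup
        self.nodes: list[str] = sorted(
            set(dedup["node_a"]) | set(dedup["node_b"])
        )
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self._ia = dedup["node_a"].map(self._index).to_numpy()
        self._ib = dedup["node_b"].map(self._index).to_numpy()
        self._evidence = dedup["evidence"].to_numpy()
        self._adj_cache: dict[int, np.ndarray] = {}

    def __contains__(self, node: str) -> bool:
        return node in self._index

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self, min_evidence: int = 1) -> np.ndarray:
        """Dense boolean adjacency over edges with evidence >= threshold."""
        if min_evidence not in self._adj_cache:
            n = self.n_nodes
            adj = np.zeros((n, n), dtype=bool)
            keep = self._evidence >= min_evidence
            ia, ib = self._ia[keep], self._ib[keep]
            adj[ia, ib] = True
            adj[ib, ia] = True
            self._adj_cache[min_evidence] = adj
        return self._adj_cache[min_evidence]

    def to_networkx(self, min_evidence: int = 1) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        keep = self.edges["evidence"] >= min_evidence
        g.add_weighted_edges_from(
            self.edges.loc[keep, ["node_a", "node_b", "evidence"]].itertuples(
                index=False, name=None
            ),
            weight="evidence",
        )
        return g

    @classmethod
    def from_tsv(cls, path) -> "Interactome":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


@dataclass
class SubnetworkResult:
    """Expanded subnetwork: seeds, intermediates, edges and its metrics."""

    seed_nodes: list[str]
    intermediate_nodes: list[str]
    edges: list[tuple[str, str]]
    metrics: dict[str, float]
    missing_seeds: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return self.seed_nodes + self.intermediate_nodes


@dataclass
class NullDistribution:
    metric: str
    samples: np.ndarray
    n_iterations: int
    observed: float
    empirical_p: float


def _expand_indices(
    adj: np.ndarray, seed_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core expansion on integer node indices.

    Returns (member indices, intra-subgraph adjacency, intermediate indices).
    """
    n = adj.shape[0]
    seed_mask = np.zeros(n, dtype=bool)
    seed_mask[seed_idx] = True
    # a non-seed node qualifies as intermediate when adjacent to >= 2 seeds
    seed_neighbour_count = adj[seed_idx].sum(axis=0)
    inter_mask = (seed_neighbour_count >= 2) & ~seed_mask
    inter_idx = np.flatnonzero(inter_mask)
    members = np.concatenate([np.sort(seed_idx), inter_idx])
    sub = adj[np.ix_(members, members)]
    return members, sub, inter_idx


def _metrics_from_subadj(sub: np.ndarray) -> dict[str, float]:
    n_nodes = sub.shape[0]
    n_edges = int(sub.sum()) // 2
    if n_nodes == 0:
        return dict.fromkeys(METRIC_NAMES, 0.0)
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    sizes = np.bincount(labels)
    big = int(np.argmax(sizes))
    big_mask = labels == big
    lc_nodes = int(sizes[big])
    lc_edges = int(sub[np.ix_(big_mask, big_mask)].sum()) // 2
    return {
        "n_nodes": float(n_nodes),
        "n_edges": float(n_edges),
        "mean_degree": 2.0 * n_edges / n_nodes,
        "largest_component_node_count": float(lc_nodes),
        "largest_component_edge_count": float(lc_edges),
    }


def expand_subnetwork(
    g: Interactome, seeds, min_evidence: int = 2
) -> SubnetworkResult:
    """Expand seeds by one vetted intermediate and summarize connectivity.

    Edges with evidence below ``min_evidence`` are ignored; an intermediate
    must be adjacent (post-threshold) to at least two distinct seeds.  Seeds
    absent from the interactome are recorded, not fatal.
    """
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("seed set is empty")
    missing = [s for s in seeds if s not in g]
    present = [s for s in seeds if s in g]
    if not present:
        raise ValueError("no seed is present in the interactome")
    adj = g.adjacency(min_evidence)
    seed_idx = np.array([g._index[s] for s in present])
    members, sub, inter_idx = _expand_indices(adj, seed_idx)
    names = [g.nodes[i] for i in members]
    ii, jj = np.nonzero(np.triu(sub))
    edges = [(names[i], names[j]) for i, j in zip(ii, jj)]
    return SubnetworkResult(
        seed_nodes=sorted(present),
        intermediate_nodes=[g.nodes[i] for i in inter_idx],
        edges=edges,
        metrics=_metrics_from_subadj(sub),
        missing_seeds=missing,
    )


def component_metrics(sub: SubnetworkResult) -> dict[str, float]:
    """Connectivity metrics recomputed from the stored edge list.

    Covers node/edge counts, mean degree (2E/N), the number of connected
    components and the node/edge counts and share of the largest one.
    """
    g = nx.Graph()
    g.add_nodes_from(sub.nodes)
    g.add_edges_from(sub.edges)
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    comps = list(nx.connected_components(g)) if n_nodes else []
    if comps:
        big = max(comps, key=len)
        lc = g.subgraph(big)
        lc_nodes, lc_edges = lc.number_of_nodes(), lc.number_of_edges()
    else:
        lc_nodes = lc_edges = 0
    return {
        "n_nodes": float(n_nodes),
        "n_edges": float(n_edges),
        "mean_degree": 2.0 * n_edges / n_nodes if n_nodes else 0.0,
        "n_components": float(len(comps)),
        "largest_component_node_count": float(lc_nodes),
        "largest_component_edge_count": float(lc_edges),
        "largest_component_share": lc_nodes / n_nodes if n_nodes else 0.0,
    }


def monte_carlo_null(
    g: Interactome,
    universe,
    k: int,
    observed: SubnetworkResult,
    n_iterations: int = 1000,
    metric: str = "largest_component_edge_count",
    min_evidence: int = 2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Resampling null for one connectivity metric.

    Each iteration draws ``k`` nodes without replacement from ``universe``
    (the measured-protein sampling frame), expands them exactly like the
    observed seed set, and records the metric.  The empirical p-value uses
    the add-one estimator, so it is never zero.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    if n_iterations < 20:
        raise ValueError("n_iterations < 20 gives no usable p-value resolution")
    universe = [u for u in dict.fromkeys(universe) if u in g]
    if k > len(universe):
        raise ValueError(f"cannot draw {k} seeds from a universe of {len(universe)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    adj = g.adjacency(min_evidence)
    uni_idx = np.array([g._index[u] for u in universe])
    samples = np.empty(n_iterations)
    for it in range(n_iterations):
        seed_idx = rng.choice(uni_idx, size=k, replace=False)
        _, sub, _ = _expand_indices(adj, seed_idx)
        samples[it] = _metrics_from_subadj(sub)[metric]
    obs = float(observed.metrics[metric])
    p = (1.0 + np.count_nonzero(samples >= obs)) / (1.0 + n_iterations)
    return NullDistribution(
        metric=metric,
        samples=samples,
        n_iterations=n_iterations,
        observed=obs,
        empirical_p=float(p),
    )
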