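"""Disease-gene interactome construction and hub prioritization.

The disease neighborhood is the induced subgraph on a seed gene set
and its first-degree neighbors in the protein-interaction network.
After overlapping the seeds with differentially expressed genes and
reducing the network around that overlap, hub genes are prioritized by
the union of the top-k nodes under two centralities:

* degree centrality - the number of incident edges;
* bottleneck centrality - for every root s, a BFS shortest-path tree
  T_s is built (deterministic lowest-ID parent among shortest-path
  predecessors); node v scores p_s(v) = 1 iff more than |V(T_s)|/4 of
  the root-to-node paths in T_s pass through v (equivalently, v's
  subtree contains more than a quarter of the tree's nodes); the
  bottleneck score is BN(v) = sum_s p_s(v).

The root always counts itself (its subtree is the whole tree), and in
disconnected graphs each tree spans only the root's component.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import InteractionNetwork

log = logging.getLogger(__name__)


@dataclass
class PrioritizationParams:
    k: int = 100  # top-node count per centrality metric

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class NeighborhoodResult:
    network: InteractionNetwork
    seeds_present: list[str]
    seeds_missing: list[str]

    @property
    def attrition(self) -> int:
        return len(self.seeds_missing)


def disease_neighborhood(
    net: InteractionNetwork, seeds: list[str] | set[str]
) -> NeighborhoodResult:
    """Induced subgraph on (seeds in net) plus their first-degree neighbors."""
    seeds = set(seeds)
    present = sorted(s for s in seeds if net.has_node(s))
    missing = sorted(seeds - set(present))
    if not present:
        raise ValueError("none of the seed genes are present in the network")
    if missing:
        log.info("seed attrition: %d seed(s) absent from the network", len(missing))
    keep = set(present)
    for s in present:
        keep.update(net.graph.neighbors(s))
    return NeighborhoodResult(net.induced(keep), present, missing)


def overlap_stats(degs: list[str], subnet: InteractionNetwork) -> tuple[int, float]:
    """Count and percentage of DEGs present in the subnetwork."""
    deg_set = set(degs)
    n_overlap = sum(1 for g in deg_set if subnet.has_node(g))
    if not deg_set:
        return 0, float("nan")
    return n_overlap, 100.0 * n_overlap / len(deg_set)


def reduce_to_overlap_neighborhood(
    subnet: InteractionNetwork, overlap_genes: list[str] | set[str]
) -> NeighborhoodResult:
    """Network reduction: overlap genes and their first-degree neighbors."""
    return disease_neighborhood(subnet, set(overlap_genes))


def degree_centrality(net: InteractionNetwork) -> pd.Series:
    """Edge count per node, indexed by node ID (sorted)."""
    return pd.Series(
        {n: net.graph.degree(n) for n in net.graph.nodes}, name="degree"
    ).sort_index()


def _bfs_tree_parents(adj: dict[str, list[str]], root: str) -> dict[str, str | None]:
    """Shortest-path tree parents with lowest-ID parent selection.

    Processing each BFS level in ascending node order guarantees that
    the first node to claim an unvisited neighbor is the lowest-ID
    shortest-path predecessor.
    """
    parent: dict[str, str | None] = {root: None}
    level = [root]
    while level:
        nxt: list[str] = []
        for u in level:  # level already sorted ascending
            for v in adj[u]:
                if v not in parent:
                    parent[v] = u
                    nxt.append(v)
        level = sorted(set(nxt))
    return parent


def bottleneck_centrality(net: InteractionNetwork) -> pd.Series:
    """Bottleneck score BN(v) summed over shortest-path trees from every root."""
    nodes = net.nodes
    adj = {n: sorted(net.graph.neighbors(n)) for n in nodes}
    bn = {n: 0 for n in nodes}
    for root in nodes:
        parent = _bfs_tree_parents(adj, root)
        tree_nodes = list(parent)
        n_tree = len(tree_nodes)
        # subtree sizes by accumulating from the deepest nodes upward;
        # children were appended after parents, so reverse insertion order works
        size = {v: 1 for v in tree_nodes}
        for v in reversed(tree_nodes):
            p = parent[v]
            if p is not None:
                size[p] += size[v]
        for v in tree_nodes:
            if size[v] > n_tree / 4.0:
                bn[v] += 1
    return pd.Series(bn, name="bottleneck").sort_index()


def centrality_table(net: InteractionNetwork) -> pd.DataFrame:
    deg = degree_centrality(net)
    bn = bottleneck_centrality(net)
    return pd.DataFrame({"node": deg.index, "degree": deg.values, "bottleneck": bn.values})


@dataclass
class PrioritizationResult:
    union: list[str]
    top_degree: list[str]
    top_bottleneck: list[str]
    network: InteractionNetwork = field(repr=False)


def prioritize_union(
    net: InteractionNetwork, params: PrioritizationParams
) -> PrioritizationResult:
    """Union of the top-k nodes by degree and by bottleneck centrality.

    Ties are broken by node ID ascending; exactly k nodes per metric.
    k larger than the node count is clamped with a warning.
    """
    k = params.k
    if k > net.n_nodes:
        log.warning("k=%d exceeds node count %d; clamping", k, net.n_nodes)
        k = net.n_nodes
    deg = degree_centrality(net)
    bn = bottleneck_centrality(net)

    def top_k(scores: pd.Series) -> list[str]:
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return [n for n, _ in ranked[:k]]

    td, tb = top_k(deg), top_k(bn)
    union = sorted(set(td) | set(tb))
    return PrioritizationResult(union, td, tb, net.induced(union))
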