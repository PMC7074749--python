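"""Network construction, topology metrics, modularity and hub analysis.

Significant co-occurrence pairs define an undirected signed network;
confidence-1 association rules define a directed network. The topology panel
(density, average neighbors, characteristic path length, clustering
coefficient, Freeman degree centralization, degree heterogeneity) is computed
on the undirected simple view of either network, with Erdos-Renyi G(n, m)
baselines matched on node and edge counts. Module structure is found by
Newman fast-greedy modularity optimization on the positive-edge subgraph,
and rule-network hubs are classified by their exclusive role as rule targets
or rule origins — the target-only hubs being the keystone-species candidates.

Conventions (matching the NetworkAnalyzer tool the panel mirrors):
* characteristic path length averages over connected ordered node pairs only;
* nodes of degree < 2 contribute a local clustering of 0 to the mean;
* centralization is Freeman's degree centralization, sum(d_max - d_i) over
  (N-1)(N-2), which is 1 for a star and 0 for a regular graph;
* heterogeneity is the population coefficient of variation of the degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .data import FragmentAnnotation, PresenceAbsenceMatrix, ValidationError, BACTERIAL
from .cooccurrence import PairTestResult, POSITIVE
from .rules import AssociationRule


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    avg_neighbors: float
    characteristic_path_length: float
    clustering_coefficient: float
    centralization: float
    heterogeneity: float
    coverage: float | None = None
    random_cpl: float | None = None
    random_cc: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class ModulePartition:
    membership: dict[str, int]
    q: float
    module_sizes: dict[int, int]

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_modules_gt3(self) -> int:
        return sum(1 for s in self.module_sizes.values() if s > 3)


@dataclass(frozen=True)
class HubReport:
    """Node roles in the rule network and the top-k exclusive hubs."""

    roles: dict[str, str]  # node -> target_only | origin_only | mixed
    in_degree: dict[str, int]
    out_degree: dict[str, int]
    top_targets: list[str]  # target_only nodes by descending in-degree
    top_origins: list[str]  # origin_only nodes by descending out-degree
    top_target_bacterial_fraction: float | None = None
    top_origin_bacterial_fraction: float | None = None


@dataclass(frozen=True)
class HubNeighborhood:
    """A hub, its rule-adjacent fragments, and the co-occurrence overlay."""

    hub: str
    nodes: list[str]
    rule_edges: list[tuple[str, str]]
    overlay_edges: list[frozenset]

    def as_multigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.rule_edges:
            g.add_edge(u, v, kind="rule")
        for e in self.overlay_edges:
            u, v = sorted(e)
            g.add_edge(u, v, kind="cooccurrence")
        return g


# ---------------------------------------------------------------------------
# construction


def build_cooccurrence_network(
    results: Sequence[PairTestResult],
    annotations: Mapping[str, FragmentAnnotation] | None = None,
) -> nx.Graph:
    """Undirected signed network over fragments in >= 1 significant pair."""
    g = nx.Graph()
    for r in results:
        if not r.significant:
            continue
        g.add_edge(r.fragment_1, r.fragment_2, sign=r.sign, p_adj=r.p_adj)
    if annotations:
        for n in g.nodes:
            g.nodes[n]["domain"] = annotations[n].domain
    return g


def build_rule_network(
    rules: Sequence[AssociationRule],
    annotations: Mapping[str, FragmentAnnotation] | None = None,
) -> nx.DiGraph:
    """Directed simple graph over fragments participating in >= 1 rule."""
    g = nx.DiGraph()
    for r in rules:
        g.add_edge(r.origin, r.target, support_origin=r.support_origin)
    if annotations:
        for n in g.nodes:
            g.nodes[n]["domain"] = annotations[n].domain
    return g


# ---------------------------------------------------------------------------
# metrics on adjacency matrices


def _undirected_adjacency(net: nx.Graph) -> tuple[np.ndarray, list[str]]:
    """Boolean adjacency of the undirected simple view (reciprocal edges merge)."""
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in net.edges:
        if u == v:
            continue
        adj[index[u], index[v]] = True
        adj[index[v], index[u]] = True
    return adj, nodes


def _cpl(adj: np.ndarray) -> float:
    """Mean shortest-path distance over connected ordered node pairs."""
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        raise ValidationError("characteristic path length undefined: no connected node pair")
    return float(dist[finite].mean())


def _clustering_mean(adj: np.ndarray) -> float:
    """Mean local clustering; nodes of degree < 2 contribute 0."""
    a = adj.astype(np.float32)
    deg = adj.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(deg >= 2, 2.0 * triangles / (deg * (deg - 1.0)), 0.0)
    return float(local.mean())


def _degree_stats(adj: np.ndarray) -> tuple[float, float]:
    """(centralization, heterogeneity) of the degree distribution."""
    deg = adj.sum(axis=1).astype(float)
    n = deg.size
    if n < 3:
        raise ValidationError("degree centralization undefined for networks with < 3 nodes")
    centralization = float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))
    mean = deg.mean()
    heterogeneity = float(deg.std() / mean) if mean > 0 else 0.0
    return centralization, heterogeneity


def topology(
    net: nx.Graph,
    all_fragments_count: int | None = None,
    er_reps: int = 0,
    er_seed: int | np.random.Generator = 0,
) -> TopologySummary:
    """Topology panel of a network's undirected simple view.

    Directed networks are collapsed first (reciprocal edge pairs merge into
    one undirected edge). When ``all_fragments_count`` is given, coverage is
    the fraction of all detected fragments present in the network. With
    ``er_reps`` > 0, mean characteristic path length and clustering over that
    many G(n, m) random graphs with matching node/edge counts are included.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("topology undefined for an empty network")
    adj, _ = _undirected_adjacency(net)
    n = adj.shape[0]
    e = int(adj.sum()) // 2
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_neighbors = 2.0 * e / n
    cpl = _cpl(adj)
    cc = _clustering_mean(adj)
    centralization, heterogeneity = _degree_stats(adj)
    coverage = n / all_fragments_count if all_fragments_count else None
    random_cpl = random_cc = None
    if er_reps > 0:
        stats = er_baseline(n, e, n_reps=er_reps, seed=er_seed)
        random_cpl, random_cc = stats.mean_cpl, stats.mean_clustering
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        density=density,
        avg_neighbors=avg_neighbors,
        characteristic_path_length=cpl,
        clustering_coefficient=cc,
        centralization=centralization,
        heterogeneity=heterogeneity,
        coverage=coverage,
        random_cpl=random_cpl,
        random_cc=random_cc,
    )


# ---------------------------------------------------------------------------
# Erdos-Renyi G(n, m) baseline


def er_random_graph(n: int, m: int, seed: int | np.random.Generator) -> nx.Graph:
    """Uniform draw of m distinct edges among all unordered pairs of n nodes."""
    adj, nodes = _er_adjacency(n, m, np.random.default_rng(seed))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(adj, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


def _er_adjacency(n: int, m: int, rng: np.random.Generator) -> tuple[np.ndarray, range]:
    total = n * (n - 1) // 2
    if m > total:
        raise ValidationError(f"cannot place {m} edges among {total} possible pairs")
    chosen = rng.choice(total, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[chosen], ju[chosen]] = True
    adj |= adj.T
    return adj, range(n)


@dataclass(frozen=True)
class ErBaseline:
    mean_cpl: float
    mean_clustering: float
    cpl_values: tuple[float, ...]
    clustering_values: tuple[float, ...]

    @property
    def cpl_sem(self) -> float:
        v = np.asarray(self.cpl_values)
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0

    @property
    def clustering_sem(self) -> float:
        v = np.asarray(self.clustering_values)
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def er_baseline(
    n: int, m: int, n_reps: int = 100, seed: int | np.random.Generator = 0
) -> ErBaseline:
    """Mean CPL and clustering over ``n_reps`` G(n, m) draws."""
    rng = np.random.default_rng(seed)
    cpls, ccs = [], []
    for _ in range(n_reps):
        adj, _ = _er_adjacency(n, m, rng)
        cpls.append(_cpl(adj))
        ccs.append(_clustering_mean(adj))
    return ErBaseline(float(np.mean(cpls)), float(np.mean(ccs)), tuple(cpls), tuple(ccs))


# ---------------------------------------------------------------------------
# modularity


def modularity_q(g: nx.Graph, membership: Mapping[str, int]) -> float:
    """Direct evaluation of Newman's Q = sum_c (e_cc - a_c^2) for a partition."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict[int, int] = {}
    deg_sum: dict[int, int] = {}
    for u, v in g.edges:
        if membership[u] == membership[v]:
            intra[membership[u]] = intra.get(membership[u], 0) + 1
    for node, d in g.degree:
        c = membership[node]
        deg_sum[c] = deg_sum.get(c, 0) + d
    return float(
        sum(intra.get(c, 0) / m - (deg_sum.get(c, 0) / (2 * m)) ** 2 for c in set(membership.values()))
    )


def modularity_partition(net: nx.Graph) -> ModulePartition:
    """Newman fast-greedy modularity partition of the positive-edge subgraph.

    Only edges carrying sign="positive" enter the optimization; unsigned
    graphs (e.g. test fixtures) are used as-is. Modules are numbered from 1
    in decreasing size, ties broken by smallest member id.
    """
    signed = any("sign" in d for _, _, d in net.edges(data=True))
    if signed:
        sub = nx.Graph()
        sub.add_edges_from(
            (u, v) for u, v, d in net.edges(data=True) if d.get("sign") == POSITIVE
        )
    else:
        sub = nx.Graph(net)
    if sub.number_of_edges() == 0:
        raise ValidationError("modularity requires at least one positive edge")
    communities = nx.community.greedy_modularity_communities(sub)
    ordered = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    membership = {node: i + 1 for i, comm in enumerate(ordered) for node in comm}
    q = modularity_q(sub, membership)
    sizes = {i + 1: len(c) for i, c in enumerate(ordered)}
    return ModulePartition(membership=membership, q=q, module_sizes=sizes)


# ---------------------------------------------------------------------------
# degree profiles and hubs


def degree_domain_profile(
    net: nx.Graph, annotations: Mapping[str, FragmentAnnotation]
) -> pd.DataFrame:
    """Per observed degree value: node count and fraction of bacterial nodes."""
    adj, nodes = _undirected_adjacency(net)
    deg = adj.sum(axis=1)
    is_bact = np.array([annotations[n].domain == BACTERIAL for n in nodes])
    rows = []
    for d in sorted(set(deg.tolist())):
        mask = deg == d
        rows.append(
            {
                "degree": int(d),
                "n_nodes": int(mask.sum()),
                "fraction_bacterial": float(is_bact[mask].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["degree", "n_nodes", "fraction_bacterial"])


def hub_roles(
    rnet: nx.DiGraph,
    k: int = 25,
    annotations: Mapping[str, FragmentAnnotation] | None = None,
) -> HubReport:
    """Classify rule-network nodes by exclusive role and rank the hubs.

    ``target_only`` nodes have incoming rules only, ``origin_only`` outgoing
    only; top-k lists rank them by the relevant degree, ties broken by
    fragment id for determinism. Target-only hubs with high in-degree are the
    keystone-species candidates.
    """
    if rnet.number_of_nodes() == 0:
        raise ValidationError("hub analysis requires a non-empty rule network")
    in_deg = dict(rnet.in_degree)
    out_deg = dict(rnet.out_degree)
    roles = {}
    for n in rnet.nodes:
        i, o = in_deg[n], out_deg[n]
        roles[n] = (
            "target_only" if i > 0 and o == 0
            else "origin_only" if o > 0 and i == 0
            else "mixed" if i > 0 and o > 0
            else "isolated"
        )
    target_only = sorted(
        (n for n, r in roles.items() if r == "target_only"), key=lambda n: (-in_deg[n], n)
    )
    origin_only = sorted(
        (n for n, r in roles.items() if r == "origin_only"), key=lambda n: (-out_deg[n], n)
    )
    top_t, top_o = target_only[:k], origin_only[:k]

    def bact_frac(nodes: list[str]) -> float | None:
        if annotations is None or not nodes:
            return None
        return sum(annotations[n].domain == BACTERIAL for n in nodes) / len(nodes)

    return HubReport(
        roles=roles,
        in_degree=in_deg,
        out_degree=out_deg,
        top_targets=top_t,
        top_origins=top_o,
        top_target_bacterial_fraction=bact_frac(top_t),
        top_origin_bacterial_fraction=bact_frac(top_o),
    )


def hub_neighborhood(rnet: nx.DiGraph, cnet: nx.Graph, hub: str) -> HubNeighborhood:
    """Rule neighborhood of a hub with the positive co-occurrence overlay.

    The neighborhood holds the hub plus all rule-adjacent fragments, every
    rule edge among them, and — as the overlay — every positive significant
    co-occurrence edge among those nodes.
    """
    if hub not in rnet:
        raise KeyError(f"hub {hub!r} not in rule network")
    nodes = {hub} | set(rnet.predecessors(hub)) | set(rnet.successors(hub))
    rule_edges = [(u, v) for u, v in rnet.edges if u in nodes and v in nodes]
    overlay = [
        frozenset((u, v))
        for u, v, d in cnet.edges(data=True)
        if u in nodes and v in nodes and d.get("sign") == POSITIVE
    ]
    return HubNeighborhood(
        hub=hub, nodes=sorted(nodes), rule_edges=sorted(rule_edges), overlay_edges=overlay
    )


def rule_cooccurrence_intersection(
    rnet: nx.DiGraph, cnet: nx.Graph
) -> tuple[int, float, list[tuple[str, str]]]:
    """Rules whose unordered fragment pair is also a significant co-occurrence edge.

    Returns (count, fraction of rules, list of those rule edges).
    """
    n_rules = rnet.number_of_edges()
    hits = [(u, v) for u, v in rnet.edges if cnet.has_edge(u, v)]
    fraction = len(hits) / n_rules if n_rules else 0.0
    return len(hits), fraction, sorted(hits)
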