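"""Median-joining haplotype networks and maximum-parsimony post-processing.

The minimum-spanning network (MSN) unites every minimum spanning tree of
the sampled haplotypes under a weighted mutational distance.  The
median-joining (MJ) construction augments it with *median vectors* --
site-wise majority consensus haplotypes of connected triplets, interpretable
as unsampled or extinct intermediates -- whenever adding one shortens the
network.  Maximum-parsimony (MP) post-processing then extracts the
minimum-weighted-length trees spanning all sampled haplotypes (median
vectors act as optional Steiner points) and prunes everything not on such a
tree.

All tie-breaking is lexicographic on node ids; there is no randomness, and
permuting the input order changes node ids at most, never edge structure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx

from .haplotypes import (
    HaploPanel,
    Haplotype,
    intersect_regions,
    is_excluded,
    key_label,
    pairwise_distance,
)
from .sites import ExclusionSet, WeightScheme


@dataclass
class MJParams:
    """Parameters of network construction.

    ``epsilon`` is the weighted tolerance on feasible links: at each merge
    step every cross-component link within ``epsilon`` of the minimal
    connecting distance is added (0 reproduces the strict MSN).
    """

    epsilon: int = 0
    weights: WeightScheme | None = None
    excluded: ExclusionSet | None = None
    merge_contiguous_deletions: bool = True
    max_median_rounds: int = 500
    annotate_sites: tuple[int, ...] = (7697,)

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class NetNode:
    """A network node: a sampled haplotype class or an inferred median."""

    id: str
    haplotype: Haplotype
    sampled: bool = True
    multiplicity: int = 1
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sampled and self.multiplicity != 0:
            raise ValueError("median vectors must have multiplicity 0")


class HaploNetwork:
    """A haplotype network: a weighted, site-labelled undirected graph."""

    def __init__(self, graph: nx.Graph, params: MJParams):
        self.graph = graph
        self.params = params

    def node(self, node_id: str) -> NetNode:
        return self.graph.nodes[node_id]["node"]

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def sampled_ids(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.node(n).sampled)

    @property
    def median_ids(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if not self.node(n).sampled)

    def total_weight(self) -> float:
        return self.graph.size(weight="weight")

    def edge_table(self) -> str:
        """Edge list as TSV: node1, node2, site_labels, weight."""
        lines = ["node1\tnode2\tsite_labels\tweight"]
        for u, v, data in sorted(self.graph.edges(data=True)):
            labels = ",".join(key_label(k) for k in data["keys"])
            lines.append(f"{u}\t{v}\t{labels}\t{data['weight']}")
        return "\n".join(lines) + "\n"

    def to_graphml(self, path: str) -> None:
        g = nx.Graph()
        for n in self.graph.nodes:
            node = self.node(n)
            g.add_node(
                n,
                sampled=node.sampled,
                multiplicity=node.multiplicity,
                variants=",".join(sorted(v.label for v in node.haplotype.variants)),
                **{k: str(v) for k, v in node.annotations.items()},
            )
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                weight=float(data["weight"]),
                site_labels=",".join(key_label(k) for k in data["keys"]),
            )
        nx.write_graphml(g, path)

    def to_dot(self) -> str:
        """Figure-ready DOT export with multiplicity-scaled nodes and state
        fractions at the annotation sites (see ``MJParams.annotate_sites``)."""
        lines = ["graph haplonetwork {", "  node [shape=circle];"]
        for n in self.node_ids:
            node = self.node(n)
            if node.sampled:
                extra = "; ".join(
                    f"{k}={v:.2f}" if isinstance(v, float) else f"{k}={v}"
                    for k, v in sorted(node.annotations.items())
                )
                label = f"{n} (n={node.multiplicity})"
                if extra:
                    label += "\\n" + extra
                lines.append(
                    f'  "{n}" [label="{label}", width={0.3 + 0.12 * node.multiplicity:.2f}];'
                )
            else:
                lines.append(
                    f'  "{n}" [label="", shape=point, width=0.12];'
                )
        for u, v, data in sorted(self.graph.edges(data=True)):
            labels = ",".join(key_label(k) for k in data["keys"])
            lines.append(f'  "{u}" -- "{v}" [label="{labels}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass
class MPTree:
    """A minimum-length (Steiner) tree extracted from a network."""

    graph: nx.Graph
    total_weighted_length: float
    root: str | None = None

    def node(self, node_id: str) -> NetNode:
        return self.graph.nodes[node_id]["node"]

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def sampled_ids(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.node(n).sampled)

    def rooted_at(self, node_id: str) -> "MPTree":
        if node_id not in self.graph:
            raise ValueError(f"root {node_id!r} is not a node of the tree")
        return MPTree(self.graph, self.total_weighted_length, node_id)


# ---------------------------------------------------------------------------
# collapsing and distances


def _coverage_key(h: Haplotype) -> tuple:
    return tuple((r.start, r.end) for r in h.covered_regions)


def _state_signature(h: Haplotype, excluded) -> tuple:
    items = []
    for v in sorted(h.variants, key=lambda v: (v.position, v.kind, v.insert_index)):
        if is_excluded(excluded, v.position, v.kind):
            continue
        items.append((v.position, v.kind, v.insert_index, v.derived_allele))
    return (tuple(items), _coverage_key(h))


def collapse_panel(panel: HaploPanel, params: MJParams) -> list[NetNode]:
    """Group identical haplotypes (over non-excluded sites, with identical
    coverage) into one node each; node id is the lexicographically smallest
    member id and annotations carry state fractions at the annotation sites."""
    groups: dict[tuple, list[Haplotype]] = {}
    for h in panel.haplotypes:
        groups.setdefault(_state_signature(h, params.excluded), []).append(h)
    nodes = []
    for sig, members in groups.items():
        members.sort(key=lambda h: h.id)
        rep = members[0]
        annotations = {}
        for pos in params.annotate_sites:
            derived = ref = unknown = 0
            for m in members:
                if not m.covers(pos):
                    unknown += 1
                elif any(
                    v.position == pos and v.kind == "substitution"
                    for v in m.variants
                ):
                    derived += 1
                else:
                    ref += 1
            n = len(members)
            annotations[f"frac_{pos}_derived"] = derived / n
            annotations[f"frac_{pos}_reference"] = ref / n
            annotations[f"frac_{pos}_unknown"] = unknown / n
        nodes.append(
            NetNode(
                id=rep.id,
                haplotype=rep,
                sampled=True,
                multiplicity=len(members),
                annotations=annotations,
            )
        )
    nodes.sort(key=lambda n: n.id)
    return nodes


def _distances(nodes: list[NetNode], params: MJParams) -> dict[tuple[str, str], float]:
    dist = {}
    for a, b in itertools.combinations(sorted(nodes, key=lambda n: n.id), 2):
        d, _ = pairwise_distance(
            a.haplotype,
            b.haplotype,
            weights=params.weights,
            excluded=params.excluded,
            merge_contiguous_deletions=params.merge_contiguous_deletions,
        )
        dist[(a.id, b.id)] = d
    return dist


def _msn_edge_set(
    node_ids: list[str], dist: dict[tuple[str, str], float], epsilon: float
) -> set[tuple[str, str]]:
    """Feasible links of the minimum-spanning network.

    Kruskal-style: repeatedly take the minimal distance joining two distinct
    components and add *every* cross-component link within ``epsilon`` of it
    (components assessed before any link of the step is added)."""
    parent = {n: n for n in node_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: set[tuple[str, str]] = set()
    while True:
        cross = [
            (d, pair) for pair, d in dist.items() if find(pair[0]) != find(pair[1])
        ]
        if not cross:
            break
        d_min = min(d for d, _ in cross)
        step = sorted(pair for d, pair in cross if d <= d_min + epsilon)
        edges.update(step)
        for a, b in step:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    return edges


def _graph_from(
    nodes: list[NetNode],
    edges: set[tuple[str, str]],
    params: MJParams,
) -> nx.Graph:
    by_id = {n.id: n for n in nodes}
    g = nx.Graph()
    for n in sorted(by_id):
        g.add_node(n, node=by_id[n])
    for a, b in sorted(edges):
        d, keys = pairwise_distance(
            by_id[a].haplotype,
            by_id[b].haplotype,
            weights=params.weights,
            excluded=params.excluded,
            merge_contiguous_deletions=params.merge_contiguous_deletions,
        )
        g.add_edge(a, b, weight=d, keys=tuple(keys))
    return g


def build_msn(panel: HaploPanel, params: MJParams | None = None) -> HaploNetwork:
    """Minimum-spanning network of a panel under the weighted distance."""
    params = params or MJParams()
    nodes = collapse_panel(panel, params)
    if not nodes:
        raise ValueError("empty panel")
    dist = _distances(nodes, params)
    edges = _msn_edge_set([n.id for n in nodes], dist, params.epsilon)
    return HaploNetwork(_graph_from(nodes, edges, params), params)


# ---------------------------------------------------------------------------
# median vectors


def _median_haplotype(
    h1: Haplotype, h2: Haplotype, h3: Haplotype, excluded
) -> Haplotype | None:
    """Site-wise majority consensus of three haplotypes.

    Returns None when some site shows three distinct states (no quasi-median
    generation: control-region data are overwhelmingly biallelic per site).
    """
    triple = (h1, h2, h3)
    keys = set()
    for h in triple:
        for v in h.variants:
            if is_excluded(excluded, v.position, v.kind):
                continue
            keys.add(v.key)
    coverage = intersect_regions(
        intersect_regions(h1.covered_regions, h2.covered_regions),
        h3.covered_regions,
    )
    if not coverage:
        return None
    variants = []
    for key in keys:
        pos = key[0]
        if not all(h.covers(pos) for h in triple):
            # a haplotype with no data at the site cannot vote; skip medians
            # whose state would be guesswork
            return None
        states = [h.by_key().get(key) for h in triple]
        tags = [(v is not None, v.derived_allele if v else "") for v in states]
        winner = None
        for tag in set(tags):
            if tags.count(tag) >= 2:
                winner = tag
                break
        if winner is None:
            return None
        if winner[0]:
            variants.append(next(v for v in states if v is not None and
                                 (True, v.derived_allele) == winner))
    return Haplotype(
        id="median",
        variants=frozenset(variants),
        covered_regions=coverage,
    )


def build_mj(panel: HaploPanel, params: MJParams | None = None) -> HaploNetwork:
    """Median-joining network: MSN iteratively augmented with median vectors.

    Each round proposes the majority consensus of every connected triplet in
    the current MSN and greedily adds the median whose inclusion most
    shortens the network, until no admissible median helps.  The returned
    network is the MSN over the final node set united with the MSN over the
    sampled nodes alone, so it always contains the plain MSN as a subgraph.
    """
    params = params or MJParams()
    sampled = collapse_panel(panel, params)
    if not sampled:
        raise ValueError("empty panel")
    nodes: list[NetNode] = list(sampled)
    dist = _distances(nodes, params)
    sampled_edges = _msn_edge_set([n.id for n in nodes], dist, params.epsilon)

    existing_sigs = {_state_signature(n.haplotype, params.excluded) for n in nodes}
    mv_counter = 0

    def msn_length(ns: list[NetNode]) -> float:
        d = _distances(ns, params)
        e = _msn_edge_set([n.id for n in ns], d, params.epsilon)
        return sum(d[pair] for pair in e), e

    def mst_length(ns: list[NetNode]) -> float:
        # Kruskal over the complete distance graph; the weight is unique even
        # when tie-broken edge choices are not
        d = _distances(ns, params)
        parent = {n.id: n.id for n in ns}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        total = 0.0
        for (a, b), w in sorted(d.items(), key=lambda kv: (kv[1], kv[0])):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
                total += w
        return total

    def distance(h1, h2):
        d, _ = pairwise_distance(
            h1,
            h2,
            weights=params.weights,
            excluded=params.excluded,
            merge_contiguous_deletions=params.merge_contiguous_deletions,
        )
        return d

    for _ in range(params.max_median_rounds):
        _, cur_edges = msn_length(nodes)
        cur_len = mst_length(nodes)
        adj: dict[str, set[str]] = {n.id: set() for n in nodes}
        for a, b in cur_edges:
            adj[a].add(b)
            adj[b].add(a)
        by_id = {n.id: n for n in nodes}
        # candidate medians of connected triplets, with the minimal
        # connection cost d(u,m)+d(v,m)+d(w,m) over proposing triplets
        candidates: dict[tuple, tuple[float, Haplotype]] = {}
        for center in sorted(adj):
            for a, b in itertools.combinations(sorted(adj[center]), 2):
                triplet = (by_id[a], by_id[center], by_id[b])
                med = _median_haplotype(
                    triplet[0].haplotype,
                    triplet[1].haplotype,
                    triplet[2].haplotype,
                    params.excluded,
                )
                if med is None:
                    continue
                sig = _state_signature(med, params.excluded)
                if sig in existing_sigs:
                    continue
                cost = sum(distance(t.haplotype, med) for t in triplet)
                old = candidates.get(sig)
                if old is None or cost < old[0]:
                    candidates[sig] = (cost, med)
        if not candidates:
            break
        lam = min(cost for cost, _ in candidates.values())
        # admit every minimal-cost median whose inclusion does not lengthen
        # the network; they land on shortest connections by construction
        admitted = []
        for sig in sorted(candidates):
            cost, med = candidates[sig]
            if cost > lam + params.epsilon:
                continue
            trial = NetNode(id="mv?", haplotype=med, sampled=False, multiplicity=0)
            if mst_length(nodes + [trial]) <= cur_len:
                admitted.append((sig, med))
        if not admitted:
            break
        for sig, med in admitted:
            mv_counter += 1
            mid = f"mv{mv_counter}"
            nodes.append(
                NetNode(
                    id=mid,
                    haplotype=replace(med, id=mid),
                    sampled=False,
                    multiplicity=0,
                )
            )
            existing_sigs.add(sig)
    else:
        raise RuntimeError(
            f"median-joining did not converge in {params.max_median_rounds} rounds"
        )

    _, final_edges = msn_length(nodes)
    edges = final_edges | sampled_edges
    graph = _graph_from(nodes, edges, params)
    # prune median vectors that ended up pendant or isolated
    while True:
        drop = [
            n
            for n in graph.nodes
            if not graph.nodes[n]["node"].sampled and graph.degree(n) <= 1
        ]
        if not drop:
            break
        graph.remove_nodes_from(drop)
    return HaploNetwork(graph, params)


# ---------------------------------------------------------------------------
# maximum-parsimony extraction


def _tree_weight(g: nx.Graph) -> float:
    return g.size(weight="weight")


def mp_extract(
    net: HaploNetwork, size_cap: int = 25, mode: str = "auto"
) -> tuple[list[MPTree], HaploNetwork, int]:
    """Extract all minimum-weighted-length trees spanning the sampled nodes.

    Median vectors are optional Steiner points: the search enumerates
    subsets of medians, takes minimum spanning trees of each induced
    connected subgraph, and keeps every distinct tree attaining the global
    minimum.  ``pruned`` is the union of all such trees and ``n_trees``
    their count.  Above ``size_cap`` total nodes the exact search is
    refused (``mode="exact"``) or replaced by a documented heuristic with a
    warning (``mode="auto"``/``"heuristic"``): a single minimum spanning
    tree over all nodes with unsampled leaves iteratively pruned.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(g):
        raise ValueError("network is not connected")
    sampled = [n for n in g.nodes if g.nodes[n]["node"].sampled]
    medians = sorted(n for n in g.nodes if not g.nodes[n]["node"].sampled)

    if mode not in ("auto", "exact", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")
    too_big = g.number_of_nodes() > size_cap
    if mode == "exact" and too_big:
        raise ValueError(
            f"network has {g.number_of_nodes()} nodes (> size_cap={size_cap}); "
            "exact Steiner enumeration refused -- use mode='heuristic'"
        )
    if mode == "heuristic" or (mode == "auto" and too_big):
        if mode == "auto":
            warnings.warn(
                f"network has {g.number_of_nodes()} nodes > size_cap={size_cap}; "
                "falling back to the single-MST heuristic (n_trees is a lower bound)"
            )
        t = nx.minimum_spanning_tree(g, weight="weight")
        while True:
            leaves = [
                n
                for n in t.nodes
                if t.degree(n) <= 1 and not t.nodes[n]["node"].sampled
            ]
            if not leaves:
                break
            t.remove_nodes_from(leaves)
        tree = MPTree(t, _tree_weight(t))
        return [tree], HaploNetwork(t.copy(), net.params), 1

    if len(sampled) == 1:
        t = g.subgraph(sampled).copy()
        tree = MPTree(t, 0.0)
        return [tree], HaploNetwork(t.copy(), net.params), 1

    best_w = float("inf")
    per_subset: list[nx.Graph] = []
    for r in range(len(medians) + 1):
        for extra in itertools.combinations(medians, r):
            node_set = sampled + list(extra)
            sub = g.subgraph(node_set)
            if not nx.is_connected(sub):
                continue
            w = _tree_weight(nx.minimum_spanning_tree(sub, weight="weight"))
            if w < best_w:
                best_w = w
            per_subset.append(sub)

    found: dict[frozenset, nx.Graph] = {}
    for sub in per_subset:
        for t in nx.SpanningTreeIterator(sub.copy(), weight="weight", minimum=True):
            w = _tree_weight(t)
            if w > best_w + 1e-9:
                break
            eset = frozenset(frozenset((u, v)) for u, v in t.edges)
            if eset not in found:
                found[eset] = g.edge_subgraph(t.edges).copy()
    trees = [
        MPTree(t, best_w)
        for _, t in sorted(found.items(), key=lambda kv: sorted(map(sorted, kv[0])))
    ]
    union = nx.Graph()
    for t in trees:
        for n in t.graph.nodes:
            union.add_node(n, **g.nodes[n])
        for u, v, data in t.graph.edges(data=True):
            union.add_edge(u, v, **data)
    pruned = HaploNetwork(union, net.params)
    return trees, pruned, len(trees)


def count_back_mutations(tree: MPTree) -> int:
    """Extra state changes beyond a single origin per site on a tree.

    For every differing-site key, each edge labelled with it beyond the
    first implies a recurrent or back mutation; the count sums those
    excesses over all keys.
    """
    counts: dict[tuple, int] = {}
    for _, _, data in tree.graph.edges(data=True):
        for key in data["keys"]:
            counts[key] = counts.get(key, 0) + 1
    return sum(c - 1 for c in counts.values() if c > 1)


def find_nodes_by_motif(graph: nx.Graph, motif_labels: set[str]) -> list[str]:
    """Node ids whose haplotype's variant labels equal ``motif_labels``."""
    want = frozenset(motif_labels)
    return sorted(
        n
        for n in graph.nodes
        if graph.nodes[n]["node"].haplotype.labels() == want
    )
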