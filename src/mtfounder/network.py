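"""Haplotype networks: reduced-median construction and tree resolution.

Haplotypes are encoded as binary presence/absence characters, one per
derived allele per position (multistate sites therefore split into
several binary characters).  The reduced-median construction proceeds in
three steps:

1. *Reduction*: for each pair of incompatible characters (all four
   gametes observed), the rarer character is split into independent
   per-background characters when the frequency ratio reaches the
   reduction parameter ``r`` — i.e. the rarer change is accepted as
   recurrent.  This mirrors the classical reduced-median preprocessing.
2. *Median closure*: the node set is closed under coordinatewise
   majority of triples (bitwise, so this is cheap), which adds the
   inferred median haplotypes; edges connect nodes one mutation apart.
   Remaining character conflicts surface as cycles (reticulations).
3. *Resolution* (:func:`resolve_to_tree`): a minimum-weight Steiner tree
   connecting the observed haplotypes and the designated root is
   extracted from the network.  Character weights implement the
   rate-guided preference — recurrences are assigned to cheap
   (hotspot/high-rate) characters — and near-ties are broken in favour
   of keeping sample-rich nodes intact.

For large datasets an agglomerative builder (:func:`build_tree`) inserts
haplotypes into a growing tree, creating median junction nodes where
lineages diverge; it trades guaranteed parsimony optimality for speed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .haplotype_io import MitoHaplotype, Mutation, PositionConfig

__all__ = [
    "Character",
    "HaploNetwork",
    "RootedHaploTree",
    "RootingError",
    "build_reduced_median",
    "resolve_to_tree",
    "build_tree",
    "export_newick",
]


class RootingError(ValueError):
    """The requested root haplotype cannot be placed in the network."""


@dataclass(frozen=True, order=True)
class Character:
    """A binary presence/absence character: a mutation plus a split tag."""

    mutation: Mutation
    tag: int = 0


class HaploNetwork:
    """Reduced-median network over bitmask-encoded haplotypes."""

    def __init__(self, graph: nx.Graph, chars: list[Character], weights: np.ndarray):
        self.graph = graph
        self.chars = chars
        self.weights = weights  # per-character weight, aligned with chars

    @property
    def total_multiplicity(self) -> int:
        return sum(d.get("multiplicity", 0) for _, d in self.graph.nodes(data=True))

    def node_variants(self, node: int) -> frozenset[Mutation]:
        return frozenset(
            self.chars[i].mutation for i in range(len(self.chars)) if node >> i & 1
        )

    def edge_mutation(self, u: int, v: int) -> Mutation:
        i = (u ^ v).bit_length() - 1
        return self.chars[i].mutation

    def has_reticulation(self) -> bool:
        g = self.graph
        return g.number_of_edges() > g.number_of_nodes() - 1


# ---------------------------------------------------------------------------
# Reduced-median construction
# ---------------------------------------------------------------------------


def _collapse(haps: Sequence[MitoHaplotype]):
    """Group haplotypes by masked substitution profile."""
    groups: dict[frozenset[Mutation], list[MitoHaplotype]] = {}
    for h in haps:
        groups.setdefault(h.substitutions, []).append(h)
    profiles = sorted(groups, key=lambda p: (len(p), sorted(m.token() for m in p)))
    return profiles, groups


def _incompatible(a: frozenset, b: frozenset, universe: int) -> bool:
    """Four-gamete test on carrier sets over ``universe`` haplotypes."""
    return bool(a & b) and bool(a - b) and bool(b - a) and len(a | b) < universe


def _reduce_characters(carriers, weights, r, n_haps):
    """Split rarer members of incompatible character pairs (ratio >= r)."""
    changed = True
    guard = 0
    while changed and guard < 100:
        changed = False
        guard += 1
        keys = sorted(carriers)
        for c1, c2 in itertools.combinations(keys, 2):
            if c1 not in carriers or c2 not in carriers:
                continue
            s1, s2 = carriers[c1], carriers[c2]
            if not _incompatible(s1, s2, n_haps):
                continue
            f1, f2 = len(s1), len(s2)
            if max(f1, f2) < r * min(f1, f2):
                continue
            split, other = (c2, c1) if f2 < f1 else (c1, c2)
            s_split, s_other = carriers[split], carriers[other]
            tag = max(c.tag for c in carriers) + 1
            a = Character(split.mutation, tag)
            b = Character(split.mutation, tag + 1)
            w = weights.pop(split)
            del carriers[split]
            carriers[a] = s_split & s_other
            carriers[b] = s_split - s_other
            weights[a] = weights[b] = w
            changed = True
            break
    return carriers, weights


def _median_closure(nodes: set[int], cap: int) -> set[int]:
    """Close a node set under bitwise majority of triples."""
    frontier = set(nodes)
    while frontier and len(nodes) <= cap:
        new: set[int] = set()
        node_list = sorted(nodes)
        for a in sorted(frontier):
            for b, c in itertools.combinations(node_list, 2):
                m = (a & b) | (a & c) | (b & c)
                if m not in nodes and m not in new:
                    new.add(m)
        if len(nodes) + len(new) > cap:
            warnings.warn(
                "median closure truncated: network may be incomplete", RuntimeWarning
            )
            new = set(sorted(new)[: cap - len(nodes)])
        nodes |= new
        frontier = new
    return nodes


def _geodesic_chain(u: int, v: int) -> list[int]:
    """Intermediate bitmasks flipping differing bits in index order."""
    diff = u ^ v
    chain = []
    cur = u
    bits = [i for i in range(diff.bit_length()) if diff >> i & 1]
    for i in bits[:-1]:
        cur ^= 1 << i
        chain.append(cur)
    return chain


def build_reduced_median(
    haps: Sequence[MitoHaplotype],
    cfg: PositionConfig | None = None,
    r: float = 2.0,
    max_nodes: int = 4096,
    reduction: bool = True,
) -> HaploNetwork:
    """Build a reduced-median network from (already masked) haplotypes.

    With ``reduction=False`` the character-splitting step is skipped and
    the full median closure is returned (the reduction commits rare
    conflicting characters to recurrence up front, which is the right
    display and large-data behaviour but can exclude a minimum tree in
    chained conflicts).
    """
    cfg = cfg or PositionConfig.default()
    profiles, groups = _collapse(haps)
    n = len(profiles)

    # characters with carrier sets (indices into profiles)
    carriers: dict[Character, frozenset[int]] = {}
    by_pos: dict[int, set[str]] = {}
    for mut in sorted({m for p in profiles for m in p}):
        carr = frozenset(i for i, p in enumerate(profiles) if mut in p)
        carriers[Character(mut)] = carr
        by_pos.setdefault(mut.position, set()).add(mut.derived_allele)
    multi = {pos for pos, alleles in by_pos.items() if len(alleles) > 1}
    if multi:
        warnings.warn(
            f"multistate positions split into binary characters: {sorted(multi)}",
            RuntimeWarning,
        )
    weights = {c: cfg.weight(c.mutation.position) for c in carriers}
    if reduction:
        carriers, weights = _reduce_characters(carriers, weights, r, n)

    chars = sorted(carriers)
    w = np.array([weights[c] for c in chars], dtype=float)
    bit = {c: i for i, c in enumerate(chars)}

    observed: dict[int, int] = {}
    for i, prof in enumerate(profiles):
        mask = 0
        for c in chars:
            if i in carriers[c]:
                mask |= 1 << bit[c]
        observed[i] = mask

    nodes = _median_closure(set(observed.values()), cap=max_nodes)

    g = nx.Graph()
    for v in nodes:
        g.add_node(v, multiplicity=0, sample_ids=(), observed=False)
    for i, prof in enumerate(profiles):
        v = observed[i]
        samples = tuple(h.sample_id for h in groups[prof])
        g.nodes[v]["multiplicity"] += len(samples)
        g.nodes[v]["sample_ids"] = g.nodes[v]["sample_ids"] + samples
        g.nodes[v]["observed"] = True
    node_list = sorted(nodes)
    for a, b in itertools.combinations(node_list, 2):
        if (a ^ b).bit_count() == 1:
            i = (a ^ b).bit_length() - 1
            g.add_edge(a, b, weight=w[i], char=i)

    _connect_components(g, w)
    _prune_unobserved_leaves(g)
    return HaploNetwork(g, chars, w)


def _connect_components(g: nx.Graph, w: np.ndarray) -> None:
    """Chain-connect components along canonical geodesics if needed."""
    comps = list(nx.connected_components(g))
    while len(comps) > 1:
        base = comps[0]
        best = None
        for other in comps[1:]:
            for u in sorted(base):
                for v in sorted(other):
                    d = (u ^ v).bit_count()
                    if best is None or d < best[0]:
                        best = (d, u, v)
        _, u, v = best
        prev = u
        for mid in _geodesic_chain(u, v) + [v]:
            if mid not in g:
                g.add_node(mid, multiplicity=0, sample_ids=(), observed=False)
            i = (prev ^ mid).bit_length() - 1
            g.add_edge(prev, mid, weight=w[i], char=i)
            prev = mid
        comps = list(nx.connected_components(g))


def _prune_unobserved_leaves(g: nx.Graph) -> None:
    while True:
        drop = [
            v for v, d in g.nodes(data=True)
            if not d["observed"] and g.degree(v) <= 1
        ]
        if not drop:
            return
        g.remove_nodes_from(drop)


# ---------------------------------------------------------------------------
# Rooted tree
# ---------------------------------------------------------------------------


class RootedHaploTree:
    """Tree of haplotypes with directed edges away from the root.

    Nodes are opaque string labels; each carries ``variants`` (the
    haplotype's mutation set), ``multiplicity`` and ``sample_ids``.
    Edges carry ``mutations`` — the tuple of mutations separating the
    endpoints (length >= 1).
    """

    def __init__(self, graph: nx.DiGraph, root: str):
        self.graph = graph
        self.root = root
        self.sample_node: dict[str, str] = {}
        for v, d in graph.nodes(data=True):
            for sid in d.get("sample_ids", ()):
                self.sample_node[sid] = v
        self._depth: dict[str, int] | None = None

    @property
    def n_samples(self) -> int:
        return sum(d.get("multiplicity", 0) for _, d in self.graph.nodes(data=True))

    def parent(self, node: str) -> str | None:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def depth(self, node: str) -> int:
        """Number of mutations on the root -> node path."""
        if self._depth is None:
            self._depth = {self.root: 0}
            for u, v in nx.bfs_edges(self.graph, self.root):
                self._depth[v] = self._depth[u] + len(self.graph.edges[u, v]["mutations"])
        return self._depth[node]

    def path_nodes(self, node: str) -> list[str]:
        """Nodes on the root -> node path, root first."""
        path = [node]
        while (p := self.parent(path[-1])) is not None:
            path.append(p)
        return path[::-1]

    def subtended_counts(self, counts: dict[str, int]) -> dict[str, int]:
        """Sum per-node counts over each subtree (post-order)."""
        out = {v: counts.get(v, 0) for v in self.graph.nodes}
        for v in reversed(list(nx.topological_sort(self.graph))):
            for c in self.graph.successors(v):
                out[v] += out[c]
        return out

    def is_binary_consistent(self) -> bool:  # pragma: no cover - debug aid
        return nx.is_arborescence(self.graph)


def _finalize_tree(
    und: nx.Graph, root_key, label_of, variants_of
) -> RootedHaploTree:
    """Orient an undirected tree away from the root and relabel nodes."""
    dg = nx.DiGraph()
    names = {}
    obs_i = med_i = 0
    order = [root_key] + [v for _, v in nx.bfs_edges(und, root_key)]
    for key in order:
        d = und.nodes[key]
        if d.get("sample_ids"):
            obs_i += 1
            name = label_of(key) or f"H{obs_i}"
        else:
            med_i += 1
            name = label_of(key) or f"m{med_i}"
        names[key] = name
        dg.add_node(
            name,
            variants=variants_of(key),
            multiplicity=d.get("multiplicity", 0),
            sample_ids=tuple(d.get("sample_ids", ())),
            observed=bool(d.get("observed")),
        )
    for u, v in nx.bfs_edges(und, root_key):
        muts = und.edges[u, v].get("mutations")
        if muts is None:
            muts = tuple(sorted(variants_of(u) ^ variants_of(v)))
        dg.add_edge(names[u], names[v], mutations=tuple(muts))
    return RootedHaploTree(dg, names[root_key])


# ---------------------------------------------------------------------------
# Steiner-tree resolution of reticulations
# ---------------------------------------------------------------------------


def _steiner_exact(g: nx.Graph, costs: dict, terminals: list[int]) -> nx.Graph:
    """Dreyfus–Wagner minimum Steiner tree (exact, small instances)."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    for u, v in g.edges:
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        data += [costs[u, v], costs[u, v]]
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    dist, pred = dijkstra(adj, directed=False, return_predecessors=True)

    t = len(terminals)
    tidx = [idx[v] for v in terminals]
    full = (1 << t) - 1
    INF = np.inf
    dp = np.full((1 << t, n), INF)
    back: dict[tuple[int, int], tuple] = {}
    for i, ti in enumerate(tidx):
        dp[1 << i] = dist[ti]
        # walking from the terminal itself
    for S in range(1, full + 1):
        if S.bit_count() <= 1:
            continue
        merged = np.full(n, INF)
        sub = (S - 1) & S
        while sub:
            T = sub
            U = S ^ T
            if T < U:  # each unordered split once
                cand = dp[T] + dp[U]
                better = cand < merged
                if better.any():
                    for v in np.nonzero(better)[0]:
                        merged[v] = cand[v]
                        back[(S, v)] = ("merge", T, v)
            sub = (sub - 1) & S
        # relax through the metric: dp[S][v] = min_u merged[u] + dist[u][v]
        total = merged[:, None] + dist
        u_best = np.argmin(total, axis=0)
        vals = total[u_best, np.arange(n)]
        dp[S] = vals
        for v in range(n):
            u = int(u_best[v])
            if u != v and np.isfinite(vals[v]):
                back[(S, v)] = ("walk", u, back.get((S, u), ("merge", None, u)))

    # choose root of reconstruction at terminal 0
    v0 = tidx[0]
    edges: set[tuple[int, int]] = set()

    def add_path(a: int, b: int):
        while b != a:
            p = pred[a, b]
            edges.add((min(p, b), max(p, b)))
            b = p

    def rec(S: int, v: int):
        if S.bit_count() == 1:
            ti = tidx[(S.bit_length() - 1)]
            add_path(ti, v)
            return
        entry = back.get((S, v))
        if entry is None:
            return
        if entry[0] == "walk":
            u = entry[1]
            add_path(u, v)
            rec(S, u)
        else:
            T, u = entry[1], entry[2]
            rec(T, u)
            rec(S ^ T, u)

    rec(full, v0)
    tree = nx.Graph()
    tree.add_nodes_from((v, g.nodes[nodes[idx[v]]]) for v in g.nodes if False)
    for i, j in edges:
        u, v = nodes[i], nodes[j]
        tree.add_node(u, **g.nodes[u])
        tree.add_node(v, **g.nodes[v])
        tree.add_edge(u, v, **g.edges[u, v])
    if not tree.nodes:  # single-terminal degenerate case
        v = terminals[0]
        tree.add_node(v, **g.nodes[v])
    return tree


def resolve_to_tree(
    net: HaploNetwork,
    cfg: PositionConfig | None = None,
    root_hint: MitoHaplotype | None = None,
    exact_limit: int = 11,
) -> RootedHaploTree:
    """Resolve a network to a rooted tree.

    Reticulations are resolved by extracting a minimum-weight Steiner
    tree over the network graph: recurrent changes land on the cheaper
    (down-weighted, high-rate) characters, and a small multiplicity
    bonus breaks exact ties in favour of sample-rich nodes.  Dropped
    network edges are recorded in ``tree.graph.graph["dropped_edges"]``
    for audit.
    """
    g = net.graph.copy()
    chars, w = net.chars, net.weights

    root_mask = _insert_root(g, net, root_hint)

    terminals = sorted(
        {v for v, d in g.nodes(data=True) if d["observed"]} | {root_mask}
    )
    total_mult = sum(d["multiplicity"] for _, d in g.nodes(data=True)) or 1
    eps = 1e-7 / (2 * total_mult)

    def edge_costs(graph):
        out = {}
        for u, v, d in graph.edges(data=True):
            bonus = (
                graph.nodes[u].get("multiplicity", 0)
                + graph.nodes[v].get("multiplicity", 0)
            )
            out[u, v] = out[v, u] = d["weight"] - eps * bonus
        return out

    costs = edge_costs(g)

    if len(chars) <= 10 and len(terminals) <= exact_limit:
        # search the full character hypercube: the optimum may require
        # Steiner points outside the median closure (even a tree-shaped
        # closure need not be minimal)
        cube = _hypercube_graph(g, chars, w)
        tree_und = _steiner_exact(cube, edge_costs(cube), terminals)
    elif g.number_of_edges() == g.number_of_nodes() - 1:
        tree_und = g  # already a tree
    elif len(terminals) <= exact_limit and g.number_of_nodes() <= 700:
        tree_und = _steiner_exact(g, costs, terminals)
    else:
        h = nx.Graph()
        h.add_nodes_from(g.nodes(data=True))
        for (u, v), c in list(costs.items()):
            if u < v:
                h.add_edge(u, v, weight=c, **{k: d for k, d in g.edges[u, v].items() if k != "weight"})
        tree_und = nx.minimum_spanning_tree(h)
        for v, d in g.nodes(data=True):  # restore attrs
            tree_und.nodes[v].update(d)
        _prune_unobserved_leaves_keep(tree_und, keep={root_mask})

    for v, d in g.nodes(data=True):
        if v in tree_und:
            tree_und.nodes[v].update(d)
    dropped = [
        (u, v, net.chars[d["char"]].mutation.token())
        for u, v, d in net.graph.edges(data=True)
        if u in tree_und and v in tree_und and not tree_und.has_edge(u, v)
    ]

    def variants_of(mask: int) -> frozenset[Mutation]:
        return frozenset(
            chars[i].mutation for i in range(len(chars)) if mask >> i & 1
        )

    for u, v in tree_und.edges:
        i = (u ^ v).bit_length() - 1
        tree_und.edges[u, v]["mutations"] = (chars[i].mutation,)

    tree = _finalize_tree(tree_und, root_mask, lambda k: None, variants_of)
    tree.graph.graph["dropped_edges"] = dropped
    return tree


def _hypercube_graph(g: nx.Graph, chars, w) -> nx.Graph:
    """The full binary hypercube over the character set, carrying the
    network's node attributes where nodes coincide."""
    s = len(chars)
    cube = nx.Graph()
    for v in range(1 << s):
        attrs = g.nodes[v] if v in g else {
            "multiplicity": 0, "sample_ids": (), "observed": False,
        }
        cube.add_node(v, **attrs)
    for v in range(1 << s):
        for i in range(s):
            u = v | (1 << i)
            if u != v:
                cube.add_edge(v, u, weight=w[i], char=i)
    return cube


def _prune_unobserved_leaves_keep(g: nx.Graph, keep: set) -> None:
    while True:
        drop = [
            v for v, d in g.nodes(data=True)
            if not d.get("observed") and v not in keep and g.degree(v) <= 1
        ]
        if not drop:
            return
        g.remove_nodes_from(drop)


def _insert_root(g: nx.Graph, net: HaploNetwork, root_hint) -> int:
    """Locate or insert the root haplotype in the network graph."""
    chars, w = net.chars, net.weights
    if root_hint is None:
        root_vars: frozenset[Mutation] = frozenset()
    else:
        root_vars = root_hint.substitutions
    known = {c.mutation for c in chars}
    if not root_vars <= known:
        raise RootingError(
            f"root haplotype carries mutations absent from the network: "
            f"{sorted(m.token() for m in root_vars - known)}"
        )
    # bitmask: for split characters prefer the lowest tag
    mask = 0
    for mut in root_vars:
        cands = [i for i, c in enumerate(chars) if c.mutation == mut]
        mask |= 1 << cands[0]
    if mask in g:
        return mask
    # chain-connect to the nearest node
    best = min(g.nodes, key=lambda v: ((v ^ mask).bit_count(), v))
    g.add_node(mask, multiplicity=0, sample_ids=(), observed=False)
    prev = mask
    for mid in _geodesic_chain(mask, best) + [best]:
        if mid not in g:
            g.add_node(mid, multiplicity=0, sample_ids=(), observed=False)
        i = (prev ^ mid).bit_length() - 1
        if not g.has_edge(prev, mid):
            g.add_edge(prev, mid, weight=w[i], char=i)
        prev = mid
    return mask


# ---------------------------------------------------------------------------
# Scalable agglomerative builder
# ---------------------------------------------------------------------------


def _build_tree_joining(
    haps: Sequence[MitoHaplotype],
    cfg: PositionConfig,
    root_hint: MitoHaplotype | None,
) -> RootedHaploTree:
    root_vars: frozenset[Mutation] = (
        root_hint.substitutions if root_hint is not None else frozenset()
    )
    profiles, groups = _collapse(haps)

    und = nx.Graph()
    und.add_node(root_vars, multiplicity=0, sample_ids=(), observed=False)

    order = sorted(profiles, key=lambda p: (len(p ^ root_vars), sorted(m.token() for m in p)))
    for prof in order:
        samples = tuple(h.sample_id for h in groups[prof])
        if prof in und:
            d = und.nodes[prof]
            d["multiplicity"] += len(samples)
            d["sample_ids"] = d["sample_ids"] + samples
            d["observed"] = True
            continue
        # nearest existing node
        c = min(
            und.nodes,
            key=lambda v: (
                len(v ^ prof),
                -und.nodes[v]["multiplicity"],
                sorted(m.token() for m in v),
            ),
        )
        # junction improvement: median with each neighbour segment
        best_m, best_v, best_d = None, None, len(c ^ prof)
        for v in und.neighbors(c):
            m = (c & v) | (c & prof) | (v & prof)
            if m != c and m != v and len(m ^ prof) < best_d:
                best_m, best_v, best_d = m, v, len(m ^ prof)
        if best_m is not None:
            und.remove_edge(c, best_v)
            if best_m not in und:
                und.add_node(best_m, multiplicity=0, sample_ids=(), observed=False)
            und.add_edge(c, best_m)
            und.add_edge(best_m, best_v)
            attach = best_m
        else:
            attach = c
        und.add_node(prof, multiplicity=len(samples), sample_ids=samples, observed=True)
        if attach != prof:
            und.add_edge(attach, prof)
        else:  # profile coincided with a junction median
            d = und.nodes[prof]
            d["multiplicity"] = len(samples)
            d["sample_ids"] = samples
            d["observed"] = True

    return _finalize_tree(und, root_vars, lambda k: None, lambda k: k)


def build_tree(
    haps: Sequence[MitoHaplotype],
    cfg: PositionConfig | None = None,
    root_hint: MitoHaplotype | None = None,
    method: str = "auto",
    r: float = 2.0,
) -> RootedHaploTree:
    """Build a rooted haplotype tree from masked haplotypes.

    ``method="exact"`` runs reduced-median construction plus exact
    Steiner resolution; ``"joining"`` uses the agglomerative builder;
    ``"auto"`` picks exact for small inputs (<= 24 distinct haplotypes).
    """
    cfg = cfg or PositionConfig.default()
    n_unique = len({h.substitutions for h in haps})
    if method == "auto":
        method = "exact" if n_unique <= 24 else "joining"
    if method == "exact":
        # resolve without the reduction step: its early recurrence
        # commitments can exclude a minimum-parsimony tree
        net = build_reduced_median(haps, cfg, r=r, reduction=False)
        return resolve_to_tree(net, cfg, root_hint)
    if method == "joining":
        return _build_tree_joining(haps, cfg, root_hint)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_newick(tree: RootedHaploTree, include_mutations: bool = False) -> str:
    """Serialise a resolved tree as newick.

    Branch lengths are mutation counts; node comments carry haplotype
    multiplicities (``[&mult=N]``) and, optionally, the mutations on the
    subtending branch.
    """
    g = tree.graph

    def fmt(node: str, blen: int | None, muts) -> str:
        children = sorted(g.successors(node))
        label = node
        mult = g.nodes[node].get("multiplicity", 0)
        comment = f"[&mult={mult}" + (
            f",muts={'/'.join(m.token() for m in muts)}]" if include_mutations and muts else "]"
        )
        inner = (
            "(" + ",".join(
                fmt(c, len(g.edges[node, c]["mutations"]), g.edges[node, c]["mutations"])
                for c in children
            ) + ")"
            if children
            else ""
        )
        out = f"{inner}{label}{comment}"
        if blen is not None:
            out += f":{blen}"
        return out

    return fmt(tree.root, None, ()) + ";"


def export_edge_list(tree: RootedHaploTree) -> str:
    """Tab-separated parent/child/mutation lines for graph tooling."""
    lines = ["parent\tchild\tmutations\tchild_multiplicity"]
    for u, v, d in tree.graph.edges(data=True):
        muts = "/".join(m.token() for m in d["mutations"])
        lines.append(f"{u}\t{v}\t{muts}\t{tree.graph.nodes[v]['multiplicity']}")
    return "\n".join(lines) + "\n"
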