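"""Parsimony-based recurrent-mutation (homoplasy) filter.

On a non-recombining locus every SNP is expected to mutate once on the
genealogy; sites whose minimum number of changes on a maximum-parsimony tree
exceeds two, with every change on a terminal branch, are flagged as likely
sequencing errors and removed.

The tree is stored rooted-binary (the root is a virtual degree-2 node placed
on an edge), which represents an unrooted binary topology; all parsimony
counts are rooting-invariant.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .haplotype_io import HaplotypeMatrix

__all__ = [
    "PhyloTree",
    "SiteMutationProfile",
    "build_parsimony_tree",
    "count_site_changes",
    "filter_recurrent_sites",
    "parsimony_length",
    "enumerate_unrooted_topologies",
]


class SiteMutationProfile(NamedTuple):
    position: int
    min_changes: int
    all_terminal: bool


@dataclasses.dataclass
class PhyloTree:
    """Rooted-binary tree over the matrix samples (leaves 0..n-1)."""

    parent: np.ndarray  # int64; parent[root] == -1
    leaf_labels: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.n_leaves = len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch

    def postorder(self) -> np.ndarray:
        """Node order in which every child precedes its parent."""
        ch = self.children()
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(ch[v])
        return np.array(order[::-1], dtype=np.int64)

    def newick(self) -> str:
        ch = self.children()

        def fmt(v: int) -> str:
            if not ch[v]:
                return self.leaf_labels[v]
            return "(" + ",".join(fmt(c) for c in ch[v]) + ")"

        return fmt(self.root) + ";"

    @classmethod
    def from_genealogy(cls, genealogy) -> "PhyloTree":
        return cls(
            parent=np.asarray(genealogy.parent, dtype=np.int64),
            leaf_labels=list(genealogy.leaf_labels),
        )


# ---------------------------------------------------------------------------
# Fitch parsimony (two-state, vectorized across sites)
# ---------------------------------------------------------------------------

def _leaf_state_sets(genotypes: np.ndarray) -> np.ndarray:
    """Bitmask state sets: 1 = {0}, 2 = {1}, 3 = {0,1} (missing)."""
    sets = np.full(genotypes.shape, 3, dtype=np.uint8)
    sets[genotypes == 0] = 1
    sets[genotypes == 1] = 2
    return sets


def _fitch_down_pass(
    tree: PhyloTree, genotypes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return per-node state sets and per-site minimum change counts."""
    n_nodes, n_leaves = tree.n_nodes, tree.n_leaves
    n_sites = genotypes.shape[1]
    sets = np.zeros((n_nodes, n_sites), dtype=np.uint8)
    sets[:n_leaves] = _leaf_state_sets(genotypes)
    changes = np.zeros(n_sites, dtype=np.int64)
    ch = tree.children()
    for v in tree.postorder():
        kids = ch[v]
        if not kids:
            continue
        acc = sets[kids[0]].copy()
        for c in kids[1:]:
            inter = acc & sets[c]
            union = acc | sets[c]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, union, inter)
        sets[v] = acc
    return sets, changes


def parsimony_length(tree: PhyloTree, m: HaplotypeMatrix) -> int:
    """Total Fitch parsimony length over all sites."""
    _, changes = _fitch_down_pass(tree, m.genotypes)
    return int(changes.sum())


def count_site_changes(
    tree: PhyloTree, m: HaplotypeMatrix
) -> list[SiteMutationProfile]:
    """Per-site minimum change counts plus a terminal/internal classification.

    A single canonical most-parsimonious reconstruction is fixed by the
    down-pass tie rule (ambiguous state sets resolve to state 0); a site is
    ``all_terminal`` only if every change in that reconstruction lies on a
    branch whose child is a leaf.
    """
    if tree.n_leaves != m.n_samples or tree.leaf_labels != m.sample_ids:
        raise ValueError("tree leaves do not match matrix samples")
    sets, min_changes = _fitch_down_pass(tree, m.genotypes)
    # canonical up-pass: prefer the parent's state, else state 0 if available
    n_nodes = tree.n_nodes
    n_sites = m.n_sites
    state = np.zeros((n_nodes, n_sites), dtype=np.uint8)
    preferred = np.where(sets & 1, 0, 1).astype(np.uint8)  # 0 when allowed
    order = tree.postorder()[::-1]  # preorder
    root = tree.root
    state[root] = preferred[root]
    parent = tree.parent
    for v in order:
        p = parent[v]
        if p < 0:
            continue
        ps = state[p]
        in_set = (sets[v] >> ps) & 1  # parent state available at v?
        state[v] = np.where(in_set.astype(bool), ps, preferred[v])
    is_leaf = np.zeros(n_nodes, dtype=bool)
    is_leaf[: tree.n_leaves] = True
    change = np.zeros(n_sites, dtype=np.int64)
    internal_change = np.zeros(n_sites, dtype=bool)
    for v in range(n_nodes):
        p = parent[v]
        if p < 0:
            continue
        diff = state[v] != state[p]
        change += diff
        if not is_leaf[v]:
            internal_change |= diff
    # the canonical reconstruction realizes the Fitch minimum
    assert np.array_equal(change, min_changes), "reconstruction not parsimonious"
    return [
        SiteMutationProfile(
            position=site.position,
            min_changes=int(min_changes[j]),
            all_terminal=bool(min_changes[j] > 0 and not internal_change[j]),
        )
        for j, site in enumerate(m.sites)
    ]


def filter_recurrent_sites(
    m: HaplotypeMatrix, profiles: Sequence[SiteMutationProfile]
) -> tuple[HaplotypeMatrix, pd.DataFrame]:
    """Drop sites that mutated more than twice, and only on terminal branches."""
    by_pos = {p.position: p for p in profiles}
    missing = [s.position for s in m.sites if s.position not in by_pos]
    if missing:
        raise ValueError(f"profiles missing for positions {missing[:5]}")
    removed = np.array(
        [
            by_pos[s.position].min_changes > 2 and by_pos[s.position].all_terminal
            for s in m.sites
        ]
    )
    report = pd.DataFrame(
        {
            "position": [s.position for s in m.sites],
            "min_changes": [by_pos[s.position].min_changes for s in m.sites],
            "all_terminal": [by_pos[s.position].all_terminal for s in m.sites],
            "removed": removed,
        }
    )
    return m.take_sites(np.flatnonzero(~removed)), report


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def _adjacency_to_tree(
    adj: dict[int, set[int]], n_leaves: int, leaf_labels: list[str]
) -> PhyloTree:
    """Root an unrooted adjacency on the edge next to leaf 0."""
    internal_ids = sorted(i for i in adj if i >= n_leaves)
    remap = {i: i for i in range(n_leaves)}
    remap.update({old: n_leaves + k for k, old in enumerate(internal_ids)})
    n_nodes = n_leaves + len(internal_ids) + 1  # + virtual root
    root = n_nodes - 1
    parent = np.full(n_nodes, -2, dtype=np.int64)
    parent[root] = -1
    nbr = next(iter(adj[0]))
    parent[0] = root
    parent[remap[nbr]] = root
    stack = [(nbr, 0)]
    while stack:
        v, came_from = stack.pop()
        for w in adj[v]:
            if w != came_from and parent[remap[w]] == -2:
                parent[remap[w]] = remap[v]
                stack.append((w, v))
    return PhyloTree(parent=parent, leaf_labels=leaf_labels)


def _tree_to_adjacency(tree: PhyloTree) -> dict[int, set[int]]:
    """Unrooted adjacency; the degree-2 root is suppressed."""
    adj: dict[int, set[int]] = {v: set() for v in range(tree.n_nodes)}
    for v, p in enumerate(tree.parent):
        if p >= 0:
            adj[v].add(int(p))
            adj[int(p)].add(v)
    root = tree.root
    if len(adj[root]) == 2:
        a, b = adj[root]
        adj[a].discard(root)
        adj[b].discard(root)
        adj[a].add(b)
        adj[b].add(a)
        del adj[root]
    return adj


def enumerate_unrooted_topologies(n_leaves: int):
    """Yield every unrooted binary topology on leaves 0..n-1 as an adjacency.

    Built by sequentially attaching leaf k to each edge of each partial
    topology; there are (2k-5)!! topologies for k leaves.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")

    def edges(adj):
        return [(u, v) for u in adj for v in adj[u] if u < v]

    def clone(adj):
        return {u: set(vs) for u, vs in adj.items()}

    base = {0: {n_leaves}, 1: {n_leaves}, 2: {n_leaves}, n_leaves: {0, 1, 2}}
    partials = [base]
    for k in range(3, n_leaves):
        new_partials = []
        for adj in partials:
            for (u, v) in edges(adj):
                a = clone(adj)
                w = max(a) + 1
                a[u].discard(v)
                a[v].discard(u)
                a[u].add(w)
                a[v].add(w)
                a[w] = {u, v, k}
                a[k] = {w}
                new_partials.append(a)
        partials = new_partials
    yield from partials


def _nj_start(m: HaplotypeMatrix) -> dict[int, set[int]]:
    """Neighbor-joining start topology from pairwise Hamming distances."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    G = m.genotypes
    obs = G >= 0
    Gf = np.where(obs, G, 0).astype(np.float64)
    of = obs.astype(np.float64)
    # pairwise count of differing sites among mutually observed sites
    both = of @ of.T
    same = Gf @ Gf.T + (of - Gf) @ (of - Gf).T
    dist = both - same
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    ids = [str(i) for i in range(m.n_samples)]
    tree = nj(SkbioDM(dist, ids))
    adj: dict[int, set[int]] = {}
    counter = [m.n_samples]
    node_id: dict[int, int] = {}

    def get_id(node) -> int:
        key = id(node)
        if key not in node_id:
            if node.is_tip():
                node_id[key] = int(node.name)
            else:
                node_id[key] = counter[0]
                counter[0] += 1
        return node_id[key]

    for node in tree.traverse(include_self=True):
        u = get_id(node)
        adj.setdefault(u, set())
        for child in node.children:
            v = get_id(child)
            adj.setdefault(v, set())
            adj[u].add(v)
            adj[v].add(u)
    # suppress any degree-2 nodes (skbio roots the NJ tree)
    for u in [u for u, vs in adj.items() if len(vs) == 2]:
        a, b = adj[u]
        adj[a].discard(u)
        adj[b].discard(u)
        adj[a].add(b)
        adj[b].add(a)
        del adj[u]
    return adj


def _nni_neighbors(adj: dict[int, set[int]], u: int, v: int):
    """The two NNI rearrangements around internal edge (u, v)."""
    a, b = [x for x in adj[u] if x != v]
    c, d = [x for x in adj[v] if x != u]
    for swap_u, swap_v in ((a, c), (a, d)):
        new = {x: set(ys) for x, ys in adj.items()}
        new[u].discard(swap_u)
        new[v].discard(swap_v)
        new[swap_u].discard(u)
        new[swap_v].discard(v)
        new[u].add(swap_v)
        new[swap_v].add(u)
        new[v].add(swap_u)
        new[swap_u].add(v)
        yield new


def build_parsimony_tree(
    m: HaplotypeMatrix,
    seed: int = 0,
    method: str = "auto",
    max_nni_rounds: int = 10,
) -> PhyloTree:
    """Maximum-parsimony tree search.

    For up to 8 leaves every unrooted topology is scored (the returned tree
    attains the exact minimum).  For larger matrices a neighbor-joining start
    is refined by nearest-neighbor-interchange hill climbing; the search is
    deterministic given the input (``seed`` is accepted for interface
    stability).
    """
    n = m.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to build a tree")
    if method == "auto":
        method = "exhaustive" if n <= 8 else "heuristic"
    if method == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive search is limited to small trees")
        best_tree, best_len = None, None
        for adj in enumerate_unrooted_topologies(n):
            tree = _adjacency_to_tree(adj, n, list(m.sample_ids))
            length = parsimony_length(tree, m)
            if best_len is None or length < best_len:
                best_tree, best_len = tree, length
        return best_tree
    # heuristic: NJ + NNI
    adj = _nj_start(m)
    tree = _adjacency_to_tree(adj, n, list(m.sample_ids))
    best_len = parsimony_length(tree, m)
    for _ in range(max_nni_rounds):
        improved = False
        internal_edges = [
            (u, v)
            for u in sorted(adj)
            for v in sorted(adj[u])
            if u < v and u >= n and v >= n
        ]
        for (u, v) in internal_edges:
            if v not in adj.get(u, ()):  # edge gone after an accepted swap
                continue
            for cand in _nni_neighbors(adj, u, v):
                cand_tree = _adjacency_to_tree(cand, n, list(m.sample_ids))
                cand_len = parsimony_length(cand_tree, m)
                if cand_len < best_len:
                    adj, best_len = cand, cand_len
                    improved = True
                    break
        if not improved:
            break
    return _adjacency_to_tree(adj, n, list(m.sample_ids))


def write_removal_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
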