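"""Neighbor-joining trees and parsimony diagnostics for alignment comparison.

These are the per-alignment tree statistics used to judge how well each
alignment supports grouping: the NJ tree and its branch-length sum (minimum
evolution score), the Fitch parsimony tree length with consistency and
retention indices, and the g1 skewness of the tree-length distribution over
random topologies (strongly negative g1 = phylogenetic signal; ~0 = noise).

Conventions: gaps and ambiguity codes are missing data and contribute no
constraint at a site; negative NJ branch-length estimates are clamped to zero
(the count of clamped branches is recorded); CI/RI are computed over all
sites, with a flag to exclude parsimony-uninformative ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import MISSING_CODE, MultipleAlignment
from .distances import DistanceMatrix

__all__ = [
    "UnrootedTree",
    "ParsimonyScores",
    "G1Result",
    "MEScore",
    "IncompleteMatrixError",
    "nj_tree",
    "fitch_scores",
    "g1_statistic",
    "me_score",
]

_FULL_SET = np.uint8(0b1111)  # {A, C, G, T}


class IncompleteMatrixError(ValueError):
    """NJ requires every pairwise distance to be defined."""


@dataclass(frozen=True)
class UnrootedTree:
    """Unrooted binary tree over integer nodes.

    Nodes ``0 .. len(leaf_names)-1`` are the leaves (in ``leaf_names`` order);
    higher indices are internal (degree 3).  ``n_clamped`` counts branches
    whose NJ length estimate was negative and was clamped to zero.
    """

    leaf_names: tuple[str, ...]
    edges: tuple[tuple[int, int, float], ...]
    n_clamped: int = 0

    def __post_init__(self) -> None:
        for u, v, w in self.edges:
            if w < 0:
                raise ValueError("branch lengths must be non-negative (clamp first)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def total_length(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in self.edges:
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        return adj

    def rooted_children(self) -> tuple[int, dict[int, list[int]]]:
        """Root the tree by subdividing its first edge; returns (root, children).

        The synthetic root has exactly two children, every other internal node
        two as well — so small-parsimony passes see a strictly binary tree.
        """
        adj = {u: [v for v, _ in nb] for u, nb in self.adjacency().items()}
        u0, v0, _ = self.edges[0]
        root = max(adj) + 1
        adj[u0] = [x for x in adj[u0] if x != v0] + [root]
        adj[v0] = [x for x in adj[v0] if x != u0] + [root]
        adj[root] = [u0, v0]
        children: dict[int, list[int]] = {}
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            kids = [x for x in adj[node] if x != parent]
            children[node] = kids
            for k in kids:
                stack.append((k, node))
        return root, children

    def leaf_distances(self) -> np.ndarray:
        """Patristic (path-length) distances between all leaf pairs."""
        adj = self.adjacency()
        n = self.n_leaves
        out = np.zeros((n, n))
        for src in range(n):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nb, w in adj[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + w
                        stack.append(nb)
            for leaf in range(n):
                out[src, leaf] = dist[leaf]
        return out

    def to_newick(self) -> str:
        root, children = self.rooted_children()
        length = {}
        for u, v, w in self.edges:
            length[(u, v)] = length[(v, u)] = w
        u0, v0, w0 = self.edges[0]
        length[(root, u0)] = length[(u0, root)] = w0 / 2.0
        length[(root, v0)] = length[(v0, root)] = w0 / 2.0

        def rec(node: int, parent: int) -> str:
            if node < self.n_leaves:
                label = self.leaf_names[node]
            else:
                kids = ",".join(rec(k, node) for k in children[node])
                label = f"({kids})"
            if parent < 0:
                return label
            return f"{label}:{length[(parent, node)]:.10g}"

        return rec(root, -1) + ";"


@dataclass(frozen=True)
class ParsimonyScores:
    """Fitch tree length with homoplasy indices.

    ``tree_length`` is the total number of substitutions S implied by the
    topology; ``min_steps`` (M) and ``max_steps`` (G) the per-site minima and
    maxima summed over sites; ``ci = M/S`` and ``ri = (G-S)/(G-M)``.
    """

    tree_length: int
    min_steps: int
    max_steps: int
    ci: float
    ri: float


@dataclass(frozen=True)
class G1Result:
    """Tree-length distribution over uniformly random topologies.

    ``g1`` is the sample skewness (third central moment over cubed standard
    deviation); ``degenerate`` marks a zero-variance length distribution.
    """

    n_trees: int
    seed: int
    lengths: np.ndarray = field(repr=False)
    g1: float
    degenerate: bool = False


@dataclass(frozen=True)
class MEScore:
    """Sum of (clamped) branch lengths of the NJ tree."""

    me: float


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou–Nei neighbor joining with the Studier–Keppler criterion.

    Ties in the Q matrix are broken by the lowest (i, j) index pair, so the
    result is deterministic.  Negative branch-length estimates are clamped to
    zero and counted in ``n_clamped``.  Requires a fully defined matrix and at
    least 3 taxa.
    """
    n = dm.n
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    if not dm.defined.all():
        raise IncompleteMatrixError(
            f"{dm.n_undefined_pairs()} undefined pairwise distances; NJ needs a complete matrix"
        )
    D = dm.d.astype(float).copy()
    active = list(range(n))  # node ids for current D rows
    next_node = n
    raw_edges: list[tuple[int, int, float]] = []

    while len(active) > 3:
        r = len(active)
        rowsum = D.sum(axis=1)
        Q = (r - 2) * D - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum in row-major order = lowest (i, j)
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        bi = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2.0 * (r - 2))
        bj = D[i, j] - bi
        raw_edges.append((active[i], next_node, bi))
        raw_edges.append((active[j], next_node, bj))
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[k] for k in keep] + [next_node]
        next_node += 1

    a, b, c = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = next_node
    raw_edges.append((a, center, 0.5 * (dab + dac - dbc)))
    raw_edges.append((b, center, 0.5 * (dab + dbc - dac)))
    raw_edges.append((c, center, 0.5 * (dac + dbc - dab)))

    n_clamped = sum(1 for _, _, w in raw_edges if w < 0)
    edges = tuple((u, v, max(0.0, w)) for u, v, w in raw_edges)
    return UnrootedTree(tuple(dm.ids), edges, n_clamped=n_clamped)


def me_score(tree: UnrootedTree) -> MEScore:
    """Minimum-evolution score: the NJ tree's branch-length sum."""
    return MEScore(me=tree.total_length())


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _leaf_state_sets(aln: MultipleAlignment, leaf_names: tuple[str, ...]) -> np.ndarray:
    """Per-leaf bitmask state sets, (n_leaves, L) uint8; missing = full set."""
    index = {sid: k for k, sid in enumerate(aln.ids)}
    missing = [name for name in leaf_names if name not in index]
    if missing:
        raise KeyError(f"tree leaves absent from alignment: {missing[:5]}")
    enc = aln.encoded()[[index[name] for name in leaf_names]]
    sets = np.where(enc == MISSING_CODE, _FULL_SET, (1 << enc).astype(np.uint8))
    return sets.astype(np.uint8)


def _fitch_lengths_per_site(
    children: dict[int, list[int]], root: int, leaf_sets: np.ndarray
) -> np.ndarray:
    """Vectorised Fitch down-pass; returns per-site step counts."""
    L = leaf_sets.shape[1]
    steps = np.zeros(L, dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    order: list[int] = []
    stack = [root]
    while stack:  # iterative post-order
        node = stack.pop()
        order.append(node)
        stack.extend(children.get(node, []))
    for node in reversed(order):
        kids = children.get(node, [])
        if not kids:
            state[node] = leaf_sets[node]
            continue
        s = state.pop(kids[0])
        for k in kids[1:]:
            t = state.pop(k)
            inter = s & t
            empty = inter == 0
            steps += empty
            s = np.where(empty, s | t, inter)
        state[node] = s
    return steps


def fitch_scores(
    tree: UnrootedTree,
    aln: MultipleAlignment,
    include_uninformative: bool = True,
) -> ParsimonyScores:
    """Fitch tree length plus consistency and retention indices.

    Per site: ``s`` = small-parsimony steps on the topology, ``m`` = distinct
    determinate states minus one (the best any tree could do), ``g`` = taxa
    with a determinate state minus the count of the most frequent state (the
    worst, a star tree).  ``ci = M/S`` (1.0 when S = 0) and
    ``ri = (G-S)/(G-M)`` (1.0 when G = M).  Gaps/ambiguities are
    unconstrained.  With ``include_uninformative=False`` the sums run over
    parsimony-informative sites only.
    """
    leaf_sets = _leaf_state_sets(aln, tree.leaf_names)
    root, children = tree.rooted_children()
    s_i = _fitch_lengths_per_site(children, root, leaf_sets)

    index = {sid: k for k, sid in enumerate(aln.ids)}
    enc = aln.encoded()[[index[name] for name in tree.leaf_names]]
    counts = np.stack([(enc == s).sum(axis=0) for s in range(4)])  # (4, L)
    n_det = counts.sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    m_i = np.maximum(n_states - 1, 0)
    g_i = np.where(n_det > 0, n_det - counts.max(axis=0), 0)

    if not include_uninformative:
        informative = (counts >= 2).sum(axis=0) >= 2
        s_i, m_i, g_i = s_i[informative], m_i[informative], g_i[informative]

    S = int(s_i.sum())
    M = int(m_i.sum())
    G = int(g_i.sum())
    ci = 1.0 if S == 0 else M / S
    ri = 1.0 if G == M else (G - S) / (G - M)
    return ParsimonyScores(tree_length=S, min_steps=M, max_steps=G, ci=ci, ri=ri)


# ---------------------------------------------------------------------------
# g1 signal statistic
# ---------------------------------------------------------------------------

def _random_topology_edges(n_leaves: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform unrooted binary topology by random sequential leaf addition."""
    edges = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        w = next_internal
        next_internal += 1
        edges.extend([(u, w), (w, v), (w, leaf)])
    return edges


def g1_statistic(
    aln: MultipleAlignment, n_trees: int = 10_000, seed: int = 0
) -> G1Result:
    """Skewness of the Fitch tree-length distribution over ``n_trees``
    uniformly random unrooted binary topologies (seeded, deterministic).

    Left-skewed (negative g1) distributions indicate that few topologies are
    much better than the bulk, i.e. phylogenetic signal; structure-free data
    give g1 near zero.  Requires >= 4 sequences and >= 100 trees.
    """
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    if aln.n_sequences < 4:
        raise ValueError("g1 requires at least 4 sequences")
    rng = np.random.default_rng(seed)
    leaf_sets = _leaf_state_sets(aln, aln.ids)
    n = aln.n_sequences
    lengths = np.empty(n_trees)
    for t in range(n_trees):
        edges = _random_topology_edges(n, rng)
        # root by subdividing the first edge
        u0, v0 = edges[0]
        root = max(max(e) for e in edges) + 1
        adj: dict[int, list[int]] = {}
        for u, v in [(u0, root), (root, v0)] + edges[1:]:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        children: dict[int, list[int]] = {}
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            kids = [x for x in adj[node] if x != parent]
            children[node] = kids
            for kk in kids:
                stack.append((kk, node))
        lengths[t] = _fitch_lengths_per_site(children, root, leaf_sets).sum()
    sd = lengths.std()
    if sd == 0:
        return G1Result(n_trees=n_trees, seed=seed, lengths=lengths, g1=0.0, degenerate=True)
    g1 = float(stats.skew(lengths, bias=True))
    return G1Result(n_trees=n_trees, seed=seed, lengths=lengths, g1=g1, degenerate=False)
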