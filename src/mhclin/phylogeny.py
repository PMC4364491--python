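"""Distance-based phylogenetics: p-distance, Neighbor-Joining, bootstrap.

These primitives mirror the classical MEGA-style workflow for protein
alignments: proportion distances with pairwise deletion of missing data,
Saitou–Nei Neighbor-Joining, and Felsenstein column-resampling bootstrap
with bipartition-based clade support. They are written from scratch (they
are the analysis core, not plumbing); independent implementations are used
only as cross-checks in the test suite.

Conventions
-----------
* A site is *comparable* for a pair iff both residues are standard amino
  acids — gaps and ``X`` are treated as missing (pairwise deletion).
* Unrooted trees are stored with a single trifurcating root for n >= 3.
* Q-matrix ties are broken by the lowest (row, column) pair in the current
  working order, which is itself deterministic, so the whole construction
  is reproducible.
* Negative NJ branch lengths are clamped to zero with the deficit moved to
  the sister branch; raw lengths are kept on the node (``raw_length``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import STANDARD_AA, AlignedSet, MHCSequence

_STANDARD_BYTES = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)


class ZeroComparableError(ValueError):
    """A sequence pair shares no comparable (non-missing) sites."""

    def __init__(self, id_a: str, id_b: str):
        self.pair = (id_a, id_b)
        super().__init__(f"no comparable sites between {id_a!r} and {id_b!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distances with per-pair comparable-site counts."""

    labels: tuple[str, ...]
    values: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _alignment_matrix(aligned: AlignedSet) -> np.ndarray:
    rows = [np.frombuffer(m.sequence.encode(), dtype=np.uint8) for m in aligned.members]
    return np.vstack(rows)


def p_distance(aligned: AlignedSet) -> DistanceMatrix:
    """Pairwise p-distance with pairwise deletion.

    distance(i, j) = differing sites / comparable sites, where a site is
    comparable iff both residues are one of the 20 standard amino acids.
    Raises :class:`ZeroComparableError` naming the first offending pair.
    """
    n = len(aligned)
    if n < 2:
        raise ValueError("p-distance needs at least 2 sequences")
    mat = _alignment_matrix(aligned)
    valid = np.isin(mat, _STANDARD_BYTES)
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(comp, valid.sum(axis=1))
    ids = aligned.ids()
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nc = int(both.sum())
            if nc == 0:
                raise ZeroComparableError(ids[i], ids[j])
            diff = int(((mat[i] != mat[j]) & both).sum())
            d[i, j] = d[j, i] = diff / nc
            comp[i, j] = comp[j, i] = nc
    return DistanceMatrix(labels=tuple(ids), values=d, comparable_sites=comp)


# ---------------------------------------------------------------------------
# Tree container


class Node:
    __slots__ = ("name", "children", "parent", "length", "support", "raw_length")

    def __init__(self, name: str = "", length: float | None = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support: float | None = None
        self.raw_length: float | None = None

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_set(self) -> frozenset[str]:
        if self.is_leaf():
            return frozenset([self.name])
        out: set[str] = set()
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                out.add(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted (trifurcating-root) or rooted tree with branch lengths.

    ``supports`` on internal nodes are bootstrap percentages for the edge
    above the node. ``warnings`` accumulates bootstrap diagnostics.
    """

    root: Node
    warnings: list[str] = field(default_factory=list)

    def leaves(self) -> list[Node]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return list(reversed(out))

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if not n.is_leaf():
                out.append(n)
                stack.extend(n.children)
        return out

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self, *, nontrivial_only: bool = True) -> dict[frozenset[str], Node]:
        """Canonical splits of the unrooted tree, mapped to defining nodes.

        Each internal edge (parent link of a non-root internal node) induces
        a split; the canonical form is the side *not* containing the
        lexicographically smallest leaf, so rooted and rerooted versions of
        one tree produce identical keys.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset[str], Node] = {}
        stack = list(self.root.children)
        while stack:
            n = stack.pop()
            if n.is_leaf():
                continue
            stack.extend(n.children)
            side = n.leaf_set()
            if anchor in side:
                side = all_leaves - side
            if nontrivial_only and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out[side] = n
        return out

    def clades_excluding(self, excluded: set[str]) -> list[frozenset[str]]:
        """All split sides disjoint from ``excluded`` (the outgroup),
        i.e. the candidate clades of the tree rooted at the outgroup."""
        all_leaves = frozenset(self.leaf_names())
        clades: set[frozenset[str]] = set()
        for side in self.bipartitions(nontrivial_only=False):
            other = all_leaves - side
            for s in (side, other):
                if s and not (s & excluded) and len(s) < len(all_leaves):
                    clades.add(s)
        return sorted(clades, key=lambda s: (len(s), sorted(s)))


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted RF distance: symmetric difference of non-trivial splits."""
    sa, sb = set(a.bipartitions()), set(b.bipartitions())
    return len(sa ^ sb)


# ---------------------------------------------------------------------------
# Neighbor-Joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei Neighbor-Joining.

    Standard agglomeration: minimise Q(i,j) = (n-2) d(i,j) - r_i - r_j,
    assign branch lengths from the three-point equations, reduce the
    matrix, and finish with a trifurcating root. Deterministic under the
    tie-break rule (lowest current (row, column) pair).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes = [Node(name=lab) for lab in dm.labels]
    if n == 2:
        d = float(dm.values[0, 1])
        root = Node()
        for node in nodes:
            node.length = node.raw_length = d / 2
            root.add_child(node)
        return PhyloTree(root=root)

    D = dm.values.astype(float).copy()
    active = list(range(n))
    node_of = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        # evaluate the upper triangle only: Q is symmetric up to floating
        # rounding, and one deterministic representative per pair is needed
        q[np.tril_indices(m)] = np.inf
        qmin = q.min()
        ties = np.argwhere(q == qmin)
        ai, aj = min((int(i), int(j)) for i, j in ties)
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        ni, nj = node_of[i_glob], node_of[j_glob]
        ni.raw_length, nj.raw_length = float(li), float(lj)
        li, lj = _clamp_pair(li, lj)
        ni.length, nj.length = li, lj
        parent.add_child(ni)
        parent.add_child(nj)
        # reduce: reuse i's slot for the new node
        for k in active:
            if k in (i_glob, j_glob):
                continue
            dk = 0.5 * (D[i_glob, k] + D[j_glob, k] - dij)
            D[i_glob, k] = D[k, i_glob] = dk
        node_of[i_glob] = parent
        active.remove(j_glob)

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = Node()
    for idx, raw in zip((a, b, c), (la, lb, lc)):
        child = node_of[idx]
        child.raw_length = float(raw)
        child.length = max(float(raw), 0.0)
        root.add_child(child)
    return PhyloTree(root=root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister so the
    leaf-to-leaf path length through the join is preserved."""
    li, lj = float(li), float(lj)
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# Bootstrap


def _resample(aligned: AlignedSet, cols: np.ndarray) -> AlignedSet:
    mat = _alignment_matrix(aligned)[:, cols]
    members = [
        MHCSequence(id=m.id, sequence=mat[i].tobytes().decode())
        for i, m in enumerate(aligned.members)
    ]
    return AlignedSet.from_sequences(members)


def bootstrap(
    aligned: AlignedSet,
    n_reps: int,
    seed: int,
    tree_builder=None,
) -> PhyloTree:
    """Felsenstein bootstrap: resample columns with replacement, rebuild the
    tree per replicate, and annotate the original tree's internal edges with
    the percentage of replicates containing the same bipartition.

    Replicate ``r`` draws from an independent substream derived from
    ``(seed, r)``, so results are reproducible and order-independent.
    Replicates in which some pair has zero comparable sites are discarded
    and counted; a warning is recorded if more than 5% are discarded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if tree_builder is None:
        tree_builder = lambda a: neighbor_joining(p_distance(a))  # noqa: E731
    # canonicalise row order so supports are invariant to the leaf order of
    # the input alignment (ties and float summation follow label order)
    aligned = AlignedSet.from_sequences(
        sorted(aligned.members, key=lambda m: m.id)
    )
    tree = tree_builder(aligned)
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    discarded = 0
    width = aligned.width
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        cols = rng.integers(0, width, size=width)
        try:
            rep_tree = tree_builder(_resample(aligned, cols))
        except ZeroComparableError:
            discarded += 1
            continue
        rep_splits = rep_tree.bipartitions()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    valid = n_reps - discarded
    if valid == 0:
        raise ValueError("all bootstrap replicates discarded")
    for s, node in splits.items():
        node.support = 100.0 * counts[s] / valid
    if discarded > 0.05 * n_reps:
        tree.warnings.append(
            f"bootstrap: {discarded}/{n_reps} replicates discarded "
            "(zero-comparable pair)"
        )
    return tree


def clade_support(tree: PhyloTree, leaf_set) -> float | None:
    """Support of the edge inducing the ``leaf_set`` bipartition.

    Returns ``None`` when the clade is absent from the tree. Singleton
    leaf sets are trivially present with support 100 (terminal-edge
    convention).
    """
    leaf_set = frozenset(leaf_set)
    all_leaves = frozenset(tree.leaf_names())
    unknown = leaf_set - all_leaves
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if len(leaf_set) == 1 or leaf_set == all_leaves:
        return 100.0
    side = leaf_set
    if min(all_leaves) in side:
        side = all_leaves - side
    splits = tree.bipartitions()
    node = splits.get(side)
    if node is None:
        return None
    return node.support


def root_at_outgroup(tree: PhyloTree, outgroup: set[str]) -> PhyloTree:
    """Return a display-rooted copy with the root placed on the edge above
    the outgroup (its clade node when monophyletic, else its first leaf).

    Rooting is presentational only: the set of bipartitions is unchanged.
    The tree is rebuilt from its undirected edge set by a traversal from
    the new root; the rerooted edge's length is split evenly.
    """
    outgroup = set(outgroup)
    all_leaves = set(tree.leaf_names())
    if not outgroup <= all_leaves:
        raise ValueError("outgroup labels not all present in tree")
    target = None
    stack = [tree.root]
    while stack:
        n = stack.pop()
        stack.extend(n.children)
        if n is not tree.root and n.leaf_set() == frozenset(outgroup):
            target = n
            break
    if target is None:
        target = next(n for n in tree.leaves() if n.name in outgroup)

    adj: dict[int, list] = {}
    nodes: dict[int, Node] = {}

    def add_edge(a: Node, b: Node) -> None:
        nodes[id(a)], nodes[id(b)] = a, b
        length = b.length if b.length is not None else 0.0
        adj.setdefault(id(a), []).append((id(b), length, b.support))
        adj.setdefault(id(b), []).append((id(a), length, b.support))

    stack = [tree.root]
    while stack:
        n = stack.pop()
        for c in n.children:
            add_edge(n, c)
            stack.append(c)

    def build(orig_id: int, came_from: int, length: float, support) -> Node:
        orig = nodes[orig_id]
        n = Node(name=orig.name if orig.is_leaf() else "")
        n.length = length
        if not orig.is_leaf():
            n.support = support
        for nb, l, s in adj[orig_id]:
            if nb == came_from:
                continue
            n.add_child(build(nb, orig_id, l, s))
        return n

    half = (target.length or 0.0) / 2
    new_root = Node()
    new_root.add_child(build(id(target), id(target.parent), half, target.support))
    new_root.add_child(build(id(target.parent), id(target), half, target.support))
    # splice out any internal node left with a single child
    def splice(node: Node) -> None:
        for i, c in enumerate(list(node.children)):
            splice(c)
        if len(node.children) == 1 and node.parent is not None:
            only = node.children[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            node.parent.children[node.parent.children.index(node)] = only
            only.parent = node.parent

    splice(new_root.children[0])
    splice(new_root.children[1])
    return PhyloTree(root=new_root, warnings=list(tree.warnings))
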