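"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mhclin.phylogeny import PhyloTree
from mhclin.reference import load_reference_bundle
from mhclin.seqio import STANDARD_AA, AlignedSet, MHCSequence


@pytest.fixture(scope="session")
def bundle():
    return load_reference_bundle()


@pytest.fixture(scope="session")
def hla(bundle):
    return bundle.hla_a2


def random_protein(rng: np.random.Generator, length: int, alphabet: str = STANDARD_AA) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def naive_p_distance(a: str, b: str) -> tuple[int, int]:
    """Independent per-pair recount: (differences, comparable sites)."""
    diff = comp = 0
    for x, y in zip(a, b):
        if x in STANDARD_AA and y in STANDARD_AA:
            comp += 1
            if x != y:
                diff += 1
    return diff, comp


# ---------------------------------------------------------------------------
# Random additive trees (oracle for NJ reconstruction)


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (labels, distance matrix, set of canonical non-trivial splits).
    Built edge-by-edge on an adjacency map; distances are exact path sums,
    so the matrix is additive by construction.
    """
    labels = [f"t{i}" for i in range(n)]
    # adjacency: node -> {neighbor: length}; leaves are 0..n-1, internals >= n
    adj: dict[int, dict[int, float]] = {}
    next_internal = n

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def blen():
        return float(rng.uniform(0.05, 1.0))

    center = next_internal
    next_internal += 1
    for leaf in range(3):
        connect(center, leaf, blen())
    edges = [(center, leaf) for leaf in range(3)]
    for leaf in range(3, n):
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = next_internal
        next_internal += 1
        del adj[a][b], adj[b][a]
        u = float(rng.uniform(0.2, 0.8)) * w
        connect(a, mid, u)
        connect(mid, b, w - u)
        connect(mid, leaf, blen())
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (mid, leaf)]

    def bfs_dist(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    D = np.zeros((n, n))
    for i in range(n):
        d = bfs_dist(i)
        for j in range(n):
            D[i, j] = d[j]

    # canonical non-trivial splits: remove each internal-internal edge
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    splits = set()
    for a in list(adj):
        for b in adj[a]:
            if a < b and a >= n and b >= n:
                side = set()
                stack = [a]
                seen = {a, b}
                while stack:
                    u = stack.pop()
                    if u < n:
                        side.add(labels[u])
                    for v in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                s = frozenset(side)
                if anchor in s:
                    s = all_leaves - s
                if 2 <= len(s) <= n - 2:
                    splits.add(s)
    return labels, D, splits


def tree_distance_matrix(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a PhyloTree (independent of NJ math)."""

    dists: dict[tuple[str, str], float] = {}

    def walk(node, acc):
        if node.is_leaf():
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(walk(c, acc + (c.length or 0.0)))
        return out

    # distances via root paths: d(a,b) = depth(a) + depth(b) - 2*depth(lca)
    def leaf_depths(node, depth, path):
        if node.is_leaf():
            yield node.name, depth, path
        for c in node.children:
            yield from leaf_depths(c, depth + (c.length or 0.0), path + [id(node)])

    info = {name: (depth, path) for name, depth, path in leaf_depths(tree.root, 0.0, [])}
    depth_of_node: dict[int, float] = {}

    def record_depths(node, depth):
        depth_of_node[id(node)] = depth
        for c in node.children:
            record_depths(c, depth + (c.length or 0.0))

    record_depths(tree.root, 0.0)
    names = sorted(info)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa, pb = info[a][1], info[b][1]
            common = 0
            for x, y in zip(pa, pb):
                if x == y:
                    common += 1
                else:
                    break
            lca_depth = depth_of_node[pa[common - 1]] if common else 0.0
            dists[(a, b)] = info[a][0] + info[b][0] - 2 * lca_depth
    return dists


def make_aligned(rows: dict[str, str]) -> AlignedSet:
    return AlignedSet.from_sequences(
        [MHCSequence(id=k, sequence=v) for k, v in rows.items()]
    )
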