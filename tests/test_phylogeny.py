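"""p-distance, Neighbor-Joining, bootstrap and clade support.

NJ is validated two ways: against the additivity property (random additive
matrices must be reconstructed exactly) and against scikit-bio's
independent implementation on generic matrices.
"""

import numpy as np
import pytest

from conftest import (
    make_aligned,
    naive_p_distance,
    random_additive_tree,
    random_protein,
    tree_distance_matrix,
)
from mhclin.phylogeny import (
    DistanceMatrix,
    ZeroComparableError,
    bootstrap,
    clade_support,
    neighbor_joining,
    p_distance,
    robinson_foulds,
    root_at_outgroup,
)
from mhclin.simulate import simulate_star_alignment


class TestPDistance:
    def test_single_difference(self):
        dm = p_distance(make_aligned({"a": "ACDE", "b": "ACDF"}))
        assert dm.get("a", "b") == 0.25

    def test_pairwise_deletion_excludes_gap_columns(self):
        dm = p_distance(make_aligned({"a": "A-CD", "b": "AGCD"}))
        assert dm.get("a", "b") == 0.0
        assert dm.comparable_sites[0, 1] == 3

    def test_x_treated_as_missing(self):
        dm = p_distance(make_aligned({"a": "AXCD", "b": "AGCD"}))
        assert dm.comparable_sites[0, 1] == 3

    def test_zero_comparable_pair_named(self):
        with pytest.raises(ZeroComparableError, match="a.*b"):
            p_distance(make_aligned({"a": "A--", "b": "-CC", "c": "ACC"}))

    def test_matches_naive_oracle_random_pairs(self):
        rng = np.random.default_rng(12)
        alphabet = "ACDEFGHIKLX-"
        for _ in range(200):
            a = random_protein(rng, 50, alphabet)
            b = random_protein(rng, 50, alphabet)
            diff, comp = naive_p_distance(a, b)
            if comp == 0:
                continue
            dm = p_distance(make_aligned({"a": a, "b": b}))
            assert dm.get("a", "b") == diff / comp
            assert dm.comparable_sites[0, 1] == comp

    def test_bounds_and_self_distance(self):
        rng = np.random.default_rng(2)
        rows = {f"s{i}": random_protein(rng, 40) for i in range(6)}
        dm = p_distance(make_aligned(rows))
        assert np.all(dm.values >= 0) and np.all(dm.values <= 1)
        assert np.all(np.diag(dm.values) == 0)


class TestNeighborJoining:
    def test_three_taxa_branch_lengths(self):
        # unique solution of the three-point equations: a=1, b=1, c=3
        dm = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0.0, 2, 4], [2, 0, 4], [4, 4, 0.0]]),
            comparable_sites=np.full((3, 3), 10),
        )
        tree = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(
            labels=("A", "B"),
            values=np.array([[0.0, 0.4], [0.4, 0.0]]),
            comparable_sites=np.full((2, 2), 10),
        )
        tree = neighbor_joining(dm)
        d = tree_distance_matrix(tree)
        assert d[("A", "B")] == pytest.approx(0.4)

    def test_one_taxon_rejected(self):
        dm = DistanceMatrix(
            labels=("A",), values=np.zeros((1, 1)),
            comparable_sites=np.ones((1, 1), dtype=int),
        )
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    @pytest.mark.parametrize("n", [4, 6, 9, 12])
    def test_recovers_additive_trees(self, n):
        """On an additive matrix NJ must return the generating topology
        and branch lengths (checked via path-length additivity)."""
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            labels, D, true_splits = random_additive_tree(n, rng)
            dm = DistanceMatrix(
                labels=tuple(labels), values=D,
                comparable_sites=np.full((n, n), 100),
            )
            tree = neighbor_joining(dm)
            assert set(tree.bipartitions()) == true_splits
            td = tree_distance_matrix(tree)
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    key = (a, b) if (a, b) in td else (b, a)
                    assert td[key] == pytest.approx(
                        D[labels.index(a), labels.index(b)], abs=1e-9
                    )

    def test_matches_scikit_bio_topology(self):
        """Independent-oracle cross-check on generic random alignments."""
        import skbio

        rng = np.random.default_rng(77)
        from mhclin.seqio import read_newick

        for _ in range(5):
            rows = {f"s{i}": random_protein(rng, 80) for i in range(8)}
            aligned = make_aligned(rows)
            dm = p_distance(aligned)
            mine = neighbor_joining(dm)
            sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
            sk_tree = skbio.tree.nj(sk_dm)
            theirs = read_newick(str(sk_tree))
            assert robinson_foulds(mine, theirs) == 0

    def test_equal_distances_deterministic(self):
        values = np.full((5, 5), 0.5)
        np.fill_diagonal(values, 0.0)
        dm = DistanceMatrix(
            labels=tuple("ABCDE"), values=values,
            comparable_sites=np.full((5, 5), 10),
        )
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        assert set(t1.bipartitions()) == set(t2.bipartitions())
        lengths = {round(leaf.length, 12) for leaf in t1.leaves()}
        assert len(lengths) == 1  # symmetric input, equal terminal branches

    def test_negative_branches_clamped_with_raw_kept(self):
        # a matrix violating the four-point condition produces a negative
        # NJ branch; the stored length is clamped, the raw value retained
        values = np.array(
            [
                [0.0, 0.1, 0.45, 0.45],
                [0.1, 0.0, 0.50, 0.10],
                [0.45, 0.50, 0.0, 0.60],
                [0.45, 0.10, 0.60, 0.0],
            ]
        )
        dm = DistanceMatrix(
            labels=tuple("ABCD"), values=values,
            comparable_sites=np.full((4, 4), 10),
        )
        tree = neighbor_joining(dm)
        all_nodes = tree.internal_nodes() + tree.leaves()
        assert all(n.length is None or n.length >= 0 for n in all_nodes)
        raws = [n.raw_length for n in all_nodes if n.raw_length is not None]
        assert any(r < 0 for r in raws)


class TestBootstrap:
    def test_fully_diagnostic_split_support_100(self):
        aligned = simulate_star_alignment(
            4, 200, splits=[(["s1", "s2"], 1.0)], seed=0
        )
        tree = bootstrap(aligned, 100, seed=5)
        assert clade_support(tree, {"s1", "s2"}) == 100.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        rows = {f"s{i}": random_protein(rng, 120) for i in range(6)}
        aligned = make_aligned(rows)
        t1 = bootstrap(aligned, 50, seed=9)
        t2 = bootstrap(aligned, 50, seed=9)
        s1 = {s: n.support for s, n in t1.bipartitions().items()}
        s2 = {s: n.support for s, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_leaf_order_permutation_invariance(self):
        rng = np.random.default_rng(14)
        rows = {f"s{i}": random_protein(rng, 150) for i in range(6)}
        aligned = make_aligned(rows)
        shuffled = make_aligned(dict(reversed(list(rows.items()))))
        s1 = {
            s: n.support for s, n in bootstrap(aligned, 60, seed=3).bipartitions().items()
        }
        s2 = {
            s: n.support for s, n in bootstrap(shuffled, 60, seed=3).bipartitions().items()
        }
        assert s1 == s2

    def test_conflicting_signals_split_support_near_half(self):
        """50/50 conflicting diagnostic columns: either resolution is a
        coin flip per replicate, so support sits near 50%."""
        aligned = simulate_star_alignment(
            4, 200,
            splits=[(["s1", "s2"], 0.5), (["s1", "s3"], 0.5)],
            seed=1,
        )
        tree = bootstrap(aligned, 1000, seed=2)
        sup = clade_support(tree, {"s1", "s2"}) or clade_support(tree, {"s1", "s3"})
        assert 45 <= sup <= 55

    def test_discarded_replicates_warn(self):
        # the (a, b) pair shares a single comparable column: resampling
        # misses it with probability (1 - 1/w)^w ~ 37%, forcing discards
        rows = {
            "a": "K" + "X" * 9 + "KKKK",
            "b": "K" + "K" * 9 + "XXXX",
            "c": "KKKKKKKKKKKKKK",
            "d": "EEEEEEEEEEEEEE",
        }
        rows["b"] = "K" + "X" * 9 + "XXXX"  # overlap only at column 1
        rows["a"] = "K" + "K" * 9 + "KKKK"
        aligned = make_aligned(rows)
        tree = bootstrap(aligned, 100, seed=0)
        assert any("discarded" in w for w in tree.warnings)


class TestCladeSupport:
    def _supported_tree(self):
        aligned = simulate_star_alignment(
            4, 100, splits=[(["s1", "s2"], 1.0)], seed=0
        )
        return bootstrap(aligned, 50, seed=1)

    def test_absent_clade_is_none(self):
        tree = self._supported_tree()
        assert clade_support(tree, {"s1", "s3"}) is None

    def test_singleton_convention(self):
        tree = self._supported_tree()
        assert clade_support(tree, {"s1"}) == 100.0

    def test_unknown_leaf_rejected(self):
        tree = self._supported_tree()
        with pytest.raises(ValueError, match="unknown"):
            clade_support(tree, {"nope"})

    def test_complement_side_equivalent(self):
        tree = self._supported_tree()
        assert clade_support(tree, {"s3", "s4"}) == clade_support(tree, {"s1", "s2"})


class TestRooting:
    def test_outgroup_rooting_preserves_bipartitions(self):
        rng = np.random.default_rng(21)
        rows = {f"s{i}": random_protein(rng, 100) for i in range(7)}
        aligned = make_aligned(rows)
        tree = neighbor_joining(p_distance(aligned))
        rooted = root_at_outgroup(tree, {"s6"})
        assert set(rooted.leaf_names()) == set(tree.leaf_names())
        assert set(rooted.bipartitions()) == set(tree.bipartitions())
        assert len(rooted.root.children) == 2
        sides = [c.leaf_set() for c in rooted.root.children]
        assert frozenset({"s6"}) in sides
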