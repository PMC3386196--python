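"""Neighbour-joining, bootstrap supports and lineage detection."""

import math

import numpy as np
import pytest

import barcodetax as bt
from barcodetax.trees import single_linkage_components
from conftest import make_alignment, matrix_from_pct, random_additive_tree


class TestNeighbourJoining:
    def test_three_taxon_branch_lengths(self):
        # d(ab)=0.2, d(ac)=0.3, d(bc)=0.4 -> branches 0.05, 0.15, 0.25
        m = bt.DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = bt.nj_tree(m)
        lengths = {leaf.name: leaf.branch_length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"a": 0.05, "b": 0.15, "c": 0.25})

    def test_four_taxon_additive_topology(self, rng):
        # known tree ((a,b),(c,d)) with internal branch 0.1; oracle: the
        # unique additive topology among the 3 unrooted alternatives
        gen = random_additive_tree(4, rng)
        dm = gen.path_distances()
        tree = bt.nj_tree(dm)
        assert tree.canonical_splits() == gen.canonical_splits()

    @pytest.mark.parametrize("trial", range(10))
    def test_additive_matrices_recovered_exactly(self, trial):
        rng = np.random.default_rng(5000 + trial)
        gen = random_additive_tree(int(rng.integers(5, 9)), rng)
        dm = gen.path_distances()
        tree = bt.nj_tree(dm)
        assert tree.canonical_splits() == gen.canonical_splits()
        assert np.max(np.abs(tree.path_distances().values - dm.values)) < 1e-9

    def test_matches_independent_nj_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sknj

        for trial in range(5):
            gen = random_additive_tree(int(rng.integers(5, 9)), rng)
            dm = gen.path_distances()
            mine = bt.nj_tree(dm)
            sk = sknj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
            names = set(dm.labels)
            anchor = min(names)
            sk_splits = set()
            for node in sk.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(names) - 1:
                    sk_splits.add(
                        side if anchor not in side else frozenset(names - side)
                    )
            assert sk_splits == mine.canonical_splits()

    def test_all_equal_matrix_is_deterministic(self):
        values = np.full((5, 5), 0.3)
        np.fill_diagonal(values, 0.0)
        labels = tuple("abcde")
        t1 = bt.nj_tree(bt.DistanceMatrix(labels, values))
        t2 = bt.nj_tree(bt.DistanceMatrix(labels, values))
        assert t1.to_newick() == t2.to_newick()

    def test_undefined_entries_rejected(self):
        values = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(ValueError, match="undefined"):
            bt.nj_tree(bt.DistanceMatrix(("a", "b", "c"), values))

    def test_branch_lengths_non_negative(self, rng):
        # noisy (non-additive) matrices can produce negative estimates that
        # must be clamped
        for _ in range(10):
            n = 6
            values = rng.uniform(0.01, 0.4, size=(n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 0.0)
            tree = bt.nj_tree(
                bt.DistanceMatrix(tuple(f"t{i}" for i in range(n)), values)
            )
            for node in tree.root.walk():
                assert node.branch_length >= 0.0


class TestBootstrap:
    def test_separated_clades_get_high_support(self, two_clade_alignment):
        tree = bt.bootstrap_support(two_clade_alignment, replicates=200, seed=11)
        splits = tree.bipartitions()
        species = dict(
            zip(two_clade_alignment.sample_ids, two_clade_alignment.species_labels)
        )
        clade1 = frozenset(
            s for s, sp in species.items() if sp == "Species_01"
        )
        separating = [
            node.support
            for side, node in splits.items()
            if side == clade1 or side == frozenset(species) - clade1
        ]
        assert separating and min(separating) >= 95.0

    def test_single_replicate_supports_are_binary(self, two_clade_alignment):
        tree = bt.bootstrap_support(two_clade_alignment, replicates=1, seed=5)
        supports = [
            n.support for n in tree.root.walk() if n.support is not None
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_same_seed_reproduces_supports(self, two_clade_alignment):
        t1 = bt.bootstrap_support(two_clade_alignment, replicates=50, seed=7)
        t2 = bt.bootstrap_support(two_clade_alignment, replicates=50, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_seed_is_required(self, two_clade_alignment):
        with pytest.raises(ValueError, match="seed"):
            bt.bootstrap_support(two_clade_alignment, replicates=10)


class TestLineageDetection:
    def test_single_lineage_not_flagged(self):
        m = matrix_from_pct(
            ["x1", "x2", "x3"],
            [[0, 0.3, 0.3], [0.3, 0, 0.3], [0.3, 0.3, 0]],
        )
        result = bt.detect_lineages(m, ["X"] * 3, ["NIT"] * 3, 2.0)
        sl = result.by_species["X"]
        assert sl.n_lineages == 1
        assert not sl.flagged

    def test_divergent_geographic_lineages_flagged(self):
        # two groups: within 0.4%, between 9.4% (deep intraspecific split)
        labels = ["n1", "n2", "s1", "s2"]
        pct = [
            [0, 0.4, 9.4, 9.4],
            [0.4, 0, 9.4, 9.4],
            [9.4, 9.4, 0, 0.4],
            [9.4, 9.4, 0.4, 0],
        ]
        m = matrix_from_pct(labels, pct)
        result = bt.detect_lineages(
            m, ["Nat"] * 4, ["NIT", "NIT", "CIT", "SIT"], 2.0
        )
        sl = result.by_species["Nat"]
        assert sl.flagged and sl.n_lineages == 2
        (between,) = sl.between_means_pct.values()
        assert between == pytest.approx(9.4)
        profiles = [l.locality_profile for l in sl.lineages]
        assert profiles == [{"NIT": 2}, {"CIT": 1, "SIT": 1}]

    def test_matches_brute_force_single_linkage(self, rng):
        for _ in range(20):
            n = 10
            values = rng.uniform(0, 0.1, size=(n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 0.0)
            cutoff = float(rng.uniform(1, 8))
            comps = single_linkage_components(values * 100, cutoff)
            # oracle: exhaustive graph traversal
            adj = {i: set() for i in range(n)}
            for i in range(n):
                for j in range(n):
                    if i != j and values[i, j] * 100 < cutoff:
                        adj[i].add(j)
            seen, expected = set(), []
            for start in range(n):
                if start in seen:
                    continue
                stack, comp = [start], set()
                while stack:
                    k = stack.pop()
                    if k in comp:
                        continue
                    comp.add(k)
                    stack.extend(adj[k] - comp)
                seen |= comp
                expected.append(sorted(comp))
            assert [sorted(c) for c in comps] == sorted(expected)

    def test_cutoff_extremes(self):
        labels = ["x1", "x2", "x3"]
        pct = [[0, 1.0, 1.5], [1.0, 0, 1.2], [1.5, 1.2, 0]]
        m = matrix_from_pct(labels, pct)
        high = bt.detect_lineages(m, ["X"] * 3, [None] * 3, 5.0)
        assert high.by_species["X"].n_lineages == 1
        low = bt.detect_lineages(m, ["X"] * 3, [None] * 3, 0.5)
        assert low.by_species["X"].n_lineages == 3

    def test_support_annotation_from_tree(self, two_clade_alignment):
        tree = bt.bootstrap_support(two_clade_alignment, replicates=100, seed=3)
        m = bt.distance_matrix(two_clade_alignment)
        result = bt.detect_lineages(
            m,
            two_clade_alignment.species_labels,
            two_clade_alignment.locality_groups,
            2.0,
            support_tree=tree,
            min_support=95.0,
        )
        for sl in result.by_species.values():
            for lineage in sl.lineages:
                if lineage.clade_support is not None:
                    assert 0.0 <= lineage.clade_support <= 100.0
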