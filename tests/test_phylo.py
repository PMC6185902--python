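"""Distance trees, rooting and monophyly classification."""

import numpy as np
import pytest

from sporekit.phylo import (
    DistanceMatrix,
    bionj,
    bootstrap_support,
    classify_grouping,
    p_distance,
    pairwise_divergence_scan,
    scan_chromosome,
)
from sporekit.trees import PhyloTree, root_tree
from sporekit.core import VariantMatrix

from conftest import (
    distance_matrix_from,
    random_rooted_tree,
    random_unrooted_tree,
    tuple_tree_clades,
    tuple_tree_distances,
    tuple_tree_splits,
)


def dm_from(names, d, v=None):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(names), d, d.copy() if v is None else np.asarray(v, float))


def unrooted_splits(tree: PhyloTree) -> set:
    universe = tree.leaf_names()
    splits = set()
    for clade in tree.clades(min_size=2):
        if len(clade) < len(universe) - 1:
            other = universe - clade
            splits.add(min(clade, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return splits


class TestPDistance:
    def test_identical_rows_give_zero(self):
        mat = np.tile(np.array([0, 1, 2, 3]), (3, 1))
        dm = p_distance(mat, ["a", "b", "c"])
        assert np.all(dm.d == 0)

    def test_brute_force_pair_counts(self):
        rng = np.random.default_rng(5)
        mat = rng.integers(0, 4, size=(4, 50)).astype(np.int8)
        dm = p_distance(mat, list("abcd"))
        for i in range(4):
            for j in range(4):
                expected = sum(mat[i, k] != mat[j, k] for k in range(50)) / 50
                assert dm.d[i, j] == pytest.approx(expected)

    def test_variance_initialized_to_distance(self):
        rng = np.random.default_rng(6)
        mat = rng.integers(0, 4, size=(3, 20)).astype(np.int8)
        dm = p_distance(mat, list("abc"))
        np.testing.assert_array_equal(dm.d, dm.v)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            p_distance(np.zeros((2, 10), dtype=np.int8), ["a", "b"])


class TestBioNJ:
    def test_three_taxon_closed_form(self):
        dm = dm_from("abc", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = bionj(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"a": 0.05, "b": 0.15, "c": 0.25})

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive matrix
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float
        )
        tree = bionj(dm_from("abcd", d))
        got = tree.path_distances()
        names = list("abcd")
        for i in range(4):
            for j in range(i + 1, 4):
                assert got[(names[i], names[j])] == pytest.approx(d[i, j], abs=1e-9)
        assert frozenset("ab") in unrooted_splits(tree)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(42)
        for rep in range(20):
            n = int(rng.integers(4, 9))
            names = [f"t{i}" for i in range(n)]
            truth = random_unrooted_tree(rng, names)
            dists = tuple_tree_distances(truth)
            d = distance_matrix_from(names, dists)
            tree = bionj(dm_from(names, d))
            got = tree.path_distances()
            for key, val in dists.items():
                assert got[key] == pytest.approx(val, abs=1e-9)
            assert unrooted_splits(tree) == tuple_tree_splits(truth, names)

    def test_degenerate_variances_match_plain_nj(self):
        # a zero variance matrix pins the mixing weight at 1/2 throughout,
        # which reduces BioNJ exactly to plain neighbor joining
        import skbio

        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 6
            names = [f"t{i}" for i in range(n)]
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            mine = bionj(dm_from(names, d, np.zeros((n, n))))
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, names))
            got = mine.path_distances()
            for i in range(n):
                for j in range(i + 1, n):
                    expect = ref.find(names[i]).distance(ref.find(names[j]))
                    key = tuple(sorted((names[i], names[j])))
                    assert got[key] == pytest.approx(expect, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            dm_from("abc", d)


class TestRooting:
    def test_single_outgroup(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,C:1,OUT:4);")
        rooted = root_tree(t, ["OUT"])
        assert rooted.rooted
        # OUT is sister to everything else
        assert frozenset(["A", "B", "C"]) in rooted.clades(min_size=2)

    def test_outgroup_cherry(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(O1:1,O2:1):2,C:1);")
        rooted = root_tree(t, ["O1", "O2"])
        assert frozenset(["O1", "O2"]) in rooted.clades(min_size=2)
        assert frozenset(["A", "B", "C"]) in rooted.clades(min_size=2)

    def test_non_monophyletic_outgroup_falls_back(self, caplog):
        t = PhyloTree.from_newick("((O1:1,A:1):1,(O2:1,B:1):1,C:1);")
        with caplog.at_level("WARNING"):
            rooted = root_tree(t, ["O1", "O2"])
        assert rooted.rooted
        assert "not monophyletic" in caplog.text
        # rooted on O1's terminal edge: O1 is sister to all the rest
        assert frozenset(["A", "B", "C", "O2"]) in rooted.clades(min_size=2)

    def test_missing_outgroup_id(self):
        t = PhyloTree.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(KeyError):
            root_tree(t, ["ZZZ"])

    def test_branch_lengths_preserved(self):
        t = PhyloTree.from_newick("((A:1,B:2):3,C:4,OUT:6);")
        rooted = root_tree(t, ["OUT"])
        d = rooted.path_distances()
        assert d[("A", "OUT")] == pytest.approx(1 + 3 + 6)
        assert d[("A", "B")] == pytest.approx(3)


class TestClassifyGrouping:
    FOCAL = frozenset(["F1", "F2", "F3", "F4"])

    def test_full_monophyly(self):
        t = PhyloTree.from_newick(
            "((((F1:1,F2:1):1,(F3:1,F4:1):1):1,(S1:1,S2:1):1):1,OUT:1);",
            rooted=True,
        )
        assert classify_grouping(t, self.FOCAL) == self.FOCAL

    def test_partial_grouping(self):
        t = PhyloTree.from_newick(
            "((((F1:1,F2:1):1,F3:1):1,((F4:1,S1:1):1,S2:1):1):1,OUT:1);",
            rooted=True,
        )
        assert classify_grouping(t, self.FOCAL) == frozenset(["F1", "F2", "F3"])

    def test_no_pair_groups(self):
        t = PhyloTree.from_newick(
            "(((F1:1,S1:1):1,(F2:1,S2:1):1):1,OUT:1);", rooted=True
        )
        assert classify_grouping(t, frozenset(["F1", "F2"])) == frozenset()

    def test_anchor_smallest_clade(self):
        t = PhyloTree.from_newick(
            "(((K:1,F2:1):1,(F1:1,F3:1):1):1,OUT:1);", rooted=True
        )
        got = classify_grouping(t, frozenset(["F1", "F2", "F3"]), anchor="K")
        assert got == frozenset(["F2"])

    def test_anchor_without_admissible_clade(self):
        t = PhyloTree.from_newick(
            "(((K:1,S1:1):1,(F1:1,F2:1):1):1,OUT:1);", rooted=True
        )
        got = classify_grouping(t, frozenset(["F1", "F2"]), anchor="K")
        assert got == frozenset()

    def test_unrooted_tree_rejected(self):
        t = PhyloTree.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            classify_grouping(t, frozenset(["A", "B"]))

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(99)
        names = [f"F{i}" for i in range(4)] + [f"S{i}" for i in range(4)]
        focal = frozenset(n for n in names if n.startswith("F"))
        for _ in range(30):
            truth = random_rooted_tree(rng, list(rng.permutation(names)))
            clades = tuple_tree_clades(truth)
            candidates = [c for c in clades if len(c) >= 2 and c <= focal]
            if candidates:
                best = max(
                    candidates, key=lambda c: (len(c), tuple(sorted(c))[::-1])
                )
                # replicate lexicographic tie-break independently
                size = max(len(c) for c in candidates)
                expected = min(
                    (tuple(sorted(c)) for c in candidates if len(c) == size)
                )
                expected = frozenset(expected)
            else:
                expected = frozenset()
            tree = PhyloTree.from_newick(truth.newick(), rooted=True)
            assert classify_grouping(tree, focal) == expected


def window_matrix(groups, n_sites_per_group):
    """Samples x sites matrix where each listed group shares derived alleles
    at its own block of sites."""
    names = [n for grp in groups for n in grp]
    total = n_sites_per_group * len(groups)
    mat = np.zeros((len(names), total), dtype=np.int8)
    row = 0
    for gi, grp in enumerate(groups):
        block = slice(gi * n_sites_per_group, (gi + 1) * n_sites_per_group)
        for name in grp:
            mat[row, block] = 1
            row += 1
    return names, mat


class TestBootstrapSupport:
    def test_clean_separation_gives_full_support(self):
        # focal clade separated by 10 fixed differences from everyone else
        names = ["F1", "F2", "F3", "S1", "S2", "OUT"]
        mat = np.zeros((6, 50), dtype=np.int8)
        mat[0:3, 0:10] = 1  # focal-defining sites
        mat[5, 40:50] = 2  # outgroup depth
        cat, support = bootstrap_support(
            mat, names, ["F1", "F2", "F3"], ["OUT"], reps=100, seed=0
        )
        assert cat == frozenset(["F1", "F2", "F3"])
        assert support >= 0.99

    def test_single_rep_is_reproducible(self):
        names = ["F1", "F2", "S1", "OUT"]
        rng_mat = np.random.default_rng(3).integers(0, 4, (4, 50)).astype(np.int8)
        out = [
            bootstrap_support(rng_mat, names, ["F1", "F2"], ["OUT"], reps=1, seed=42)
            for _ in range(2)
        ]
        assert out[0] == out[1]
        assert out[0][1] in (None, 0.0, 1.0)

    def test_identical_sequences_yield_empty_category(self):
        mat = np.zeros((5, 50), dtype=np.int8)
        cat, support = bootstrap_support(
            mat, list("abcde"), ["a", "b"], ["e"], reps=10, seed=0
        )
        assert cat == frozenset() and support is None


class TestScan:
    def test_bin_proportions_sum_to_one(self, sim_params):
        from sporekit.simulate import simulate_scan_matrix

        vm = simulate_scan_matrix(sim_params)
        calls, summary = scan_chromosome(
            vm, "chr3", sim_params.killers_a, sim_params.outgroups,
            reps=0, bin_size=50,
        )
        for props, size in zip(summary.bins, summary.bin_sizes):
            assert sum(props.values()) == pytest.approx(1.0)
        assert summary.bin_sizes[-1] == len(calls) - 50 * (len(summary.bins) - 1)

    def test_bin_of_one_is_indicator(self, sim_params):
        from sporekit.simulate import simulate_scan_matrix

        vm = simulate_scan_matrix(sim_params)
        calls, summary = scan_chromosome(
            vm, "chr3", sim_params.killers_a, sim_params.outgroups,
            reps=0, bin_size=1,
        )
        for call, props in zip(calls, summary.bins):
            assert props == {call.category: 1.0}

    def test_planted_tract_detected(self, sim_params):
        from sporekit.simulate import simulate_scan_matrix

        vm = simulate_scan_matrix(sim_params)
        calls, _ = scan_chromosome(
            vm, "chr3", sim_params.killers_a, sim_params.outgroups, reps=0
        )
        full = frozenset(sim_params.killers_a)
        three = full - {"KA4"}
        (sample, t0, t1), = sim_params.tracts
        for i, call in enumerate(calls):
            iv = call.interval
            if iv.start >= t0 and iv.end <= t1:
                assert call.category == three, f"window {i} inside tract"
            elif iv.end <= t0 or iv.start >= t1:
                assert call.category == full, f"window {i} outside tract"


class TestPairwiseDivergenceScan:
    def _vm(self, mat, positions):
        return VariantMatrix(
            ["a", "b", "c"],
            {"chr1": np.asarray(positions)},
            {"chr1": np.asarray(mat, dtype=np.int8)},
        )

    def test_identical_samples_zero(self):
        vm = self._vm([[0, 1], [0, 1], [2, 2]], [100, 9000])
        table = pairwise_divergence_scan(vm, "chr1", "a", "b", 20_000)
        assert (table.frame["divergence"] == 0).all()

    def test_ten_differences_in_one_window(self):
        positions = np.arange(10) * 100 + 1000
        mat = np.zeros((3, 10), dtype=np.int8)
        mat[1] = 1
        vm = self._vm(mat, positions)
        table = pairwise_divergence_scan(vm, "chr1", "a", "b", 10_000)
        assert table.frame["divergence"][0] == pytest.approx(0.001)

    def test_overlapping_windows_match_naive_recount(self):
        rng = np.random.default_rng(12)
        positions = np.sort(rng.choice(50_000, size=400, replace=False))
        mat = rng.integers(0, 4, size=(3, 400)).astype(np.int8)
        vm = self._vm(mat, positions)
        table = pairwise_divergence_scan(vm, "chr1", "a", "c", 50_000)
        ia, ic = 0, 2
        for row in table.frame.itertuples():
            naive = sum(
                mat[ia, k] != mat[ic, k]
                for k in range(400)
                if row.start <= positions[k] < row.end
            )
            assert row.divergence == pytest.approx(naive / (row.end - row.start))
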