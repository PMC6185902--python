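"""NG86 counting, diversity/divergence, MK tables, bootstrap null and the
age bound."""

import itertools

import numpy as np
import pytest

from sporekit.molevol import (
    SENSE_CODONS,
    CodonAlignment,
    GeneStats,
    MKTable,
    age_lower_bound,
    aggregate,
    bootstrap_null,
    gene_divergence,
    gene_diversity,
    gene_stats,
    neutrality_index,
    ng86_site_counts,
    pairwise_codon_diffs,
    polymorphism_counts,
)


class TestSiteCounts:
    def test_phe_ttt(self):
        n, s = ng86_site_counts("TTT")
        assert (n, s) == (pytest.approx(8 / 3), pytest.approx(1 / 3))

    def test_met_atg(self):
        assert ng86_site_counts("ATG") == (pytest.approx(3.0), pytest.approx(0.0))

    def test_counts_sum_to_three_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            n, s = ng86_site_counts(codon)
            assert n + s == pytest.approx(3.0)
            assert s >= 0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TGA")


class TestPairwiseDiffs:
    def test_single_nonsynonymous(self):
        assert pairwise_codon_diffs("TTT", "TTA") == (1.0, 0.0)

    def test_two_step_pathway_average(self):
        assert pairwise_codon_diffs("TTT", "GTA") == (pytest.approx(1.5), pytest.approx(0.5))

    def test_identical(self):
        assert pairwise_codon_diffs("AAA", "AAA") == (0.0, 0.0)

    def test_sums_to_hamming_on_sample(self):
        rng = np.random.default_rng(8)
        codons = list(SENSE_CODONS)
        for _ in range(200):
            a, b = rng.choice(codons, 2)
            n, s = pairwise_codon_diffs(a, b)
            assert n + s == pytest.approx(sum(x != y for x, y in zip(a, b)))

    def test_symmetry(self):
        assert pairwise_codon_diffs("TTT", "GTA") == pairwise_codon_diffs("GTA", "TTT")


class TestGeneDiversity:
    def test_identical_sequences(self):
        aln = CodonAlignment("g", {"a": "TTTAAAGGG", "b": "TTTAAAGGG"})
        div = gene_diversity(aln)
        assert div.pi_total == 0 and div.pi_n == 0 and div.pi_s == 0

    def test_single_synonymous_change(self):
        # TTT->TTC is synonymous; S_sites averaged over the pair
        aln = CodonAlignment("g", {"a": "TTTAAAGGG", "b": "TTCAAAGGG"})
        div = gene_diversity(aln)
        s_sites = sum(ng86_site_counts(c)[1] for c in ("TTT", "AAA", "GGG")) / 2 + sum(
            ng86_site_counts(c)[1] for c in ("TTC", "AAA", "GGG")
        ) / 2
        assert div.pi_n == 0
        assert div.pi_s == pytest.approx(1 / s_sites)
        assert div.pi_total == pytest.approx(1 / 9)

    def test_three_sequences_mean_of_pairs(self):
        seqs = {"a": "TTTAAA", "b": "TTCAAA", "c": "TTTAAG"}
        div = gene_diversity(CodonAlignment("g", seqs))
        pair_pis = []
        for x, y in itertools.combinations(sorted(seqs), 2):
            d = gene_diversity(CodonAlignment("p", {x: seqs[x], y: seqs[y]}))
            pair_pis.append(d.pi_s)
        assert div.pi_s == pytest.approx(np.mean(pair_pis))

    def test_ambiguous_codon_excluded_pairwise(self):
        aln = CodonAlignment("g", {"a": "TTTAAA", "b": "TTCNNN"})
        div = gene_diversity(aln)
        # only the first codon is usable; the synonymous diff is still seen
        assert div.pi_s > 0

    def test_internal_stop_flags_gene(self):
        aln = CodonAlignment("g", {"a": "TTTTGAGGG", "b": "TTTTGAGGG"})
        with pytest.raises(ValueError, match="stop"):
            gene_stats(aln)


class TestDivergence:
    def test_fixed_synonymous_difference(self):
        aln = CodonAlignment(
            "g", {"a": "TTTAAA", "b": "TTTAAA"}, {"o1": "TTCAAA", "o2": "TTCAAA"}
        )
        assert gene_divergence(aln) == (0.0, pytest.approx(1.0))

    def test_polymorphic_position_not_divergent(self):
        aln = CodonAlignment(
            "g", {"a": "TTTAAA", "b": "TTCAAA"}, {"o1": "TTAAAA"}
        )
        assert gene_divergence(aln) == (0.0, 0.0)

    def test_identical_groups(self):
        aln = CodonAlignment("g", {"a": "TTTAAA", "b": "TTTAAA"}, {"o": "TTTAAA"})
        assert gene_divergence(aln) == (0.0, 0.0)


class TestPolymorphism:
    def test_biallelic_codon_counted_once(self):
        aln = CodonAlignment("g", {"a": "TTTAAA", "b": "TTCAAA", "c": "TTTAAA"})
        assert polymorphism_counts(aln) == (0.0, pytest.approx(1.0))

    def test_nonsynonymous_polymorphism(self):
        aln = CodonAlignment("g", {"a": "TTTAAA", "b": "TTTGAA", "c": "TTTAAA"})
        p_n, p_s = polymorphism_counts(aln)
        assert (p_n, p_s) == (pytest.approx(1.0), 0.0)


class TestAggregate:
    def test_single_gene_identity(self):
        aln = CodonAlignment("g", {"a": "TTTAAAGGG", "b": "TTCAAAGGG"})
        gs = gene_stats(aln)
        div, mk = aggregate([gs])
        assert div.pi_s == pytest.approx(gs.pi_s)
        assert (mk.p_n, mk.p_s) == (gs.p_n, gs.p_s)

    def test_counts_add(self):
        def fake(pn, ps, dn, ds):
            return GeneStats(
                "g", 300, [("a", "b")],
                np.array([1.0]), np.array([1.0]), np.array([100.0]),
                np.array([50.0]), np.array([2.0]), pn, ps, dn, ds,
            )

        _, mk = aggregate([fake(1, 2, 3, 4), fake(2, 2, 3, 4)])
        assert (mk.p_n, mk.p_s, mk.d_n, mk.d_s) == (3, 4, 6, 8)

    def test_pooling_equals_concatenation(self):
        rng = np.random.default_rng(17)
        samples = ["a", "b", "c"]
        genes = []
        seqs_concat = {s: "" for s in samples}
        for g in range(4):
            n_codons = int(rng.integers(5, 15))
            seqs = {}
            for s in samples:
                codons = rng.choice(len(SENSE_CODONS), size=n_codons)
                seqs[s] = "".join(SENSE_CODONS[c] for c in codons)
            genes.append(gene_stats(CodonAlignment(f"g{g}", seqs)))
            for s in samples:
                seqs_concat[s] += seqs[s]
        pooled, _ = aggregate(genes)
        concat = gene_diversity(CodonAlignment("concat", seqs_concat))
        assert pooled.pi_n == pytest.approx(concat.pi_n, abs=1e-12)
        assert pooled.pi_s == pytest.approx(concat.pi_s, abs=1e-12)
        assert pooled.pi_total == pytest.approx(concat.pi_total, abs=1e-12)


class TestNeutralityIndex:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((770, 1499, 2985, 7360), 1.27),
            ((58_830, 153_013, 59_077, 132_834), 0.86),
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_reference_values(self, counts, expected):
        assert round(neutrality_index(MKTable(*counts)), 2) == expected

    def test_undefined_denominators(self):
        with pytest.raises(ValueError):
            neutrality_index(MKTable(1, 0, 1, 1))
        with pytest.raises(ValueError):
            neutrality_index(MKTable(1, 1, 0, 1))


def make_gene(rng, length=900, scale=1.0):
    """Background gene with Poisson counts proportional to its length."""
    lam = length / 900 * scale
    return GeneStats(
        "g", length, [("a", "b")],
        np.array([float(rng.poisson(3 * lam))]),
        np.array([float(rng.poisson(6 * lam))]),
        np.array([length * 0.7]),
        np.array([length * 0.3]),
        np.array([float(rng.poisson(9 * lam))]),
        float(rng.poisson(4 * lam)),
        float(rng.poisson(6 * lam)),
        float(rng.poisson(8 * lam)),
        float(rng.poisson(12 * lam)),
    )


class TestBootstrapNull:
    def test_identical_background_zero_width(self):
        g = GeneStats(
            "g", 900, [("a", "b")],
            np.array([2.0]), np.array([3.0]), np.array([600.0]),
            np.array([300.0]), np.array([5.0]), 4, 6, 8, 12,
        )
        null = bootstrap_null([g] * 5, 3, region_length=2700, reps=100, seed=0)
        ni = null["ni"]
        assert ni.lower == pytest.approx(ni.upper)
        assert ni.lower == pytest.approx((4 / 6) / (8 / 12))

    def test_observed_in_bulk_gives_large_p(self):
        rng = np.random.default_rng(1)
        background = [make_gene(rng) for _ in range(100)]
        region = [make_gene(rng) for _ in range(10)]
        from sporekit.molevol import _pooled_stats

        observed = _pooled_stats(region, scale=1.0)
        null = bootstrap_null(
            background, 10, region_length=sum(g.length for g in region),
            reps=300, seed=5, observed=observed,
        )
        assert null["ni"].p_value > 0.05
        assert null["ni"].lower <= observed["ni"] <= null["ni"].upper

    def test_reps_floor(self):
        with pytest.raises(ValueError):
            bootstrap_null([make_gene(np.random.default_rng(0))], 1, 900, reps=10)


class TestAgeBound:
    def test_identical_panel_gives_zero_age(self):
        genes = {"g1": "TTTAAAGGG"}
        panel = {"g1": {"s1": "TTTAAAGGG", "s2": "TTTAAAGGG"}}
        est = age_lower_bound(genes, panel, 1e-8)
        assert est.age_years == 0

    def test_closed_form(self):
        # one synonymous difference over the gene's synonymous sites
        region = {"g1": "TTTAAAGGG"}
        panel = {"g1": {"s1": "TTCAAAGGG"}}
        est = age_lower_bound(region, panel, 1e-8)
        s_sites = (
            sum(ng86_site_counts(c)[1] for c in ("TTT", "AAA", "GGG"))
            + sum(ng86_site_counts(c)[1] for c in ("TTC", "AAA", "GGG"))
        ) / 2
        expected_ds = 1 / s_sites
        assert est.pooled_ds == pytest.approx(expected_ds)
        assert est.age_years == pytest.approx(expected_ds / 2e-8)

    def test_closer_panel_member_cannot_increase_age(self):
        region = {"g1": "TTTAAAGGG"}
        far = {"g1": {"s1": "TTCAAGGGT"}}
        with_near = {"g1": {"s1": "TTCAAGGGT", "s2": "TTCAAAGGG"}}
        age_far = age_lower_bound(region, far, 1e-8).age_years
        age_near = age_lower_bound(region, with_near, 1e-8).age_years
        assert age_near <= age_far

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            age_lower_bound({"g": "TTT"}, {"g": {"s": "TTT"}}, 0)
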