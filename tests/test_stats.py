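"""Codon usage, rank tests, tetranucleotide signatures, network edges.

scipy and scikit-bio act as independent cross-checks of the hand-written
statistics; they are never the code path under test.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu

from mmavirome.records import SequenceRecord, ValidationError, revcomp
from mmavirome.stats import (
    TETRAMERS,
    anosim,
    codon_frequencies,
    gene_sharing_edges,
    mann_whitney_u,
    pc_edge_significance,
    profile_correlation_matrix,
    tetranucleotide_profile,
)
from mmavirome.synthetic import generate_codon_genomes, random_sequence


class TestCodonFrequencies:
    def test_hand_counted_example(self):
        cs = codon_frequencies("g", ["TGTTGCATG"])
        assert cs.n_codons == 3
        assert cs.freq["C"] == pytest.approx(2 / 3)
        assert cs.freq["M"] == pytest.approx(1 / 3)

    def test_no_cysteine_codons(self):
        cs = codon_frequencies("g", ["ATGGGGAAA"])
        assert cs.freq["C"] == 0.0

    def test_frequencies_sum_to_one_with_stops(self):
        cs = codon_frequencies("g", ["ATGTAA", "TGTTGA"])
        assert sum(cs.freq.values()) == pytest.approx(1.0, abs=1e-9)
        assert cs.freq["*"] == pytest.approx(0.5)

    def test_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="partial codon"):
            cs = codon_frequencies("g", ["ATGAA"])
        assert cs.n_codons == 1

    def test_empty_cds_set_errors(self):
        with pytest.raises(ValidationError):
            codon_frequencies("g", [])

    def test_planted_cys_enrichment_shifts_group_median(self):
        enriched, control = generate_codon_genomes(50, delta=0.01, seed=13)
        cys_e = [codon_frequencies(f"e{i}", g).freq["C"] for i, g in enumerate(enriched)]
        cys_c = [codon_frequencies(f"c{i}", g).freq["C"] for i, g in enumerate(control)]
        assert np.median(cys_e) > np.median(cys_c)


class TestMannWhitney:
    def test_enumerated_small_example(self):
        """x=[1,2], y=[3,4]: U=0 and exact two-sided p = 2/6 over C(4,2) labelings."""
        r = mann_whitney_u([1, 2], [3, 4], "two-sided")
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3)
        assert r.method == "mwu_exact"

    def test_identical_multisets_p_one(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0

    def test_all_values_identical(self):
        assert mann_whitney_u([5, 5], [5, 5, 5]).p_value == 1.0

    @pytest.mark.parametrize("n1, n2", [(3, 3), (4, 5), (6, 6), (8, 7)])
    def test_exact_p_matches_scipy_enumeration_without_ties(self, n1, n2):
        rng = np.random.default_rng(21)
        for _ in range(5):
            x = rng.permutation(np.arange(n1 + n2))[:n1].astype(float)
            y = np.setdiff1d(np.arange(n1 + n2), x).astype(float)
            for alt in ("two-sided", "greater", "less"):
                ours = mann_whitney_u(x, y, alt)
                ref = scipy_mwu(x, y, alternative=alt, method="exact")
                assert ours.statistic == ref.statistic
                assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_p_with_ties_matches_direct_enumeration(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0]
        from scipy.stats import rankdata
        pooled = np.array(x + y)
        ranks = rankdata(pooled)
        n1 = len(x)

        def u1(idx):
            return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

        obs = min(u1(range(n1)), n1 * len(y) - u1(range(n1)))
        labelings = list(itertools.combinations(range(len(pooled)), n1))
        p = sum(min(u1(i), n1 * len(y) - u1(i)) <= obs + 1e-9 for i in labelings) / len(labelings)
        assert mann_whitney_u(x, y).p_value == pytest.approx(p)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        ours = mann_whitney_u(x, y)
        ref = scipy_mwu(x, y, method="asymptotic")
        assert ours.method == "mwu_normal"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays within [0.03, 0.07]."""
        rng = np.random.default_rng(17)
        rejections = 0
        for _ in range(1000):
            x, y = rng.normal(size=30), rng.normal(size=30)
            if mann_whitney_u(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


class TestTetranucleotide:
    def test_homopolymer_both_strand_counting(self):
        prof = tetranucleotide_profile("g", "AAAA")
        assert prof.vector[TETRAMERS.index("AAAA")] == 0.5
        assert prof.vector[TETRAMERS.index("TTTT")] == 0.5
        assert prof.vector.sum() == 1.0

    def test_strand_symmetry(self):
        seq = random_sequence(3000, np.random.default_rng(4))
        a = tetranucleotide_profile("g", seq).vector
        b = tetranucleotide_profile("g", revcomp(seq)).vector
        np.testing.assert_allclose(a, b, atol=0)

    def test_matches_dictionary_counting_oracle(self):
        seq = random_sequence(10_000, np.random.default_rng(6))
        counts = dict.fromkeys(TETRAMERS, 0)
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - 3):
                counts[s[i:i + 4]] += 1
        expected = np.array([counts[k] for k in TETRAMERS], dtype=float)
        expected /= expected.sum()
        np.testing.assert_allclose(tetranucleotide_profile("g", seq).vector, expected)

    def test_n_windows_skipped(self):
        prof = tetranucleotide_profile("g", "AAAANAAAA")
        assert prof.vector[TETRAMERS.index("AAAA")] == 0.5

    def test_too_short_errors(self):
        with pytest.raises(ValidationError):
            tetranucleotide_profile("g", "ACG")


class TestProfileCorrelation:
    def _profiles(self, seqs):
        return [tetranucleotide_profile(f"g{i}", s) for i, s in enumerate(seqs)]

    def test_self_correlation_and_symmetry(self):
        rng = np.random.default_rng(19)
        profs = self._profiles([random_sequence(2000, rng) for _ in range(4)])
        r = profile_correlation_matrix(profs)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T, atol=1e-12)
        assert ((r >= -1 - 1e-12) & (r <= 1 + 1e-12)).all()

    def test_shared_composition_correlates_more(self):
        from mmavirome.synthetic import _order_transition, markov_sequence
        rng = np.random.default_rng(19)
        t1, t2 = _order_transition(0, 1.5), _order_transition(3, 1.5)
        a1 = markov_sequence(20_000, t1, rng)
        a2 = markov_sequence(20_000, t1, rng)
        b = markov_sequence(20_000, t2, rng)
        r = profile_correlation_matrix(self._profiles([a1, a2, b]))
        assert r[0, 1] > r[0, 2]


class TestAnosim:
    def _sep_matrix(self):
        # two groups of 3; all between-distances (10..) > all within (1..)
        d = np.zeros((6, 6))
        labels = ["a"] * 3 + ["b"] * 3
        rng = np.random.default_rng(23)
        for i in range(6):
            for j in range(i + 1, 6):
                d[i, j] = d[j, i] = (1 + rng.random()) if labels[i] == labels[j] \
                    else (10 + rng.random())
        return d, labels

    def test_full_separation_gives_r_one(self):
        d, labels = self._sep_matrix()
        assert anosim(d, labels, 99, seed=0).statistic == pytest.approx(1.0)

    def test_constant_distances_give_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        assert anosim(d, ["a"] * 3 + ["b"] * 3, 99, seed=0).statistic == 0.0

    def test_sampler_p_matches_exhaustive_enumeration(self):
        """6 points, 2 groups: compare the sampled p with the full 720-permutation null."""
        d, labels = self._sep_matrix()
        labels = np.asarray(labels)
        iu = np.triu_indices(6, k=1)
        from scipy.stats import rankdata
        ranks = rankdata(d[iu])

        def r_stat(lab):
            same = lab[iu[0]] == lab[iu[1]]
            return (ranks[~same].mean() - ranks[same].mean()) / (len(ranks) / 2)

        r_obs = r_stat(labels)
        perms = [np.array(p) for p in itertools.permutations(labels)]
        exact_p = sum(r_stat(p) >= r_obs - 1e-12 for p in perms) / len(perms)
        got = anosim(d, labels, n_permutations=4999, seed=23)
        assert got.statistic == pytest.approx(r_obs)
        assert got.p_value == pytest.approx(exact_p, abs=0.02)  # Monte-Carlo error

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(31)
        pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(2, 1, (4, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 4 + ["b"] * 4
        ours = anosim(d, labels, 999, seed=0)
        ref = skbio_stats.anosim(skbio_stats.DistanceMatrix(d), grouping=labels,
                                 permutations=999)
        assert ours.statistic == pytest.approx(ref["test statistic"])
        assert abs(ours.p_value - ref["p-value"]) < 0.05

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(37)
        n = 12
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        rs = []
        iu = np.triu_indices(n, k=1)
        from scipy.stats import rankdata
        ranks = rankdata(d[iu])
        base = np.array(["a"] * 6 + ["b"] * 6)
        for _ in range(10_000):
            lab = rng.permutation(base)
            same = lab[iu[0]] == lab[iu[1]]
            rs.append((ranks[~same].mean() - ranks[same].mean()) / (len(ranks) / 2))
        assert abs(np.mean(rs)) < 0.02

    def test_all_singleton_groups_error(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValidationError):
            anosim(d, ["a", "b", "c"], 99, seed=0)


class TestEdgeSignificance:
    def test_exact_hypergeometric_hand_case(self):
        """|A|=|B|=5 of 10 total, all 5 shared: P = 1/C(10,5) = 1/252."""
        e = pc_edge_significance("a", set(range(5)), "b", set(range(5)), 10)
        assert e.shared_pcs == 5
        assert e.significance == pytest.approx(math.log10(252), abs=1e-9)

    def test_no_shared_pcs_no_edge(self):
        e = pc_edge_significance("a", {1, 2}, "b", {3, 4}, 10)
        assert e.shared_pcs == 0 and e.significance == 0.0
        assert gene_sharing_edges({"a": {1, 2}, "b": {3, 4}}, 10, 0.0) == []

    def test_monotone_in_shared_count(self):
        total, size = 200, 20
        prev = -1.0
        for c in range(size + 1):
            a = set(range(size))
            b = set(range(c)) | set(range(size, 2 * size - c))
            sig = pc_edge_significance("a", a, "b", b, total).significance
            assert sig >= prev - 1e-9
            prev = sig

    def test_threshold_filters_edges(self):
        pcs = {"a": set(range(30)), "b": set(range(30)), "c": {100, 101}}
        edges = gene_sharing_edges(pcs, 1000, sig_min=10)
        assert [(e.genome_a, e.genome_b) for e in edges] == [("a", "b")]
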