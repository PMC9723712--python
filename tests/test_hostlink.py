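"""Spacer/tRNA/taxonomy/binning host linking against naive oracles."""

import numpy as np
import pytest

from mmavirome.hostlink import (
    HostLink,
    aggregate_links,
    best_hosts,
    binning_link,
    criterion_counts,
    detect_cross_domain,
    find_spacer_matches,
    find_trna_matches,
    spacer_matches_to_links,
    taxonomy_vote_link,
)
from mmavirome.records import (
    BinRecord,
    Config,
    CrisprArrayRecord,
    OrfTaxonomy,
    SequenceRecord,
    ValidationError,
    revcomp,
)
from mmavirome.synthetic import mutate_sequence, random_sequence

CFG = Config()
ARCH = ("Archaea", "Halobacterota", "Methanosarcinia", "Methanosarcinales")
BACT = ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfuromonadales")


def _array(spacer_seq, level=4, host="h1"):
    return CrisprArrayRecord(host, f"{host}_a", level,
                             [SequenceRecord(f"{host}_sp", spacer_seq)])


def naive_scan(spacer: str, virus: str, max_mm: int):
    """O(n*m) sliding-window Hamming oracle over both strands."""
    hits = []
    for proto, strand in ((spacer, "+"), (revcomp(spacer), "-")):
        for pos in range(len(virus) - len(proto) + 1):
            window = virus[pos:pos + len(proto)]
            mm = sum(1 for a, b in zip(proto, window) if a != b or a == "N" or b == "N")
            if mm <= max_mm:
                hits.append((pos, strand, mm))
    return sorted(hits)


class TestSpacerMatching:
    def _plant(self, spacer, mismatches, strand, rng):
        virus = random_sequence(2000, rng)
        proto = mutate_sequence(spacer, mismatches / len(spacer) - 1e-9, 5) if mismatches else spacer
        if strand == "-":
            proto = revcomp(proto)
        pos = int(rng.integers(0, 2000 - len(proto)))
        return virus[:pos] + proto + virus[pos + len(proto):], pos

    def test_exact_planting_found(self):
        rng = np.random.default_rng(0)
        spacer = random_sequence(32, rng)
        virus, pos = self._plant(spacer, 0, "+", rng)
        m = find_spacer_matches([_array(spacer)], [SequenceRecord("v", virus)], CFG)
        assert [(x.position, x.strand, x.mismatches) for x in m] == [(pos, "+", 0)]

    def test_one_mismatch_found_two_not(self):
        rng = np.random.default_rng(1)
        spacer = random_sequence(32, rng)
        v1, _ = self._plant(spacer, 1, "+", rng)
        v2, _ = self._plant(spacer, 2, "+", rng)
        arrays = [_array(spacer)]
        m1 = find_spacer_matches(arrays, [SequenceRecord("v1", v1)], CFG)
        m2 = find_spacer_matches(arrays, [SequenceRecord("v2", v2)], CFG)
        assert [x.mismatches for x in m1] == [1]
        assert m2 == []

    def test_reverse_complement_planting(self):
        rng = np.random.default_rng(2)
        spacer = random_sequence(30, rng)
        virus, pos = self._plant(spacer, 0, "-", rng)
        m = find_spacer_matches([_array(spacer)], [SequenceRecord("v", virus)], CFG)
        assert [(x.position, x.strand) for x in m] == [(pos, "-")]

    def test_low_evidence_arrays_skipped(self):
        rng = np.random.default_rng(3)
        spacer = random_sequence(30, rng)
        virus, _ = self._plant(spacer, 0, "+", rng)
        m = find_spacer_matches([_array(spacer, level=3)], [SequenceRecord("v", virus)], CFG)
        assert m == []

    def test_n_counts_as_mismatch(self):
        spacer = "ACGGATTCACGGTTAGCCAT"
        virus = "TTTT" + spacer[:10] + "N" + spacer[11:] + "TTTT"
        m = find_spacer_matches([_array(spacer)], [SequenceRecord("v", virus)], CFG)
        assert [x.mismatches for x in m] == [1]
        spacer_n = spacer[:10] + "N" + spacer[11:]
        m = find_spacer_matches([_array(spacer_n)], [SequenceRecord("v", virus)], CFG)
        assert [x.mismatches for x in m] == [1]  # N vs N still a mismatch

    def test_spacer_longer_than_virus_no_match(self):
        m = find_spacer_matches([_array("ACGTACGTACGT")],
                                [SequenceRecord("v", "ACGTA")], CFG)
        assert m == []

    @pytest.mark.parametrize("mismatches", [0, 1, 2])
    def test_matches_naive_oracle_on_planted_cases(self, mismatches):
        rng = np.random.default_rng(3)
        for case in range(50):
            spacer = random_sequence(int(rng.integers(25, 41)), rng)
            strand = "+" if case % 2 else "-"
            virus, _ = self._plant(spacer, mismatches, strand, rng)
            got = find_spacer_matches([_array(spacer)], [SequenceRecord("v", virus)], CFG)
            got_set = sorted((m.position, m.strand, m.mismatches) for m in got)
            assert got_set == naive_scan(spacer, virus, CFG.spacer_max_mismatch)

    def test_lowering_evidence_floor_never_removes_links(self):
        rng = np.random.default_rng(9)
        arrays, viruses = [], []
        for i in range(10):
            spacer = random_sequence(30, rng)
            virus, _ = self._plant(spacer, 0, "+", rng)
            arrays.append(_array(spacer, level=int(rng.integers(1, 5)), host=f"h{i}"))
            viruses.append(SequenceRecord(f"v{i}", virus))
        strict = find_spacer_matches(arrays, viruses, Config(crispr_min_evidence=4))
        loose = find_spacer_matches(arrays, viruses, Config(crispr_min_evidence=1))
        assert set(strict) <= set(loose)


class TestTrnaMatching:
    def test_identical_trna_links(self):
        t = random_sequence(72, np.random.default_rng(0))
        links = find_trna_matches({"v": [SequenceRecord("vt", t)]},
                                  {"h": [SequenceRecord("ht", t)]}, {"h": ARCH})
        assert [(l.virus_id, l.host_id, l.criterion) for l in links] == [("v", "h", "trna")]

    def test_single_substitution_breaks_link(self):
        t = random_sequence(72, np.random.default_rng(1))
        near = mutate_sequence(t, 1 / 72 - 1e-9, 2)
        links = find_trna_matches({"v": [SequenceRecord("vt", near)]},
                                  {"h": [SequenceRecord("ht", t)]}, {"h": ARCH})
        assert links == []

    def test_reverse_complement_links(self):
        """Convention cross-checked against exhaustive pairwise comparison."""
        rng = np.random.default_rng(2)
        virus_trnas = {"v": [SequenceRecord("vt", revcomp(random_sequence(72, rng)))]}
        host_trnas = {"h1": [SequenceRecord("t1", random_sequence(72, rng))],
                      "h2": [SequenceRecord("t2", revcomp(virus_trnas["v"][0].seq))]}
        links = find_trna_matches(virus_trnas, host_trnas, {"h1": ARCH, "h2": ARCH})
        expected = []
        for h, ts in host_trnas.items():
            for ht in ts:
                for vt in virus_trnas["v"]:
                    if vt.seq in (ht.seq, revcomp(ht.seq)):
                        expected.append(("v", h))
        assert [(l.virus_id, l.host_id) for l in links] == sorted(expected)


class TestTaxonomyVote:
    TARGETS = {"Methanosarcinales": ARCH,
               "Methanobacteriales": ("Archaea", "Euryarchaeota", "Methanobacteria",
                                      "Methanobacteriales")}

    def _orfs(self, contig, lineages, contig_lineage=()):
        taxa = [OrfTaxonomy(contig, i + 1, lin) for i, lin in enumerate(lineages)]
        if contig_lineage:
            taxa.append(OrfTaxonomy(contig, 0, (), contig_lineage))
        return taxa

    def test_contig_level_call_links_without_votes(self):
        taxa = self._orfs("v", [], contig_lineage=ARCH)
        links = taxonomy_vote_link(taxa, self.TARGETS, CFG)
        assert [(l.virus_id, l.host_id, l.support) for l in links] == \
            [("v", "Methanosarcinales", 0)]

    def test_five_votes_link_four_do_not(self):
        mb = self.TARGETS["Methanobacteriales"]
        other = ("Bacteria", "x", "y", "z")
        taxa5 = self._orfs("v", [mb] * 5 + [other] * 15)
        taxa4 = self._orfs("v", [mb] * 4 + [other] * 16)
        assert len(taxonomy_vote_link(taxa5, self.TARGETS, CFG)) == 1
        assert taxonomy_vote_link(taxa5, self.TARGETS, CFG)[0].support == 5
        assert taxonomy_vote_link(taxa4, self.TARGETS, CFG) == []

    def test_split_votes_count_per_lineage(self):
        taxa = self._orfs("v", [ARCH] * 3 + [self.TARGETS["Methanobacteriales"]] * 3)
        assert taxonomy_vote_link(taxa, self.TARGETS, CFG) == []


class TestBinning:
    BIN = BinRecord("bin1", frozenset({"v", "hc"}), 80, 2, ARCH)
    TARGETS = {"Methanosarcinales": ARCH}

    def test_binned_with_one_orf_links(self):
        links = binning_link(["v"], [self.BIN], {("v", "Methanosarcinales"): 1},
                             self.TARGETS, CFG)
        assert [(l.virus_id, l.host_id, l.criterion) for l in links] == \
            [("v", "bin1", "binning")]

    def test_binned_without_orf_vote_no_link(self):
        assert binning_link(["v"], [self.BIN], {}, self.TARGETS, CFG) == []

    def test_non_target_bin_no_link(self):
        b = BinRecord("bin2", frozenset({"v"}), 80, 2, BACT)
        assert binning_link(["v"], [b], {("v", "Desulfuromonadales"): 1},
                            self.TARGETS, CFG) == []

    def test_contig_in_two_bins_errors(self):
        b2 = BinRecord("bin2", frozenset({"v"}), 80, 2, ARCH)
        with pytest.raises(ValidationError, match="two bins"):
            binning_link(["v"], [self.BIN, b2], {}, self.TARGETS, CFG)


class TestAggregation:
    def test_same_pair_two_criteria_gives_two_rows(self):
        links = [HostLink("v", "h", ARCH, "crispr"), HostLink("v", "h", ARCH, "trna")]
        table = aggregate_links(links)
        assert len(table) == 2
        assert criterion_counts(table) == {"crispr": 1, "trna": 1,
                                           "taxonomy_vote": 0, "binning": 0}

    def test_duplicate_rows_deduplicated(self):
        links = [HostLink("v", "h", ARCH, "crispr", 2), HostLink("v", "h", ARCH, "crispr", 1)]
        table = aggregate_links(links)
        assert len(table) == 1 and table["support"].iloc[0] == 2

    def test_empty_input_empty_table(self):
        assert aggregate_links([]).empty

    def test_best_host_follows_criterion_precedence(self):
        links = [HostLink("v", "b", ARCH, "binning"), HostLink("v", "h", ARCH, "trna")]
        best = best_hosts(aggregate_links(links))
        assert best["criterion"].tolist() == ["trna"]


class TestCrossDomain:
    def test_two_domains_is_cross_domain(self):
        links = [HostLink("v", "h1", ARCH, "crispr"), HostLink("v", "h2", BACT, "crispr")]
        calls = detect_cross_domain(aggregate_links(links))
        assert [c.is_cross_domain for c in calls] == [True]

    def test_two_archaeal_orders_is_not(self):
        other = ("Archaea", "Euryarchaeota", "Methanococci", "Methanococcales")
        links = [HostLink("v", "h1", ARCH, "crispr"), HostLink("v", "h2", other, "crispr")]
        calls = detect_cross_domain(aggregate_links(links))
        assert [c.is_cross_domain for c in calls] == [False]

    def test_no_links_no_calls(self):
        assert detect_cross_domain(aggregate_links([])) == []
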