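"""Synthetic community generator with a planted-truth ledger.

Everything the pipeline consumes on real data (host genomes, viral contigs,
CRISPR arrays, tRNAs, ORF annotations and taxonomy, bins, detector scores,
read alignments) is generated here with known answers, so every stage can be
scored against ground truth:

* host genomes are order-specific first-order Markov sequences, giving each
  host order a distinct tetranucleotide signature that its viruses inherit;
* CRISPR spacers are planted on viruses as protospacers at 0/1/2 mismatches
  and from confidence tiers 3 and 4, straddling both linking rules;
* tRNAs are planted identical (either strand) or one substitution off;
* ORF taxonomy rows drive the >=5-vote rule from both sides of the boundary;
* one virus is integrated verbatim into a host genome (provirus), others
  carry integrase labels;
* AMG candidates are planted with every verdict class;
* read alignments achieve per-sample target breadths straddling the 85%
  presence rule.

The ledger records, for every planted item, whether the pipeline *should*
recover it under the default thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .records import (
    AlignmentRecord,
    BinRecord,
    CrisprArrayRecord,
    GeneRecord,
    OrfTaxonomy,
    SequenceRecord,
    ValidationError,
    ViralCandidateRecord,
    revcomp,
)

BASES = "ACGT"

# (order, domain, phylum, class); the last entry is the bacterial partner
HOST_ORDERS = (
    ("Methanosarcinales", "Archaea", "Halobacterota", "Methanosarcinia"),
    ("Methanobacteriales", "Archaea", "Euryarchaeota", "Methanobacteria"),
    ("Methanomicrobiales", "Archaea", "Halobacterota", "Methanomicrobia"),
    ("Methanococcales", "Archaea", "Euryarchaeota", "Methanococci"),
    ("Methanomassiliicoccales", "Archaea", "Thermoplasmatota", "Thermoplasmata"),
    ("Desulfuromonadales", "Bacteria", "Proteobacteria", "Deltaproteobacteria"),
)


def order_lineage(order: str) -> tuple[str, str, str, str]:
    for o, dom, phy, cls in HOST_ORDERS:
        if o == order:
            return (dom, phy, cls, o)
    raise ValidationError(f"unknown host order {order!r}")


@dataclass
class GeneratorParams:
    """Knobs of the synthetic community; defaults define the study conditions."""

    n_samples: int = 4
    host_genome_length: int = 30_000
    virus_length: int = 10_000
    spacer_len_range: tuple[int, int] = (25, 40)
    spacers_per_array: int = 4
    trnas_per_host: int = 2
    trna_len_range: tuple[int, int] = (72, 90)
    gene_length: int = 600
    gene_spacing: int = 700
    read_length: int = 150
    background_reads: int = 20_000  # non-viral mapped reads per sample
    composition_strength: float = 1.5  # order-specific Markov bias
    codon_delta: float = 0.01  # planted Cys codon-fraction enrichment
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "host_genome_length", "virus_length",
                     "read_length", "gene_length", "gene_spacing"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


# --------------------------------------------------------------------------
# sequence primitives

def _order_transition(order_idx: int, strength: float) -> np.ndarray:
    """Deterministic order-specific 4x4 transition matrix (rows sum to 1).

    The bias is a fixed pseudo-random perturbation keyed on the order index
    only, so an order's composition is a property of the order, not of the
    community seed.
    """
    rng = np.random.default_rng(10_000 + order_idx)
    t = 1.0 + strength * rng.random((4, 4))
    return t / t.sum(axis=1, keepdims=True)


def markov_sequence(length: int, transition: np.ndarray, rng: np.random.Generator) -> str:
    cum = np.cumsum(transition, axis=1).tolist()
    draws = rng.random(length).tolist()
    state = int(rng.integers(4))
    out = []
    for r in draws:
        row = cum[state]
        state = 0 if r < row[0] else 1 if r < row[1] else 2 if r < row[2] else 3
        out.append(state)
    return "".join(BASES[s] for s in out)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_sequence(seq: str, divergence: float, seed: int) -> str:
    """Substitute exactly ceil(divergence * len) positions, no indels."""
    if not (0 <= divergence < 1):
        raise ValidationError("divergence must be in [0, 1)")
    if divergence == 0:
        return seq
    rng = np.random.default_rng(seed)
    n_sub = math.ceil(divergence * len(seq))
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in BASES if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _plant(seq: str, insert: str, position: int) -> str:
    """Overwrite seq[position:position+len(insert)] with insert."""
    if position + len(insert) > len(seq):
        raise ValidationError("planted segment extends beyond the sequence")
    return seq[:position] + insert + seq[position + len(insert):]


# --------------------------------------------------------------------------
# hosts

@dataclass
class HostGenome:
    host_id: str
    order: str
    lineage: tuple[str, ...]
    record: SequenceRecord
    arrays: list[CrisprArrayRecord]
    trnas: list[SequenceRecord]
    provirus_coords: Optional[tuple[int, int]] = None


def generate_host_genome(
    params: GeneratorParams,
    host_id: str,
    order: str,
    seed: int,
    provirus: Optional[SequenceRecord] = None,
) -> HostGenome:
    """One host genome with CRISPR arrays (tiers 3 and 4) and tRNAs.

    When ``provirus`` is given, the viral sequence is inserted verbatim and
    the integration coordinates recorded.
    """
    rng = np.random.default_rng(seed)
    order_idx = [o for o, *_ in HOST_ORDERS].index(order)
    trans = _order_transition(order_idx, params.composition_strength)
    seq = markov_sequence(params.host_genome_length, trans, rng)
    coords = None
    if provirus is not None:
        pos = int(rng.integers(1000, len(seq) - provirus.length - 1000))
        seq = seq[:pos] + provirus.seq + seq[pos:]
        coords = (pos, pos + provirus.length)

    arrays = []
    for level in (4, 3):
        spacers = []
        for k in range(params.spacers_per_array):
            slen = int(rng.integers(params.spacer_len_range[0], params.spacer_len_range[1] + 1))
            spacers.append(SequenceRecord(f"{host_id}_L{level}_sp{k + 1}",
                                          random_sequence(slen, rng)))
        arrays.append(CrisprArrayRecord(host_id, f"{host_id}_array_L{level}", level, spacers))

    trnas = []
    for k in range(params.trnas_per_host):
        tlen = int(rng.integers(params.trna_len_range[0], params.trna_len_range[1] + 1))
        trnas.append(SequenceRecord(f"{host_id}_trna{k + 1}", random_sequence(tlen, rng)))

    return HostGenome(host_id, order, order_lineage(order), SequenceRecord(host_id, seq),
                      arrays, trnas, coords)


# --------------------------------------------------------------------------
# planted truth ledger

@dataclass
class PlantedTruth:
    """Ground truth for every planted signal, with should_find flags."""

    rng_seed: int = 0
    spacer_links: list[dict] = field(default_factory=list)
    trna_links: list[dict] = field(default_factory=list)
    taxonomy_links: list[dict] = field(default_factory=list)
    binning_links: list[dict] = field(default_factory=list)
    cross_domain_viruses: list[str] = field(default_factory=list)
    provirus_coords: dict[str, list] = field(default_factory=dict)  # virus -> [host, s, e]
    lifestyle: dict[str, dict] = field(default_factory=dict)  # virus -> {lysogenic, signals}
    triage_expected: dict[str, dict] = field(default_factory=dict)  # contig -> {accepted, rule}
    abundance: list[dict] = field(default_factory=list)  # virus/sample/breadth/reads/present
    sample_totals: dict[str, int] = field(default_factory=dict)
    amg_genes: list[dict] = field(default_factory=list)  # virus/gene_index/verdict
    codon_effect: float = 0.0
    cysh_viruses: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# --------------------------------------------------------------------------
# community

@dataclass
class CommunityBundle:
    params: GeneratorParams
    hosts: list[HostGenome]
    viruses: list[SequenceRecord]  # includes triage decoys
    genes: list[GeneRecord]
    taxonomy: list[OrfTaxonomy]
    candidates: list[ViralCandidateRecord]
    bins: list[BinRecord]
    virus_trnas: dict[str, list[SequenceRecord]]
    alignments: dict[str, list[AlignmentRecord]]  # sample -> rows
    truth: PlantedTruth

    @property
    def host_lineages(self) -> dict[str, tuple[str, ...]]:
        return {h.host_id: h.lineage for h in self.hosts}

    @property
    def lengths(self) -> dict[str, int]:
        d = {v.id: v.length for v in self.viruses}
        d.update({h.host_id: h.record.length for h in self.hosts})
        return d


_HOST_PLAN = [  # (host_id, order)
    ("h01", "Methanosarcinales"), ("h02", "Methanosarcinales"),
    ("h03", "Methanobacteriales"), ("h04", "Methanobacteriales"),
    ("h05", "Methanomicrobiales"), ("h06", "Methanococcales"),
    ("h07", "Methanomassiliicoccales"), ("h08", "Desulfuromonadales"),
]

VIRAL_LABEL_POOL = ("PF04860", "PF05133", "PF05136", "PF04466")  # portal/terminase/capsid/tail
INTEGRASE_LABEL = "PF00589"
CYSH_LABEL = "K00390"
DCM_LABEL = "PF00145"


def _virus_genes(virus_id: str, length: int, params: GeneratorParams,
                 viral_like: bool = True) -> list[GeneRecord]:
    genes = []
    idx = 0
    pos = 50
    while pos + params.gene_length <= length - 50:
        idx += 1
        genes.append(GeneRecord(virus_id, idx, pos, pos + params.gene_length,
                                "+" if idx % 2 else "-",
                                labels=frozenset({VIRAL_LABEL_POOL[idx % len(VIRAL_LABEL_POOL)]}),
                                category="", viral_like=viral_like))
        pos += params.gene_spacing
    return genes


def _codon_cds(n_codons: int, delta: float, rng: np.random.Generator) -> str:
    """A CDS drawn codon-by-codon; delta boosts the two Cys codons equally."""
    from .stats import _STANDARD_CODE
    codons = sorted(_STANDARD_CODE)
    p = np.full(len(codons), 1.0 / len(codons))
    if delta:
        for cys in ("TGT", "TGC"):
            p[codons.index(cys)] += delta / 2
        p /= p.sum()
    picks = rng.choice(len(codons), size=n_codons, p=p)
    return "".join(codons[i] for i in picks)


def generate_codon_genomes(
    n_per_group: int,
    delta: float,
    seed: int,
    genes_per_genome: int = 10,
    codons_per_gene: int = 300,
) -> tuple[list[list[str]], list[list[str]]]:
    """(enriched_group, control_group) of per-genome CDS lists.

    The enriched group's codons are drawn with the two cysteine codons each
    boosted by delta/2, so the expected Cys fraction difference between the
    groups is ~delta; methionine is untouched in both.
    """
    rng = np.random.default_rng(seed)
    enriched = [[_codon_cds(codons_per_gene, delta, rng) for _ in range(genes_per_genome)]
                for _ in range(n_per_group)]
    control = [[_codon_cds(codons_per_gene, 0.0, rng) for _ in range(genes_per_genome)]
               for _ in range(n_per_group)]
    return enriched, control


def generate_clustering_families(
    n_families: int,
    n_singletons: int,
    seed: int,
    child_divergence: float = 0.03,
    singleton_divergence: float = 0.12,
    parent_len_range: tuple[int, int] = (1500, 3000),
) -> tuple[list[SequenceRecord], list[frozenset[str]]]:
    """Planted clustering families plus far-mutant singletons.

    Each family is a parent and a shorter child at ``child_divergence``
    substitutions (co-clusters at 95/85); each singleton is a mutant of some
    parent at ``singleton_divergence`` (must not co-cluster). Returns the
    sequences and the true co-membership partition.
    """
    rng = np.random.default_rng(seed)
    seqs: list[SequenceRecord] = []
    partition: list[frozenset[str]] = []
    parents: list[SequenceRecord] = []
    for f in range(n_families):
        length = int(rng.integers(*parent_len_range))
        parent = SequenceRecord(f"fam{f:02d}_p", random_sequence(length, rng))
        child_seq = mutate_sequence(parent.seq[: int(0.8 * length)], child_divergence,
                                    int(rng.integers(2 ** 31)))
        child = SequenceRecord(f"fam{f:02d}_c", child_seq)
        seqs += [parent, child]
        parents.append(parent)
        partition.append(frozenset({parent.id, child.id}))
    for s in range(n_singletons):
        src = parents[s % len(parents)]
        far = mutate_sequence(src.seq, singleton_divergence, int(rng.integers(2 ** 31)))
        rec = SequenceRecord(f"sing{s:02d}", far)
        seqs.append(rec)
        partition.append(frozenset({rec.id}))
    return seqs, partition


def generate_read_alignments(
    contig_id: str,
    contig_length: int,
    target_breadth: float,
    n_reads: Optional[int],
    params: GeneratorParams,
    sample_id: str,
) -> list[AlignmentRecord]:
    """Alignment rows achieving the target breadth within +-0.01.

    Reads of ``params.read_length`` tile the covered prefix contiguously;
    surplus reads (to reach ``n_reads``) stack on the first window so breadth
    is unchanged. An explicit ``n_reads`` too small to reach the breadth is
    an error.
    """
    if not (0 <= target_breadth <= 1):
        raise ValidationError("target breadth must be in [0,1]")
    covered = round(target_breadth * contig_length)
    if covered == 0:
        return []
    rl = params.read_length
    tiles = math.ceil(covered / rl)
    if n_reads is None:
        n_reads = tiles
    if n_reads < tiles:
        raise ValidationError(
            f"{contig_id}/{sample_id}: breadth {target_breadth} unreachable with "
            f"{n_reads} reads of length {rl}")
    rows = []
    for k in range(tiles):
        start = k * rl
        end = min(start + rl, covered)
        rows.append(AlignmentRecord(f"{sample_id}_{contig_id}_r{k + 1}", contig_id,
                                    start, end, end - start))
    for k in range(n_reads - tiles):
        rows.append(AlignmentRecord(f"{sample_id}_{contig_id}_x{k + 1}", contig_id,
                                    0, min(rl, covered), min(rl, covered)))
    return rows


# breadth patterns cycled across viruses; they straddle the 0.85 rule
_BREADTH_CYCLE = [
    (0.95, 0.86, 0.84, 0.0),
    (0.86, 0.0, 0.95, 0.84),
    (0.84, 0.95, 0.0, 0.86),
    (0.0, 0.84, 0.86, 0.95),
]


def generate_community(params: Optional[GeneratorParams] = None) -> CommunityBundle:
    """The default synthetic community with every signal class planted."""
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(params.rng_seed)
    truth = PlantedTruth(rng_seed=params.rng_seed, codon_effect=params.codon_delta)

    # ---- viruses are drafted first (the provirus must exist before its host)
    order_of = {h: o for h, o in _HOST_PLAN}
    order_idx = {o: i for i, (o, *_) in enumerate(HOST_ORDERS)}

    def draft_virus(virus_id: str, source_order: str, length: int) -> SequenceRecord:
        trans = _order_transition(order_idx[source_order], params.composition_strength)
        return SequenceRecord(virus_id, markov_sequence(length, trans, rng))

    virus_sources = {
        "v01": "Methanosarcinales", "v02": "Methanobacteriales",
        "v03": "Methanomicrobiales", "v04": "Methanosarcinales",
        "v05": "Methanococcales", "v06": "Methanomassiliicoccales",
        "v07": "Methanosarcinales", "v08": "Methanobacteriales",
        "v09": "Methanomicrobiales", "v10": "Methanosarcinales",
        "v11": "Methanosarcinales", "v12": "Methanomicrobiales",
        "v13": "Methanococcales", "v14": "Methanosarcinales",
        "v15": "Methanosarcinales", "v16": "Methanobacteriales",
        "v17": "Methanomicrobiales", "v18": "Methanococcales",
        "v19": "Methanosarcinales", "v20": "Methanobacteriales",
    }
    viruses = {vid: draft_virus(vid, src, params.virus_length)
               for vid, src in virus_sources.items()}

    # ---- hosts (h02 carries v14 as an integrated provirus)
    hosts: list[HostGenome] = []
    for i, (host_id, order) in enumerate(_HOST_PLAN):
        provirus = viruses["v14"] if host_id == "h02" else None
        h = generate_host_genome(params, host_id, order,
                                 seed=int(rng.integers(2 ** 31)), provirus=provirus)
        hosts.append(h)
    host_by_id = {h.host_id: h for h in hosts}
    truth.provirus_coords["v14"] = ["h02", *host_by_id["h02"].provirus_coords]

    def level4_spacer(host_id: str, k: int = 0) -> SequenceRecord:
        return host_by_id[host_id].arrays[0].spacers[k]

    def level3_spacer(host_id: str, k: int = 0) -> SequenceRecord:
        return host_by_id[host_id].arrays[1].spacers[k]

    def plant_spacer(virus_id: str, spacer: SequenceRecord, host_id: str,
                     mismatches: int, position: int, strand: str,
                     should_find: bool) -> None:
        proto = spacer.seq
        if mismatches:
            # ceil((m/len - eps) * len) == m and substitutions always change
            # the base, so the planted Hamming distance is exactly `mismatches`
            proto = mutate_sequence(proto, mismatches / len(proto) - 1e-9,
                                    int(rng.integers(2 ** 31)))
        if strand == "-":
            proto = revcomp(proto)
        viruses[virus_id] = SequenceRecord(virus_id, _plant(viruses[virus_id].seq, proto, position))
        truth.spacer_links.append({
            "host": host_id, "virus": virus_id, "spacer_id": spacer.id,
            "position": position, "strand": strand, "mismatches": mismatches,
            "should_find": should_find,
        })

    plant_spacer("v01", level4_spacer("h01"), "h01", 0, 100, "+", True)
    plant_spacer("v02", level4_spacer("h03"), "h03", 1, 2000, "+", True)
    plant_spacer("v03", level4_spacer("h05"), "h05", 2, 500, "+", False)
    plant_spacer("v04", level3_spacer("h01"), "h01", 0, 750, "+", False)
    plant_spacer("v13", level4_spacer("h06", 1), "h06", 0, 300, "-", True)
    plant_spacer("v13", level4_spacer("h08"), "h08", 1, 4000, "+", True)
    truth.cross_domain_viruses.append("v13")

    # ---- tRNA plantings
    virus_trnas: dict[str, list[SequenceRecord]] = {}
    t_h06 = host_by_id["h06"].trnas[0]
    virus_trnas["v05"] = [SequenceRecord("v05_trna1", revcomp(t_h06.seq))]
    truth.trna_links.append({"host": "h06", "virus": "v05", "should_find": True})
    t_h07 = host_by_id["h07"].trnas[0]
    near = mutate_sequence(t_h07.seq, 1 / len(t_h07.seq) - 1e-9, int(rng.integers(2 ** 31)))
    virus_trnas["v06"] = [SequenceRecord("v06_trna1", near)]
    truth.trna_links.append({"host": "h07", "virus": "v06", "should_find": False})

    # ---- genes, lifestyle, AMGs
    genes: list[GeneRecord] = []
    for vid in virus_sources:
        genes += _virus_genes(vid, viruses[vid].length, params,
                              viral_like=(vid != "v19"))

    def set_gene(virus_id: str, gene_index: int, **updates) -> GeneRecord:
        for i, g in enumerate(genes):
            if g.contig_id == virus_id and g.gene_index == gene_index:
                genes[i] = dataclasses.replace(g, **updates)
                return genes[i]
        raise ValidationError(f"no gene {virus_id}:{gene_index}")

    set_gene("v02", 3, labels=frozenset({INTEGRASE_LABEL}))
    lysogenic_plan = {
        "v02": ["integrase_gene"],
        "v14": ["provirus_integration"],
    }
    for vid in virus_sources:
        signals = lysogenic_plan.get(vid, [])
        truth.lifestyle[vid] = {"lysogenic": bool(signals), "signals": signals}

    def plant_amg(virus_id: str, gene_index: int, label: str, category: str,
                  aux_score: int, verdict: str) -> None:
        set_gene(virus_id, gene_index, labels=frozenset({label}), category=category,
                 aux_score=aux_score, viral_like=False)
        truth.amg_genes.append({"virus": virus_id, "gene_index": gene_index,
                                "label": label, "verdict": verdict})

    plant_amg("v15", 5, CYSH_LABEL, "sulfur metabolism", 2, "kept")
    plant_amg("v16", 5, DCM_LABEL, "methylation", 1, "kept")
    plant_amg("v17", 5, "K01520", "carbohydrate metabolism", 4, "rejected_score")
    plant_amg("v18", 5, "K00560", "nucleotide metabolism", 2, "rejected_category")
    plant_amg("v19", 5, "K02078", "lipid metabolism", 2, "rejected_flank")
    truth.cysh_viruses.append("v15")

    # Cys-enriched CDS segments embedded in the cysH/dcm viruses
    for vid in ("v15", "v16"):
        cds = _codon_cds(300, params.codon_delta, rng)
        viruses[vid] = SequenceRecord(vid, _plant(viruses[vid].seq, cds, 6000))

    # ---- ORF taxonomy plantings
    taxonomy: list[OrfTaxonomy] = []

    def plant_votes(virus_id: str, order: str, n_votes: int) -> None:
        lin = order_lineage(order)
        for k in range(1, n_votes + 1):
            taxonomy.append(OrfTaxonomy(virus_id, k, lin))

    plant_votes("v07", "Methanosarcinales", 6)
    truth.taxonomy_links.append({"virus": "v07", "lineage": "Methanosarcinales",
                                 "votes": 6, "contig_call": False, "should_find": True})
    plant_votes("v08", "Methanobacteriales", 4)
    truth.taxonomy_links.append({"virus": "v08", "lineage": "Methanobacteriales",
                                 "votes": 4, "contig_call": False, "should_find": False})
    taxonomy.append(OrfTaxonomy("v09", 0, (), order_lineage("Methanomicrobiales")))
    truth.taxonomy_links.append({"virus": "v09", "lineage": "Methanomicrobiales",
                                 "votes": 0, "contig_call": True, "should_find": True})
    plant_votes("v10", "Methanosarcinales", 3)
    plant_votes_start = max(t.gene_index for t in taxonomy if t.contig_id == "v10")
    lin_mb = order_lineage("Methanobacteriales")
    for k in range(plant_votes_start + 1, plant_votes_start + 4):
        taxonomy.append(OrfTaxonomy("v10", k, lin_mb))
    truth.taxonomy_links.append({"virus": "v10", "lineage": "split_3_3",
                                 "votes": 3, "contig_call": False, "should_find": False})

    # ---- bins (binning criterion + MAG quality filter)
    plant_votes("v11", "Methanosarcinales", 1)
    bins = [
        BinRecord("bin_h02", frozenset({"h02", "v11"}), 82.0, 2.5,
                  order_lineage("Methanosarcinales")),
        BinRecord("bin_h05", frozenset({"h05", "v12"}), 76.0, 4.0,
                  order_lineage("Methanomicrobiales")),
        BinRecord("bin_h08", frozenset({"h08"}), 91.0, 1.0,
                  order_lineage("Desulfuromonadales")),
        BinRecord("bin_lowq", frozenset({"h07"}), 42.0, 3.0,
                  order_lineage("Methanomassiliicoccales")),
        BinRecord("bin_contam", frozenset({"h06"}), 88.0, 15.0,
                  order_lineage("Methanococcales")),
    ]
    truth.binning_links.append({"virus": "v11", "bin": "bin_h02",
                                "lineage": "Methanosarcinales", "orf_votes": 1,
                                "should_find": True})
    truth.binning_links.append({"virus": "v12", "bin": "bin_h05",
                                "lineage": "Methanomicrobiales", "orf_votes": 0,
                                "should_find": False})

    # ---- triage candidates (viruses + decoys)
    decoys = [
        SequenceRecord("d01", random_sequence(4000, rng)),
        SequenceRecord("d02", random_sequence(8000, rng)),
        SequenceRecord("d03", random_sequence(6000, rng)),
    ]
    candidates: list[ViralCandidateRecord] = []
    vlist = sorted(virus_sources)
    for i, vid in enumerate(vlist):
        if i < 8:
            cand = ViralCandidateRecord(vid, ev_pipeline_hit=True,
                                        provirus_flag=(vid == "v14"))
            rule = "ev_pipeline"
        elif i < 16:
            cand = ViralCandidateRecord(vid, sorter_category=1 + i % 2,
                                        provirus_flag=(vid == "v14"))
            rule = "sorter_cat12"
        else:
            cand = ViralCandidateRecord(vid, sorter_category=3, dl_score=0.95,
                                        dl_p=0.01, provirus_flag=(vid == "v14"))
            rule = "sorter_cat3_dl"
        candidates.append(cand)
        truth.triage_expected[vid] = {"accepted": True, "rule": rule}
    candidates.append(ViralCandidateRecord("d01", ev_pipeline_hit=True))
    truth.triage_expected["d01"] = {"accepted": False, "rule": "none"}
    candidates.append(ViralCandidateRecord("d02"))
    truth.triage_expected["d02"] = {"accepted": False, "rule": "none"}
    candidates.append(ViralCandidateRecord("d03", sorter_category=3, dl_score=0.95, dl_p=0.01))
    truth.triage_expected["d03"] = {"accepted": True, "rule": "sorter_cat3_dl"}

    # v14's provirus flag must also live on the candidate used in lifestyle calls
    # (set above); decoys carry no lifestyle truth.

    # ---- abundance
    samples = [f"s{j + 1:02d}" for j in range(params.n_samples)]
    alignments: dict[str, list[AlignmentRecord]] = {s: [] for s in samples}
    for i, vid in enumerate(vlist):
        pattern = _BREADTH_CYCLE[i % len(_BREADTH_CYCLE)]
        for j, sample in enumerate(samples):
            breadth = pattern[j % len(pattern)]
            length = viruses[vid].length
            tiles = math.ceil(round(breadth * length) / params.read_length)
            n_reads = tiles + 5 * i if breadth else 0
            rows = generate_read_alignments(vid, length, breadth, n_reads or None,
                                            params, sample)
            alignments[sample] += rows
            truth.abundance.append({
                "virus": vid, "sample": sample, "target_breadth": breadth,
                "n_reads": len(rows), "expect_present": breadth >= 0.85,
            })
    for sample in samples:
        truth.sample_totals[sample] = len(alignments[sample]) + params.background_reads

    virus_records = [viruses[v] for v in vlist] + decoys
    return CommunityBundle(params, hosts, virus_records, genes, taxonomy,
                           candidates, bins, virus_trnas, alignments, truth)


# --------------------------------------------------------------------------
# on-disk bundle

def write_bundle(bundle: CommunityBundle, outdir) -> None:
    """Serialise the community as the pipeline's plain-text input bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_fasta([h.record for h in bundle.hosts], outdir / "hosts.fasta")
    mio.write_fasta(bundle.viruses, outdir / "viruses.fasta")
    mio.write_gene_table(bundle.genes, outdir / "genes.tsv")
    mio.write_taxonomy_table(bundle.taxonomy, outdir / "taxonomy.tsv")
    mio.write_crispr_table([a for h in bundle.hosts for a in h.arrays],
                           outdir / "crispr.tsv")
    mio.write_trna_table({h.host_id: h.trnas for h in bundle.hosts},
                         outdir / "trna_host.tsv")
    mio.write_trna_table(bundle.virus_trnas, outdir / "trna_virus.tsv")
    mio.write_candidate_table(bundle.candidates, outdir / "candidates.tsv")
    mio.write_bin_table(bundle.bins, outdir / "bins.tsv")
    host_rows = [{"host_id": h.host_id, "order": h.order,
                  "lineage": ";".join(h.lineage)} for h in bundle.hosts]
    pd.DataFrame(host_rows).to_csv(outdir / "hosts.tsv", sep="\t", index=False)
    for sample, rows in bundle.alignments.items():
        mio.write_alignment_table(rows, outdir / f"alignments_{sample}.tsv")
    totals = pd.DataFrame(
        [{"sample_id": s, "total_mapped_reads": t}
         for s, t in bundle.truth.sample_totals.items()])
    totals.to_csv(outdir / "sample_totals.tsv", sep="\t", index=False)
    bundle.truth.to_json(outdir / "truth.json")
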