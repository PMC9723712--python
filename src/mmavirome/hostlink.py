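"""Four-criterion virus-host prediction and cross-domain detection.

The four evidence classes, in decreasing confidence:

1. ``crispr``        — a host CRISPR spacer (from a confidence-tier-4 array)
                       occurs on the virus with at most ``spacer_max_mismatch``
                       substitutions over its full length (no indels);
2. ``trna``          — a virus-encoded tRNA is exactly identical to a host
                       tRNA (either strand);
3. ``taxonomy_vote`` — the contig itself, or at least ``min_orf_votes`` of
                       its ORFs, classify within a target host lineage;
4. ``binning``       — the viral contig was binned into a target-lineage MAG
                       and carries at least ``min_binned_orf_votes`` ORFs of
                       that lineage.

Spacer scanning is vectorised: every window of the virus is compared to the
spacer byte-wise over both strands, counting Hamming mismatches; ambiguous
bases (N) never match anything, including another N.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    BinRecord,
    Config,
    CrisprArrayRecord,
    OrfTaxonomy,
    SequenceRecord,
    ValidationError,
    revcomp,
)

CRITERIA = ("crispr", "trna", "taxonomy_vote", "binning")
# reporting precedence for the "best host" of a virus; lower index wins
CRITERION_RANK = {c: i for i, c in enumerate(CRITERIA)}


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    host_id: str
    virus_id: str
    position: int  # 0-based start on the virus, forward coordinates
    strand: str  # '+' spacer as given, '-' its reverse complement
    mismatches: int


@dataclass(frozen=True)
class HostLink:
    virus_id: str
    host_id: str
    host_lineage: tuple[str, ...]
    criterion: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValidationError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class CrossDomainCall:
    virus_id: str
    host_groups: frozenset[tuple[str, tuple[str, ...]]]  # (domain, lineage)
    is_cross_domain: bool


# distinct codes for query vs target ambiguity so N never matches, even N vs N
_Q_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_T_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}


def _encode(seq: str, table: dict[str, int]) -> np.ndarray:
    lut = np.full(128, 7, dtype=np.int8)
    for base, code in table.items():
        lut[ord(base)] = code
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan(spacer: np.ndarray, target: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All (position, mismatches) of full-length ungapped occurrences."""
    m, n = len(spacer), len(target)
    if m > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(target, m)
    mism = (windows != spacer).sum(axis=1)
    hits = np.nonzero(mism <= max_mm)[0]
    return [(int(p), int(mism[p])) for p in hits]


def find_spacer_matches(
    arrays: list[CrisprArrayRecord],
    viruses: list[SequenceRecord],
    cfg: Config,
) -> list[SpacerMatch]:
    """Scan trusted-array spacers against every virus on both strands.

    Arrays below ``cfg.crispr_min_evidence`` are ignored. Every qualifying
    occurrence is reported, including overlapping ones and hits on both
    strands at the same locus; deduplication to virus-host pairs happens at
    aggregation.
    """
    matches: list[SpacerMatch] = []
    encoded = [(v, _encode(v.seq, _T_CODE)) for v in viruses]
    for arr in arrays:
        if arr.evidence_level < cfg.crispr_min_evidence:
            continue
        for sp in arr.spacers:
            fwd = _encode(sp.seq, _Q_CODE)
            rev = _encode(revcomp(sp.seq), _Q_CODE)
            for virus, tgt in encoded:
                for pos, mm in _scan(fwd, tgt, cfg.spacer_max_mismatch):
                    matches.append(SpacerMatch(sp.id, arr.host_id, virus.id, pos, "+", mm))
                for pos, mm in _scan(rev, tgt, cfg.spacer_max_mismatch):
                    matches.append(SpacerMatch(sp.id, arr.host_id, virus.id, pos, "-", mm))
    return matches


def spacer_matches_to_links(
    matches: list[SpacerMatch],
    host_lineages: dict[str, tuple[str, ...]],
) -> list[HostLink]:
    """Collapse spacer matches into one crispr link per (virus, host)."""
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for m in matches:
        counts[(m.virus_id, m.host_id)] += 1
    return [HostLink(v, h, host_lineages.get(h, ()), "crispr", support=c)
            for (v, h), c in sorted(counts.items())]


def find_trna_matches(
    virus_trnas: dict[str, list[SequenceRecord]],
    host_trnas: dict[str, list[SequenceRecord]],
    host_lineages: dict[str, tuple[str, ...]],
) -> list[HostLink]:
    """Link a virus to a host when any tRNA is identical (either strand)."""
    index: dict[str, set[str]] = defaultdict(set)
    for host_id, trnas in host_trnas.items():
        for t in trnas:
            index[t.seq].add(host_id)
            index[revcomp(t.seq)].add(host_id)
    pairs: dict[tuple[str, str], int] = defaultdict(int)
    for virus_id, trnas in virus_trnas.items():
        for t in trnas:
            for host_id in index.get(t.seq, ()):
                pairs[(virus_id, host_id)] += 1
    return [HostLink(v, h, host_lineages.get(h, ()), "trna", support=c)
            for (v, h), c in sorted(pairs.items())]


def _rank_value(lineage: tuple[str, ...], rank: str) -> str:
    idx = OrfTaxonomy.RANKS.index(rank)
    return lineage[idx] if idx < len(lineage) else ""


def taxonomy_vote_link(
    orf_taxa: list[OrfTaxonomy],
    target_lineages: dict[str, tuple[str, ...]],
    cfg: Config,
) -> list[HostLink]:
    """Link a contig to a target lineage by whole-contig call or ORF votes.

    ``target_lineages`` maps a lineage name at ``cfg.host_rank`` (e.g. an
    order) to its full lineage. Votes are counted per target lineage; the
    whole-contig call links regardless of vote count.
    """
    votes: dict[tuple[str, str], int] = defaultdict(int)
    contig_call: dict[str, set[str]] = defaultdict(set)
    for t in orf_taxa:
        for name in target_lineages:
            if t.gene_index > 0 and _rank_value(t.lineage, cfg.host_rank) == name:
                votes[(t.contig_id, name)] += 1
            if t.contig_lineage and _rank_value(t.contig_lineage, cfg.host_rank) == name:
                contig_call[t.contig_id].add(name)
    links = []
    contigs = {t.contig_id for t in orf_taxa}
    for contig in sorted(contigs):
        for name in sorted(target_lineages):
            n_votes = votes.get((contig, name), 0)
            if name in contig_call.get(contig, ()) or n_votes >= cfg.min_orf_votes:
                links.append(HostLink(contig, name, target_lineages[name],
                                      "taxonomy_vote", support=n_votes))
    return links


def binning_link(
    virus_contig_ids: list[str],
    bins: list[BinRecord],
    bin_orf_votes: dict[tuple[str, str], int],
    target_lineages: dict[str, tuple[str, ...]],
    cfg: Config,
) -> list[HostLink]:
    """Link a viral contig co-binned into a target-lineage MAG.

    ``bin_orf_votes`` maps (contig_id, lineage_name) -> number of ORFs on the
    contig classified as that lineage. Bins must partition contigs.
    """
    membership: dict[str, BinRecord] = {}
    for b in bins:
        for c in b.member_contigs:
            if c in membership:
                raise ValidationError(f"contig {c} is a member of two bins")
            membership[c] = b
    links = []
    for contig in virus_contig_ids:
        b = membership.get(contig)
        if b is None:
            continue
        name = _rank_value(b.lineage, cfg.host_rank)
        if name not in target_lineages:
            continue
        n_votes = bin_orf_votes.get((contig, name), 0)
        if n_votes >= cfg.min_binned_orf_votes:
            links.append(HostLink(contig, b.bin_id, b.lineage, "binning", support=n_votes))
    return links


def aggregate_links(all_links: list[HostLink]) -> pd.DataFrame:
    """Deduplicate links by (virus, host lineage, criterion) into a table.

    Returns a DataFrame with columns virus_id, host_id, host_lineage,
    criterion, support; support sums over duplicate rows. Use
    ``criterion_counts`` / ``best_hosts`` for the derived summaries.
    """
    rows = [{
        "virus_id": l.virus_id, "host_id": l.host_id,
        "host_lineage": ";".join(l.host_lineage), "criterion": l.criterion,
        "support": l.support,
    } for l in all_links]
    df = pd.DataFrame(rows, columns=["virus_id", "host_id", "host_lineage",
                                     "criterion", "support"])
    if df.empty:
        return df
    df = (df.groupby(["virus_id", "host_lineage", "criterion"], as_index=False)
            .agg(host_id=("host_id", "min"), support=("support", "max")))
    return df[["virus_id", "host_id", "host_lineage", "criterion", "support"]] \
        .sort_values(["virus_id", "criterion", "host_lineage"], ignore_index=True)


def criterion_counts(table: pd.DataFrame) -> dict[str, int]:
    counts = {c: 0 for c in CRITERIA}
    if not table.empty:
        counts.update(table["criterion"].value_counts().to_dict())
    return counts


def best_hosts(table: pd.DataFrame) -> pd.DataFrame:
    """One row per virus: the link from the highest-confidence criterion."""
    if table.empty:
        return table
    ranked = table.assign(_rank=table["criterion"].map(CRITERION_RANK))
    idx = ranked.sort_values(["virus_id", "_rank", "host_lineage"]) \
                .groupby("virus_id", as_index=False).head(1).index
    return table.loc[idx].sort_values("virus_id", ignore_index=True)


def detect_cross_domain(table: pd.DataFrame) -> list[CrossDomainCall]:
    """Flag viruses linked to hosts in two or more domains."""
    calls = []
    if table.empty:
        return calls
    for virus_id, grp in table.groupby("virus_id"):
        groups = set()
        for lin_str in grp["host_lineage"]:
            lin = tuple(lin_str.split(";")) if lin_str else ()
            domain = lin[0] if lin else ""
            groups.add((domain, lin))
        domains = {d for d, _ in groups if d}
        calls.append(CrossDomainCall(virus_id, frozenset(groups), len(domains) >= 2))
    return sorted(calls, key=lambda c: c.virus_id)
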