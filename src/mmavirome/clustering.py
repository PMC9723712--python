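"""Pairwise ANI/AF, greedy species-rank clustering (vOTUs), novelty calls.

ANI (average nucleotide identity) is the percent identity over aligned
columns of the best glocal alignment of the shorter sequence into the
longer; AF (aligned fraction) is the percentage of the shorter sequence
covered by that alignment. Species-rank viral clusters (vOTUs) use 95% ANI
over 85% AF; the same engine dereplicates MAGs at 99% ANI.

Clustering is greedy on length-descending order (ties broken by id), each
sequence joining the first existing cluster whose *representative* it
matches, so the longest member is the representative by construction and the
result is deterministic for a fixed input set.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .records import SequenceRecord, ValidationError


@dataclass(frozen=True)
class AniResult:
    query_id: str
    target_id: str
    ani: float  # % identity over aligned columns
    af: float  # % of the shorter sequence covered by the alignment


@dataclass(frozen=True)
class VOTU:
    votu_id: str
    representative_id: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValidationError(f"{self.votu_id}: representative not a member")


@dataclass(frozen=True)
class NoveltyCall:
    votu_id: str
    status: str  # novel | improved | redundant


def _parse_cigar(cigar: str) -> tuple[int, int, int]:
    """Return (matches, columns, query_aligned_bases) from an extended cigar."""
    matches = columns = qbases = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
            qbases += n
        elif ch == "X":
            qbases += n
        elif ch == "I":  # insertion in target relative to query
            qbases += n
        elif ch != "D":
            raise ValueError(f"unexpected cigar op {ch!r}")
    return matches, columns, qbases


def pairwise_ani_af(a: SequenceRecord, b: SequenceRecord) -> AniResult:
    """ANI/AF between two sequences, symmetric under argument swap.

    The shorter sequence (ties broken by id) is aligned as an infix of the
    longer, allowing substitutions and indels; ANI is computed over all
    aligned columns including gap columns, AF over the shorter length.
    """
    if not a.seq or not b.seq:
        raise ValidationError("pairwise_ani_af requires non-empty sequences")
    short, long_ = sorted((a, b), key=lambda r: (r.length, r.id))
    res = edlib.align(short.seq, long_.seq, mode="HW", task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        return AniResult(a.id, b.id, 0.0, 0.0)
    matches, columns, qbases = _parse_cigar(res["cigar"])
    ani = 100.0 * matches / columns if columns else 0.0
    af = 100.0 * qbases / short.length
    return AniResult(a.id, b.id, ani, af)


def greedy_cluster(
    seqs: list[SequenceRecord],
    ani_min: float,
    af_min: float,
    prefix: str = "vOTU",
) -> list[VOTU]:
    """Greedy centroid clustering at the given ANI/AF thresholds.

    Sequences are processed longest-first (ties by id); each joins the first
    existing cluster whose representative satisfies both thresholds, else
    founds a new cluster. The output partitions the input.
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids in clustering input")
    ordered = sorted(seqs, key=lambda s: (-s.length, s.id))
    reps: list[SequenceRecord] = []
    members: dict[str, list[str]] = {}
    for seq in ordered:
        placed = False
        for rep in reps:
            r = pairwise_ani_af(seq, rep)
            if r.ani >= ani_min and r.af >= af_min:
                members[rep.id].append(seq.id)
                placed = True
                break
        if not placed:
            reps.append(seq)
            members[seq.id] = [seq.id]
    return [
        VOTU(f"{prefix}_{i:05d}", rep.id, frozenset(members[rep.id]))
        for i, rep in enumerate(reps, start=1)
    ]


def classify_novelty(
    votus: list[VOTU],
    study_ids: set[str],
    reference_ids: set[str],
    lengths: dict[str, int],
) -> list[NoveltyCall]:
    """Classify each study-containing vOTU against the reference collection.

    novel: no reference member; improved: reference members exist but the
    longest study member is strictly longer than every reference member;
    redundant: otherwise. Clusters with no study member are excluded, the
    reference-only case carrying no information about the study.
    """
    calls = []
    for v in votus:
        study = [m for m in v.member_ids if m in study_ids]
        ref = [m for m in v.member_ids if m in reference_ids]
        if not study:
            continue
        if not ref:
            status = "novel"
        elif max(lengths[m] for m in study) > max(lengths[m] for m in ref):
            status = "improved"
        else:
            status = "redundant"
        calls.append(NoveltyCall(v.votu_id, status))
    return calls
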