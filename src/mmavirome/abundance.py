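"""Coverage breadth/depth, RPKM, presence calls and occupancy summaries.

Presence of a virus in a sample is called from coverage *breadth* alone: the
fraction of the contig covered by at least one read must reach
``cfg.breadth_min`` (default 0.85). RPKM (reads per kilobase per million
mapped reads) quantifies relative abundance but never gates presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import AlignmentRecord, Config, ValidationError


@dataclass(frozen=True)
class CoverageResult:
    contig_id: str
    sample_id: str
    mapped_reads: int
    breadth: float  # fraction of bases covered >= 1x
    mean_depth: float
    rpkm: float
    present: bool


@dataclass(frozen=True)
class OccupancySummary:
    n_samples: int
    counts: dict[str, int]  # votu -> number of samples present (>=1 only)
    histogram: dict[int, int]  # occupancy -> number of vOTUs
    fraction_single_sample: float
    fraction_below_4_samples: float


def coverage_from_alignments(
    alignments: list[AlignmentRecord],
    contig_length: int,
    identity_min: float | None = None,
) -> tuple[float, float, int]:
    """(breadth, mean_depth, mapped_reads) from alignment intervals.

    Breadth uses the union of intervals; mean depth the sum of interval
    lengths over the contig length. Each alignment row counts as one mapped
    read. ``identity_min``, when given, drops rows below the threshold.
    """
    if contig_length <= 0:
        raise ValidationError("contig_length must be positive")
    ivals = []
    for a in alignments:
        if a.contig_end > contig_length:
            raise ValidationError(
                f"alignment {a.read_id} ends at {a.contig_end} beyond contig length {contig_length}")
        if identity_min is not None and a.identity < identity_min:
            continue
        ivals.append((a.contig_start, a.contig_end))
    if not ivals:
        return 0.0, 0.0, 0
    ivals.sort()
    covered = 0
    cur_s, cur_e = ivals[0]
    total = 0
    for s, e in ivals:
        total += e - s
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / contig_length, total / contig_length, len(ivals)


def rpkm(mapped_reads: int, contig_length_bases: int, total_mapped_reads_in_sample: int) -> float:
    """reads / (length/1e3 * total/1e6); errors when the sample total is 0."""
    if total_mapped_reads_in_sample <= 0:
        raise ValidationError("total mapped reads in sample must be positive")
    if contig_length_bases <= 0:
        raise ValidationError("contig length must be positive")
    return mapped_reads / ((contig_length_bases / 1e3) * (total_mapped_reads_in_sample / 1e6))


def presence_call(breadth: float, cfg: Config) -> bool:
    """Present iff breadth >= cfg.breadth_min (inclusive)."""
    return breadth >= cfg.breadth_min


def profile_sample(
    alignments_by_contig: dict[str, list[AlignmentRecord]],
    lengths: dict[str, int],
    sample_id: str,
    total_mapped_reads: int,
    cfg: Config,
) -> list[CoverageResult]:
    """CoverageResult for every contig of one sample."""
    results = []
    for contig_id in sorted(lengths):
        aln = alignments_by_contig.get(contig_id, [])
        breadth, depth, n = coverage_from_alignments(aln, lengths[contig_id], cfg.identity_min)
        value = rpkm(n, lengths[contig_id], total_mapped_reads) if total_mapped_reads else 0.0
        results.append(CoverageResult(contig_id, sample_id, n, breadth, depth,
                                      value, presence_call(breadth, cfg)))
    return results


def presence_matrix(results: list[CoverageResult]) -> pd.DataFrame:
    """Boolean vOTU x sample matrix from per-sample coverage results."""
    rows = [{"contig_id": r.contig_id, "sample_id": r.sample_id, "present": r.present}
            for r in results]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    return (df.pivot(index="contig_id", columns="sample_id", values="present")
              .fillna(False).astype(bool))


def rpkm_matrix(results: list[CoverageResult]) -> pd.DataFrame:
    rows = [{"contig_id": r.contig_id, "sample_id": r.sample_id, "rpkm": r.rpkm}
            for r in results]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    return df.pivot(index="contig_id", columns="sample_id", values="rpkm").fillna(0.0)


def occupancy_summary(matrix: pd.DataFrame) -> OccupancySummary:
    """Occupancy per vOTU and corpus fractions (singletons, <4 samples).

    vOTUs absent everywhere are excluded from the fractions: a virus never
    observed cannot be "found in" any number of samples.
    """
    if matrix.empty:
        return OccupancySummary(0, {}, {}, float("nan"), float("nan"))
    occ = matrix.sum(axis=1).astype(int)
    found = occ[occ > 0]
    hist = found.value_counts().sort_index()
    n_found = len(found)
    frac1 = float((found == 1).sum() / n_found) if n_found else float("nan")
    frac_lt4 = float((found < 4).sum() / n_found) if n_found else float("nan")
    return OccupancySummary(
        n_samples=matrix.shape[1],
        counts=found.to_dict(),
        histogram={int(k): int(v) for k, v in hist.items()},
        fraction_single_sample=frac1,
        fraction_below_4_samples=frac_lt4,
    )
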