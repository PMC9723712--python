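"""Auxiliary metabolic gene (AMG) curation.

Candidate AMGs (genes carrying an auxiliary score) pass through three checks
in a fixed order, and the verdict names the first failing one:

1. score    — auxiliary score must be <= ``cfg.aux_score_max`` (default 3);
2. category — functional categories in ``cfg.excluded_amg_categories``
   (default: nucleotide metabolism, ubiquitous in viral genomes and hence
   uninformative) are rejected;
3. flank    — the genomic context must look viral: at least one viral-like
   gene within ``cfg.amg_flank_window`` genes on each side. A side with no
   genes at all (contig end) passes by itself, so a candidate at the edge is
   judged on the side that exists.

The flank rule is the codified form of the usual manual curation step:
a metabolic gene embedded among viral genes is a credible AMG, one flanked
by host-like genes is likely co-assembled host sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import Config, GeneRecord

VERDICTS = ("kept", "rejected_score", "rejected_category", "rejected_flank")


@dataclass(frozen=True)
class AmgCall:
    contig_id: str
    gene_index: int
    label: str
    aux_score: int
    verdict: str
    flank_evidence: tuple[int, int]  # viral-like genes (upstream, downstream)


def _flank_counts(genes: list[GeneRecord], pos: int, window: int) -> tuple[int, int, bool, bool]:
    up = genes[max(0, pos - window):pos]
    down = genes[pos + 1:pos + 1 + window]
    n_up = sum(g.viral_like for g in up)
    n_down = sum(g.viral_like for g in down)
    return n_up, n_down, len(up) == 0, len(down) == 0


def curate_amgs(genes: list[GeneRecord], cfg: Config) -> list[AmgCall]:
    """Apply the score -> category -> flank verdict chain per candidate.

    ``genes`` may span several contigs; each contig's genes are ordered by
    start coordinate before flanks are inspected. Candidates are the genes
    whose ``aux_score`` is present.
    """
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    excluded = {c.lower() for c in cfg.excluded_amg_categories}
    calls: list[AmgCall] = []
    for contig_id in sorted(by_contig):
        ordered = sorted(by_contig[contig_id], key=lambda g: g.start)
        for pos, g in enumerate(ordered):
            if g.aux_score is None:
                continue
            n_up, n_down, no_up, no_down = _flank_counts(ordered, pos, cfg.amg_flank_window)
            if g.aux_score > cfg.aux_score_max:
                verdict = "rejected_score"
            elif g.category.lower() in excluded:
                verdict = "rejected_category"
            elif (n_up >= 1 or no_up) and (n_down >= 1 or no_down):
                verdict = "kept"
            else:
                verdict = "rejected_flank"
            label = min(g.labels) if g.labels else ""
            calls.append(AmgCall(contig_id, g.gene_index, label, g.aux_score,
                                 verdict, (n_up, n_down)))
    return calls
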