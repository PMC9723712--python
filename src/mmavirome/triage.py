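"""Stepwise viral-candidate triage, MAG quality filter, lysogeny calls.

Triage follows a fixed confidence ladder: contigs below the length gate are
rejected outright; otherwise the first accepting rule wins, so the per-rule
counts are disjoint by construction:

1. ``ev_pipeline``    — hit by the reference-virome detection protocol;
2. ``sorter_cat12``   — sorter virus/provirus category 1 or 2;
3. ``sorter_cat3_dl`` — sorter category 3 rescued by the deep-learning
   detector (score >= dl_score_min and p < dl_p_max).

A contig is called lysogenic when it carries an integrase gene (Pfam family
in ``cfg.integrase_labels``) or was detected as an integrated provirus;
either signal alone suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import BinRecord, Config, GeneRecord, ValidationError, ViralCandidateRecord

TRIAGE_RULES = ("ev_pipeline", "sorter_cat12", "sorter_cat3_dl", "none")


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    accepted: bool
    rule_fired: str

    def __post_init__(self) -> None:
        if self.rule_fired not in TRIAGE_RULES:
            raise ValidationError(f"unknown triage rule {self.rule_fired!r}")
        if self.accepted and self.rule_fired == "none":
            raise ValidationError("accepted decision must name a rule")


@dataclass(frozen=True)
class LifestyleCall:
    contig_id: str
    lysogenic: bool
    signals: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.lysogenic != bool(self.signals):
            raise ValidationError("lysogenic iff signals non-empty")


def triage_viral_candidates(
    candidates: list[ViralCandidateRecord],
    lengths: dict[str, int],
    cfg: Config,
) -> list[TriageDecision]:
    """Apply the stepwise acceptance ladder to every candidate contig.

    Missing scores are non-accepting, never errors: a contig with no
    detector support simply falls through to rejection.
    """
    decisions = []
    for cand in candidates:
        if cand.contig_id not in lengths:
            raise ValidationError(f"no length for contig {cand.contig_id}")
        rule = "none"
        if lengths[cand.contig_id] >= cfg.viral_min_len:
            if cand.ev_pipeline_hit:
                rule = "ev_pipeline"
            elif cand.sorter_category in {1, 2}:
                rule = "sorter_cat12"
            elif (cand.sorter_category == 3 and cand.dl_score is not None
                  and cand.dl_score >= cfg.dl_score_min and cand.dl_p < cfg.dl_p_max):
                rule = "sorter_cat3_dl"
        decisions.append(TriageDecision(cand.contig_id, rule != "none", rule))
    return decisions


def filter_mags(bins: list[BinRecord], cfg: Config) -> list[BinRecord]:
    """Keep bins with completeness >= 50% and contamination <= 10% (inclusive)."""
    return [b for b in bins
            if b.completeness >= cfg.mag_completeness_min
            and b.contamination <= cfg.mag_contamination_max]


def classify_lifestyle(
    genes: list[GeneRecord],
    candidate: ViralCandidateRecord,
    cfg: Config,
) -> LifestyleCall:
    """Call lysogeny from integrase annotation and/or provirus integration."""
    signals = set()
    integrase = set(cfg.integrase_labels)
    for g in genes:
        if g.contig_id != candidate.contig_id:
            raise ValidationError(
                f"gene on {g.contig_id} passed with candidate {candidate.contig_id}")
        if g.labels & integrase:
            signals.add("integrase_gene")
    if candidate.provirus_flag:
        signals.add("provirus_integration")
    return LifestyleCall(candidate.contig_id, bool(signals), frozenset(signals))
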