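"""Domain records and the validated configuration object.

All coordinates inside the package are 0-based half-open. File readers and
writers convert to/from 1-based inclusive where the on-disk standard (GFF3)
requires it.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Optional

_VALID_BASES = frozenset("ACGTN")
_WS = re.compile(r"\s")

COMPLETENESS_TIERS = ("complete", "high", "medium", "low", "undetermined")


class ValidationError(ValueError):
    """Raised when an input record or configuration violates an invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """A contig, genome, spacer or tRNA as uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or _WS.search(self.id):
            raise ValidationError(f"sequence id {self.id!r} is empty or contains whitespace")
        seq = self.seq.upper()
        if seq != self.seq:
            object.__setattr__(self, "seq", seq)
        if not seq:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValidationError(f"sequence {self.id!r} contains invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """A called ORF with its functional annotation.

    ``aux_score`` is the DRAM-v style auxiliary score (lower means the gene
    sits in a more confidently viral context); ``None`` when the gene is not
    an AMG candidate. ``viral_like`` flags hallmark/viral-origin genes used by
    the flanking-gene curation rule.
    """

    contig_id: str
    gene_index: int  # 1-based ordinal along the contig
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    labels: frozenset[str] = field(default_factory=frozenset)
    category: str = ""
    viral_like: bool = False
    aux_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.contig_id}:{self.gene_index}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.contig_id}:{self.gene_index}: bad coordinates [{self.start},{self.end})"
            )
        if self.gene_index < 1:
            raise ValidationError(f"gene index must be >= 1, got {self.gene_index}")
        if self.aux_score is not None and self.aux_score < 0:
            raise ValidationError("aux_score must be >= 0")
        self.labels = frozenset(self.labels)


@dataclass
class OrfTaxonomy:
    """Per-ORF lineage plus the whole-contig lineage call.

    Lineages are ordered rank lists domain -> species; absent ranks are empty
    strings. ``gene_index`` of 0 denotes the contig-level row.
    """

    contig_id: str
    gene_index: int
    lineage: tuple[str, ...]
    contig_lineage: tuple[str, ...] = ()

    RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

    def __post_init__(self) -> None:
        for lin in (self.lineage, self.contig_lineage):
            seen_empty = False
            for rank in lin:
                if rank == "":
                    seen_empty = True
                elif seen_empty:
                    raise ValidationError(
                        f"{self.contig_id}:{self.gene_index}: lineage not prefix-consistent: {lin}"
                    )


@dataclass
class CrisprArrayRecord:
    """A CRISPR array on a host genome with its confidence tier (1-4)."""

    host_id: str
    array_id: str
    evidence_level: int
    spacers: list[SequenceRecord]

    def __post_init__(self) -> None:
        if self.evidence_level not in {1, 2, 3, 4}:
            raise ValidationError(
                f"array {self.array_id}: evidence_level must be 1-4, got {self.evidence_level}"
            )
        for sp in self.spacers:
            if sp.length < 8:
                raise ValidationError(f"spacer {sp.id} shorter than 8 nt")


@dataclass
class AlignmentRecord:
    """One read alignment interval on a contig (PAF-like minimal columns)."""

    read_id: str
    contig_id: str
    contig_start: int
    contig_end: int
    read_length: int
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.contig_start < self.contig_end):
            raise ValidationError(
                f"alignment {self.read_id}: bad interval [{self.contig_start},{self.contig_end})"
            )
        if self.read_length <= 0:
            raise ValidationError(f"alignment {self.read_id}: read_length must be positive")
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"alignment {self.read_id}: identity outside [0,1]")


@dataclass
class ViralCandidateRecord:
    """Per-contig outputs of the upstream virus detectors, consumed by triage."""

    contig_id: str
    ev_pipeline_hit: bool = False
    sorter_category: Optional[int] = None
    dl_score: Optional[float] = None
    dl_p: Optional[float] = None
    provirus_flag: bool = False
    completeness_tier: str = "undetermined"

    def __post_init__(self) -> None:
        if self.sorter_category is not None and self.sorter_category not in {1, 2, 3}:
            raise ValidationError(f"{self.contig_id}: sorter_category must be 1-3")
        if (self.dl_score is None) != (self.dl_p is None):
            raise ValidationError(f"{self.contig_id}: dl_p present iff dl_score present")
        if self.completeness_tier not in COMPLETENESS_TIERS:
            raise ValidationError(f"{self.contig_id}: unknown completeness tier {self.completeness_tier!r}")


@dataclass
class BinRecord:
    """A metagenome-assembled genome bin with CheckM-style quality."""

    bin_id: str
    member_contigs: frozenset[str]
    completeness: float
    contamination: float
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100):
            raise ValidationError(f"bin {self.bin_id}: completeness outside [0,100]")
        if self.contamination < 0:
            raise ValidationError(f"bin {self.bin_id}: contamination < 0")
        self.member_contigs = frozenset(self.member_contigs)


# Default Pfam accessions taken as integrase evidence (common phage-integrase
# families: tyrosine recombinase core + SAM-like N-terminal domains and the
# serine recombinase/resolvase family).
DEFAULT_INTEGRASE_LABELS = ("PF00589", "PF02899", "PF13495", "PF00239")

DEFAULT_EXCLUDED_AMG_CATEGORIES = ("nucleotide metabolism",)


@dataclass
class Config:
    """Every threshold used by the pipeline, with published defaults.

    No operation in the package hard-codes a numeric threshold; each takes it
    from here, so the study's values are auditable and overridable in one
    place.
    """

    ani_min: float = 95.0  # % identity for species-rank (vOTU) clustering
    af_min: float = 85.0  # % of the shorter sequence that must align
    derep_ani: float = 99.0  # % identity for MAG dereplication
    spacer_max_mismatch: int = 1  # Hamming tolerance over the full spacer
    min_orf_votes: int = 5  # ORF votes for the taxonomy criterion
    min_binned_orf_votes: int = 1  # ORF votes for the co-binning criterion
    crispr_min_evidence: int = 4  # CRISPR array confidence tier required
    breadth_min: float = 0.85  # covered fraction for a presence call
    dl_score_min: float = 0.9  # deep-learning virus score floor
    dl_p_max: float = 0.05  # deep-learning p-value ceiling
    aux_score_max: int = 3  # AMG auxiliary-score ceiling
    edge_sig_min: float = 10.0  # -log10 hypergeometric tail for network edges
    mag_completeness_min: float = 50.0  # %
    mag_contamination_max: float = 10.0  # %
    viral_min_len: int = 5000  # bases; triage length gate
    bin_min_len: int = 2000  # bases; binning length gate
    rng_seed: int = 0
    host_rank: str = "order"  # rank at which host lineages are matched
    identity_min: Optional[float] = None  # optional read-identity filter
    amg_flank_window: int = 3  # genes checked on each side of an AMG candidate
    integrase_labels: tuple[str, ...] = DEFAULT_INTEGRASE_LABELS
    excluded_amg_categories: tuple[str, ...] = DEFAULT_EXCLUDED_AMG_CATEGORIES

    _RANGES = {
        "ani_min": (0, 100),
        "af_min": (0, 100),
        "derep_ani": (0, 100),
        "breadth_min": (0, 1),
        "dl_score_min": (0, 1),
        "dl_p_max": (0, 1),
        "mag_completeness_min": (0, 100),
        "mag_contamination_max": (0, 100),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            val = getattr(self, key)
            if not (lo <= val <= hi):
                raise ValidationError(f"config {key}={val} outside [{lo},{hi}]")
        for key in ("spacer_max_mismatch", "aux_score_max"):
            if getattr(self, key) < 0:
                raise ValidationError(f"config {key} must be >= 0")
        for key in ("min_orf_votes", "min_binned_orf_votes", "viral_min_len",
                    "bin_min_len", "amg_flank_window"):
            if getattr(self, key) < 1:
                raise ValidationError(f"config {key} must be >= 1")
        if self.crispr_min_evidence not in {1, 2, 3, 4}:
            raise ValidationError("config crispr_min_evidence must be 1-4")
        if self.edge_sig_min < 0:
            raise ValidationError("config edge_sig_min must be >= 0")
        if self.host_rank not in OrfTaxonomy.RANKS:
            raise ValidationError(f"config host_rank must be one of {OrfTaxonomy.RANKS}")
        if self.identity_min is not None and not (0 <= self.identity_min <= 1):
            raise ValidationError("config identity_min outside [0,1]")
        self.integrase_labels = tuple(self.integrase_labels)
        self.excluded_amg_categories = tuple(self.excluded_amg_categories)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["integrase_labels"] = list(self.integrase_labels)
        d["excluded_amg_categories"] = list(self.excluded_amg_categories)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
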