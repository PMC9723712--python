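"""File readers and writers: FASTA, GFF3 subset, fixed-header TSVs, config.

TSV layouts (tab-separated, one header row):

==================  =========================================================
table               columns
==================  =========================================================
genes               contig_id, gene_index, start, end, strand, labels
                    (comma-joined), category, viral_like (0/1), aux_score
                    ('' when absent); start/end are 0-based half-open
taxonomy            contig_id, gene_index (0 for the contig-level row),
                    lineage, contig_lineage (semicolon-joined ranks)
crispr              host_id, array_id, evidence_level, spacer_id, spacer_seq
                    (one row per spacer)
trna                owner_id, trna_id, seq
alignments          read_id, read_length, contig_id, contig_start,
                    contig_end, identity (PAF-like minimal columns,
                    0-based half-open)
bins                bin_id, contig_id, completeness, contamination, lineage
                    (one row per member contig)
candidates          contig_id, ev_pipeline_hit (0/1), sorter_category (''),
                    dl_score (''), dl_p (''), provirus_flag (0/1),
                    completeness_tier
==================  =========================================================

GFF3 carries 1-based inclusive coordinates on disk; they are converted to the
internal 0-based half-open convention on read and back on write.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import (
    AlignmentRecord,
    BinRecord,
    Config,
    CrisprArrayRecord,
    GeneRecord,
    OrfTaxonomy,
    SequenceRecord,
    ValidationError,
    ViralCandidateRecord,
)

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords.

    Order is preserved, multi-line sequences are concatenated and lowercase
    is uppercased. Duplicate ids and empty sequences are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def load_config(path: Optional[PathLike] = None) -> Config:
    """Load a YAML/JSON key-value config; missing keys take the defaults.

    Unknown keys and out-of-range values raise ValidationError naming the key.
    """
    if path is None:
        return Config()
    with _open_text(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return Config.from_dict(data)


def save_config(cfg: Config, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _read_tsv(path: PathLike, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _check_coord(path, row_no, contig_id, end, lengths) -> None:
    if lengths is not None and contig_id in lengths and end > lengths[contig_id]:
        raise ValidationError(
            f"{path} row {row_no}: coordinate {end} outside contig {contig_id} "
            f"(length {lengths[contig_id]})"
        )


GENE_COLUMNS = ["contig_id", "gene_index", "start", "end", "strand",
                "labels", "category", "viral_like", "aux_score"]


def read_gene_table(path: PathLike, lengths: Optional[dict[str, int]] = None) -> list[GeneRecord]:
    df = _read_tsv(path, GENE_COLUMNS)
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        _check_coord(path, i, row.contig_id, int(row.end), lengths)
        genes.append(GeneRecord(
            contig_id=row.contig_id,
            gene_index=int(row.gene_index),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            labels=frozenset(x for x in row.labels.split(",") if x),
            category=row.category,
            viral_like=row.viral_like == "1",
            aux_score=None if row.aux_score == "" else int(row.aux_score),
        ))
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: PathLike) -> None:
    rows = [{
        "contig_id": g.contig_id, "gene_index": g.gene_index,
        "start": g.start, "end": g.end, "strand": g.strand,
        "labels": ",".join(sorted(g.labels)), "category": g.category,
        "viral_like": int(g.viral_like),
        "aux_score": "" if g.aux_score is None else g.aux_score,
    } for g in genes]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_gff(path: PathLike, lengths: Optional[dict[str, int]] = None) -> list[GeneRecord]:
    """Read a GFF3 subset (CDS features) into GeneRecords.

    Recognised attributes: ID, gene_index, labels (comma-joined), category,
    viral_like (0/1), aux_score. 1-based inclusive coordinates are converted
    to 0-based half-open.
    """
    genes: list[GeneRecord] = []
    counters: dict[str, int] = defaultdict(int)
    with _open_text(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValidationError(f"{path} row {row_no}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            counters[seqid] += 1
            start0, end0 = int(start) - 1, int(end)
            _check_coord(path, row_no, seqid, end0, lengths)
            genes.append(GeneRecord(
                contig_id=seqid,
                gene_index=int(attr.get("gene_index", counters[seqid])),
                start=start0,
                end=end0,
                strand=strand if strand in "+-" else "+",
                labels=frozenset(x for x in attr.get("labels", "").split(",") if x),
                category=attr.get("category", ""),
                viral_like=attr.get("viral_like", "0") == "1",
                aux_score=int(attr["aux_score"]) if "aux_score" in attr else None,
            ))
    return genes


def write_genes_gff(genes: Iterable[GeneRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.contig_id}_{g.gene_index}", f"gene_index={g.gene_index}"]
            if g.labels:
                attrs.append("labels=" + ",".join(sorted(g.labels)))
            if g.category:
                attrs.append(f"category={g.category}")
            attrs.append(f"viral_like={int(g.viral_like)}")
            if g.aux_score is not None:
                attrs.append(f"aux_score={g.aux_score}")
            fh.write("\t".join([
                g.contig_id, "mmavirome", "CDS", str(g.start + 1), str(g.end),
                ".", g.strand, "0", ";".join(attrs),
            ]) + "\n")


TAXONOMY_COLUMNS = ["contig_id", "gene_index", "lineage", "contig_lineage"]


def _split_lineage(s: str) -> tuple[str, ...]:
    return tuple(s.split(";")) if s else ()


def read_taxonomy_table(path: PathLike) -> list[OrfTaxonomy]:
    df = _read_tsv(path, TAXONOMY_COLUMNS)
    return [OrfTaxonomy(
        contig_id=row.contig_id,
        gene_index=int(row.gene_index),
        lineage=_split_lineage(row.lineage),
        contig_lineage=_split_lineage(row.contig_lineage),
    ) for row in df.itertuples(index=False)]


def write_taxonomy_table(taxa: Iterable[OrfTaxonomy], path: PathLike) -> None:
    rows = [{
        "contig_id": t.contig_id, "gene_index": t.gene_index,
        "lineage": ";".join(t.lineage), "contig_lineage": ";".join(t.contig_lineage),
    } for t in taxa]
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).to_csv(path, sep="\t", index=False)


CRISPR_COLUMNS = ["host_id", "array_id", "evidence_level", "spacer_id", "spacer_seq"]


def read_crispr_table(path: PathLike) -> list[CrisprArrayRecord]:
    df = _read_tsv(path, CRISPR_COLUMNS)
    arrays: dict[str, CrisprArrayRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        level = int(row.evidence_level)
        if level not in {1, 2, 3, 4}:
            raise ValidationError(f"{path} row {i}: evidence_level must be 1-4, got {level}")
        arr = arrays.get(row.array_id)
        if arr is None:
            arr = arrays[row.array_id] = CrisprArrayRecord(row.host_id, row.array_id, level, [])
        elif arr.evidence_level != level or arr.host_id != row.host_id:
            raise ValidationError(f"{path} row {i}: inconsistent array metadata for {row.array_id}")
        arr.spacers.append(SequenceRecord(row.spacer_id, row.spacer_seq))
    return list(arrays.values())


def write_crispr_table(arrays: Iterable[CrisprArrayRecord], path: PathLike) -> None:
    rows = [{
        "host_id": a.host_id, "array_id": a.array_id,
        "evidence_level": a.evidence_level, "spacer_id": sp.id, "spacer_seq": sp.seq,
    } for a in arrays for sp in a.spacers]
    pd.DataFrame(rows, columns=CRISPR_COLUMNS).to_csv(path, sep="\t", index=False)


TRNA_COLUMNS = ["owner_id", "trna_id", "seq"]


def read_trna_table(path: PathLike) -> dict[str, list[SequenceRecord]]:
    """Map owner (contig/genome) id -> its tRNA sequences."""
    df = _read_tsv(path, TRNA_COLUMNS)
    out: dict[str, list[SequenceRecord]] = defaultdict(list)
    for row in df.itertuples(index=False):
        out[row.owner_id].append(SequenceRecord(row.trna_id, row.seq))
    return dict(out)


def write_trna_table(trnas: dict[str, list[SequenceRecord]], path: PathLike) -> None:
    rows = [{"owner_id": owner, "trna_id": t.id, "seq": t.seq}
            for owner, items in trnas.items() for t in items]
    pd.DataFrame(rows, columns=TRNA_COLUMNS).to_csv(path, sep="\t", index=False)


ALIGNMENT_COLUMNS = ["read_id", "read_length", "contig_id", "contig_start",
                     "contig_end", "identity"]


def read_alignment_table(path: PathLike, lengths: Optional[dict[str, int]] = None) -> list[AlignmentRecord]:
    df = _read_tsv(path, ALIGNMENT_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        _check_coord(path, i, row.contig_id, int(row.contig_end), lengths)
        out.append(AlignmentRecord(
            read_id=row.read_id, contig_id=row.contig_id,
            contig_start=int(row.contig_start), contig_end=int(row.contig_end),
            read_length=int(row.read_length), identity=float(row.identity),
        ))
    return out


def write_alignment_table(alignments: Iterable[AlignmentRecord], path: PathLike) -> None:
    rows = [{
        "read_id": a.read_id, "read_length": a.read_length, "contig_id": a.contig_id,
        "contig_start": a.contig_start, "contig_end": a.contig_end,
        "identity": f"{a.identity:g}",
    } for a in alignments]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


BIN_COLUMNS = ["bin_id", "contig_id", "completeness", "contamination", "lineage"]


def read_bin_table(path: PathLike) -> list[BinRecord]:
    df = _read_tsv(path, BIN_COLUMNS)
    groups: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        g = groups.setdefault(row.bin_id, {
            "members": set(),
            "completeness": float(row.completeness),
            "contamination": float(row.contamination),
            "lineage": _split_lineage(row.lineage),
        })
        g["members"].add(row.contig_id)
    return [BinRecord(bin_id=b, member_contigs=frozenset(g["members"]),
                      completeness=g["completeness"], contamination=g["contamination"],
                      lineage=g["lineage"])
            for b, g in groups.items()]


def write_bin_table(bins: Iterable[BinRecord], path: PathLike) -> None:
    rows = [{
        "bin_id": b.bin_id, "contig_id": c, "completeness": f"{b.completeness:g}",
        "contamination": f"{b.contamination:g}", "lineage": ";".join(b.lineage),
    } for b in bins for c in sorted(b.member_contigs)]
    pd.DataFrame(rows, columns=BIN_COLUMNS).to_csv(path, sep="\t", index=False)


CANDIDATE_COLUMNS = ["contig_id", "ev_pipeline_hit", "sorter_category",
                     "dl_score", "dl_p", "provirus_flag", "completeness_tier"]


def read_candidate_table(path: PathLike) -> list[ViralCandidateRecord]:
    df = _read_tsv(path, CANDIDATE_COLUMNS)
    return [ViralCandidateRecord(
        contig_id=row.contig_id,
        ev_pipeline_hit=row.ev_pipeline_hit == "1",
        sorter_category=None if row.sorter_category == "" else int(row.sorter_category),
        dl_score=None if row.dl_score == "" else float(row.dl_score),
        dl_p=None if row.dl_p == "" else float(row.dl_p),
        provirus_flag=row.provirus_flag == "1",
        completeness_tier=row.completeness_tier or "undetermined",
    ) for row in df.itertuples(index=False)]


def write_candidate_table(candidates: Iterable[ViralCandidateRecord], path: PathLike) -> None:
    rows = [{
        "contig_id": c.contig_id, "ev_pipeline_hit": int(c.ev_pipeline_hit),
        "sorter_category": "" if c.sorter_category is None else c.sorter_category,
        "dl_score": "" if c.dl_score is None else f"{c.dl_score:g}",
        "dl_p": "" if c.dl_p is None else f"{c.dl_p:g}",
        "provirus_flag": int(c.provirus_flag), "completeness_tier": c.completeness_tier,
    } for c in candidates]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)
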