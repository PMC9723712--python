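"""End-to-end orchestration: simulate -> triage -> cluster -> hostlink ->
abundance -> lifestyle -> amg -> stats, with a run manifest and summary.

Every stage writes its plain-text table before the next starts, so any
stage can also be run standalone on converted outputs of the real upstream
tools (virus sorters, CRISPR detectors, tRNA scanners, binners).
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import amg as amg_mod
from . import clustering as cl
from . import hostlink as hl
from . import io as mio
from . import stats as st
from . import triage as tr
from .records import Config, ValidationError

log = logging.getLogger("mmavirome")

REQUIRED_INPUTS = [
    "viruses.fasta", "hosts.fasta", "hosts.tsv", "genes.tsv", "taxonomy.tsv",
    "crispr.tsv", "trna_host.tsv", "trna_virus.tsv", "candidates.tsv",
    "bins.tsv", "sample_totals.tsv",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(cfg: Config, input_dir, output_dir) -> dict:
    """Run every stage on an input bundle; returns the run manifest."""
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    for name in REQUIRED_INPUTS:
        if not (input_dir / name).exists():
            raise ValidationError(f"missing input table: {name}")

    counts: dict[str, int] = {}

    # ---- load inputs
    viruses = mio.read_fasta(input_dir / "viruses.fasta")
    hosts = mio.read_fasta(input_dir / "hosts.fasta")
    lengths = {r.id: r.length for r in viruses}
    lengths.update({r.id: r.length for r in hosts})
    host_df = pd.read_csv(input_dir / "hosts.tsv", sep="\t", dtype=str)
    host_lineages = {row.host_id: tuple(row.lineage.split(";"))
                     for row in host_df.itertuples(index=False)}
    genes = mio.read_gene_table(input_dir / "genes.tsv", lengths)
    taxa = mio.read_taxonomy_table(input_dir / "taxonomy.tsv")
    arrays = mio.read_crispr_table(input_dir / "crispr.tsv")
    host_trnas = mio.read_trna_table(input_dir / "trna_host.tsv")
    virus_trnas = mio.read_trna_table(input_dir / "trna_virus.tsv")
    candidates = mio.read_candidate_table(input_dir / "candidates.tsv")
    bins = mio.read_bin_table(input_dir / "bins.tsv")
    totals_df = pd.read_csv(input_dir / "sample_totals.tsv", sep="\t")
    sample_totals = dict(zip(totals_df["sample_id"], totals_df["total_mapped_reads"]))

    # ---- stage 1: triage
    decisions = tr.triage_viral_candidates(candidates, lengths, cfg)
    _write_tsv(pd.DataFrame(
        [{"contig_id": d.contig_id, "accepted": int(d.accepted), "rule_fired": d.rule_fired}
         for d in decisions], columns=["contig_id", "accepted", "rule_fired"]),
        output_dir / "triage.tsv")
    accepted = sorted(d.contig_id for d in decisions if d.accepted)
    counts["triage_accepted"] = len(accepted)
    log.info("triage: %d/%d contigs accepted", len(accepted), len(decisions))

    # ---- stage 2: MAG quality filter
    mags = tr.filter_mags(bins, cfg)
    mio.write_bin_table(mags, output_dir / "mags.tsv")
    counts["mags_retained"] = len(mags)
    log.info("mag filter: %d/%d bins retained", len(mags), len(bins))

    # ---- stage 3: vOTU clustering of accepted viral contigs
    accepted_records = [r for r in viruses if r.id in set(accepted)]
    votus = cl.greedy_cluster(accepted_records, cfg.ani_min, cfg.af_min)
    votu_rows = [{"member_id": m, "votu_id": v.votu_id,
                  "representative": int(m == v.representative_id)}
                 for v in votus for m in sorted(v.member_ids)]
    _write_tsv(pd.DataFrame(votu_rows, columns=["member_id", "votu_id", "representative"]),
               output_dir / "votus.tsv")
    counts["votus"] = len(votus)
    reps = {v.representative_id for v in votus}
    mio.write_fasta([r for r in accepted_records if r.id in reps],
                    output_dir / "votu_representatives.fasta")
    log.info("clustering: %d vOTUs from %d contigs", len(votus), len(accepted_records))

    # ---- stage 4: host linking
    accepted_set = set(accepted)
    target_lineages = {lin[-1]: lin for lin in host_lineages.values()}
    matches = hl.find_spacer_matches(arrays, accepted_records, cfg)
    links = hl.spacer_matches_to_links(matches, host_lineages)
    links += hl.find_trna_matches(
        {v: t for v, t in virus_trnas.items() if v in accepted_set},
        host_trnas, host_lineages)
    virus_taxa = [t for t in taxa if t.contig_id in accepted_set]
    links += hl.taxonomy_vote_link(virus_taxa, target_lineages, cfg)
    bin_votes: dict[tuple[str, str], int] = defaultdict(int)
    for t in virus_taxa:
        if t.gene_index > 0 and len(t.lineage) >= 4:
            bin_votes[(t.contig_id, t.lineage[3])] += 1
    links += hl.binning_link(accepted, mags, dict(bin_votes), target_lineages, cfg)
    table = hl.aggregate_links(links)
    _write_tsv(table, output_dir / "links.tsv")
    counts.update({f"links_{k}": v for k, v in hl.criterion_counts(table).items()})
    cross = hl.detect_cross_domain(table)
    _write_tsv(pd.DataFrame(
        [{"virus_id": c.virus_id, "is_cross_domain": int(c.is_cross_domain),
          "domains": ",".join(sorted({d for d, _ in c.host_groups if d}))}
         for c in cross], columns=["virus_id", "is_cross_domain", "domains"]),
        output_dir / "cross_domain.tsv")
    counts["cross_domain_viruses"] = sum(c.is_cross_domain for c in cross)
    log.info("host linking: %d links, %d cross-domain viruses",
             len(table), counts["cross_domain_viruses"])

    # ---- stage 5: abundance
    results = []
    rep_lengths = {r: lengths[r] for r in sorted(reps)}
    for sample in sorted(sample_totals):
        aln_path = input_dir / f"alignments_{sample}.tsv"
        rows = mio.read_alignment_table(aln_path, lengths) if aln_path.exists() else []
        by_contig: dict[str, list] = defaultdict(list)
        for a in rows:
            by_contig[a.contig_id].append(a)
        results += ab.profile_sample(by_contig, rep_lengths, sample,
                                     int(sample_totals[sample]), cfg)
    _write_tsv(pd.DataFrame(
        [{"contig_id": r.contig_id, "sample_id": r.sample_id,
          "mapped_reads": r.mapped_reads, "breadth": f"{r.breadth:.6f}",
          "mean_depth": f"{r.mean_depth:.6f}", "rpkm": f"{r.rpkm:.6f}",
          "present": int(r.present)} for r in results],
        columns=["contig_id", "sample_id", "mapped_reads", "breadth",
                 "mean_depth", "rpkm", "present"]), output_dir / "coverage.tsv")
    pres = ab.presence_matrix(results)
    pres.astype(int).to_csv(output_dir / "presence_matrix.tsv", sep="\t")
    ab.rpkm_matrix(results).to_csv(output_dir / "rpkm_matrix.tsv", sep="\t",
                                   float_format="%.6f")
    occ = ab.occupancy_summary(pres)
    counts["votus_present_somewhere"] = len(occ.counts)
    log.info("abundance: %d coverage rows", len(results))

    # ---- stage 6: lifestyle
    genes_by_contig: dict[str, list] = defaultdict(list)
    for g in genes:
        genes_by_contig[g.contig_id].append(g)
    lifestyle_calls = [
        tr.classify_lifestyle(genes_by_contig.get(c.contig_id, []), c, cfg)
        for c in candidates if c.contig_id in accepted_set]
    _write_tsv(pd.DataFrame(
        [{"contig_id": c.contig_id, "lysogenic": int(c.lysogenic),
          "signals": ",".join(sorted(c.signals))} for c in lifestyle_calls],
        columns=["contig_id", "lysogenic", "signals"]), output_dir / "lifestyle.tsv")
    counts["lysogenic"] = sum(c.lysogenic for c in lifestyle_calls)
    log.info("lifestyle: %d/%d lysogenic", counts["lysogenic"], len(lifestyle_calls))

    # ---- stage 7: AMG curation
    viral_genes = [g for g in genes if g.contig_id in accepted_set]
    amg_calls = amg_mod.curate_amgs(viral_genes, cfg)
    _write_tsv(pd.DataFrame(
        [{"contig_id": c.contig_id, "gene_index": c.gene_index, "label": c.label,
          "aux_score": c.aux_score, "verdict": c.verdict,
          "flank_up": c.flank_evidence[0], "flank_down": c.flank_evidence[1]}
         for c in amg_calls], columns=["contig_id", "gene_index", "label",
                                      "aux_score", "verdict", "flank_up",
                                      "flank_down"]), output_dir / "amg.tsv")
    counts["amgs_kept"] = sum(c.verdict == "kept" for c in amg_calls)
    log.info("amg: %d kept of %d candidates", counts["amgs_kept"], len(amg_calls))

    # ---- stage 8: comparative statistics
    profiles = {r.id: st.tetranucleotide_profile(r.id, r.seq)
                for r in accepted_records + hosts}
    names = sorted(profiles)
    tests_rows: list[dict] = []
    if len(names) >= 2:
        corr = st.profile_correlation_matrix([profiles[n] for n in names])
        pd.DataFrame(corr, index=names, columns=names).to_csv(
            output_dir / "tetra_corr.tsv", sep="\t", float_format="%.6f")
        host_order = {row.host_id: row.order for row in host_df.itertuples(index=False)}
        host_ids = sorted(host_order)
        # the tetra-signature group comparison needs >= 2 host orders and a
        # repeated order; skipped (not failed) on degenerate communities
        orders = [host_order[h] for h in host_ids]
        counts_per_order = pd.Series(orders).value_counts() if orders else pd.Series(dtype=int)
        if len(counts_per_order) >= 2 and (counts_per_order >= 2).any():
            hidx = [names.index(h) for h in host_ids]
            dist = 1.0 - corr[np.ix_(hidx, hidx)]
            np.fill_diagonal(dist, 0.0)
            anosim_res = st.anosim(dist, orders, n_permutations=999, seed=cfg.rng_seed)
            tests_rows.append({"test": "anosim_host_orders_tetra",
                               "statistic": f"{anosim_res.statistic:.6f}",
                               "p_value": f"{anosim_res.p_value:.6f}",
                               "method": anosim_res.method})
    else:
        pd.DataFrame(index=names, columns=names).to_csv(
            output_dir / "tetra_corr.tsv", sep="\t")
    _write_tsv(pd.DataFrame(tests_rows, columns=["test", "statistic", "p_value", "method"]),
               output_dir / "tests.tsv")

    pcs_by_contig = {c: {l for g in genes_by_contig[c] for l in g.labels}
                     for c in accepted if genes_by_contig.get(c)}
    total_pcs = len({l for s in pcs_by_contig.values() for l in s}) or 1
    edges = st.gene_sharing_edges(pcs_by_contig, total_pcs, cfg.edge_sig_min)
    _write_tsv(pd.DataFrame(
        [{"genome_a": e.genome_a, "genome_b": e.genome_b,
          "shared_pcs": e.shared_pcs, "significance": f"{e.significance:.4f}"}
         for e in edges], columns=["genome_a", "genome_b", "shared_pcs",
                                   "significance"]), output_dir / "edges.tsv")
    counts["network_edges"] = len(edges)

    # ---- manifest
    manifest = {
        "version": __version__,
        "seed": cfg.rng_seed,
        "config": cfg.to_dict(),
        "input_digests": {name: _sha256(input_dir / name) for name in REQUIRED_INPUTS},
        "stage_counts": counts,
    }
    with open(output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    (output_dir / "report.txt").write_text(report(output_dir))
    return manifest


def report(output_dir) -> str:
    """Deterministic human-readable summary regenerated from stage outputs."""
    output_dir = Path(output_dir)

    def tsv(name: str) -> pd.DataFrame:
        path = output_dir / name
        if not path.exists():
            raise ValidationError(f"missing stage output: {name}")
        return pd.read_csv(path, sep="\t")

    triage = tsv("triage.tsv")
    lines = ["mmavirome run summary", "====================="]
    lines.append(f"contigs triaged: {len(triage)}; accepted: {int(triage['accepted'].sum())}")
    if len(triage):
        rule_counts = triage.loc[triage["accepted"] == 1, "rule_fired"].value_counts()
        for rule, n in rule_counts.sort_index().items():
            lines.append(f"  rule {rule}: {n}")
    votus = tsv("votus.tsv")
    n_votus = votus["votu_id"].nunique() if len(votus) else 0
    lines.append(f"vOTUs: {n_votus} from {len(votus)} member contigs")
    links = tsv("links.tsv")
    lines.append(f"virus-host links: {len(links)}")
    if len(links):
        for crit in hl.CRITERIA:
            lines.append(f"  {crit}: {int((links['criterion'] == crit).sum())}")
    cross = tsv("cross_domain.tsv")
    n_cross = int(cross["is_cross_domain"].sum()) if len(cross) else 0
    lines.append(f"cross-domain viruses: {n_cross}")
    life = tsv("lifestyle.tsv")
    n_lys = int(life["lysogenic"].sum()) if len(life) else 0
    frac = n_lys / len(life) if len(life) else 0.0
    lines.append(f"lysogenic: {n_lys}/{len(life)} ({100 * frac:.2f}%)")
    amg = tsv("amg.tsv")
    if len(amg):
        for verdict, n in amg["verdict"].value_counts().sort_index().items():
            lines.append(f"  amg {verdict}: {n}")
    else:
        lines.append("  amg candidates: 0")
    tests = tsv("tests.tsv")
    for row in tests.itertuples(index=False):
        lines.append(f"test {row.test}: statistic={row.statistic} p={row.p_value}")
    edges = tsv("edges.tsv")
    lines.append(f"gene-sharing edges above threshold: {len(edges)}")
    return "\n".join(lines) + "\n"
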