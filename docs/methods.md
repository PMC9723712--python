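# Methods

This note documents the models and procedures implemented in `mmavirome`,
the conventions chosen where the underlying methods are under-specified in
common usage, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinate and sequence conventions

All coordinates inside the package are 0-based half-open; GFF3 I/O converts
to and from the standard's 1-based inclusive form at the file boundary.
Sequences are uppercased on ingest over the alphabet {A,C,G,T,N}. Ambiguous
bases (N) are treated conservatively and deterministically everywhere: they
count as mismatches in spacer matching (including N vs N), invalidate
tetranucleotide windows, and skip codons in codon counting.

## Configuration

`Config` is the single source of thresholds. Defaults (units in
parentheses): `ani_min=95` (%), `af_min=85` (%), `derep_ani=99` (%),
`spacer_max_mismatch=1` (substitutions over the full spacer),
`min_orf_votes=5`, `min_binned_orf_votes=1`, `crispr_min_evidence=4`
(confidence tier), `breadth_min=0.85` (fraction), `dl_score_min=0.9`,
`dl_p_max=0.05`, `aux_score_max=3`, `edge_sig_min=10` (−log₁₀ p),
`mag_completeness_min=50` (%), `mag_contamination_max=10` (%),
`viral_min_len=5000` (bases), `bin_min_len=2000` (bases). Boundary
comparisons follow the inequality directions as commonly printed
(≥ for floors, ≤ for ceilings, strict < for the detector p-value).
Out-of-range values and unknown keys are rejected at load time, before any
stage runs.

## Triage

The acceptance ladder is evaluated in a fixed precedence (reference-virome
protocol hit → sorter category 1/2 → category 3 + deep-learning rescue) and
only the first accepting rule is recorded, so per-rule counts are disjoint —
this reproduces stepwise accounting where each step reports only the
*additional* contigs it contributes. Missing detector scores are
non-accepting, never errors. Triage is monotone: adding evidence can only
move a contig toward acceptance.

## vOTU clustering

ANI/AF is computed from the best glocal (infix) alignment of the shorter
sequence into the longer (edlib, substitutions and indels allowed): ANI is
percent identity over all aligned columns including gap columns, AF the
percent of the shorter sequence covered. A design simplification relative to
BLAST-style implementations that merge several non-overlapping local
alignments: we report the single best infix alignment. For sequences related
by substitutions and truncation — the regime the thresholds are meant to
separate — the two definitions coincide, and the test suite bounds the
deviation from a full global dynamic-programming oracle at ±0.5 ANI on
mutated pairs. The practical consequence is that AF is 100 whenever an
alignment exists and the clustering decision rests on ANI; partial-overlap
chimeras would need the multi-alignment extension (a known limitation).

Greedy clustering processes sequences longest-first (ties broken
lexicographically by id) and joins each sequence to the first cluster whose
*representative* passes both thresholds. This makes the longest member the
representative by construction, makes the output deterministic, and is the
same centroid scheme used by the standard ANI-clustering scripts distributed
with viral quality-control tooling. Raising `ani_min` only refines the
partition (never merges), which the tests assert. MAG dereplication reuses
the engine at 99% ANI.

Novelty against a reference set: *novel* (no reference member in the
cluster), *improved* (longest study member strictly longer than every
reference member), *redundant* (otherwise). "More complete" is
operationalised as longer, since length is always available; completeness
tiers can be supplied instead where estimated.

## Host linking

* **CRISPR** — only arrays at the highest confidence tier (4) are trusted.
  Spacer matching is ungapped Hamming comparison over the entire spacer on
  both strands ("over the entire spacer length" implies fixed-length,
  indel-free comparison; the oligo-search tools used for this task behave
  the same way). Every occurrence is reported, including overlapping hits
  and both-strand hits at one locus; deduplication to (virus, host) pairs
  happens at aggregation. Lowering the evidence floor can only add links.
* **tRNA** — exact string identity on either strand. Re-running an aligner
  would only weaken "complete match" into a score threshold.
* **Taxonomy votes** — host lineages are matched at the order rank by
  default (`host_rank` configurable), votes counted per target lineage;
  a whole-contig classification links regardless of vote count. Votes split
  across two lineages do not sum.
* **Co-binning** — bins must partition contigs; a viral contig in a
  target-lineage bin links when it carries at least one ORF of that
  lineage.

For single-host reporting the criteria are ranked crispr > trna >
taxonomy_vote > binning, mirroring their relative specificity. A virus
linked to hosts in ≥ 2 domains is flagged cross-domain.

## Abundance and presence

Breadth is computed from the union of alignment intervals, mean depth from
their summed lengths; each alignment row counts as one mapped read (the
generator never emits multi-mappers, and the mapper's own multi-mapping
policy is out of scope). RPKM uses *mapped* reads in the denominator, the
literal reading of the unit. Presence is gated by breadth only — a deeply
but narrowly covered contig is absent — with the ≥ 0.85 boundary inclusive.
An optional `identity_min` filter can drop low-identity alignments before
counting; it defaults to off. Occupancy summaries exclude vOTUs absent from
every sample, since a never-observed virus is not "found in" any number of
samples.

## Lysogeny

Either signal suffices: a gene annotated with one of the configured
integrase Pfam families (default: the tyrosine-recombinase core and
SAM-like N-terminal domains plus the serine-recombinase family —
PF00589, PF02899, PF13495, PF00239) or an upstream detector's provirus
integration flag. The default family list is a package choice, configurable
because annotation pipelines differ in which integrase families they emit.

## AMG curation

Verdicts are assigned in a fixed order — auxiliary score, category
exclusion, flanking context — and a candidate failing several rules reports
the first, so counts per failure mode are unambiguous. The flanking rule
codifies the usual manual curation step deterministically: at least one
viral-like gene within `amg_flank_window` (default 3) genes on each side;
a side with no genes at all (contig end) passes by itself. The window size
is a declared approximation of a protocol that is otherwise prose.

## Statistics

* **Codon usage** — amino-acid-level codon fractions pooled per genome
  (per-gene pooling available), stop codons included in the denominator as
  a fixed documented convention; comparative conclusions are unaffected by
  the denominator choice. Cysteine counts TGT+TGC, methionine ATG.
* **Mann–Whitney U** — midranks; the exact null is enumerated over all
  C(n₁+n₂, n₁) labelings when both groups have ≤ 8 observations (correct
  under ties, where the classical tables are not), otherwise the normal
  approximation with tie and continuity corrections. Degenerate data
  (all values equal) gives p = 1.
* **Tetranucleotide signatures** — 4-mer frequencies counted on both
  strands and normalised, so profiles are invariant to the arbitrary strand
  of assembled contigs. Similarity is Pearson correlation; zero-variance
  profiles yield missing values rather than arbitrary numbers.
* **ANOSIM** — Clarke's R = (r̄_between − r̄_within)/(M/2) on midranked
  distances, M = n(n−1)/2; p = (1 + #{R_perm ≥ R_obs})/(n_perm + 1).
  Singleton groups contribute no within-pairs; all-singleton groupings are
  rejected. The implementation is cross-checked against scikit-bio in the
  test suite.
* **Gene-sharing edges** — significance of c shared protein clusters
  between genomes with |A| and |B| clusters out of a universe of size T is
  the −log₁₀ hypergeometric upper tail P(X ≥ c), accumulated in log space
  so deep tails do not underflow; edges require significance ≥ 10. The
  additional pair-count correction applied by some network tools is omitted
  for a minimal reproducible definition; the threshold remains
  configurable.

## Synthetic community

The generator's defaults define the study conditions: 8 hosts (two orders
represented twice, five methanogen/methanotroph orders plus one
sulfate-reducing bacterial order) of 30 kb each, 20 viruses of 10 kb, three
triage decoys, 4 samples, 150 nt reads, a planted cysteine codon-fraction
enrichment of δ = 0.01, spacers of 25–40 nt, clustering families at 3%
child divergence and 12% far-mutant divergence. These sizes keep every
experiment well-powered for its planted effect while the full suite runs in
tens of seconds.

Mechanisms worth knowing:

* Host (and derived virus) sequences come from order-specific first-order
  Markov chains; the per-order transition bias is keyed on the order alone,
  so composition is a property of the order, not of the run seed. This is
  the minimal mechanism producing the host–virus tetranucleotide affinity
  signal; real oligonucleotide signatures are higher-order.
* Mutation is substitution-only (exactly ⌈divergence·len⌉ sites), which
  keeps the Hamming spacer logic and the alignment oracles exact. Indel
  divergence is not modelled.
* Planted protospacers overwrite a recorded window of the virus at an exact
  Hamming distance of 0, 1 or 2, on a recorded strand; tier-3 arrays and
  2-mismatch plantings are recorded as *should not find*.
* Read "alignments" are emitted directly (no sequencing-error model, no
  FASTQ): reads tile a prefix achieving each target breadth within ±0.01,
  surplus reads stack on the first window so read counts can be varied
  independently of breadth. Sample totals include a constant background of
  non-viral mapped reads.
* The ledger (`truth.json`) records every planted item with its expected
  recovery status; the pipeline tests assert recall 1.0 and zero false
  links at the default thresholds.

What passing these tests shows: the implementation applies the stated rules
exactly, deterministically, and at the stated boundaries. What it does not
show: robustness to real-data phenomena the generator omits — indels and
chimeric contigs (which stress the single-alignment ANI simplification),
sequencing error, multi-mapping reads, mis-binning, and taxonomic
misclassification upstream.

## Determinism

All randomness flows from explicit seeds (`rng_seed` in the config or
generator parameters). Two runs at the same seed produce byte-identical
bundles and stage outputs, which both the test suite and the acceptance
script verify by re-running the full chain.

## Problem sizes used in the automated checks

The acceptance suite exercises: 200 planted spacer cases; 30 families + 30
singletons (≈ 90 sequences, all-pairs oracle) for clustering; the default
8-host/23-contig community end-to-end; 50 + 50 genomes of 3000 codons for
the codon-bias experiment; 1000 null replicates at n = 30/30 for rank-test
calibration; exhaustive 6!-permutation enumeration for ANOSIM. Published
corpus-scale ratios (e.g. 123/577, 9761/15048, 1463/15048, 9892/6264/1088,
22/1/80/18) are re-derived by running the corresponding operations on
constructed inputs of exactly those sizes.
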