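"""Comparative statistics: codon usage, tetranucleotide signatures,
Mann-Whitney U, ANOSIM, and gene-sharing edge significance.

The rank tests are authored here rather than delegated: the exact
Mann-Whitney null is enumerated for small samples (both groups <= 8), and
ANOSIM implements Clarke's R with an add-one permutation p-value. Library
routines (scipy, scikit-bio) serve as independent cross-checks in the test
suite only.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, norm, rankdata

from .records import ValidationError

# --------------------------------------------------------------------------
# codon usage

_STANDARD_CODE = {}
for _c, _aa in {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}.items():
    _STANDARD_CODE[_c] = _aa

AMINO_ACIDS = tuple(sorted(set(_STANDARD_CODE.values())))


@dataclass(frozen=True)
class CodonStats:
    genome_id: str
    n_codons: int
    freq: dict[str, float]  # amino acid (incl '*') -> fraction of codons


def codon_frequencies(genome_id: str, cds_seqs: list[str]) -> CodonStats:
    """Amino-acid-level codon frequencies pooled over a genome's CDSs.

    Frequencies are fractions of all codons (stop codons included in the
    denominator); cysteine counts TGT+TGC, methionine ATG. A trailing
    partial codon is dropped with a warning; codons containing ambiguous
    bases are skipped.
    """
    if not cds_seqs:
        raise ValidationError(f"{genome_id}: empty CDS set")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for seq in cds_seqs:
        seq = seq.upper()
        if len(seq) % 3:
            warnings.warn(f"{genome_id}: CDS length {len(seq)} not divisible by 3; "
                          "trailing partial codon dropped")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            aa = _STANDARD_CODE.get(seq[i:i + 3])
            if aa is None:
                continue  # ambiguous codon
            counts[aa] += 1
            total += 1
    if total == 0:
        raise ValidationError(f"{genome_id}: no translatable codons")
    return CodonStats(genome_id, total, {aa: c / total for aa, c in counts.items()})


# --------------------------------------------------------------------------
# Mann-Whitney U

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # mwu_exact | mwu_normal | anosim_perm


def _u_statistic(ranks: np.ndarray, idx: tuple[int, ...], n1: int) -> float:
    return float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U with midranks.

    The exact null is enumerated over all C(n1+n2, n1) group labelings when
    both samples have <= 8 observations; otherwise the normal approximation
    with tie and continuity corrections is used. ``statistic`` is U of the
    first sample. When every pooled value is identical the test is vacuous
    and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValidationError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u2 = n1 * n2 - u1

    if np.ptp(pooled) == 0:
        return TestResult(u1, 1.0, "mwu_exact" if max(n1, n2) <= 8 else "mwu_normal")

    if max(n1, n2) <= 8:
        n = n1 + n2
        total = 0
        hits = 0
        if alternative == "two-sided":
            obs = min(u1, u2)
        elif alternative == "greater":
            obs = u1
        else:
            obs = u1
        eps = 1e-9
        for idx in itertools.combinations(range(n), n1):
            up1 = _u_statistic(ranks, idx, n1)
            up2 = n1 * n2 - up1
            total += 1
            if alternative == "two-sided":
                if min(up1, up2) <= obs + eps:
                    hits += 1
            elif alternative == "greater":
                if up1 >= obs - eps:
                    hits += 1
            else:
                if up1 <= obs + eps:
                    hits += 1
        return TestResult(u1, hits / total, "mwu_exact")

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u1, 1.0, "mwu_normal")
    mu = n1 * n2 / 2.0
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u1 - mu) - 0.5) / sigma
        p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    elif alternative == "greater":
        z = (u1 - mu - 0.5) / sigma
        p = float(norm.sf(z))
    else:
        z = (u1 - mu + 0.5) / sigma
        p = float(norm.cdf(z))
    return TestResult(u1, p, "mwu_normal")


# --------------------------------------------------------------------------
# tetranucleotide signatures

_TETRA_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
TETRAMERS = tuple("".join(p) for p in itertools.product("ACGT", repeat=4))


@dataclass(frozen=True)
class TetraProfile:
    genome_id: str
    vector: np.ndarray  # 256 frequencies summing to 1

    def __post_init__(self) -> None:
        if self.vector.shape != (256,):
            raise ValidationError("tetranucleotide vector must have 256 entries")


def tetranucleotide_profile(genome_id: str, seq: str) -> TetraProfile:
    """Strand-symmetric tetranucleotide frequencies.

    Every 4-mer window of the sequence and of its reverse complement is
    counted (windows containing an ambiguous base are skipped) and the
    combined counts normalised to 1, so profile(s) == profile(revcomp(s)).
    """
    seq = seq.upper()
    if len(seq) < 4:
        raise ValidationError(f"{genome_id}: sequence shorter than 4")
    lut = np.full(128, -1, dtype=np.int64)
    for base, code in _TETRA_BASE.items():
        lut[ord(base)] = code
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    counts = np.zeros(256, dtype=np.int64)
    for arr in (codes, 3 - codes[::-1]):  # revcomp: complement (3-x) then reverse
        bad = (arr < 0) | (arr > 3)  # ambiguous bases on either strand
        safe = np.where(bad, 0, arr)
        w = safe[:-3] * 64 + safe[1:-2] * 16 + safe[2:-1] * 4 + safe[3:]
        valid = ~(bad[:-3] | bad[1:-2] | bad[2:-1] | bad[3:])
        counts += np.bincount(w[valid], minlength=256)
    total = counts.sum()
    if total == 0:
        raise ValidationError(f"{genome_id}: no unambiguous 4-mer window")
    return TetraProfile(genome_id, counts / total)


def profile_correlation_matrix(profiles: list[TetraProfile]) -> np.ndarray:
    """Pearson correlation between profiles; NaN for zero-variance profiles."""
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    mat = np.vstack([p.vector for p in profiles])
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    return r


# --------------------------------------------------------------------------
# ANOSIM

def _anosim_r(ranks_condensed: np.ndarray, labels: np.ndarray, n: int) -> float:
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    m = ranks_condensed.size
    if same.all():
        raise ValidationError("ANOSIM needs at least one between-group pair")
    r_within = ranks_condensed[same].mean() if same.any() else 0.0
    r_between = ranks_condensed[~same].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(distance_matrix: np.ndarray, group_labels, n_permutations: int = 999,
           seed: int = 0) -> TestResult:
    """Clarke's analysis of similarities on a square distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 midranked distances; p = (1 + #{permuted R >= observed}) /
    (n_permutations + 1). Groups of size 1 contribute no within-pairs.
    """
    d = np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(group_labels)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be square and symmetric")
    if labels.size != n:
        raise ValidationError("one label per observation required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts >= 2).sum() == 0:
        raise ValidationError("ANOSIM needs at least one group with >= 2 members")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    r_obs = _anosim_r(ranks, labels, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm, n) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return TestResult(r_obs, p, "anosim_perm")


# --------------------------------------------------------------------------
# gene-sharing network edge significance

@dataclass(frozen=True)
class NetworkEdge:
    genome_a: str
    genome_b: str
    shared_pcs: int
    significance: float  # -log10 hypergeometric upper-tail probability


def pc_edge_significance(genome_a: str, pcs_a: set, genome_b: str, pcs_b: set,
                         total_pcs: int) -> NetworkEdge:
    """Hypergeometric significance of shared protein-cluster content.

    With c shared clusters out of |A| and |B| drawn from ``total_pcs``,
    significance = -log10 P(X >= c), computed in log space so deep tails do
    not underflow. c = 0 carries no evidence and scores 0.
    """
    if total_pcs < len(pcs_a | pcs_b):
        raise ValidationError("total_pcs smaller than the union of the two sets")
    c = len(pcs_a & pcs_b)
    if c == 0:
        return NetworkEdge(genome_a, genome_b, 0, 0.0)
    ks = np.arange(c, min(len(pcs_a), len(pcs_b)) + 1)
    logp = logsumexp(hypergeom.logpmf(ks, total_pcs, len(pcs_a), len(pcs_b)))
    sig = max(0.0, -logp / math.log(10))
    return NetworkEdge(genome_a, genome_b, c, float(sig))


def gene_sharing_edges(pcs_by_genome: dict[str, set], total_pcs: int,
                       sig_min: float) -> list[NetworkEdge]:
    """All pairwise edges meeting the significance threshold."""
    edges = []
    names = sorted(pcs_by_genome)
    for a, b in itertools.combinations(names, 2):
        e = pc_edge_significance(a, pcs_by_genome[a], b, pcs_by_genome[b], total_pcs)
        if e.shared_pcs > 0 and e.significance >= sig_min:
            edges.append(e)
    return edges
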