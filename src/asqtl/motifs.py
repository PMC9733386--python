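"""Variant-centric motif discovery.

Significant allele-specific QTL variants are turned into 21-bp sequences
(variant centred, plus the reverse complement), clustered by complete
linkage on Levenshtein distances over the central nine bases with the tree
cut at height 3, and each cluster of at least ten sequences becomes a
position frequency matrix.  From the PFM we derive an IUPAC/regex consensus
(cumulative base frequency 0.85 per column after trimming uninformative
flanks), count its genomic occurrences against the expectation from
background base frequencies, test the central alleles for skew away from
uniform with an exact/Monte-Carlo multinomial log-likelihood-ratio test,
and match the PFM against a JASPAR-format database with a percent-similarity
score.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SEQ_LEN = 21
CENTER = 10  # 0-based position of the variant in the 21-mer
CENTRAL_SLICE = slice(CENTER - 4, CENTER + 5)  # the central nine bases

CLUSTER_CUT_HEIGHT = 3
MIN_CLUSTER_SIZE = 10

# default asbQTL selection thresholds per histone mark; aseQTL threshold and
# the TSS proximity window are separate because expression QTL are far more
# numerous
ASB_MOTIF_P = {"h3k4me1": 1e-8, "h3k4me3": 1e-7, "h3k27ac": 1e-6}
ASE_MOTIF_P = 1e-15
ASE_TSS_WINDOW = 10_000

# genome-wide base frequencies (A, C, G, T) typical of a mammalian autosome
DEFAULT_BASE_FREQS = (0.291, 0.209, 0.209, 0.291)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class VariantSequence:
    variant_id: str
    seq: str  # 21 bases, variant at index 10
    orientation: str  # "forward" | "revcomp"
    positive_allele: str  # allele increasing binding/expression, orientation-adjusted
    reference_allele: str

    def central(self) -> str:
        return self.seq[CENTRAL_SLICE]


@dataclass
class SequenceCluster:
    members: List[VariantSequence]

    @property
    def size(self) -> int:
        return len(self.members)

    def pfm(self) -> np.ndarray:
        """4 x 21 position frequency matrix of base counts."""
        counts = np.zeros((4, SEQ_LEN), dtype=int)
        for m in self.members:
            for j, b in enumerate(m.seq):
                counts[BASES.index(b), j] += 1
        return counts


# ------------------------------------------------------- variant selection

def select_variants_for_motifs(asb_results: Optional[pd.DataFrame],
                               ase_results: Optional[pd.DataFrame],
                               peaks: Optional[pd.DataFrame] = None,
                               exons: Optional[pd.DataFrame] = None,
                               asb_thresholds: Dict[str, float] = None,
                               ase_threshold: float = ASE_MOTIF_P,
                               tss_window: int = ASE_TSS_WINDOW) -> pd.DataFrame:
    """Pick the variants whose flanking sequence enters motif discovery.

    asbQTL variants must fall below their mark's p threshold and (except
    for H3K27ac) lie inside the peak they associate with; aseQTL variants
    must fall below ``ase_threshold`` and lie within ``tss_window`` bp of
    their exon's start.  Result columns include the source label.

    ``asb_results`` needs mark, feature_id, dsnp_id, pos, test1_p,
    slope_sign; ``ase_results`` the same minus mark.
    """
    asb_thresholds = asb_thresholds or ASB_MOTIF_P
    frames = []
    if asb_results is not None and len(asb_results):
        peak_iv = peaks.set_index("feature_id") if peaks is not None else None
        for mark, sub in asb_results.groupby("mark"):
            key = str(mark).lower()
            if key not in asb_thresholds:
                raise ValueError(f"unknown mark {mark!r}")
            sel = sub[sub["test1_p"] < asb_thresholds[key]].copy()
            if key != "h3k27ac" and peak_iv is not None and len(sel):
                st = peak_iv["start"].reindex(sel["feature_id"]).to_numpy()
                en = peak_iv["end"].reindex(sel["feature_id"]).to_numpy()
                sel = sel[(sel["pos"].to_numpy() >= st) & (sel["pos"].to_numpy() < en)]
            sel["source"] = key
            frames.append(sel)
    if ase_results is not None and len(ase_results):
        sel = ase_results[ase_results["test1_p"] < ase_threshold].copy()
        if exons is not None and len(sel):
            tss = exons.set_index("feature_id")["start"]
            d = np.abs(sel["pos"].to_numpy() - tss.reindex(sel["feature_id"]).to_numpy())
            sel = sel[d <= tss_window]
        sel["source"] = "ase"
        frames.append(sel)
    if not frames:
        return pd.DataFrame(columns=["dsnp_id", "pos", "slope_sign", "source"])
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(subset=["dsnp_id", "source"]).reset_index(drop=True)


# --------------------------------------------------------- sequence extract

def extract_sequences(variants: pd.DataFrame, genome: Dict[str, str],
                      snps: pd.DataFrame) -> Tuple[List[VariantSequence], pd.DataFrame]:
    """21-bp variant-centred sequences, forward and reverse complement.

    ``variants`` needs dsnp_id and slope_sign; chrom/pos/ref/alt are joined
    from the SNP table.  The positive allele is the alternate allele when
    the effect sign is positive, the reference allele otherwise; both
    alleles are complemented on the reverse-complement entry.  Variants
    within 10 bp of a contig end or with non-ACGT flanks are skipped and
    logged.
    """
    info = snps.set_index("snp_id")
    out: List[VariantSequence] = []
    skipped = []
    for row in variants.itertuples(index=False):
        sid = row.dsnp_id
        try:
            rec = info.loc[sid]
        except KeyError:
            skipped.append((sid, "unknown-snp"))
            continue
        chrom, pos = rec["chrom"], int(rec["pos"])
        contig = genome.get(chrom)
        if contig is None:
            skipped.append((sid, "unknown-chrom"))
            continue
        if pos < CENTER or pos + (SEQ_LEN - CENTER) > len(contig):
            skipped.append((sid, "contig-end"))
            continue
        seq = contig[pos - CENTER: pos - CENTER + SEQ_LEN].upper()
        if set(seq) - set(BASES):
            skipped.append((sid, "non-acgt"))
            continue
        sign = int(getattr(row, "slope_sign", 1)) or 1
        pos_allele = str(rec["alt"]) if sign > 0 else str(rec["ref"])
        ref_allele = str(rec["ref"])
        out.append(VariantSequence(sid, seq, "forward", pos_allele, ref_allele))
        out.append(VariantSequence(sid, revcomp(seq), "revcomp",
                                   pos_allele.translate(_COMPLEMENT),
                                   ref_allele.translate(_COMPLEMENT)))
    log = pd.DataFrame(skipped, columns=["variant_id", "reason"])
    return out, log


# ---------------------------------------------------------------- clustering

def central_distance_matrix(seqs: Sequence[VariantSequence]) -> np.ndarray:
    """Pairwise Levenshtein distances over the central nine bases."""
    cores = [s.central() for s in seqs]
    n = len(cores)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = edlib.align(cores[i], cores[j],
                                            task="distance")["editDistance"]
    return d


def cluster_sequences(seqs: Sequence[VariantSequence],
                      cut_height: float = CLUSTER_CUT_HEIGHT,
                      min_size: int = MIN_CLUSTER_SIZE) -> List[SequenceCluster]:
    """Complete-linkage clusters of the central 9-mers, cut at ``cut_height``
    (every intra-cluster pairwise edit distance <= cut_height); clusters
    smaller than ``min_size`` are discarded."""
    seqs = list(seqs)
    if not seqs:
        return []
    if len(seqs) == 1:
        labels = np.array([1])
    else:
        d = central_distance_matrix(seqs)
        z = linkage(squareform(d, checks=False), method="complete")
        labels = fcluster(z, t=cut_height, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = [s for s, l in zip(seqs, labels) if l == lab]
        if len(members) >= min_size:
            clusters.append(SequenceCluster(members=members))
    clusters.sort(key=lambda c: -c.size)
    return clusters


# ----------------------------------------------------------------- consensus

@dataclass
class ConsensusMotif:
    start: int  # retained PFM span within the 21 columns
    end: int
    iupac: str
    regex: str
    columns: List[str]  # included bases per retained column

    def __len__(self) -> int:
        return self.end - self.start


_IUPAC_OF = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "AC": "M", "AG": "R", "AT": "W", "CG": "S", "CT": "Y", "GT": "K",
    "ACG": "V", "ACT": "H", "AGT": "D", "CGT": "B", "ACGT": "N",
}


def _column_entropy(freqs: np.ndarray) -> float:
    f = freqs[freqs > 0]
    return float(-(f * np.log2(f)).sum())


def build_consensus(pfm: np.ndarray, entropy_threshold: float = 0.2,
                    cum_freq: float = 0.85,
                    literal_entropy_trim: bool = False) -> ConsensusMotif:
    """IUPAC/regex consensus from a PFM.

    Flanking columns are trimmed while their information content
    (2 - entropy, bits) is below ``entropy_threshold`` — i.e. near-random
    flanks are dropped.  With ``literal_entropy_trim`` the raw entropy is
    compared against the threshold instead, which trims conserved columns.
    For each retained column, bases are sorted by descending frequency
    (ties in fixed A,C,G,T order) and accumulated until the running sum
    exceeds ``cum_freq``; a single base is emitted bare, several as a
    bracketed class.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.shape[0] != 4:
        raise ValueError("PFM must be 4 x width")
    width = pfm.shape[1]
    totals = pfm.sum(axis=0)
    freqs = pfm / np.where(totals > 0, totals, 1.0)

    def informative(j):
        ent = _column_entropy(freqs[:, j])
        score = ent if literal_entropy_trim else 2.0 - ent
        return score >= entropy_threshold

    start, end = 0, width
    while start < end and not informative(start):
        start += 1
    while end > start and not informative(end - 1):
        end -= 1
    if start >= end:
        raise ValueError("all PFM columns trimmed; no consensus")

    cols, regex_parts, iupac_chars = [], [], []
    for j in range(start, end):
        order = np.argsort(-freqs[:, j], kind="stable")  # ties keep A,C,G,T order
        run, included = 0.0, []
        for b in order:
            included.append(BASES[b])
            run += freqs[b, j]
            if run > cum_freq:
                break
        included_sorted = "".join(sorted(included))
        cols.append(included_sorted)
        iupac_chars.append(_IUPAC_OF[included_sorted])
        regex_parts.append(included_sorted if len(included_sorted) == 1
                           else f"[{included_sorted}]")
    return ConsensusMotif(start=start, end=end, iupac="".join(iupac_chars),
                          regex="".join(regex_parts), columns=cols)


# ---------------------------------------------------------------- enrichment

@dataclass
class MotifEnrichment:
    observed: int
    expected: float

    @property
    def enrichment(self) -> float:
        if self.expected <= 0:
            raise ZeroDivisionError("expected count is zero")
        return self.observed / self.expected


def genomic_enrichment(motif: ConsensusMotif, genome: Dict[str, str],
                       base_freqs: Sequence[float] = DEFAULT_BASE_FREQS,
                       ) -> MotifEnrichment:
    """Observed non-overlapping forward-strand regex matches across all
    contigs versus the count expected under independent bases.

    expected = prod_over_columns(sum of included base frequencies) x total
    sequence length.  Reverse complements are not scanned separately: they
    already entered the cluster pool as sequences.
    """
    if not motif.regex:
        raise ValueError("empty motif regex")
    pat = re.compile(motif.regex)
    observed = sum(len(pat.findall(contig.upper())) for contig in genome.values())
    total_len = sum(len(c) for c in genome.values())
    freq_of = dict(zip(BASES, base_freqs))
    expected = float(total_len)
    for col in motif.columns:
        expected *= sum(freq_of[b] for b in col)
    return MotifEnrichment(observed=observed, expected=expected)


def base_frequencies(genome: Dict[str, str]) -> Tuple[float, float, float, float]:
    """Empirical A,C,G,T frequencies of a genome (non-ACGT ignored)."""
    counts = np.zeros(4)
    for contig in genome.values():
        up = contig.upper()
        for i, b in enumerate(BASES):
            counts[i] += up.count(b)
    return tuple(counts / counts.sum())


# ----------------------------------------------------------------- skew test

@dataclass
class SkewTestResult:
    counts: Tuple[int, int, int, int]
    llr: float
    p: float
    method: str  # "exact" | "monte-carlo"


def multinomial_llr(counts: Sequence[int]) -> float:
    """2 * sum n_b ln(n_b / (N/4)) with 0 ln 0 = 0."""
    n = np.asarray(counts, dtype=float)
    total = n.sum()
    if total == 0:
        raise ValueError("empty allele list")
    expect = total / 4.0
    nz = n[n > 0]
    return float(2.0 * (nz * np.log(nz / expect)).sum())


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def allele_skew_test(alleles: Sequence[str], exact_max_n: int = 20,
                     n_draws: int = 100_000, seed: int = 0) -> SkewTestResult:
    """Test whether cluster alleles deviate from 25% per base.

    Exact enumeration of the multinomial null for N <= ``exact_max_n``,
    seeded Monte-Carlo otherwise; the p-value is the null probability of a
    log-likelihood ratio at least as large as observed.
    """
    counts = tuple(sum(1 for a in alleles if a.upper() == b) for b in BASES)
    n = sum(counts)
    if n == 0:
        raise ValueError("no alleles supplied")
    obs = multinomial_llr(counts)
    if n <= exact_max_n:
        log_quarter = math.log(0.25)
        logfact = [math.lgamma(k + 1) for k in range(n + 1)]
        p = 0.0
        for comp in _compositions(n, 4):
            llr = multinomial_llr(comp)
            if llr >= obs - 1e-9:
                logp = (logfact[n] - sum(logfact[k] for k in comp)
                        + n * log_quarter)
                p += math.exp(logp)
        return SkewTestResult(counts=counts, llr=obs, p=min(p, 1.0), method="exact")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, [0.25] * 4, size=n_draws)
    expect = n / 4.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(draws > 0, draws * np.log(draws / expect), 0.0)
    llrs = 2.0 * terms.sum(axis=1)
    p = float((llrs >= obs - 1e-9).mean())
    p = max(p, 1.0 / n_draws)
    return SkewTestResult(counts=counts, llr=obs, p=p, method="monte-carlo")


def summarize_skew(clusters: Sequence[SequenceCluster], alpha: float = 0.05,
                   seed: int = 0) -> pd.DataFrame:
    """Percent of clusters whose positive-effect alleles (and, separately,
    reference alleles) are significantly skewed away from uniform."""
    n = len(clusters)
    res = {"n_clusters": n}
    for label, attr in (("positive", "positive_allele"), ("reference", "reference_allele")):
        if n == 0:
            res[f"{label}_significant_pct"] = 0.0
            continue
        sig = sum(
            allele_skew_test([getattr(m, attr) for m in c.members], seed=seed).p < alpha
            for c in clusters)
        res[f"{label}_significant_pct"] = 100.0 * sig / n
    return pd.DataFrame([res])


# ------------------------------------------------------------ PFM similarity

@dataclass
class PfmMatch:
    query_id: str
    database_id: str
    name: str
    collection: str
    rel_score: float


def _pfm_freqs(counts: np.ndarray) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    tot = c.sum(axis=0)
    return c / np.where(tot > 0, tot, 1.0)


def pfm_similarity_score(query: np.ndarray, target: np.ndarray) -> float:
    """Percent-of-maximum similarity between two PFMs.

    Columns are normalized to frequencies; the shorter matrix slides fully
    inside the longer (ungapped); each aligned column scores
    2 - sum_b |q_b - t_b|; relScore = 100 * total / (2 * aligned width),
    maximized over offsets.
    """
    q = _pfm_freqs(query)
    t = _pfm_freqs(target)
    if q.shape[1] > t.shape[1]:
        q, t = t, q
    wq, wt = q.shape[1], t.shape[1]
    best = 0.0
    for off in range(wt - wq + 1):
        window = t[:, off:off + wq]
        score = (2.0 - np.abs(q - window).sum(axis=0)).sum()
        best = max(best, 100.0 * score / (2.0 * wq))
    return best


def pfm_similarity(query_id: str, query_counts: np.ndarray,
                   database: Iterable[Tuple[str, str, np.ndarray, str]],
                   min_rel_score: float = 90.0) -> List[PfmMatch]:
    """Matches of a query PFM against a database of (id, name, counts,
    collection) tuples, keeping relScore above ``min_rel_score``, sorted
    descending."""
    out = []
    for mid, name, counts, collection in database:
        score = pfm_similarity_score(query_counts, counts)
        if score > min_rel_score:
            out.append(PfmMatch(query_id=query_id, database_id=mid, name=name,
                                collection=collection, rel_score=score))
    out.sort(key=lambda m: -m.rel_score)
    return out


def read_jaspar_pfms(path, default_collection: str = "CORE",
                     ) -> List[Tuple[str, str, np.ndarray, str]]:
    """Load a JASPAR-format PFM text database as (id, name, counts,
    collection) tuples; the collection label comes from a third header
    token when present."""
    from Bio import motifs as bio_motifs

    collections = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                toks = line[1:].split()
                if len(toks) >= 3:
                    collections[toks[0]] = toks[2]
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        mid = getattr(m, "matrix_id", None) or m.name
        out.append((mid, m.name, counts, collections.get(mid, default_collection)))
    return out


def write_jaspar_pfms(path, pfms: Dict[str, np.ndarray]) -> None:
    """Write PFMs (id -> 4 x width count matrix) in JASPAR text format."""
    with open(path, "w") as fh:
        for mid, counts in pfms.items():
            fh.write(f">{mid} {mid}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{int(v):6d}" for v in np.asarray(counts)[i])
                fh.write(f"{b}  [{row} ]\n")
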