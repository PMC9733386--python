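"""Parental-origin assignment, per-feature allele-count aggregation, and the
within-feature heterogeneity G-test.

Allele-specific phenotypes require knowing which haplotype came from the dam
and which from the sire.  Where the sire is homozygous this is immediate;
where the sire is heterozygous the orientation is carried from the nearest
previously resolved SNP on the same chromosome using the input phasing; a
heterozygous site with no previously resolved SNP stays unphased and is
excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from asqtl.datatypes import PhasedGenotypePanel, FeatureSet

# provenance codes for ParentalPhaseMatrix entries
HOMOZYGOUS = 0
SIRE_HOMOZYGOUS = 1
CARRIED_PHASE = 2
UNPHASED = 3
MENDEL_INCONSISTENT = 4

PROVENANCE_LABELS = {
    HOMOZYGOUS: "homozygous",
    SIRE_HOMOZYGOUS: "sire-homozygous",
    CARRIED_PHASE: "carried-phase",
    UNPHASED: "unphased",
    MENDEL_INCONSISTENT: "mendel-inconsistent",
}


@dataclass
class ParentalPhaseMatrix:
    """Maternal/paternal allele assignment per animal x SNP with provenance."""

    snps: pd.DataFrame
    maternal: np.ndarray  # int8 (n_animals, n_snps)
    paternal: np.ndarray
    provenance: np.ndarray  # int8 codes above
    animals: List[str]

    def usable(self) -> np.ndarray:
        """Heterozygous entries with resolved parental origin."""
        return np.isin(self.provenance, (SIRE_HOMOZYGOUS, CARRIED_PHASE))

    def dsnp_coding(self, snp_index: int) -> np.ndarray:
        """Driver-SNP haplotype coding: +1 for 1|0 (alt maternal), -1 for 0|1,
        0 for homozygous; unresolved entries are coded NaN."""
        x = np.zeros(self.maternal.shape[0], dtype=float)
        m = self.maternal[:, snp_index]
        p = self.paternal[:, snp_index]
        x[(m == 1) & (p == 0)] = 1.0
        x[(m == 0) & (p == 1)] = -1.0
        bad = np.isin(self.provenance[:, snp_index], (UNPHASED, MENDEL_INCONSISTENT))
        x[bad] = np.nan
        return x


def assign_parental_origin(child_hap1: np.ndarray, child_hap2: np.ndarray,
                           sire: np.ndarray, snps: pd.DataFrame,
                           animals: List[str]) -> ParentalPhaseMatrix:
    """Orient phased child genotypes as maternal|paternal using sire genotypes.

    Parameters
    ----------
    child_hap1, child_hap2 : int arrays (n_animals, n_snps) of the two
        phased child haplotypes in input order (phase-consistent along each
        chromosome but with arbitrary parental labels).
    sire : int array (n_animals, n_snps), sire genotypes coded 0/1/2.
    snps : SNP table with chrom and pos, column order matching the arrays.

    Rules, applied per animal along each chromosome in position order:

    * homozygous child entries are kept unchanged;
    * a heterozygous child with a homozygous sire takes the sire's allele as
      paternal (and this fixes the haplotype orientation for carrying);
    * a heterozygous child with a heterozygous sire inherits the orientation
      of the nearest previously resolved SNP (``carried-phase``), or stays
      ``unphased`` when there is none;
    * entries where neither child allele appears in the sire genotype are
      flagged Mendelian-inconsistent and excluded downstream.
    """
    h1 = np.asarray(child_hap1, dtype=np.int8)
    h2 = np.asarray(child_hap2, dtype=np.int8)
    sire = np.asarray(sire, dtype=np.int8)
    n, m = h1.shape
    maternal = h1.copy()
    paternal = h2.copy()
    provenance = np.full((n, m), UNPHASED, dtype=np.int8)

    chroms = snps["chrom"].to_numpy()
    order = np.arange(m)  # assumed position-sorted per chromosome
    for chrom in pd.unique(chroms):
        cols = order[chroms == chrom]
        # orientation state per animal: 0 unknown, +1 hap1==maternal, -1 hap1==paternal
        state = np.zeros(n, dtype=np.int8)
        for j in cols:
            het = h1[:, j] != h2[:, j]
            hom = ~het
            provenance[hom, j] = HOMOZYGOUS
            # Mendelian check on homozygous children too: child bb, sire aa
            bad_hom = hom & ((sire[:, j] == 0) & (h1[:, j] == 1)
                             | (sire[:, j] == 2) & (h1[:, j] == 0))
            provenance[bad_hom, j] = MENDEL_INCONSISTENT

            sire_hom_ref = het & (sire[:, j] == 0)
            sire_hom_alt = het & (sire[:, j] == 2)
            # sire homozygous reference: paternal allele is 0
            for mask, pat_allele in ((sire_hom_ref, 0), (sire_hom_alt, 1)):
                idx = np.flatnonzero(mask)
                if len(idx) == 0:
                    continue
                hap1_is_pat = h1[idx, j] == pat_allele
                maternal[idx, j] = np.where(hap1_is_pat, h2[idx, j], h1[idx, j])
                paternal[idx, j] = pat_allele
                provenance[idx, j] = SIRE_HOMOZYGOUS
                state[idx] = np.where(hap1_is_pat, -1, 1)

            sire_het = het & (sire[:, j] == 1)
            idx = np.flatnonzero(sire_het)
            if len(idx) > 0:
                known = state[idx] != 0
                ki = idx[known]
                hap1_mat = state[ki] == 1
                maternal[ki, j] = np.where(hap1_mat, h1[ki, j], h2[ki, j])
                paternal[ki, j] = np.where(hap1_mat, h2[ki, j], h1[ki, j])
                provenance[ki, j] = CARRIED_PHASE
                # unknown state stays UNPHASED
    return ParentalPhaseMatrix(snps=snps.reset_index(drop=True), maternal=maternal,
                               paternal=paternal, provenance=provenance,
                               animals=list(animals))


def phase_panel(panel: PhasedGenotypePanel) -> ParentalPhaseMatrix:
    """Run parental-origin assignment on a panel whose input haplotype order
    is arbitrary with respect to parental labels."""
    return assign_parental_origin(panel.maternal, panel.paternal, panel.sire,
                                  panel.snps, panel.animals)


def collect_feature_counts(phase: ParentalPhaseMatrix, per_snp_counts: pd.DataFrame,
                           features: FeatureSet, kind: Optional[str] = None,
                           ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sum per-site maternal/paternal counts into one phenotype per
    animal x feature.

    Exclusions, logged per entry: animals homozygous at a site (not
    informative), sites with unresolved parental origin, and heterozygous
    sites where one parental count is zero while the other is positive
    (monoallelic — treated as potential imputation errors).

    Returns (feature_counts, exclusion_log); feature_counts has columns
    feature_id, animal_id, maternal_count, paternal_count,
    n_informative_sites.
    """
    snp_pos_of = {s: i for i, s in enumerate(phase.snps["snp_id"])}
    animal_pos_of = {a: i for i, a in enumerate(phase.animals)}

    feats = features.features if kind is None else features.of_kind(kind)
    counts = per_snp_counts
    snp_to_features: Dict[str, List[str]] = {}
    skipped_features = []
    for fid in feats["feature_id"]:
        contained = features.snps_in_feature.get(fid, np.array([], dtype=int))
        if len(contained) == 0:
            skipped_features.append(fid)
            continue
        for s in contained:
            snp_to_features.setdefault(phase.snps["snp_id"].iloc[s], []).append(fid)

    agg: Dict[Tuple[str, str], List[int]] = {}
    excl_rows = []
    for row in counts.itertuples(index=False):
        fids = snp_to_features.get(row.snp_id)
        if not fids:
            continue
        si = snp_pos_of.get(row.snp_id)
        ai = animal_pos_of.get(row.animal_id)
        if si is None or ai is None:
            for fid in fids:
                excl_rows.append((fid, row.animal_id, row.snp_id, "unknown-id"))
            continue
        prov = phase.provenance[ai, si]
        if prov == HOMOZYGOUS:
            reason = "homozygous"
        elif prov in (UNPHASED, MENDEL_INCONSISTENT):
            reason = PROVENANCE_LABELS[prov]
        elif (row.maternal_count == 0) != (row.paternal_count == 0):
            reason = "monoallelic"
        elif row.maternal_count == 0 and row.paternal_count == 0:
            reason = "no-reads"
        else:
            reason = None
        for fid in fids:
            if reason is not None:
                excl_rows.append((fid, row.animal_id, row.snp_id, reason))
            else:
                cell = agg.setdefault((fid, row.animal_id), [0, 0, 0])
                cell[0] += int(row.maternal_count)
                cell[1] += int(row.paternal_count)
                cell[2] += 1

    out = pd.DataFrame(
        [(f, a, m, p, s) for (f, a), (m, p, s) in agg.items()],
        columns=["feature_id", "animal_id", "maternal_count",
                 "paternal_count", "n_informative_sites"])
    for fid in skipped_features:
        excl_rows.append((fid, "", "", "feature-without-snps"))
    log = pd.DataFrame(excl_rows, columns=["feature_id", "animal_id", "snp_id", "reason"])
    return out, log


@dataclass
class GTestResult:
    G: float
    df: int
    p: float
    degenerate: bool = False


def heterogeneity_g_test(table) -> GTestResult:
    """Log-likelihood-ratio (G) test that the maternal:paternal ratio is the
    same across the s sites of an s x 2 count table.

    G = 2(sum n_ij ln n_ij + n.. ln n.. - sum n.j ln n.j - sum n_i. ln n_i.)
    with the convention 0 ln 0 = 0; p from chi-squared with s-1 degrees of
    freedom.  A single-site table is degenerate: G = 0, df = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("expected an s x 2 table")
    s = t.shape[0]
    if s == 1:
        return GTestResult(G=0.0, df=0, p=1.0, degenerate=True)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    total = t.sum()
    if np.any(row <= 0) or np.any(col <= 0):
        # empty margins carry no ratio information; collapse them away
        keep = row > 0
        t = t[keep]
        if t.shape[0] <= 1 or np.any(t.sum(axis=0) <= 0):
            return GTestResult(G=0.0, df=0, p=1.0, degenerate=True)
        return heterogeneity_g_test(t)
    g = 2.0 * (xlogy(t, t).sum() + xlogy(total, total)
               - xlogy(col, col).sum() - xlogy(row, row).sum())
    g = max(float(g), 0.0)
    df = s - 1
    return GTestResult(G=g, df=df, p=float(stats.chi2.sf(g, df)))


def feature_site_tables(phase: ParentalPhaseMatrix, per_snp_counts: pd.DataFrame,
                        features: FeatureSet, kind: Optional[str] = None,
                        ) -> Dict[str, np.ndarray]:
    """Per-feature s x 2 tables of summed maternal/paternal counts per site,
    using the same retention rules as :func:`collect_feature_counts`."""
    kept, _ = _per_site_kept(phase, per_snp_counts, features, kind)
    tables: Dict[str, np.ndarray] = {}
    for fid, sub in kept.groupby("feature_id"):
        site = sub.groupby("snp_id")[["maternal_count", "paternal_count"]].sum()
        tables[fid] = site.to_numpy()
    return tables


def _per_site_kept(phase, per_snp_counts, features, kind):
    snp_pos_of = {s: i for i, s in enumerate(phase.snps["snp_id"])}
    animal_pos_of = {a: i for i, a in enumerate(phase.animals)}
    feats = features.features if kind is None else features.of_kind(kind)
    rows = []
    for fid in feats["feature_id"]:
        contained = features.snps_in_feature.get(fid, np.array([], dtype=int))
        ids = set(phase.snps["snp_id"].iloc[list(contained)])
        sub = per_snp_counts[per_snp_counts["snp_id"].isin(ids)]
        for row in sub.itertuples(index=False):
            si = snp_pos_of[row.snp_id]
            ai = animal_pos_of.get(row.animal_id)
            if ai is None:
                continue
            if phase.provenance[ai, si] not in (SIRE_HOMOZYGOUS, CARRIED_PHASE):
                continue
            if (row.maternal_count == 0) != (row.paternal_count == 0):
                continue
            if row.maternal_count == 0 and row.paternal_count == 0:
                continue
            rows.append((fid, row.snp_id, row.maternal_count, row.paternal_count))
    kept = pd.DataFrame(rows, columns=["feature_id", "snp_id",
                                       "maternal_count", "paternal_count"])
    return kept, None


def summarize_heterogeneity(tables: Dict[str, np.ndarray], alpha: float = 0.05,
                            ) -> pd.DataFrame:
    """Fraction of multi-site features whose sites disagree on the
    maternal:paternal ratio (G-test p < alpha)."""
    n_multi = 0
    n_sig = 0
    for _, t in tables.items():
        if t.shape[0] < 2:
            continue
        n_multi += 1
        if heterogeneity_g_test(t).p < alpha:
            n_sig += 1
    frac = (n_sig / n_multi) if n_multi else 0.0
    return pd.DataFrame([{"n_multi_site": n_multi, "n_heterogeneous": n_sig,
                          "fraction": frac}])
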