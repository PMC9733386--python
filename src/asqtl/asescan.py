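"""Two-stage allele-specific QTL scan.

For each feature with a parental allele-count phenotype, every SNP within
1 Mb of the feature midpoint is evaluated as a candidate driver (dSNP).

Stage one pools reads over dSNP heterozygotes onto the alternate-carrying
haplotype: with M_i/P_i the maternal/paternal counts of 1|0 animals and
N_j/Q_j those of 0|1 animals, A = sum M_i + sum Q_j, T the total, and

    Z = (A/T - 0.5) * sqrt(4 T)

is approximately standard normal under no cis effect.  dSNPs passing the
stage-one gate (p < 0.001) go to stage two, an ordinary least-squares fit of
the per-animal log allelic ratio Y_i = ln((maternal+10)/(paternal+10)) on
the haplotype coding X_i (+1 for 1|0, -1 for 0|1, 0 for homozygotes).
A dSNP is called significant when both tests give p < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from asqtl.datatypes import FeatureSet
from asqtl.phasing import ParentalPhaseMatrix

GATE_P = 1e-3
SIGNIF_P = 1e-4
WINDOW = 1_000_000
PSEUDOCOUNT = 10.0


@dataclass
class FirstTestSummary:
    A: float
    T: float
    Z: float
    p: float

    @property
    def gate(self) -> bool:
        return self.p < GATE_P


@dataclass
class SecondTestModel:
    intercept: float
    slope: float
    p: float
    n: int
    degenerate: bool = False


def first_test(maternal: np.ndarray, paternal: np.ndarray, x: np.ndarray,
               ) -> Optional[FirstTestSummary]:
    """Pooled haplotype test over dSNP heterozygotes.

    ``x`` is the per-animal haplotype coding (+1/-1/0, NaN = unphased);
    only animals with x = ±1 contribute.  Returns None when no reads are
    available (T = 0).
    """
    m = np.asarray(maternal, dtype=float)
    p = np.asarray(paternal, dtype=float)
    x = np.asarray(x, dtype=float)
    het = (x == 1) | (x == -1)
    a = m[x == 1].sum() + p[x == -1].sum()
    t = m[het].sum() + p[het].sum()
    if t <= 0:
        return None
    z = (a / t - 0.5) * np.sqrt(4.0 * t)
    pval = 2.0 * stats.norm.sf(abs(z))
    return FirstTestSummary(A=float(a), T=float(t), Z=float(z), p=float(pval))


def second_test(maternal: np.ndarray, paternal: np.ndarray, x: np.ndarray,
                ) -> Optional[SecondTestModel]:
    """OLS of the log allelic ratio on the dSNP haplotype coding.

    Animals with unresolved dSNP phase (NaN coding) are dropped; the slope
    needs at least two distinct X values.  With zero residual variance the
    slope is still reported but the p-value is undefined (degenerate flag).
    """
    m = np.asarray(maternal, dtype=float)
    p = np.asarray(paternal, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x)
    m, p, x = m[ok], p[ok], x[ok]
    if len(x) < 3 or len(np.unique(x)) < 2:
        return None
    y = np.log((m + PSEUDOCOUNT) / (p + PSEUDOCOUNT))
    xc = x - x.mean()
    sxx = (xc ** 2).sum()
    b = float((xc * y).sum() / sxx)
    a = float(y.mean() - b * x.mean())
    resid = y - a - b * x
    dof = len(x) - 2
    s2 = float((resid ** 2).sum() / dof) if dof > 0 else 0.0
    if s2 <= 0:
        return SecondTestModel(intercept=a, slope=b, p=np.nan, n=len(x), degenerate=True)
    se = np.sqrt(s2 / sxx)
    t = b / se
    pval = 2.0 * stats.t.sf(abs(t), dof)
    return SecondTestModel(intercept=a, slope=b, p=float(pval), n=len(x))


def scan_features(features: FeatureSet, kind: str, feature_counts: pd.DataFrame,
                  phase: ParentalPhaseMatrix, window: int = WINDOW,
                  gate_p: float = GATE_P, signif_p: float = SIGNIF_P,
                  ) -> pd.DataFrame:
    """Scan every feature of a kind against all SNPs within ``window`` bp of
    its midpoint.

    ``feature_counts`` is the aggregated per-animal phenotype table from
    :func:`asqtl.phasing.collect_feature_counts`.  Returns one row per
    (feature, dSNP) with A, T, Z, test1_p, slope, test2_p, slope_sign,
    distance_bp and the joint significance flag.
    """
    snps = phase.snps
    pos = snps["pos"].to_numpy()
    chroms = snps["chrom"].to_numpy()
    animal_pos_of = {a: i for i, a in enumerate(phase.animals)}
    n_animals = len(phase.animals)

    # haplotype coding matrix once: +1 / -1 / 0 / NaN
    mat = phase.maternal
    pat = phase.paternal
    x_all = np.zeros((n_animals, len(snps)), dtype=np.float32)
    x_all[(mat == 1) & (pat == 0)] = 1.0
    x_all[(mat == 0) & (pat == 1)] = -1.0
    x_all[np.isin(phase.provenance, (3, 4))] = np.nan  # unphased / inconsistent

    feats = features.of_kind(kind).set_index("feature_id")
    rows = []
    for fid, sub in feature_counts.groupby("feature_id"):
        if fid not in feats.index:
            continue
        frow = feats.loc[fid]
        mid = (int(frow["start"]) + int(frow["end"])) // 2
        on_chrom = chroms == frow["chrom"]
        in_win = on_chrom & (np.abs(pos - mid) <= window)
        cand = np.flatnonzero(in_win)
        if len(cand) == 0:
            continue
        aidx = np.array([animal_pos_of[a] for a in sub["animal_id"]])
        mvec = sub["maternal_count"].to_numpy(dtype=float)
        pvec = sub["paternal_count"].to_numpy(dtype=float)
        x = x_all[np.ix_(aidx, cand)]  # (n_with_counts, n_cand)

        is_pos = (x == 1.0)
        is_neg = (x == -1.0)  # NaN coding compares False on both
        a_stat = mvec @ is_pos + pvec @ is_neg
        t_stat = (mvec + pvec) @ (is_pos | is_neg)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (a_stat / t_stat - 0.5) * np.sqrt(4.0 * t_stat)
        p1 = 2.0 * stats.norm.sf(np.abs(z))

        for k, j in enumerate(cand):
            if t_stat[k] <= 0:
                continue
            rec = {"feature_id": fid, "dsnp_id": snps["snp_id"].iloc[j],
                   "chrom": frow["chrom"], "pos": int(pos[j]),
                   "A": float(a_stat[k]), "T": float(t_stat[k]),
                   "Z": float(z[k]), "test1_p": float(p1[k]),
                   "slope": np.nan, "test2_p": np.nan, "slope_sign": 0,
                   "distance_bp": int(pos[j]) - mid, "significant": False}
            if p1[k] < gate_p:
                m2 = second_test(mvec, pvec, x[:, k])
                if m2 is not None:
                    rec["slope"] = m2.slope
                    rec["test2_p"] = m2.p
                    rec["slope_sign"] = int(np.sign(m2.slope))
                    rec["significant"] = bool(
                        p1[k] < signif_p and not np.isnan(m2.p) and m2.p < signif_p)
            rows.append(rec)
    return pd.DataFrame(rows, columns=[
        "feature_id", "dsnp_id", "chrom", "pos", "A", "T", "Z", "test1_p",
        "slope", "test2_p", "slope_sign", "distance_bp", "significant"])
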