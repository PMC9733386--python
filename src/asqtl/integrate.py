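"""Intersection of the four QTL result sets.

Combines allele-specific binding/expression scans with the traditional
peak-height and exon-expression scans: overlap odds ratios between the sets
of features (or variants) each analysis calls significant, concordance of
effect directions, enrichment of QTL under ChIP-seq peaks, peak-exon
linking through shared driver SNPs, a 4-degree-of-freedom chi-squared
p-value combination, and the final putative-causal-variant selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapTable:
    """2x2 cross-classification of a tested universe by membership in two
    significant sets, with the cross-product odds ratio."""

    n_tested: int
    n_a: int
    n_b: int
    n_both: int

    @property
    def cells(self) -> Tuple[int, int, int, int]:
        a = self.n_both
        b = self.n_a - self.n_both
        c = self.n_b - self.n_both
        d = self.n_tested - self.n_a - self.n_b + self.n_both
        return a, b, c, d

    @property
    def odds_ratio(self) -> float:
        a, b, c, d = self.cells
        if b * c == 0:
            return float("inf") if a * d > 0 else float("nan")
        return (a * d) / (b * c)

    @property
    def infinite(self) -> bool:
        a, b, c, d = self.cells
        return b * c == 0


def overlap_odds_ratio(n_tested: int, set_a, set_b=None, n_both: Optional[int] = None,
                       ) -> OverlapTable:
    """Overlap odds ratio, either from explicit sets or from marginal counts.

    ``overlap_odds_ratio(n, set_a, set_b)`` intersects two collections;
    ``overlap_odds_ratio(n, n_a, n_b, n_both)`` works directly from the
    marginals of a published summary table.
    """
    if n_both is None:
        sa, sb = set(set_a), set(set_b)
        table = OverlapTable(n_tested=n_tested, n_a=len(sa), n_b=len(sb),
                             n_both=len(sa & sb))
    else:
        table = OverlapTable(n_tested=n_tested, n_a=int(set_a), n_b=int(set_b),
                             n_both=int(n_both))
    a, b, c, d = table.cells
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent overlap marginals")
    return table


def direction_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame,
                          key: Sequence[str] = ("feature_id", "dsnp_id"),
                          sign_a: str = "slope_sign", sign_b: str = "slope_sign",
                          ) -> Tuple[pd.DataFrame, float]:
    """Shared entries between two significant result sets and the fraction
    with the same effect sign.

    Both inputs must already use the alternate-allele sign convention
    (allele-specific slope with alt-maternal coded +1; dosage beta as count
    of alternate alleles).  Zero-sign entries are excluded from the
    fraction but kept in the merged table.
    """
    key = list(key)
    merged = results_a.merge(results_b, on=key, suffixes=("_a", "_b"))
    ca = sign_a + ("_a" if sign_a == sign_b else "")
    cb = sign_b + ("_b" if sign_a == sign_b else "")
    sa = np.sign(merged[ca].to_numpy(dtype=float))
    sb = np.sign(merged[cb].to_numpy(dtype=float))
    nonzero = (sa != 0) & (sb != 0)
    frac = float((sa[nonzero] == sb[nonzero]).mean()) if nonzero.any() else float("nan")
    merged["same_direction"] = (sa == sb) & nonzero
    return merged, frac


@dataclass
class EnrichmentCounts:
    A: float  # positions under peaks
    B: float  # positions that are QTL
    C: float  # QTL under a peak
    D: float  # positions considered

    @property
    def enrichment(self) -> float:
        if self.A <= 0 or self.B <= 0 or self.D <= 0:
            raise ZeroDivisionError("enrichment undefined: A, B and D must be positive")
        return (self.C / self.A) / (self.B / self.D)


def _merge_intervals(intervals: Iterable[Tuple[int, int]]):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def enrichment_under_peaks(qtl_positions: pd.DataFrame, peaks: pd.DataFrame,
                           genome_size: Optional[int] = None,
                           tested_positions: Optional[pd.DataFrame] = None,
                           mode: str = "sites") -> EnrichmentCounts:
    """Enrichment = (C/A)/(B/D) of QTL positions under peak intervals.

    Overlapping peak intervals are merged before counting.  In ``sites``
    mode (default) A is the number of tested sites under peaks and D the
    number of tested sites (``tested_positions`` required); in ``bp`` mode
    A is merged peak coverage in base pairs and D is ``genome_size``.
    B is the number of QTL sites, C the number under a peak, in both modes.

    ``qtl_positions`` / ``tested_positions``: DataFrames with chrom, pos.
    ``peaks``: DataFrame with chrom, start, end (0-based half-open).
    """
    merged = {c: _merge_intervals(zip(sub["start"], sub["end"]))
              for c, sub in peaks.groupby("chrom")}

    def under(df):
        cnt = 0
        for c, sub in df.groupby("chrom"):
            ivs = merged.get(c, [])
            if not ivs:
                continue
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            p = sub["pos"].to_numpy()
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
            cnt += int(ok.sum())
        return cnt

    b = len(qtl_positions)
    c = under(qtl_positions)
    if mode == "sites":
        if tested_positions is None:
            raise ValueError("sites mode requires tested_positions")
        a = under(tested_positions)
        d = len(tested_positions)
    elif mode == "bp":
        if genome_size is None:
            raise ValueError("bp mode requires genome_size")
        a = sum(e - s for ivs in merged.values() for s, e in ivs)
        d = genome_size
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EnrichmentCounts(A=a, B=b, C=c, D=d)


def link_peak_exon_pairs(peak_results: pd.DataFrame, exon_results: pd.DataFrame,
                         features: Optional[pd.DataFrame] = None,
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-exon pairs sharing at least one significant driver SNP.

    Inputs are significant result rows with feature_id and dsnp_id columns.
    Returns (pairs, summary): pairs has the shared-dSNP count and, when a
    feature table is supplied, the midpoint distance; the summary reports
    the number of pairs, median distance, mean peaks per exon and mean
    exons per peak.
    """
    pk = peak_results[["feature_id", "dsnp_id"]].drop_duplicates()
    ex = exon_results[["feature_id", "dsnp_id"]].drop_duplicates()
    joined = pk.merge(ex, on="dsnp_id", suffixes=("_peak", "_exon"))
    pairs = (joined.groupby(["feature_id_peak", "feature_id_exon"])
             .size().rename("shared_dsnps").reset_index()
             .rename(columns={"feature_id_peak": "peak_id",
                              "feature_id_exon": "exon_id"}))
    if features is not None and len(pairs):
        mids = features.set_index("feature_id").assign(
            mid=lambda d: (d["start"] + d["end"]) // 2)["mid"]
        pairs["distance_bp"] = (mids.reindex(pairs["peak_id"]).to_numpy()
                                - mids.reindex(pairs["exon_id"]).to_numpy())
    if len(pairs):
        summary = pd.DataFrame([{
            "n_pairs": len(pairs),
            "median_distance_bp": (float(np.median(np.abs(pairs["distance_bp"])))
                                   if "distance_bp" in pairs else np.nan),
            "peaks_per_exon": float(pairs.groupby("exon_id").size().mean()),
            "exons_per_peak": float(pairs.groupby("peak_id").size().mean()),
        }])
    else:
        summary = pd.DataFrame([{"n_pairs": 0, "median_distance_bp": np.nan,
                                 "peaks_per_exon": np.nan, "exons_per_peak": np.nan}])
    return pairs, summary


_TINY_P = 1e-300


def combine_pvalues(*pvalues: float) -> float:
    """Chi-squared combination: each p is mapped to its upper-tail 1-df
    chi-squared quantile, the quantiles are summed, and the combined p is
    the upper tail of chi-squared with one df per input (4 df for the four
    QTL analyses).  Zero inputs are clamped to the smallest positive value."""
    ps = np.asarray(pvalues, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    ps = np.clip(ps, _TINY_P, 1.0)
    x = stats.chi2.isf(ps, df=1).sum()
    return float(stats.chi2.sf(x, df=len(ps)))


def select_putative_causal(asb: pd.DataFrame, ase: pd.DataFrame,
                           hqtl: pd.DataFrame, eeqtl: pd.DataFrame,
                           peaks: pd.DataFrame, signif_p: float = 1e-4,
                           ) -> pd.DataFrame:
    """Select putative causal variants from the four result sets.

    Criteria: p < ``signif_p`` in the traditional hQTL and eeQTL analyses
    and in the first allele-specific test of both the binding and the
    expression scan; the variant lies inside the peak it is associated
    with; and the effect direction agrees across all four analyses.  The
    four p-values are combined (4-df chi-squared) and only the lowest
    combined p per (peak, exon) pair is kept, ties broken by genomic
    position.

    Expected columns: asb/ase - feature_id, dsnp_id, pos, test1_p,
    slope_sign; hqtl/eeqtl - feature_id, snp_id, beta, p.
    """
    h = hqtl[hqtl["p"] < signif_p].rename(columns={
        "feature_id": "peak_id", "snp_id": "dsnp_id", "p": "p_h", "beta": "beta_h"})
    ee = eeqtl[eeqtl["p"] < signif_p].rename(columns={
        "feature_id": "exon_id", "snp_id": "dsnp_id", "p": "p_ee", "beta": "beta_ee"})
    ab = asb[asb["test1_p"] < signif_p].rename(columns={
        "feature_id": "peak_id", "test1_p": "p_asb1", "slope_sign": "sign_asb"})
    ae = ase[ase["test1_p"] < signif_p].rename(columns={
        "feature_id": "exon_id", "test1_p": "p_ase1", "slope_sign": "sign_ase"})

    cand = (ab[["peak_id", "dsnp_id", "pos", "p_asb1", "sign_asb"]]
            .merge(h[["peak_id", "dsnp_id", "p_h", "beta_h"]], on=["peak_id", "dsnp_id"])
            .merge(ae[["exon_id", "dsnp_id", "p_ase1", "sign_ase"]], on="dsnp_id")
            .merge(ee[["exon_id", "dsnp_id", "p_ee", "beta_ee"]], on=["exon_id", "dsnp_id"]))
    if cand.empty:
        return pd.DataFrame(columns=["dsnp_id", "peak_id", "exon_id", "pos",
                                     "p_h", "p_ee", "p_asb1", "p_ase1",
                                     "combined_p", "in_peak", "direction_concordant"])

    pk = peaks.set_index("feature_id")
    starts = pk["start"].reindex(cand["peak_id"]).to_numpy()
    ends = pk["end"].reindex(cand["peak_id"]).to_numpy()
    cand["in_peak"] = (cand["pos"].to_numpy() >= starts) & (cand["pos"].to_numpy() < ends)

    signs = np.column_stack([np.sign(cand["beta_h"]), np.sign(cand["beta_ee"]),
                             cand["sign_asb"], cand["sign_ase"]])
    cand["direction_concordant"] = ((signs != 0).all(axis=1)
                                    & (np.abs(signs.sum(axis=1)) == signs.shape[1]))

    kept = cand[cand["in_peak"] & cand["direction_concordant"]].copy()
    if kept.empty:
        return kept.assign(combined_p=pd.Series(dtype=float))
    kept["combined_p"] = [combine_pvalues(r.p_h, r.p_ee, r.p_asb1, r.p_ase1)
                          for r in kept.itertuples()]
    kept = kept.sort_values(["combined_p", "pos"], kind="mergesort")
    best = kept.drop_duplicates(subset=["peak_id", "exon_id"], keep="first")
    cols = ["dsnp_id", "peak_id", "exon_id", "pos", "p_h", "p_ee", "p_asb1",
            "p_ase1", "combined_p", "in_peak", "direction_concordant"]
    return best[cols].reset_index(drop=True)
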