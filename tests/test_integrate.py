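"""Four-way QTL intersection: published-table odds ratios, direction
concordance, the (C/A)/(B/D) peak enrichment with a per-position brute-force
oracle, p-value combination against its closed form and Monte-Carlo, and
putative-causal-variant selection on a hand-built toy set."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asqtl.integrate import (overlap_odds_ratio, direction_concordance,
                             enrichment_under_peaks, link_peak_exon_pairs,
                             combine_pvalues, select_putative_causal,
                             EnrichmentCounts)


class TestOverlapOddsRatio:
    # reported overlap tables of the four QTL analyses:
    # (universe, n_A, n_B, n_both, published cross-product odds ratio)
    @pytest.mark.parametrize("n,na,nb,nboth,published", [
        (224_183, 15_918, 14_816, 3_656, 5.26),
        (220_588, 20_555, 18_840, 4_706, 3.9),
        (283_232, 7_963, 5_943, 243, 1.5),
        (48_456, 15_308, 25_163, 10_678, 2.97),
        (13_397_022, 1_999_869, 1_055_069, 410_022, 4.3),
        (13_397_022, 1_999_869, 981_026, 339_821, 3.4),
        (13_397_022, 1_999_869, 154_739, 53_829, 3.1),
        (13_397_022, 5_402_049, 1_234_995, 783_358, 2.8),
        (13_397_022, 5_402_049, 1_840_063, 1_082_690, 2.4),
        (13_397_022, 5_402_049, 346_175, 120_207, 0.8),
    ])
    def test_reproduces_published_tables(self, n, na, nb, nboth, published):
        table = overlap_odds_ratio(n, na, nb, n_both=nboth)
        ndp = 2 if published in (5.26, 2.97) else 1
        # at the printed precision, allowing half-ulp rounding slack
        assert abs(table.odds_ratio - published) <= 1.2 * 0.5 * 10 ** (-ndp) + 1e-9

    def test_identical_sets_infinite(self):
        t = overlap_odds_ratio(100, {1, 2, 3}, {1, 2, 3})
        assert t.infinite and np.isinf(t.odds_ratio)

    def test_disjoint_small_sets_below_one(self):
        t = overlap_odds_ratio(1000, set(range(10)), set(range(10, 20)))
        assert t.odds_ratio < 1

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(ValueError):
            overlap_odds_ratio(10, 8, 8, n_both=0)  # d would be negative

    def test_cells_sum_to_universe(self):
        t = overlap_odds_ratio(500, 100, 200, n_both=50)
        assert sum(t.cells) == 500


class TestDirectionConcordance:
    def _df(self, signs):
        return pd.DataFrame({"feature_id": [f"f{i}" for i in range(len(signs))],
                             "dsnp_id": [f"s{i}" for i in range(len(signs))],
                             "slope_sign": signs})

    def test_identical_sets_fraction_one(self):
        a = self._df([1, -1, 1])
        merged, frac = direction_concordance(a, a.copy())
        assert frac == 1.0 and len(merged) == 3

    def test_flipped_copy_fraction_zero(self):
        a = self._df([1, -1, 1])
        b = a.copy()
        b["slope_sign"] = -b["slope_sign"]
        _, frac = direction_concordance(a, b)
        assert frac == 0.0

    def test_zero_signs_excluded(self):
        a = self._df([1, 0, -1])
        b = self._df([1, 1, -1])
        merged, frac = direction_concordance(a, b)
        assert frac == 1.0  # the zero-sign pair is not in the denominator
        assert len(merged) == 3


class TestEnrichment:
    def test_printed_formula_arithmetic(self):
        assert EnrichmentCounts(A=100, B=50, C=10, D=1000).enrichment == pytest.approx(2.0)

    def test_all_qtl_in_peaks_covering_tenth(self):
        assert EnrichmentCounts(A=100, B=40, C=40, D=1000).enrichment == pytest.approx(10.0)

    def test_undefined_when_empty(self):
        with pytest.raises(ZeroDivisionError):
            EnrichmentCounts(A=0, B=5, C=0, D=100).enrichment

    def test_uniform_scatter_near_one(self, rng):
        genome = 1_000_000
        peaks = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(0, genome, 10_000),
                              "end": np.arange(0, genome, 10_000) + 2_000})
        qtl = pd.DataFrame({"chrom": "chr1",
                            "pos": rng.integers(0, genome, 100_000)})
        enr = enrichment_under_peaks(qtl, peaks, genome_size=genome, mode="bp")
        assert enr.enrichment == pytest.approx(1.0, abs=0.1)

    def test_matches_per_position_brute_force(self, rng):
        # site-mode counts equal a per-position membership scan on a small genome
        genome = 100_000
        starts = np.sort(rng.choice(genome - 500, 40, replace=False))
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(50, 500, 40)})
        tested = pd.DataFrame({"chrom": "chr1",
                               "pos": rng.choice(genome, 2_000, replace=False)})
        qtl = tested.iloc[rng.choice(2_000, 300, replace=False)]
        enr = enrichment_under_peaks(qtl, peaks, tested_positions=tested, mode="sites")
        covered = np.zeros(genome, dtype=bool)
        for r in peaks.itertuples():
            covered[r.start:r.end] = True
        assert enr.A == covered[tested["pos"].to_numpy()].sum()
        assert enr.C == covered[qtl["pos"].to_numpy()].sum()
        assert enr.B == 300 and enr.D == 2000
        # bp mode: A equals the merged coverage counted per position
        enr_bp = enrichment_under_peaks(qtl, peaks, genome_size=genome, mode="bp")
        assert enr_bp.A == covered.sum()


class TestLinkPairs:
    def _res(self, items):
        return pd.DataFrame(items, columns=["feature_id", "dsnp_id"])

    def test_no_shared_dsnps_empty(self):
        pairs, summary = link_peak_exon_pairs(
            self._res([("p1", "s1")]), self._res([("e1", "s2")]))
        assert pairs.empty and summary.iloc[0]["n_pairs"] == 0

    def test_cartesian_product_of_sharers(self):
        pk = self._res([("p1", "s1"), ("p2", "s1")])
        ex = self._res([("e1", "s1"), ("e2", "s1"), ("e3", "s1")])
        pairs, summary = link_peak_exon_pairs(pk, ex)
        assert len(pairs) == 6
        assert summary.iloc[0]["exons_per_peak"] == 3.0
        assert summary.iloc[0]["peaks_per_exon"] == 2.0

    def test_planted_links_recovered(self):
        # sparse genome so features rarely overlap: reported pairs should
        # be dominated by the planted shared-driver architecture
        from asqtl import phasing, asescan, simulate
        from asqtl.config import SimulationConfig
        cfg = SimulationConfig(n_animals=120, n_chromosomes=2,
                               chrom_length=2_000_000, n_snps_per_chrom=150,
                               n_peaks=40, n_exons=40, frac_causal_features=0.5,
                               frac_shared_drivers=1.0, seed=5)
        panel, fs, counts, _, _ = simulate.simulate_all(cfg)
        phase = phasing.phase_panel(panel)
        res = {}
        for kind in ("peak", "exon"):
            fc, _ = phasing.collect_feature_counts(
                phase, counts.allele_counts[kind], fs, kind=kind)
            r = asescan.scan_features(fs, kind, fc, phase)
            res[kind] = r[r["significant"]]
        pairs, _ = link_peak_exon_pairs(res["peak"], res["exon"], fs.features)
        truth = fs.truth.table
        planted = set()
        for snp, grp in truth.groupby("causal_variant_id"):
            pk = grp[grp["target_feature_id"].str.startswith("peak")]["target_feature_id"]
            ex = grp[grp["target_feature_id"].str.startswith("exon")]["target_feature_id"]
            planted |= {(p, e) for p in pk for e in ex}
        assert planted, "fixture should plant shared drivers"
        found = set(zip(pairs["peak_id"], pairs["exon_id"]))
        # most reported pairs correspond to planted regulatory links
        precision = len(found & planted) / max(len(found), 1)
        assert precision >= 0.8


class TestCombinePvalues:
    def test_all_ones_give_one(self):
        assert combine_pvalues(1, 1, 1, 1) == pytest.approx(1.0)

    def test_closed_form_example(self):
        # four p = 0.05: quantiles 3.8415 each, sum 15.366,
        # combined p = e^{-x/2}(1 + x/2) ~ 0.0040
        x = 4 * stats.chi2.isf(0.05, 1)
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert combine_pvalues(0.05, 0.05, 0.05, 0.05) == pytest.approx(closed, rel=1e-12)
        assert closed == pytest.approx(0.0040, abs=2e-4)

    def test_closed_form_grid(self):
        # the 4-df upper tail equals e^{-x/2}(1+x/2) over a wide grid
        for x in np.linspace(0.1, 40, 20):
            ps = [float(stats.chi2.sf(x / 4, 1))] * 4
            closed = np.exp(-x / 2) * (1 + x / 2)
            assert abs(combine_pvalues(*ps) - closed) < 1e-10

    def test_monotone_in_each_input(self, rng):
        base = [0.3, 0.2, 0.6, 0.9]
        ref = combine_pvalues(*base)
        for i in range(4):
            lower = list(base)
            lower[i] = base[i] / 2
            assert combine_pvalues(*lower) <= ref

    def test_zero_input_clamped(self):
        assert 0 < combine_pvalues(0.0, 1, 1, 1) < 1e-10

    def test_matches_monte_carlo(self, rng):
        # combined p at four p=0.3 equals the Monte-Carlo combination within 2 SE
        target = combine_pvalues(0.3, 0.3, 0.3, 0.3)
        draws = rng.uniform(size=(1_000_000, 4))
        x = stats.chi2.isf(np.clip(draws, 1e-12, 1), 1).sum(axis=1)
        x0 = 4 * stats.chi2.isf(0.3, 1)
        mc = (x >= x0).mean()
        se = np.sqrt(mc * (1 - mc) / 1e6)
        assert abs(target - mc) < 2 * se + 1e-6


class TestSelectPutativeCausal:
    def _toy(self):
        peaks = pd.DataFrame([{"feature_id": "p1", "chrom": "chr1",
                               "start": 100, "end": 200, "kind": "peak"}])
        def asrow(fid, snp, pos, p1, sign):
            return {"feature_id": fid, "dsnp_id": snp, "pos": pos,
                    "test1_p": p1, "slope_sign": sign}
        def tradrow(fid, snp, p, beta):
            return {"feature_id": fid, "snp_id": snp, "p": p, "beta": beta}
        asb = pd.DataFrame([asrow("p1", "sA", 150, 1e-6, 1),
                            asrow("p1", "sB", 300, 1e-9, 1),   # outside peak
                            asrow("p1", "sC", 160, 1e-5, 1),
                            asrow("p1", "sD", 170, 1e-8, -1)])  # discordant
        ase = pd.DataFrame([asrow("e1", "sA", 150, 1e-6, 1),
                            asrow("e1", "sB", 300, 1e-9, 1),
                            asrow("e1", "sC", 160, 1e-7, 1),
                            asrow("e1", "sD", 170, 1e-8, 1)])
        h = pd.DataFrame([tradrow("p1", "sA", 1e-6, 0.5),
                          tradrow("p1", "sB", 1e-9, 0.4),
                          tradrow("p1", "sC", 1e-5, 0.3),
                          tradrow("p1", "sD", 1e-8, 0.2)])
        ee = pd.DataFrame([tradrow("e1", "sA", 1e-6, 0.5),
                          tradrow("e1", "sB", 1e-9, 0.4),
                          tradrow("e1", "sC", 1e-6, 0.3),
                          tradrow("e1", "sD", 1e-8, 0.2)])
        return asb, ase, h, ee, peaks

    def test_filters_and_best_per_pair(self):
        asb, ase, h, ee, peaks = self._toy()
        out = select_putative_causal(asb, ase, h, ee, peaks)
        # sB fails the in-peak rule, sD fails direction concordance;
        # sA and sC pass and the smaller combined p wins the (peak, exon) pair
        assert len(out) == 1
        pa = combine_pvalues(1e-6, 1e-6, 1e-6, 1e-6)
        pc = combine_pvalues(1e-5, 1e-6, 1e-5, 1e-7)
        winner = "sA" if pa < pc else "sC"
        assert out.iloc[0]["dsnp_id"] == winner
        assert out.iloc[0]["combined_p"] == pytest.approx(min(pa, pc), rel=1e-12)

    def test_row_order_invariance(self, rng):
        asb, ase, h, ee, peaks = self._toy()
        perm = lambda df: df.sample(frac=1, random_state=3).reset_index(drop=True)
        a = select_putative_causal(asb, ase, h, ee, peaks)
        b = select_putative_causal(perm(asb), perm(ase), perm(h), perm(ee), peaks)
        pd.testing.assert_frame_equal(a, b)

    def test_outside_peak_excluded(self):
        asb, ase, h, ee, peaks = self._toy()
        keep = select_putative_causal(asb, ase, h, ee, peaks)
        assert "sB" not in set(keep["dsnp_id"])

    def test_discordant_direction_excluded(self):
        asb, ase, h, ee, peaks = self._toy()
        keep = select_putative_causal(asb, ase, h, ee, peaks)
        assert "sD" not in set(keep["dsnp_id"])
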