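"""Benchmark computations: published-table reproduction, calibration and
power studies on planted ground truth.

These routines re-run the package's own methods under fixed study
conditions and return the headline numbers; they back both the acceptance
script and the acceptance test suite.
"""

from __future__ import annotations

import re
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from asqtl import asescan, featqtl, integrate, motifs, phasing, simulate
from asqtl.config import SimulationConfig

# Published overlap tables of the four molecular-QTL analyses in the cattle
# mammary dataset this pipeline models: feature-level peak/exon overlaps and
# variant-level overlaps over the ~13.4M-SNP tested universe.
# (universe, n_A, n_B, n_both)
REPORTED_OVERLAPS: Dict[str, tuple] = {
    "or_peaks_h3k4me3": (224_183, 15_918, 14_816, 3_656),
    "or_peaks_h3k4me1": (220_588, 20_555, 18_840, 4_706),
    "or_peaks_h3k27ac": (283_232, 7_963, 5_943, 243),
    "or_exons_rna": (48_456, 15_308, 25_163, 10_678),
    "or_snps_ase_asb_h3k4me3": (13_397_022, 1_999_869, 1_055_069, 410_022),
    "or_snps_ase_asb_h3k4me1": (13_397_022, 1_999_869, 981_026, 339_821),
    "or_snps_ase_asb_h3k27ac": (13_397_022, 1_999_869, 154_739, 53_829),
    "or_snps_ee_h_h3k4me3": (13_397_022, 5_402_049, 1_234_995, 783_358),
    "or_snps_ee_h_h3k4me1": (13_397_022, 5_402_049, 1_840_063, 1_082_690),
    "or_snps_ee_h_h3k27ac": (13_397_022, 5_402_049, 346_175, 120_207),
}


def overlap_odds_ratios() -> Dict[str, float]:
    """Cross-product odds ratios recomputed from the reported marginals."""
    return {name: integrate.overlap_odds_ratio(n, a, b, n_both=both).odds_ratio
            for name, (n, a, b, both) in REPORTED_OVERLAPS.items()}


def consensus_worked_example() -> Dict[str, object]:
    """The documented consensus rule on the A=0.4/C=0.3/G=0.2/T=0.1 column."""
    pfm = np.array([[40.0], [30.0], [20.0], [10.0]])
    cons = motifs.build_consensus(pfm, entropy_threshold=0.0)
    return {"regex": cons.regex, "class_size": len(cons.columns[0])}


def chisq4_closed_form_error(n_grid: int = 20) -> float:
    """Max |implementation - closed form| of the 4-df combination, where the
    closed form of the upper tail at x is e^(-x/2)(1 + x/2)."""
    xs = np.linspace(0.1, 40.0, n_grid)
    worst = 0.0
    for x in xs:
        ps = [float(stats.chi2.sf(x / 4.0, 1))] * 4
        closed = float(np.exp(-x / 2.0) * (1.0 + x / 2.0))
        worst = max(worst, abs(integrate.combine_pvalues(*ps) - closed))
    return worst


def first_test_null_calibration(seed: int = 0, n_pairs: int = 2000,
                                n_het: int = 100, depth: int = 50,
                                ) -> Dict[str, float]:
    """Null feature-dSNP pairs with binomial counts: uniformity of the
    stage-one p and the empirical rate below the stage-two gate."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 41])
    ps = np.empty(n_pairs)
    for i in range(n_pairs):
        m = rng.binomial(depth, 0.5, n_het).astype(float)
        x = rng.choice([1.0, -1.0], n_het)
        ps[i] = asescan.first_test(m, depth - m, x).p
    return {"ks_p": float(stats.kstest(ps, "uniform").pvalue),
            "rate_below_gate": float((ps < 1e-3).mean()),
            "n": n_pairs}


def _study_config(seed: int) -> SimulationConfig:
    # 200 animals, ~100 causal features (fraction 100/240 of 240 features),
    # planted allelic log-odds 2.0 and additive log-count effect 0.5
    return SimulationConfig(
        n_animals=200, n_chromosomes=2, chrom_length=1_500_000,
        n_snps_per_chrom=250, n_peaks=120, n_exons=120,
        frac_causal_features=100 / 240, frac_causal_in_feature=0.5,
        frac_shared_drivers=0.3, effect_size_range=(2.0, 2.0),
        effect_level_scale=0.25, mean_depth=50.0, seed=seed)


def planted_recovery_study(seed: int = 0) -> Dict[str, float]:
    """Planted cis effects at study scale: allele-specific power with sign
    recovery, and direction concordance between the allele-specific and
    mixed-model scans among true positives."""
    cfg = _study_config(seed)
    panel = simulate.simulate_population(cfg)
    features = simulate.simulate_features(panel, cfg)
    counts = simulate.simulate_counts(panel, features, features.truth, cfg)
    phase = phasing.phase_panel(panel)

    truth = features.truth.table
    as_results, trad_results = {}, {}
    for kind in ("peak", "exon"):
        fc, _ = phasing.collect_feature_counts(
            phase, counts.allele_counts[kind], features, kind=kind)
        as_results[kind] = asescan.scan_features(features, kind, fc, phase)

    keep, _ = featqtl.qc_peaks(counts.peak_counts, counts.input_counts)
    peak_pheno, _ = featqtl.normalize_peak_phenotype(
        counts.peak_counts.loc[keep], counts.input_counts.loc[keep])
    exon_pheno = featqtl.transform_expression(counts.exon_counts, counts.batches)
    grm = featqtl.build_grm(panel)
    covar = counts.batches.to_frame("batch")
    trad_results["peak"] = featqtl.scan_feature_qtl(
        features, "peak", peak_pheno, panel, grm, covariates=covar)
    trad_results["exon"] = featqtl.scan_feature_qtl(
        features, "exon", exon_pheno, panel, grm, covariates=covar)

    as_all = pd.concat(as_results.values(), ignore_index=True)
    merged = truth.merge(
        as_all, left_on=["target_feature_id", "causal_variant_id"],
        right_on=["feature_id", "dsnp_id"], how="left")
    hit = (merged["significant"].fillna(False)
           & (np.sign(merged["effect_on_ratio"]) == merged["slope_sign"]))
    power = float(hit.mean())

    trad_all = pd.concat(trad_results.values(), ignore_index=True)
    trad_sig = trad_all[trad_all["p"] < 1e-4].rename(columns={"snp_id": "dsnp_id"})
    trad_sig = trad_sig.assign(slope_sign=np.sign(trad_sig["beta"]).astype(int))
    as_sig = as_all[as_all["significant"]]
    true_pairs = set(zip(truth["target_feature_id"], truth["causal_variant_id"]))
    both, frac = integrate.direction_concordance(as_sig, trad_sig)
    tp = both[[(f, s) in true_pairs for f, s in zip(both["feature_id"], both["dsnp_id"])]]
    concord = float(tp["same_direction"].mean()) if len(tp) else float("nan")
    return {"n_causal": int(len(truth)),
            "as_power_correct_sign": power,
            "as_trad_concordance_true_positives": concord,
            "n_true_positive_pairs": int(len(tp))}


def motif_recovery_study(seed: int = 0, n_planted: int = 30,
                         n_background: int = 100) -> Dict[str, float]:
    """Variants carrying a planted 9-mer (one mismatch in every third copy)
    among background variants: cluster recovery, consensus fidelity and
    genomic enrichment of the recovered consensus at a 5x planting rate."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 43])
    plant = "TGACTCAGT"
    bases = list("ACGT")

    def rand_seq(n):
        return "".join(rng.choice(bases, n))

    seqs = []
    for i in range(n_planted):
        core = list(plant)
        if i % 3 == 0:
            j = int(rng.integers(0, len(plant)))
            core[j] = str(rng.choice([b for b in bases if b != core[j]]))
        seqs.append(motifs.VariantSequence(
            f"plant{i}", rand_seq(6) + "".join(core) + rand_seq(6),
            "forward", "A", "A"))
    for i in range(n_background):
        seqs.append(motifs.VariantSequence(
            f"bg{i}", rand_seq(21), "forward", "A", "A"))

    clusters = motifs.cluster_sequences(seqs)
    planted_ids = {f"plant{i}" for i in range(n_planted)}
    if not clusters:
        return {"recovered_cluster_size": 0, "consensus_matches_plant": 0.0,
                "planted_enrichment": float("nan")}
    best = max(clusters, key=lambda c: sum(m.variant_id in planted_ids
                                           for m in c.members))
    recovered = sum(m.variant_id in planted_ids for m in best.members)
    cons = motifs.build_consensus(best.pfm())
    # fidelity on the planted columns (6..14): random flank columns can
    # survive trimming by sampling noise, so compare the central span only
    lo, hi = max(cons.start, 6), min(cons.end, 6 + len(plant))
    central_regex = "".join(
        c if len(c) == 1 else f"[{c}]"
        for c in cons.columns[lo - cons.start:hi - cons.start])
    matches = float(bool(hi > lo and re.fullmatch(central_regex,
                                                  plant[lo - 6:hi - 6])))

    genome = {"c": rand_seq(200_000)}
    probe = motifs.ConsensusMotif(0, len(plant), "", plant, list(plant))
    base_freqs = (0.25, 0.25, 0.25, 0.25)
    pre = motifs.genomic_enrichment(probe, genome, base_freqs=base_freqs)
    n_insert = max(1, int(np.ceil(5 * pre.expected)) - pre.observed)
    g = list(genome["c"])
    step = len(g) // (n_insert + 1)
    for k in range(n_insert):
        pos = (k + 1) * step
        g[pos:pos + len(plant)] = plant
    enr = motifs.genomic_enrichment(probe, {"c": "".join(g)},
                                    base_freqs=base_freqs)
    return {"recovered_cluster_size": int(recovered),
            "consensus_matches_plant": matches,
            "planted_enrichment": float(enr.enrichment)}
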