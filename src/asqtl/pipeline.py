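"""End-to-end orchestration of the synthetic molecular-QTL pipeline.

Stages: simulate -> parental phasing and allele counts -> two-stage
allele-specific scans (peaks and exons) -> traditional mixed-model scans ->
four-way intersection -> motif discovery.  Every stage's outputs are
written under the run directory and tallied into a machine-readable report.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from asqtl import asescan, featqtl, integrate, io, motifs, phasing, simulate
from asqtl.config import SimulationConfig, ConfigurationError

log = logging.getLogger("asqtl")


@dataclass
class PipelineConfig:
    """Run-level configuration: thresholds default to the analysis' standard
    values; the embedded SimulationConfig defines the synthetic study."""

    outdir: str = "asqtl_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mark: str = "h3k4me3"
    gate_p: float = 1e-3
    signif_p: float = 1e-4
    heterogeneity_alpha: float = 0.05
    window: int = 1_000_000
    rel_score: float = 90.0
    motif_min_cluster: int = 10
    literal_entropy_trim: bool = False
    enrichment_mode: str = "sites"
    asb_motif_p: Optional[float] = None  # default: per-mark table
    ase_motif_p: float = motifs.ASE_MOTIF_P
    pfm_database: Optional[str] = None

    def validate(self) -> None:
        for name in ("gate_p", "signif_p", "heterogeneity_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if self.window <= 0:
            raise ConfigurationError(f"window must be positive, got {self.window}")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            for key in ("maf_range", "feature_width_range", "effect_size_range",
                        "base_freqs"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if sim.get("planted_motifs"):
                sim["planted_motifs"] = [tuple(x) for x in sim["planted_motifs"]]
            sim = SimulationConfig(**sim)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        cfg = cls(simulation=sim, **d)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; returns (and writes) the run report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: Dict = {"stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        s = stage("simulate")
        panel, features, counts, genome, manifest = simulate.simulate_all(config.simulation)
        io.write_simulation(panel, features, counts, genome, manifest, config.outdir)
        s.update(n_animals=panel.n_animals, n_snps=panel.n_snps,
                 n_peaks=len(features.of_kind("peak")),
                 n_exons=len(features.of_kind("exon")),
                 n_causal=len(features.truth))

        s = stage("counts")
        phase = phasing.phase_panel(panel)
        feature_counts, het_summary = {}, {}
        for kind in ("peak", "exon"):
            fc, excl = phasing.collect_feature_counts(
                phase, counts.allele_counts[kind], features, kind=kind)
            feature_counts[kind] = fc
            fc.to_csv(os.path.join(config.outdir, f"feature_allele_counts_{kind}.tsv"),
                      sep="\t", index=False)
            tables = phasing.feature_site_tables(
                phase, counts.allele_counts[kind], features, kind=kind)
            het = phasing.summarize_heterogeneity(tables, config.heterogeneity_alpha)
            het_summary[kind] = het.iloc[0].to_dict()
            s[kind] = {"phenotypes": int(fc["feature_id"].nunique()),
                       "excluded_entries": int(len(excl)),
                       "heterogeneity": het_summary[kind]}

        s = stage("as_scan")
        as_results = {}
        for kind in ("peak", "exon"):
            res = asescan.scan_features(features, kind, feature_counts[kind], phase,
                                        window=config.window, gate_p=config.gate_p,
                                        signif_p=config.signif_p)
            res["mark"] = config.mark if kind == "peak" else "rna"
            as_results[kind] = res
            res.to_csv(os.path.join(config.outdir, f"as_qtl_{kind}.tsv"),
                       sep="\t", index=False)
            sig = res[res["significant"]]
            s[kind] = {
                "phenotypes_tested": int(res["feature_id"].nunique()),
                "phenotypes_significant_test1": int(
                    res.loc[res["test1_p"] < config.signif_p, "feature_id"].nunique()),
                "phenotypes_significant_both": int(sig["feature_id"].nunique()),
                "significant_dsnps": int(len(sig))}

        s = stage("trad_scan")
        keep, qc_log = featqtl.qc_peaks(counts.peak_counts, counts.input_counts)
        peak_pheno, _ = featqtl.normalize_peak_phenotype(
            counts.peak_counts.loc[keep], counts.input_counts.loc[keep])
        exon_pheno = featqtl.transform_expression(counts.exon_counts, counts.batches)
        retained_chip, _ = featqtl.pca_outlier_filter(peak_pheno)
        retained_rna, _ = featqtl.pca_outlier_filter(exon_pheno)
        grm = featqtl.build_grm(panel)
        covar = counts.batches.to_frame("batch")
        trad_results = {}
        for kind, pheno, retained in (("peak", peak_pheno, retained_chip),
                                      ("exon", exon_pheno, retained_rna)):
            res = featqtl.scan_feature_qtl(features, kind, pheno[retained],
                                           panel, grm, covariates=covar,
                                           window=config.window)
            trad_results[kind] = res
            res.to_csv(os.path.join(config.outdir, f"trad_qtl_{kind}.tsv"),
                       sep="\t", index=False)
            sig = res[res["p"] < config.signif_p]
            s[kind] = {"phenotypes_tested": int(res["feature_id"].nunique()),
                       "phenotypes_significant": int(sig["feature_id"].nunique()),
                       "significant_dsnps": int(len(sig))}
        s["peaks_removed_qc"] = int(len(qc_log))
        s["animals_removed_pca"] = {
            "chip": panel.n_animals - len(retained_chip),
            "rna": panel.n_animals - len(retained_rna)}

        s = stage("intersect")
        as_sig = {k: v[v["significant"]] for k, v in as_results.items()}
        trad_sig = {k: v[v["p"] < config.signif_p] for k, v in trad_results.items()}
        for kind in ("peak", "exon"):
            universe = set(as_results[kind]["feature_id"]) & set(
                trad_results[kind]["feature_id"])
            ov = integrate.overlap_odds_ratio(
                len(universe),
                set(as_sig[kind]["feature_id"]) & universe,
                set(trad_sig[kind]["feature_id"]) & universe)
            merged, frac = integrate.direction_concordance(
                as_sig[kind], trad_sig[kind].rename(
                    columns={"snp_id": "dsnp_id"}).assign(
                        slope_sign=lambda d: np.sign(d["beta"]).astype(int)),
                key=("feature_id", "dsnp_id"))
            s[kind] = {"tested_in_both": len(universe), "n_as": ov.n_a,
                       "n_trad": ov.n_b, "overlap": ov.n_both,
                       "odds_ratio": None if ov.infinite else round(ov.odds_ratio, 3),
                       "shared_significant_dsnps": int(len(merged)),
                       "same_direction_fraction": None if np.isnan(frac) else round(frac, 4)}
        peaks_df = features.of_kind("peak")
        tested = panel.snps.rename(columns={"snp_id": "dsnp_id"})[["dsnp_id", "chrom", "pos"]]
        qtl_pos = tested[tested["dsnp_id"].isin(
            set(as_sig["exon"]["dsnp_id"]))]
        if len(qtl_pos):
            enr = integrate.enrichment_under_peaks(
                qtl_pos, peaks_df, genome_size=config.simulation.n_chromosomes
                * config.simulation.chrom_length,
                tested_positions=tested, mode=config.enrichment_mode)
            s["ase_under_peak_enrichment"] = round(enr.enrichment, 3)
        pairs, pair_summary = integrate.link_peak_exon_pairs(
            as_sig["peak"], as_sig["exon"], features.features)
        pairs.to_csv(os.path.join(config.outdir, "peak_exon_pairs.tsv"),
                     sep="\t", index=False)
        s["peak_exon_pairs"] = pair_summary.iloc[0].to_dict()
        causal = integrate.select_putative_causal(
            as_results["peak"], as_results["exon"],
            trad_results["peak"], trad_results["exon"],
            peaks_df, signif_p=config.signif_p)
        causal.to_csv(os.path.join(config.outdir, "putative_causal.tsv"),
                      sep="\t", index=False)
        s["putative_causal_variants"] = int(causal["dsnp_id"].nunique())

        s = stage("motifs")
        if not genome:
            raise RuntimeError("motifs stage requires a reference genome")
        asb_thr = ({k: config.asb_motif_p for k in motifs.ASB_MOTIF_P}
                   if config.asb_motif_p else None)
        chosen = motifs.select_variants_for_motifs(
            as_sig["peak"], as_sig["exon"], peaks=peaks_df,
            exons=features.of_kind("exon"), asb_thresholds=asb_thr,
            ase_threshold=config.ase_motif_p)
        seqs, skip_log = motifs.extract_sequences(chosen, genome, panel.snps)
        clusters = motifs.cluster_sequences(seqs, min_size=config.motif_min_cluster)
        s["variants_selected"] = int(len(chosen))
        s["sequences"] = len(seqs)
        s["clusters"] = len(clusters)
        motif_rows = []
        pfm_db = (motifs.read_jaspar_pfms(config.pfm_database)
                  if config.pfm_database else None)
        for i, cl in enumerate(clusters):
            try:
                cons = motifs.build_consensus(
                    cl.pfm(), literal_entropy_trim=config.literal_entropy_trim)
            except ValueError:
                continue
            enr = motifs.genomic_enrichment(
                cons, genome, base_freqs=config.simulation.base_freqs)
            row = {"cluster": i, "size": cl.size, "iupac": cons.iupac,
                   "regex": cons.regex, "observed": enr.observed,
                   "expected": round(enr.expected, 2),
                   "enrichment": round(enr.enrichment, 3)}
            if pfm_db:
                matches = motifs.pfm_similarity(f"cluster_{i}", cl.pfm(), pfm_db,
                                                min_rel_score=config.rel_score)
                row["best_match"] = matches[0].database_id if matches else None
            motif_rows.append(row)
        pd.DataFrame(motif_rows).to_csv(
            os.path.join(config.outdir, "motif_consensus.tsv"), sep="\t", index=False)
        if clusters:
            skew = motifs.summarize_skew(clusters, seed=config.simulation.seed)
            s["skew"] = skew.iloc[0].to_dict()
    except Exception as exc:  # tag the failing stage, keep partial outputs
        failing = list(report["stages"])[-1] if report["stages"] else "startup"
        raise RuntimeError(f"pipeline failed in stage {failing!r}: {exc}") from exc

    with open(os.path.join(config.outdir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
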