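"""Synthetic trio-phased QTL study generator.

Generates every input the pipeline consumes with known ground truth:

* a phased genotype panel (maternal|paternal child haplotypes plus sire
  genotypes, Mendelian-consistent by construction),
* peak/exon features annotated with contained SNPs and a truth table of
  planted cis drivers,
* allele counts (beta-binomial around a logit-shifted maternal fraction),
  feature totals (negative-binomial with batch, polygenic and library-size
  structure) and genotype-independent input totals,
* a toy reference genome with planted motif instances centred on variant
  sites.

All generators derive independent random streams from the master seed so
that identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from asqtl.config import SimulationConfig, ConfigurationError
from asqtl.datatypes import PhasedGenotypePanel, FeatureSet, TruthTable, CountsBundle

BASES = np.array(["A", "C", "G", "T"])

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_POS_MARGIN = 50  # keep SNPs away from contig ends (motif extraction needs ±10)


class GenerationError(RuntimeError):
    """Raised when a requested synthetic dataset cannot be constructed."""


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_population(config: SimulationConfig) -> PhasedGenotypePanel:
    """Draw a phased population with sire genotypes.

    Maternal alleles are Bernoulli draws at the SNP's population frequency;
    the paternal allele is one of the sire's two alleles chosen at random,
    so the paternal haplotype is Mendelian-consistent with the sire by
    construction.
    """
    config.validate()
    rng = np.random.default_rng(config.stream_seed("population"))
    n = config.n_animals

    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        span = config.chrom_length - 2 * _POS_MARGIN
        if span < config.n_snps_per_chrom:
            raise ConfigurationError("chrom_length too small for n_snps_per_chrom")
        pos = np.sort(rng.choice(span, size=config.n_snps_per_chrom, replace=False)) + _POS_MARGIN
        maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps_per_chrom)
        ref_idx = rng.integers(0, 4, size=config.n_snps_per_chrom)
        alt_shift = rng.integers(1, 4, size=config.n_snps_per_chrom)
        for i in range(config.n_snps_per_chrom):
            rows.append((f"{chrom}_{pos[i]}", chrom, int(pos[i]),
                         BASES[ref_idx[i]], BASES[(ref_idx[i] + alt_shift[i]) % 4],
                         float(maf[i])))
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "maf"])

    m = len(snps)
    p = snps["maf"].to_numpy()
    maternal = (rng.random((n, m)) < p).astype(np.int8)
    sire_a1 = (rng.random((n, m)) < p).astype(np.int8)
    sire_a2 = (rng.random((n, m)) < p).astype(np.int8)
    pick = rng.integers(0, 2, size=(n, m))
    paternal = np.where(pick == 0, sire_a1, sire_a2).astype(np.int8)
    sire = (sire_a1 + sire_a2).astype(np.int8)

    animals = [f"animal_{i:04d}" for i in range(n)]
    return PhasedGenotypePanel(snps=snps, maternal=maternal, paternal=paternal,
                               sire=sire, animals=animals)


def simulate_features(panel: PhasedGenotypePanel, config: SimulationConfig) -> FeatureSet:
    """Place peak and exon intervals, each containing at least one SNP,
    and assign planted cis drivers to a random fraction of them.

    Each feature is anchored on a SNP so allele-specific phenotypes are
    defined for it.  A causal feature gets exactly one driver SNP, inside
    the feature with probability ``frac_causal_in_feature`` and otherwise
    elsewhere in the ±1 Mb cis window; the driver's allelic-ratio effect is
    drawn from ``effect_size_range`` with random sign, and its additive
    effect on the log feature total is ``effect_level_scale`` times that.
    """
    if panel.n_snps == 0:
        raise GenerationError("panel has no SNPs")
    wlo, whi = config.feature_width_range
    if whi < 1:
        raise GenerationError("feature widths must be >= 1 bp")
    if whi > config.chrom_length:
        raise GenerationError("feature wider than chromosome")
    rng = np.random.default_rng(config.stream_seed("features"))

    pos = panel.snps["pos"].to_numpy()
    chroms = panel.snps["chrom"].to_numpy()
    chrom_names = panel.snps["chrom"].unique()
    by_chrom = {c: np.flatnonzero(chroms == c) for c in chrom_names}

    feat_rows = []
    snps_in = {}
    truth_rows = []
    peak_drivers = []  # (snp index, effect_on_ratio, effect_on_level, chrom)
    for kind, count in (("peak", config.n_peaks), ("exon", config.n_exons)):
        anchors = rng.integers(0, panel.n_snps, size=count)
        widths = rng.integers(wlo, whi + 1, size=count)
        causal = rng.random(count) < config.frac_causal_features
        for k in range(count):
            a = anchors[k]
            w = int(widths[k])
            apos = int(pos[a])
            start = apos - int(rng.integers(0, w))
            start = min(max(start, 0), config.chrom_length - w)
            end = start + w
            fid = f"{kind}_{k:05d}"
            chrom = chroms[a]
            idx = by_chrom[chrom]
            lo = np.searchsorted(pos[idx], start, side="left")
            hi = np.searchsorted(pos[idx], end, side="left")
            contained = idx[lo:hi]
            feat_rows.append((fid, chrom, start, end, kind))
            snps_in[fid] = contained
            if causal[k]:
                mid = (start + end) // 2
                d = None
                # a causal exon may reuse a nearby causal peak's driver,
                # planting coordinated peak-exon regulation
                if kind == "exon" and rng.random() < config.frac_shared_drivers:
                    nearby = [pd_ for pd_ in peak_drivers
                              if pd_[3] == chrom and abs(pos[pd_[0]] - mid) <= 1_000_000]
                    if nearby:
                        d, eff, eff_level, _ = nearby[int(rng.integers(0, len(nearby)))]
                        in_peak = start <= pos[d] < end
                if d is None:
                    inside = rng.random() < config.frac_causal_in_feature
                    if inside and len(contained) > 0:
                        d = int(rng.choice(contained))
                        in_peak = True
                    else:
                        window = idx[(np.abs(pos[idx] - mid) <= 1_000_000)]
                        outside = window[(pos[window] < start) | (pos[window] >= end)]
                        if len(outside) > 0:
                            d = int(rng.choice(outside))
                            in_peak = False
                        else:
                            d = int(rng.choice(contained))
                            in_peak = True
                    eff = float(rng.uniform(*config.effect_size_range))
                    eff *= 1 if rng.random() < 0.5 else -1
                    eff_level = config.effect_level_scale * eff
                if kind == "peak":
                    peak_drivers.append((d, eff, eff_level, chrom))
                truth_rows.append((panel.snps["snp_id"].iloc[d], fid, eff,
                                   eff_level, in_peak))

    features = pd.DataFrame(feat_rows, columns=["feature_id", "chrom", "start", "end", "kind"])
    truth = TruthTable(pd.DataFrame(
        truth_rows,
        columns=["causal_variant_id", "target_feature_id",
                 "effect_on_ratio", "effect_on_level", "in_peak"]))
    return FeatureSet(features=features, snps_in_feature=snps_in, truth=truth)


def _beta_binomial(rng, n, p, rho):
    """Beta-binomial draws with mean n*p and intraclass correlation rho."""
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if rho == 0:
        return rng.binomial(n, p)
    scale = (1.0 - rho) / rho
    pp = rng.beta(np.maximum(p * scale, 1e-9), np.maximum((1.0 - p) * scale, 1e-9))
    return rng.binomial(n, pp)


def _negbin(rng, mu, dispersion):
    r = 1.0 / dispersion
    prob = r / (r + np.asarray(mu, dtype=float))
    return rng.negative_binomial(r, prob)


def simulate_counts(panel: PhasedGenotypePanel, features: FeatureSet,
                    truth: TruthTable, config: SimulationConfig) -> CountsBundle:
    """Draw allele counts, feature totals and input totals.

    Allelic counts: per heterozygous site, site depth is Poisson with mean
    ``mean_depth`` and the maternal count is beta-binomial around
    ``logistic(X * effect_on_ratio)`` where X = +1/-1 encodes which parental
    haplotype carries the alternate allele at the feature's driver SNP
    (X = 0, i.e. a 0.5 maternal fraction, for driver homozygotes and
    non-causal features).

    Feature totals: negative-binomial with log-mean
    ``log(mean_depth) + dosage * effect_on_level + batch + polygenic +
    library size``; input totals share the library structure but are
    independent of genotype.
    """
    rng = np.random.default_rng(config.stream_seed("counts"))
    n = panel.n_animals

    batches = pd.Series(rng.integers(0, config.n_batches, size=n),
                        index=panel.animals, name="batch")
    batch_eff = rng.normal(0.0, config.batch_sd, size=config.n_batches)

    # polygenic covariance from the panel's own GRM
    from asqtl.featqtl import build_grm
    grm = build_grm(panel).full()
    jitter = 1e-6 * np.eye(n)
    chol = np.linalg.cholesky(grm + jitter)

    lib_chip = np.exp(rng.normal(0.0, 0.2, size=n))
    lib_input = np.exp(rng.normal(0.0, 0.2, size=n))
    lib_rna = np.exp(rng.normal(0.0, 0.2, size=n))

    snp_ids = panel.snps["snp_id"].to_numpy()
    snp_pos_of = {s: i for i, s in enumerate(snp_ids)}
    truth_by_feature = {r.target_feature_id: r for r in truth.table.itertuples()}

    # haplotype coding at each causal driver: +1 alt-maternal, -1 alt-paternal
    def driver_x(dsnp_id):
        d = snp_pos_of[dsnp_id]
        x = np.zeros(n, dtype=np.int8)
        x[(panel.maternal[:, d] == 1) & (panel.paternal[:, d] == 0)] = 1
        x[(panel.maternal[:, d] == 0) & (panel.paternal[:, d] == 1)] = -1
        return x

    allele_counts: Dict[str, pd.DataFrame] = {}
    for kind in ("peak", "exon"):
        feats = features.of_kind(kind)
        # one allelic-effect assignment per SNP; causal features claim their
        # sites first (overlapping features share reads in reality, so a
        # site inside two features can carry only one allelic ratio)
        snp_effect: Dict[int, np.ndarray] = {}
        snp_seen: Dict[int, bool] = {}
        causal_first = sorted(feats["feature_id"],
                              key=lambda f: f not in truth_by_feature)
        for fid in causal_first:
            contained = features.snps_in_feature[fid]
            rec = truth_by_feature.get(fid)
            for s in contained:
                if s not in snp_seen:
                    snp_seen[s] = True
                    if rec is not None:
                        snp_effect[s] = _sigmoid(driver_x(rec.causal_variant_id)
                                                 * rec.effect_on_ratio)
        rows_animal, rows_snp, rows_m, rows_p = [], [], [], []
        for s in sorted(snp_seen):
            het = np.flatnonzero(panel.maternal[:, s] != panel.paternal[:, s])
            if len(het) == 0:
                continue
            depth = rng.poisson(config.mean_depth, size=len(het))
            pm = snp_effect.get(s)
            p_site = pm[het] if pm is not None else np.full(len(het), 0.5)
            mat = _beta_binomial(rng, depth, p_site, config.overdispersion)
            pat = depth - mat
            rows_animal.extend(np.asarray(panel.animals)[het])
            rows_snp.extend([snp_ids[s]] * len(het))
            rows_m.extend(mat)
            rows_p.extend(pat)
        allele_counts[kind] = pd.DataFrame({
            "animal_id": rows_animal, "snp_id": rows_snp,
            "maternal_count": np.asarray(rows_m, dtype=int),
            "paternal_count": np.asarray(rows_p, dtype=int)})

    dosage = panel.dosage()

    def totals(kind, lib, genotype_driven=True):
        feats = features.of_kind(kind)
        z = rng.standard_normal((n, len(feats)))
        poly = config.polygenic_sd * (chol @ z)
        out = np.empty((len(feats), n), dtype=int)
        for k, fid in enumerate(feats["feature_id"]):
            logmu = (np.log(config.mean_depth) + np.log(lib)
                     + batch_eff[batches.to_numpy()] + poly[:, k])
            rec = truth_by_feature.get(fid)
            if genotype_driven and rec is not None:
                d = snp_pos_of[rec.causal_variant_id]
                logmu = logmu + dosage[:, d] * rec.effect_on_level
            out[k] = _negbin(rng, np.exp(logmu), config.nb_dispersion)
        return pd.DataFrame(out, index=feats["feature_id"].to_numpy(),
                            columns=panel.animals)

    peak_counts = totals("peak", lib_chip)
    input_counts = totals("peak", lib_input, genotype_driven=False)
    exon_counts = totals("exon", lib_rna)

    return CountsBundle(allele_counts=allele_counts, peak_counts=peak_counts,
                        input_counts=input_counts, exon_counts=exon_counts,
                        batches=batches)


def simulate_reference(config: SimulationConfig,
                       panel: Optional[PhasedGenotypePanel] = None,
                       truth: Optional[TruthTable] = None,
                       ) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Background i.i.d. reference sequence with planted motif instances.

    Background bases are drawn from ``base_freqs``.  When a panel is given,
    the base at each SNP position is set to the SNP's reference allele and
    planted motifs are centred on variant positions — preferentially the
    causal in-feature drivers of ``truth`` (so discovered variants share
    sequence), falling back to random SNPs; without a panel plant sites are
    random.  Returns the genome (chrom -> sequence) and a manifest listing
    every planted instance.
    """
    for motif, _ in config.planted_motifs:
        if len(motif) > 21:
            raise GenerationError(f"planted motif {motif!r} longer than 21 bp")
        bad = set(motif.upper()) - set(IUPAC)
        if bad:
            raise GenerationError(f"planted motif {motif!r} has non-IUPAC symbols {sorted(bad)}")
    rng = np.random.default_rng(config.stream_seed("reference"))

    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    base_idx = {b: i for i, b in enumerate(BASES)}
    genome_arr: Dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        arr = rng.choice(4, size=config.chrom_length, p=np.asarray(config.base_freqs))
        genome_arr[chrom] = arr.astype(np.uint8)

    if panel is not None:
        for chrom, sub in panel.snps.groupby("chrom"):
            genome_arr[chrom][sub["pos"].to_numpy()] = [
                base_idx[b] for b in sub["ref"]]

    causal_sites: list = []
    if panel is not None and truth is not None and len(truth):
        snp_pos_of = {s: i for i, s in enumerate(panel.snps["snp_id"])}
        seen = set()
        for r in truth.table.itertuples():
            if r.in_peak and r.causal_variant_id not in seen:
                seen.add(r.causal_variant_id)
                causal_sites.append(snp_pos_of[r.causal_variant_id])

    manifest_rows = []
    planted_n = 0
    used: Dict[str, list] = {c: [] for c in chrom_names}

    def free(chrom, start, length):
        if start < 0 or start + length > config.chrom_length:
            return False
        return all(start + length <= s or start >= e for s, e in used[chrom])

    for motif, count in config.planted_motifs:
        motif = motif.upper()
        half = len(motif) // 2
        for _ in range(count):
            chrom = center = None
            if panel is not None and planted_n < len(causal_sites):
                j = causal_sites[planted_n]
                cand_chrom = panel.snps["chrom"].iloc[j]
                cand_center = int(panel.snps["pos"].iloc[j])
                if free(cand_chrom, cand_center - half, len(motif)):
                    chrom, center = cand_chrom, cand_center
                planted_n += 1
            for _try in range(200):
                if chrom is not None:
                    break
                if panel is not None and panel.n_snps > 0:
                    j = int(rng.integers(0, panel.n_snps))
                    cand_chrom = panel.snps["chrom"].iloc[j]
                    cand_center = int(panel.snps["pos"].iloc[j])
                else:
                    cand_chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                    cand_center = int(rng.integers(half, config.chrom_length
                                                   - len(motif) + half))
                if free(cand_chrom, cand_center - half, len(motif)):
                    chrom, center = cand_chrom, cand_center
            if chrom is None:  # genome too crowded for this instance
                continue
            start = center - half
            used[chrom].append((start, start + len(motif)))
            instance = "".join(IUPAC[ch][int(rng.integers(0, len(IUPAC[ch])))]
                               for ch in motif)
            genome_arr[chrom][start:start + len(motif)] = [base_idx[b] for b in instance]
            manifest_rows.append((chrom, start, center, motif, instance))

    genome = {c: "".join(BASES[a]) for c, a in genome_arr.items()}
    manifest = pd.DataFrame(manifest_rows,
                            columns=["chrom", "start", "center", "motif", "instance"])
    return genome, manifest


def simulate_all(config: SimulationConfig):
    """Run all four generators; returns (panel, features, counts, genome, manifest)."""
    panel = simulate_population(config)
    features = simulate_features(panel, config)
    counts = simulate_counts(panel, features, features.truth, config)
    genome, manifest = simulate_reference(config, panel, features.truth)
    return panel, features, counts, genome, manifest
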