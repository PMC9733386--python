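"""Simulation and pipeline configuration objects with validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trio-phased QTL study.

    The defaults describe a desk-scale version of a cis-QTL study in an
    outbred livestock population: a few hundred animals with phased
    genotypes and sire genotypes, ChIP-seq peaks and exons carrying
    heterozygous sites, and a fraction of features whose counts are driven
    in cis by one nearby variant.

    Parameters
    ----------
    n_animals : number of offspring with phenotype data.
    n_chromosomes, chrom_length : toy genome layout (bp).
    n_snps_per_chrom : biallelic SNPs per chromosome, positions uniform.
    maf_range : alternate-allele population frequency range, in (0, 0.5].
    n_peaks, n_exons : number of ChIP-seq peak / exon features.
    feature_width_range : feature width bounds in bp.
    frac_causal_features : fraction of features with a planted cis driver.
    effect_size_range : |log-odds| bounds of the allelic-ratio shift per
        alternate-carrying haplotype.
    effect_level_scale : the additive per-alt-allele effect on log feature
        count is ``effect_level_scale * effect_on_ratio`` so that allelic
        and total-count effects share a sign.
    frac_causal_in_feature : fraction of causal drivers placed inside their
        feature (the rest land in the ±1 Mb cis window outside it).
    frac_shared_drivers : probability that a causal exon reuses a nearby
        causal peak's driver SNP and effect sizes, planting the coordinated
        peak-exon regulation the intersection stage looks for.
    overdispersion : beta-binomial rho of allelic counts, in [0, 1).
    mean_depth : mean reads per informative site and mean feature count.
    nb_dispersion : negative-binomial dispersion of feature totals
        (var = mu + nb_dispersion * mu^2).
    n_batches : sequencing batches; batch_sd is the SD of batch shifts on
        the log count scale; polygenic_sd the SD of the animal-level
        polygenic term (log scale) with covariance given by the GRM.
    base_freqs : background base frequencies (A, C, G, T) of the toy
        reference sequence.
    planted_motifs : list of (IUPAC consensus, count) planted in the
        reference, centred on variant positions.
    seed : master seed; each generator derives its own stream from it.
    """

    n_animals: int = 100
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_snps_per_chrom: int = 300
    maf_range: Tuple[float, float] = (0.1, 0.5)
    n_peaks: int = 100
    n_exons: int = 100
    feature_width_range: Tuple[int, int] = (500, 2000)
    frac_causal_features: float = 0.3
    effect_size_range: Tuple[float, float] = (1.0, 2.5)
    effect_level_scale: float = 0.25
    frac_causal_in_feature: float = 0.5
    frac_shared_drivers: float = 0.5
    overdispersion: float = 0.02
    mean_depth: float = 50.0
    nb_dispersion: float = 0.05
    n_batches: int = 2
    batch_sd: float = 0.1
    polygenic_sd: float = 0.2
    base_freqs: Tuple[float, float, float, float] = (0.291, 0.209, 0.209, 0.291)
    planted_motifs: List[Tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    # fixed offsets of the per-generator random streams
    _STREAMS = {"population": 0, "features": 1, "counts": 2, "reference": 3}

    def validate(self) -> None:
        for name in ("n_animals", "n_chromosomes", "chrom_length",
                     "n_snps_per_chrom", "n_peaks", "n_exons", "n_batches"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ConfigurationError(f"{name} must be a count >= 1, got {v!r}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        wlo, whi = self.feature_width_range
        if wlo > whi:
            raise ConfigurationError(f"feature_width_range must be ordered, got {self.feature_width_range}")
        if not 0 <= self.frac_causal_features <= 1:
            raise ConfigurationError(f"frac_causal_features must be in [0,1], got {self.frac_causal_features}")
        if not 0 <= self.frac_causal_in_feature <= 1:
            raise ConfigurationError(f"frac_causal_in_feature must be in [0,1], got {self.frac_causal_in_feature}")
        if not 0 <= self.frac_shared_drivers <= 1:
            raise ConfigurationError(f"frac_shared_drivers must be in [0,1], got {self.frac_shared_drivers}")
        if not 0 <= self.overdispersion < 1:
            raise ConfigurationError(f"overdispersion must be in [0,1), got {self.overdispersion}")
        if self.mean_depth <= 0:
            raise ConfigurationError(f"mean_depth must be positive, got {self.mean_depth}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        if len(self.base_freqs) != 4 or abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ConfigurationError(f"base_freqs must be 4 probabilities summing to 1, got {self.base_freqs}")
        if any(f < 0 for f in self.base_freqs):
            raise ConfigurationError(f"base_freqs must be non-negative, got {self.base_freqs}")
        for motif, count in self.planted_motifs:
            if len(motif) > 21:
                raise ConfigurationError(f"planted_motifs: motif {motif!r} longer than 21")
            if count < 0:
                raise ConfigurationError(f"planted_motifs: negative count for {motif!r}")

    def stream_seed(self, stream: str) -> list:
        """Seed sequence entropy for a named generator stream."""
        return [int(self.seed) & 0x7FFFFFFF, self._STREAMS[stream]]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        for key in ("maf_range", "feature_width_range", "effect_size_range", "base_freqs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "planted_motifs" in d and d["planted_motifs"]:
            d["planted_motifs"] = [tuple(x) for x in d["planted_motifs"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg
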