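"""Core in-memory containers shared across the pipeline.

Conventions used throughout:

* allele codes: 0 = reference, 1 = alternate
* phased genotypes are ordered ``maternal | paternal`` (so ``1|0`` means the
  alternate allele was inherited from the dam)
* coordinates are 0-based, half-open internally; VCF positions are converted
  on read/write; BED is native.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd


@dataclass
class PhasedGenotypePanel:
    """Phased child genotypes plus sire genotypes for a set of animals.

    Attributes
    ----------
    snps : DataFrame with columns snp_id, chrom, pos (0-based), ref, alt,
        and optionally maf (the population alternate-allele frequency used
        by the simulator).  Positions are strictly increasing per chromosome.
    maternal, paternal : int8 arrays of shape (n_animals, n_snps) holding
        the allele on each parental haplotype.
    sire : int8 array (n_animals, n_snps) of sire genotypes coded 0/1/2
        (count of alternate alleles).
    animals : animal identifiers, row order of the genotype arrays.
    """

    snps: pd.DataFrame
    maternal: np.ndarray
    paternal: np.ndarray
    sire: np.ndarray
    animals: List[str]

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosage(self) -> np.ndarray:
        """Count of alternate alleles per animal x SNP (0/1/2)."""
        return (self.maternal + self.paternal).astype(np.int8)

    def het_mask(self) -> np.ndarray:
        return self.maternal != self.paternal

    def snp_index(self) -> pd.Index:
        return pd.Index(self.snps["snp_id"])


@dataclass
class TruthTable:
    """Planted causal effects: which variant drives which feature."""

    table: pd.DataFrame  # causal_variant_id, target_feature_id,
    #                      effect_on_ratio, effect_on_level, in_peak

    def __len__(self) -> int:
        return len(self.table)

    def for_feature(self, feature_id: str) -> pd.DataFrame:
        return self.table[self.table["target_feature_id"] == feature_id]


@dataclass
class FeatureSet:
    """Peak and exon intervals with their contained SNPs.

    ``features`` columns: feature_id, chrom, start, end, kind ('peak' or
    'exon').  ``snps_in_feature`` maps feature_id to the integer indices
    (into the panel's SNP table) of SNPs inside the interval.
    """

    features: pd.DataFrame
    snps_in_feature: Dict[str, np.ndarray]
    truth: Optional[TruthTable] = None

    def __len__(self) -> int:
        return len(self.features)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.features[self.features["kind"] == kind]

    def midpoint(self, feature_id: str) -> int:
        row = self.features.set_index("feature_id").loc[feature_id]
        return (int(row["start"]) + int(row["end"])) // 2


@dataclass
class CountsBundle:
    """Every count table the simulator emits.

    allele_counts : per-kind DataFrames with columns animal_id, snp_id,
        maternal_count, paternal_count — read counts assigned to the two
        parental haplotypes at heterozygous sites inside features.
    peak_counts, input_counts : DataFrames indexed by peak feature_id with
        one column per animal (ChIP and matched input totals).
    exon_counts : DataFrame indexed by exon feature_id, columns = animals.
    batches : Series mapping animal_id to sequencing-batch label.
    """

    allele_counts: Dict[str, pd.DataFrame] = field(default_factory=dict)
    peak_counts: Optional[pd.DataFrame] = None
    input_counts: Optional[pd.DataFrame] = None
    exon_counts: Optional[pd.DataFrame] = None
    batches: Optional[pd.Series] = None
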