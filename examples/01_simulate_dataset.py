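"""Generate a small synthetic molecular-QTL study with known ground truth.

Writes phased child + sire VCFs, peak/exon BED files, allele-count and
count-matrix TSVs, a reference FASTA and the truth table of planted cis
drivers under ./example_out/simulate.
"""

from asqtl import io, simulate
from asqtl.config import SimulationConfig

cfg = SimulationConfig(n_animals=60, n_chromosomes=2, chrom_length=500_000,
                       n_snps_per_chrom=120, n_peaks=30, n_exons=30,
                       frac_causal_features=0.3, seed=1)
panel, features, counts, genome, manifest = simulate.simulate_all(cfg)
paths = io.write_simulation(panel, features, counts, genome, manifest,
                            "example_out/simulate")

truth = features.truth.table
print(f"animals: {panel.n_animals}, SNPs: {panel.n_snps}")
print(f"features: {len(features)} (peaks + exons), planted drivers: {len(truth)}")
print(truth.head().to_string(index=False))
print("-> each row plants one cis driver: effect_on_ratio is the log-odds")
print("   shift of the maternal:paternal read ratio per alt-carrying")
print("   haplotype, effect_on_level the additive shift of log feature count.")
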