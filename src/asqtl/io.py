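"""Readers and writers for the pipeline's on-disk formats.

VCF carries the phased child genotypes (GT written maternal|paternal) and a
paired VCF the sire genotypes; features are BED6; allele counts, count
matrices and truth tables are TSV; the reference is FASTA.  VCF positions
are converted between the 1-based file convention and the package's 0-based
internal coordinates on read/write.
"""

from __future__ import annotations

import os
import textwrap
from typing import Dict

import numpy as np
import pandas as pd

from asqtl.datatypes import PhasedGenotypePanel, FeatureSet, TruthTable, CountsBundle

VCF_HEADER = """##fileformat=VCFv4.2
##source=asqtl
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(panel: PhasedGenotypePanel, path: str, which: str = "child") -> None:
    """Write the child (phased maternal|paternal) or sire genotypes as VCF."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in panel.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = panel.animals if which == "child" else [f"sire_of_{a}" for a in panel.animals]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in enumerate(panel.snps.itertuples()):
            if which == "child":
                gts = [f"{panel.maternal[i, j]}|{panel.paternal[i, j]}"
                       for i in range(panel.n_animals)]
            else:
                gts = ["0/0" if g == 0 else ("0/1" if g == 1 else "1/1")
                       for g in panel.sire[:, j]]
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf_pair(child_path: str, sire_path: str) -> PhasedGenotypePanel:
    """Read a child+sire VCF pair back into a panel (positions to 0-based)."""
    from cyvcf2 import VCF

    child = VCF(child_path)
    animals = list(child.samples)
    rows, mat, pat = [], [], []
    for v in child:
        rows.append((v.ID, v.CHROM, v.POS - 1, v.REF, v.ALT[0] if v.ALT else "."))
        g = np.array(v.genotypes)  # (n, 3): a1, a2, phased
        mat.append(g[:, 0])
        pat.append(g[:, 1])
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    maternal = np.array(mat, dtype=np.int8).T
    paternal = np.array(pat, dtype=np.int8).T

    sire_vcf = VCF(sire_path)
    sire_rows = []
    for v in sire_vcf:
        g = np.array(v.genotypes)
        sire_rows.append(g[:, 0] + g[:, 1])
    sire = np.array(sire_rows, dtype=np.int8).T
    if sire.shape != maternal.shape:
        raise ValueError("child and sire VCFs differ in shape")
    return PhasedGenotypePanel(snps=snps, maternal=maternal, paternal=paternal,
                               sire=sire, animals=animals)


def write_bed(features: pd.DataFrame, path: str) -> None:
    """BED6: chrom, start, end, feature_id, score 0, strand '+'."""
    bed = features[["chrom", "start", "end", "feature_id"]].copy()
    bed["score"] = 0
    bed["strand"] = "+"
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, kind: str = "peak") -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "feature_id", "score", "strand"])
    out = bed[["feature_id", "chrom", "start", "end"]].copy()
    out["kind"] = kind
    return out


def write_allele_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_count_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_count_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_truth(truth: TruthTable, path: str) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> TruthTable:
    return TruthTable(pd.read_csv(path, sep="\t"))


def write_fasta(genome: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for line in textwrap.wrap(seq, width, break_on_hyphens=False):
                fh.write(line + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(path)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_simulation(panel: PhasedGenotypePanel, features: FeatureSet,
                     counts: CountsBundle, genome: Dict[str, str],
                     manifest: pd.DataFrame, outdir: str) -> Dict[str, str]:
    """Write every simulated input under ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_vcf(panel, p("genotypes.vcf"), which="child")
    write_vcf(panel, p("sires.vcf"), which="sire")
    write_bed(features.of_kind("peak"), p("peaks.bed"))
    write_bed(features.of_kind("exon"), p("exons.bed"))
    for kind, df in counts.allele_counts.items():
        write_allele_counts(df, p(f"allele_counts_{kind}.tsv"))
    write_count_matrix(counts.peak_counts, p("peak_counts.tsv"))
    write_count_matrix(counts.input_counts, p("input_counts.tsv"))
    write_count_matrix(counts.exon_counts, p("exon_counts.tsv"))
    counts.batches.rename_axis("animal_id").to_frame().to_csv(
        p("batches.tsv"), sep="\t")
    if features.truth is not None:
        write_truth(features.truth, p("truth.tsv"))
    write_fasta(genome, p("reference.fasta"))
    manifest.to_csv(p("motif_manifest.tsv"), sep="\t", index=False)
    return paths
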