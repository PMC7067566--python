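"""Flat-file interchange: genotype matrices, phenotypes, VCF export.

Genotypes travel as a tab-delimited matrix (header = SNP ids, one row per
individual) next to a panel table, or as VCF 4.2 (unphased GT derived from
counts; phased GT when haplotypes were retained).  Positions are 1-based
in both representations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popsim import GenotypeMatrix, SnpPanel

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_panel_tsv",
    "read_panel_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_vcf",
    "read_vcf",
]

PHENO_COLUMNS = ["individual_id", "y", "y_binary", "sex", "age", "stratum", "family_id"]


def write_panel_tsv(panel: SnpPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_panel_tsv(path, within_block_r: float = 0.0) -> SnpPanel:
    return SnpPanel(pd.read_csv(path, sep="\t"), within_block_r=within_block_r)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    pd.DataFrame(genotypes.counts, columns=genotypes.panel.snp_ids).to_csv(
        path, sep="\t", index=False
    )


def read_genotypes_tsv(path, panel: SnpPanel) -> GenotypeMatrix:
    t = pd.read_csv(path, sep="\t")
    if list(t.columns) != list(panel.snp_ids):
        raise ValueError("genotype columns do not match panel SNP ids")
    return GenotypeMatrix(panel, t.to_numpy(dtype=np.int8))


def write_phenotypes_tsv(pheno: pd.DataFrame, path) -> None:
    out = pheno.copy()
    for col in PHENO_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[PHENO_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(genotypes: GenotypeMatrix, path, sample_prefix: str = "ind") -> None:
    """VCF 4.2 export; phased GT when haplotypes are present, else unphased
    genotypes derived from counts (heterozygotes written 0/1)."""
    panel = genotypes.panel.table
    n = genotypes.n
    phased = genotypes.haplotypes is not None
    samples = [f"{sample_prefix}{j:06d}" for j in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgsdesign\n")
        for chrom in pd.unique(panel["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(len(panel)):
            row = panel.iloc[j]
            # ALT is the effect allele so that ALT dosage == stored count
            if phased:
                h = genotypes.haplotypes
                gts = [f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(n)]
            else:
                c = genotypes.counts[:, j]
                lookup = {0: "0/0", 1: "0/1", 2: "1/1"}
                gts = [lookup[int(v)] for v in c]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["snp_id"]),
                str(row["other_allele"]),
                str(row["effect_allele"]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(gts) + "\n")


def read_vcf(path, within_block_r: float = 0.0) -> GenotypeMatrix:
    """Read a (plain-text) VCF into a GenotypeMatrix; ALT allele counts.

    Block ids are assigned per chromosome since the VCF carries no LD-block
    annotation; MAF is the realized ALT frequency folded to (0, 0.5].
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    rows = []
    haps = []
    phased_all = True
    for var in vcf:
        gt = np.array(var.genotypes)  # (n, 3): a1, a2, phased
        phased_all &= bool(gt[:, 2].all())
        haps.append(gt[:, :2])
        rows.append(
            {
                "snp_id": var.ID,
                "chrom": int(var.CHROM),
                "pos": var.POS,
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
            }
        )
    hap_arr = np.stack(haps, axis=-1)  # (n, 2, m)
    counts = hap_arr.sum(axis=1).astype(np.int8)
    table = pd.DataFrame(rows)
    freq = counts.mean(axis=0) / 2.0
    table["maf"] = np.clip(np.minimum(freq, 1.0 - freq), 1e-6, 0.5)
    chrom_codes = pd.factorize(table["chrom"])[0]
    table["block_id"] = chrom_codes
    panel = SnpPanel(table, within_block_r=within_block_r)
    n, _, m = hap_arr.shape
    haplotypes = None
    if phased_all:
        haplotypes = np.empty((2 * n, m), dtype=np.int8)
        haplotypes[0::2] = hap_arr[:, 0, :]
        haplotypes[1::2] = hap_arr[:, 1, :]
    return GenotypeMatrix(panel, counts, haplotypes)
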