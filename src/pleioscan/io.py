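"""Readers and writers for the standard input formats.

Genotypes travel either as VCF 4.x (GT field, biallelic records) or as a
TSV dosage matrix (animals x SNPs, header row of snp ids) accompanied by a
SNP map TSV.  Pedigrees and phenotypes are plain CSV.  All coordinates are
1-based inclusive; BED inputs are converted on read (see
:mod:`pleioscan.annotate`).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pleioscan.data import SNP_MAP_COLUMNS, GenotypeMatrix, check_pedigree


def read_genotypes(path, fmt: str = "auto", map_path=None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV.

    Parameters
    ----------
    path : str or Path
        VCF file (``.vcf``/``.vcf.gz``) or TSV dosage matrix.
    fmt : {"auto", "vcf", "tsv"}
    map_path : optional
        SNP map TSV for the TSV format (defaults to ``<path>.map.tsv``).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path, map_path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    rows, map_rows = [], []
    n_multiallelic = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        map_rows.append(
            {
                "snp_id": snp_id,
                "chrom": str(variant.CHROM),
                "pos_bp": int(variant.POS),
                "allele_a": variant.REF,
                "allele_b": variant.ALT[0],
            }
        )
        dos = np.full(len(animals), np.nan)
        for j, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if alleles:
                dos[j] = float(sum(alleles))
        rows.append(dos)
    if n_multiallelic:
        warnings.warn(
            f"skipped {n_multiallelic} multi-allelic record(s) in {path.name}",
            stacklevel=2,
        )
    snps = pd.DataFrame(map_rows, columns=SNP_MAP_COLUMNS)
    if snps["snp_id"].duplicated().any():
        dup = snps.loc[snps["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id in VCF: {dup!r}")
    dosages = np.array(rows).T if rows else np.empty((len(animals), 0))
    return GenotypeMatrix(animals=animals, snps=snps, dosages=dosages)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write biallelic GT-only VCF 4.2 (hard calls; fractional dosages error)."""
    d = geno.dosages
    hard = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not hard.all():
        raise ValueError("cannot write fractional dosages to VCF GT field")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.animals)
            + "\n"
        )
        for i, row in geno.snps.iterrows():
            gts = "\t".join(
                "./." if np.isnan(v) else gt_map[v] for v in d[:, i]
            )
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t{row.snp_id}\t{row.allele_a}\t"
                f"{row.allele_b}\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_tsv(path: Path, map_path=None) -> GenotypeMatrix:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    map_path = Path(map_path) if map_path else path.with_suffix(".map.tsv")
    if map_path.exists():
        snps = pd.read_csv(map_path, sep="\t")[SNP_MAP_COLUMNS]
    else:
        snps = pd.DataFrame(
            {
                "snp_id": mat.columns,
                "chrom": "0",
                "pos_bp": np.arange(1, mat.shape[1] + 1),
                "allele_a": "A",
                "allele_b": "B",
            }
        )
    if list(mat.columns) != list(snps["snp_id"]):
        raise ValueError("dosage matrix columns do not match the SNP map")
    return GenotypeMatrix(
        animals=[str(a) for a in mat.index],
        snps=snps,
        dosages=mat.to_numpy(dtype=float),
    )


def write_tsv(geno: GenotypeMatrix, path, map_path=None) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        geno.dosages, index=pd.Index(geno.animals, name="animal"),
        columns=geno.snps["snp_id"],
    )
    frame.to_csv(path, sep="\t")
    map_path = Path(map_path) if map_path else path.with_suffix(".map.tsv")
    geno.snps.to_csv(map_path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    return check_pedigree(ped)


def write_pedigree(ped: pd.DataFrame, path) -> None:
    check_pedigree(ped).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, dtype={"animal": str})
    if "animal" not in pheno.columns:
        raise ValueError("phenotype table must have an 'animal' column")
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)
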