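"""Readers and writers for the plain-text dataset and result tables.

Formats: pedigree CSV (animal,sire,dam,sex[,generation,litter]; 0 =
unknown parent), phenotype CSV with declared column roles, dosage TSV
(animals × SNPs, 0/1/2, NA = missing) plus a SNP map TSV (snp, chrom,
pos with 1-based bp positions, chromosomes 1–18 and X).  Every result
table starts with '#' header lines declaring its coordinate convention
and units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .envgrad import PhenotypeTable
from .relmat import GenotypeMatrix, Pedigree

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "write_table",
    "write_summary",
]

FLOAT_FMT = "%.10g"


def write_pedigree(path, pedigree: Pedigree) -> None:
    pedigree.df.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path)
    return Pedigree(df)  # reorders offspring-before-parent files


def write_phenotypes(path, pheno: PhenotypeTable) -> None:
    df = pheno.df.copy()
    df.attrs = {}
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_phenotypes(path, factors=(), covariates=(), trait="trait") -> PhenotypeTable:
    df = pd.read_csv(path)
    return PhenotypeTable(
        df, factors=list(factors), covariates=list(covariates), trait=trait
    )


def write_genotypes(dosage_path, map_path, geno: GenotypeMatrix) -> None:
    dmat = pd.DataFrame(
        geno.dosages,
        index=pd.Index(geno.ids, name="animal"),
        columns=geno.snps["snp"],
    )
    if geno.sexes is not None:
        dmat.insert(0, "sex", geno.sexes)
    dmat.to_csv(dosage_path, sep="\t", na_rep="NA", float_format="%g")
    geno.snps.to_csv(map_path, sep="\t", index=False)


def read_genotypes(dosage_path, map_path) -> GenotypeMatrix:
    snps = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    d = pd.read_csv(dosage_path, sep="\t", index_col="animal", na_values="NA")
    sexes = None
    if "sex" in d.columns:
        sexes = d.pop("sex").to_numpy()
    missing = set(snps["snp"]) - set(d.columns)
    if missing:
        raise ValueError(f"dosage file lacks SNPs from the map: "
                         f"{sorted(missing)[:10]}")
    d = d[snps["snp"]]
    bad = d.apply(lambda col: ~(col.isin([0, 1, 2]) | col.isna()))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"malformed genotype file: non-dosage value at line {r + 2}, "
            f"SNP {d.columns[c]}"
        )
    return GenotypeMatrix(
        d.index.to_numpy(), snps, d.to_numpy(dtype=float), sexes=sexes
    )


def write_table(path, df: pd.DataFrame, header_lines=()) -> None:
    """TSV with '#'-prefixed convention header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def write_summary(path, summary: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"cannot serialise {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
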