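"""Readers and writers for the plain-text interchange formats.

Genotypes travel as a PLINK-style ``.raw``-dialect table (header ``FID IID
PAT MAT SEX PHENOTYPE`` followed by one ``<snp>_<allele>`` dosage column per
SNP, ``NA`` for missing) together with a 6-column ``.bim``-like SNP map
(chromosome, id, genetic distance, 1-based position, minor allele, major
allele).  Lipidome, covariate and truth tables are TSV with a header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LipidomeMatrix
from .errors import ConfigurationError

NA_TOKEN = "NA"


def write_bim(snps: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame(
        {
            "chrom": snps["chromosome"],
            "id": snps["id"],
            "cm": 0,
            "pos": snps["position"],
            "a1": snps["allele_minor"],
            "a2": snps["allele_major"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bim(path: str) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    return pd.DataFrame(
        {
            "id": bim["id"],
            "chromosome": bim["chrom"],
            "position": bim["pos"].astype(int),
            "allele_minor": bim["a1"],
            "allele_major": bim["a2"],
        }
    )


def write_raw(genotype: GenotypeMatrix, path: str, sex=None) -> None:
    """Write dosages in the .raw dialect: one row per participant."""
    snp_cols = [
        f"{sid}_{a1}" for sid, a1 in zip(genotype.snps["id"], genotype.snps["allele_minor"])
    ]
    n = genotype.n_participants
    sex_col = np.zeros(n, int) if sex is None else np.asarray(sex, int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + snp_cols) + "\n")
        for i, pid in enumerate(genotype.participant_ids):
            row = genotype.dosages[i]
            toks = [str(pid), str(pid), "0", "0", str(int(sex_col[i])), "-9"]
            toks += [NA_TOKEN if np.isnan(v) else str(int(v)) for v in row]
            fh.write(" ".join(toks) + "\n")


def read_raw(raw_path: str, bim_path: str) -> GenotypeMatrix:
    """Read a .raw-dialect dosage table plus its .bim-like SNP map."""
    tab = pd.read_csv(raw_path, sep=r"\s+", na_values=[NA_TOKEN], dtype={"IID": str})
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta_cols if c not in tab.columns]
    if missing:
        raise ConfigurationError(f".raw file lacks header columns: {missing}")
    snps = read_bim(bim_path)
    expected = [f"{sid}_{a1}" for sid, a1 in zip(snps["id"], snps["allele_minor"])]
    absent = [c for c in expected if c not in tab.columns]
    if absent:
        raise ConfigurationError(f".raw columns do not match .bim map: {absent[:3]}...")
    dosages = tab[expected].to_numpy(float)
    return GenotypeMatrix(dosages, tab["IID"].tolist(), snps)


def write_lipidome(lipidome: LipidomeMatrix, path: str, classes_path: str | None = None) -> None:
    lipidome.concentrations.to_csv(path, sep="\t", index_label="participant_id", na_rep=NA_TOKEN)
    if classes_path is not None:
        lipidome.classes.rename("class").to_csv(classes_path, sep="\t", index_label="lipid")


def read_lipidome(path: str, classes_path: str | None = None) -> LipidomeMatrix:
    conc = pd.read_csv(path, sep="\t", index_col="participant_id", na_values=[NA_TOKEN])
    conc.index = conc.index.astype(str)
    classes = None
    if classes_path is not None and os.path.exists(classes_path):
        cl = pd.read_csv(classes_path, sep="\t", index_col="lipid")
        classes = cl["class"]
    return LipidomeMatrix(conc, classes)


def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index_label is not None, index_label=index_label)


def read_table(path: str, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], index_col=index_col)
    if index_col is not None:
        df.index = df.index.astype(str)
    return df


def read_gmt(path: str) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ...

    Returns a mapping ``set name -> frozenset of gene symbols``.
    """
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 3:
                continue
            name = toks[0]
            if name in sets:
                raise ConfigurationError(f"duplicate gene-set name: {name}")
            genes = frozenset(g for g in toks[2:] if g)
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path: str, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


def read_snp_gene_map(path: str) -> dict:
    """Read a two-column SNP -> gene TSV (one row per SNP-gene link)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp", "gene"}.issubset(tab.columns):
        raise ConfigurationError("SNP-gene map needs columns 'snp' and 'gene'")
    mapping: dict = {}
    for snp, gene in zip(tab["snp"], tab["gene"]):
        if not gene or pd.isna(gene):
            continue
        mapping.setdefault(snp, set()).add(gene)
    return mapping


def write_snp_gene_map(mapping: dict, path: str) -> None:
    rows = [(s, g) for s, genes in mapping.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["snp", "gene"]).to_csv(path, sep="\t", index=False)
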