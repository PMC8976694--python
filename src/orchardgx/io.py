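"""Readers and writers for the pipeline's file formats.

Genotypes travel as a dosage TSV plus marker-map CSV or as a minimal
unphased VCF (GT field only); phenotypes as a long CSV with one row per tree
observation; pedigree and published-locus catalogs as plain CSV.  All
formats are text so that runs are diffable and portable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from orchardgx.data import GenotypeMatrix, PedigreeTable, validate_phenotypes
from orchardgx.gwas import LociCatalog


# -- dosage TSV ---------------------------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, dosage_path, map_path) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=pd.Index(genotypes.samples, name="genotype"),
        columns=genotypes.marker_map["marker"],
    )
    df.to_csv(dosage_path, sep="\t")
    genotypes.marker_map.to_csv(map_path, index=False)


def read_dosage_tsv(dosage_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    mmap = pd.read_csv(map_path)
    if list(df.columns) != list(mmap["marker"]):
        raise ValueError("dosage columns and marker map disagree")
    dos = df.to_numpy()
    if not np.isin(dos, [0, 1, 2]).all():
        raise ValueError("dosages must be 0, 1 or 2")
    return GenotypeMatrix(dos.astype(np.int8), list(df.index.astype(str)), mmap)


# -- minimal VCF --------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write an unphased GT-only VCF (REF=A, ALT=B placeholders)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in genotypes.marker_map["chrom"].unique():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for j, row in genotypes.marker_map.iterrows():
            calls = "\t".join(gt_map[int(d)] for d in genotypes.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['marker']}\tA\tB\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into dosages; multi-allelic sites are skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, map_rows, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gts = var.genotype.array()[:, :2]
        dos = np.where((gts < 0).any(axis=1), -1, gts.clip(0, 1).sum(axis=1))
        if (dos < 0).any():
            skipped += 1
            continue
        rows.append(dos.astype(np.int8))
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        chrom = var.CHROM[3:] if str(var.CHROM).startswith("chr") else var.CHROM
        try:
            chrom = int(chrom)
        except ValueError:
            pass
        map_rows.append((name, chrom, var.POS))
    if skipped:
        warnings.warn(f"{skipped} multi-allelic or incomplete sites skipped", stacklevel=2)
    mmap = pd.DataFrame(map_rows, columns=["marker", "chrom", "pos"])
    return GenotypeMatrix(np.array(rows, dtype=np.int8).T, samples, mmap)


# -- phenotypes, pedigree, catalog -------------------------------------------

def write_phenotypes(records: pd.DataFrame, path) -> None:
    validate_phenotypes(records).to_csv(path, index=False)


def read_phenotypes(path, known_genotypes=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = validate_phenotypes(df)
    if known_genotypes is not None:
        known = set(known_genotypes)
        bad = df.loc[~df["genotype"].isin(known)]
        if not bad.empty:
            lines = ", ".join(str(i + 2) for i in bad.index[:10])  # +2: header + 1-based
            raise ValueError(
                f"{len(bad)} phenotype rows reference unknown genotypes (file lines {lines} ...)"
            )
    return df


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.table.to_csv(path, index=False)


def read_pedigree(path) -> PedigreeTable:
    return PedigreeTable(pd.read_csv(path, keep_default_na=False))


def read_catalog(path) -> LociCatalog:
    df = pd.read_csv(path)
    missing = {"trait_group", "chromosome", "segment"} - set(df.columns)
    if missing:
        raise ValueError(f"catalog lacks columns: {sorted(missing)}")
    return LociCatalog(df)


# -- fit summaries / manifests -------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
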