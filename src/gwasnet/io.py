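"""Readers and writers for the pipeline's on-disk formats.

TSV is the primary interchange format for every table. Genotypes can
additionally be written to / read from VCF (haploid-style GT for inbred
lines), and the annotation to GFF3 (1-based inclusive coordinates) and
BED (0-based half-open; start = gff_start - 1, end = gff_end).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotypes_tsv(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, sep="\t", index_label="accession")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


def write_genotypes_vcf(geno: pd.DataFrame, snp_map: pd.DataFrame,
                        path) -> None:
    """Write inbred {0,1} dosages as a minimal VCF with haploid GT."""
    pos = snp_map.set_index("snp")
    accessions = list(geno.index)
    chroms = list(dict.fromkeys(snp_map["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        for snp in snp_map["snp"]:
            row = geno[snp]
            gts = "\t".join(str(int(v)) for v in row)
            fh.write(f"{pos.loc[snp, 'chrom']}\t{pos.loc[snp, 'pos']}\t"
                     f"{snp}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes and SNP map from a VCF (haploid or homozygous
    diploid GT)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        # var.genotypes: [allele0, (allele1,) phased]; haploid GT has a
        # single allele entry, homozygous diploid two equal ones
        dosages = []
        for g in var.genotypes:
            alleles = g[:-1]
            if len(set(alleles)) > 1:
                raise ValueError(f"heterozygous call at {var.ID}: "
                                 "inbred panel expected")
            dosages.append(alleles[0])
        rows.append(np.asarray(dosages, dtype=np.int8))
        meta.append((var.ID, var.CHROM, var.POS))
    snp_map = pd.DataFrame(meta, columns=["snp", "chrom", "pos"])
    geno = pd.DataFrame(np.array(rows).T,
                        index=pd.Index(accessions, name="accession"),
                        columns=snp_map["snp"].tolist())
    return geno, snp_map


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def write_annotation_gff3(annotation: pd.DataFrame, path) -> None:
    """GFF3: 1-based inclusive [start, end], same convention as the
    in-memory table."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.iterrows():
            fh.write(f"{g['chrom']}\tgwasnet\tgene\t{g['start']}\t"
                     f"{g['end']}\t.\t+\t.\tID={g['gene']};"
                     f"order={g['order']}\n")


def read_annotation_gff3(path) -> pd.DataFrame:
    rows = []
    fallback_order = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if kv)
            order = int(attrs.get("order", fallback_order))
            rows.append((attrs["ID"], f[0], int(f[3]), int(f[4]), order))
            fallback_order += 1
    return pd.DataFrame(rows,
                        columns=["gene", "chrom", "start", "end", "order"])


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """BED: 0-based half-open; bed_start = start - 1, bed_end = end."""
    with open(path, "w") as fh:
        for _, g in annotation.iterrows():
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['end']}\t"
                     f"{g['gene']}\n")


# ---------------------------------------------------------------------------
# simple tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_structure(structure: pd.Series, path) -> None:
    structure.rename("subpop").to_csv(path, sep="\t",
                                      index_label="accession")


def read_structure(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="accession")
    return df["subpop"]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
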