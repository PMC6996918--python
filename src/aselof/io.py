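"""Readers and writers for the pipeline's on-disk formats.

Allele counts travel in the ASEReadCounter-style TSV dialect
(``contig position variantID refAllele altAllele refCount altCount
totalCount``), 1-based inclusive coordinates; optional ``sample`` and
``assay`` columns extend the dialect for multi-sample long tables.
BED files (mapability intervals, BED12 exon models) are 0-based
half-open. Genotypes are exchanged as VCF 4.2.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .config import InputFormatError

COUNT_COLUMNS = [
    "contig",
    "position",
    "variantID",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
]

_VALID_BASES = frozenset("ACGT")


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an allele-count table against the dialect's invariants.

    Raises :class:`InputFormatError` naming the first offending row.
    """
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"allele-count table missing columns {missing}")
    for col in ("refCount", "altCount", "totalCount"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise InputFormatError(f"negative {col} at row {bad[0]}")
    bad = df.index[df["refCount"] + df["altCount"] > df["totalCount"]]
    if len(bad):
        raise InputFormatError(
            f"refCount + altCount exceeds totalCount at row {bad[0]}"
        )
    for col in ("refAllele", "altAllele"):
        ok = df[col].astype(str).str.fullmatch("[ACGT]")
        bad = df.index[~ok.fillna(False)]
        if len(bad):
            raise InputFormatError(
                f"{col} must be a single A/C/G/T base at row {bad[0]}"
            )
    return df


def read_counts(path) -> pd.DataFrame:
    """Read an allele-count TSV (optionally with sample/assay columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return validate_counts(df)


def write_counts(df: pd.DataFrame, path) -> None:
    cols = COUNT_COLUMNS + [c for c in ("sample", "assay") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def ref_ratio(df: pd.DataFrame) -> pd.Series:
    """refCount / (refCount + altCount); NaN where no informative reads."""
    informative = df["refCount"] + df["altCount"]
    with np.errstate(invalid="ignore"):
        return df["refCount"] / informative.replace(0, np.nan)


# ---------------------------------------------------------------------------
# BED / intervals

def read_mapability_bed(path) -> pd.DataFrame:
    """Mapability track as BED: contig, start, end[, score].

    Missing score column means every listed interval has mapability 1.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise InputFormatError("mapability BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(score=1.0)
    df.columns = ["contig", "start", "end", "score"][: df.shape[1]]
    if df.shape[1] == 3:
        df["score"] = 1.0
    return df


def read_bed12(path) -> pd.DataFrame:
    """BED12 exon models -> one row per transcript with exon block lists."""
    names = [
        "contig", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount",
        "blockSizes", "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={0: str})
    return df


def write_bed12(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def bed12_exons(df: pd.DataFrame) -> pd.DataFrame:
    """Flatten BED12 rows to per-exon intervals (0-based half-open)."""
    rows = []
    for rec in df.itertuples(index=False):
        sizes = [int(s) for s in str(rec.blockSizes).rstrip(",").split(",")]
        starts = [int(s) for s in str(rec.blockStarts).rstrip(",").split(",")]
        if len(sizes) != rec.blockCount or len(starts) != rec.blockCount:
            raise InputFormatError(f"BED12 block mismatch for {rec.name}")
        for i, (sz, st) in enumerate(zip(sizes, starts)):
            rows.append(
                {
                    "gene": rec.name,
                    "contig": rec.contig,
                    "strand": rec.strand,
                    "exon_index": i,
                    "start": rec.start + st,
                    "end": rec.start + st + sz,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(
    genotypes: pd.DataFrame,
    path,
    samples: list[str],
    phased: bool = False,
) -> None:
    """Write a minimal VCF 4.2 with GT fields.

    ``genotypes`` carries contig, position, variantID, refAllele, altAllele
    plus one column per sample holding genotype strings ("0/1", "1|0", ...).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(genotypes["contig"].astype(str)):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in genotypes.itertuples(index=False):
            gts = "\t".join(getattr(rec, s) for s in samples)
            fh.write(
                f"{rec.contig}\t{rec.position}\t{rec.variantID}\t"
                f"{rec.refAllele}\t{rec.altAllele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf_genotypes(path) -> tuple[pd.DataFrame, list[str]]:
    """Read GT fields from a VCF into a long DataFrame.

    Returns (df, samples) where df has one row per site x sample with
    columns contig, position, variantID, refAllele, altAllele, sample,
    gt (raw string), n_ref, n_alt, phased. Multi-allelic records must be
    decomposed upstream and raise :class:`InputFormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise InputFormatError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; decompose first"
            )
        gt_strings = [
            b.split(":")[0] for b in str(var).rstrip("\n").split("\t")[9:]
        ]
        for sample, gt in zip(samples, gt_strings):
            phased = "|" in gt
            alleles = gt.replace("|", "/").split("/")
            if "." in alleles:
                n_ref = n_alt = -1
            else:
                vals = [int(a) for a in alleles]
                if any(a > 1 for a in vals):
                    raise InputFormatError(
                        f"unexpected allele index in GT {gt!r} at "
                        f"{var.CHROM}:{var.POS}"
                    )
                n_alt = sum(vals)
                n_ref = len(vals) - n_alt
            rows.append(
                {
                    "contig": var.CHROM,
                    "position": var.POS,
                    "variantID": var.ID or ".",
                    "refAllele": var.REF,
                    "altAllele": var.ALT[0],
                    "sample": sample,
                    "gt": gt,
                    "n_ref": n_ref,
                    "n_alt": n_alt,
                    "phased": phased,
                }
            )
    return pd.DataFrame(rows), samples


# ---------------------------------------------------------------------------
# Simple TSV tables

def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    need = {"sample", "contig", "start", "end", "major_cn", "minor_cn"}
    if not need.issubset(df.columns):
        raise InputFormatError(f"segments table needs columns {sorted(need)}")
    return df


def read_isoform_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_antisense_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_methylation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
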