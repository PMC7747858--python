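"""Readers and writers for the pipeline's plain-text table dialects.

All tables are tab-separated with a header line.  Variant tables use
1-based positions; coverage tables use 0-based half-open intervals
(BED convention).  Missing population frequencies are written as ``.``.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "qphred",
    "vclass",
    "gene",
    "consequence",
    "pop_freq",
    "context5",
    "context3",
]

COVERAGE_COLUMNS = ["chrom", "start", "end", "depth"]
CATALOG_COLUMNS = ["chrom", "pos", "ref", "alt", "frequency"]

_VARIANT_DTYPES = {
    "sample": str,
    "chrom": str,
    "pos": np.int64,
    "ref": str,
    "alt": str,
    "depth": np.int64,
    "alt_reads": np.int64,
    "qphred": float,
    "vclass": str,
    "gene": str,
    "consequence": str,
    "context5": str,
    "context3": str,
}


class CatalogFormatError(ValueError):
    """Raised when a germline catalog row cannot be parsed."""


def read_variant_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a variant table TSV, splitting multi-allelic rows.

    Rows whose ``alt`` field contains comma-separated alleles are split
    into one biallelic record per allele; read counts are not divided
    (the caller's upstream caller must provide per-allele counts for
    real data — the synthetic generator always emits biallelic rows).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks columns: {missing}")
    if df["alt"].str.contains(",").any():
        df = df.assign(alt=df["alt"].str.split(",")).explode("alt", ignore_index=True)
    for col, dt in _VARIANT_DTYPES.items():
        df[col] = df[col].fillna("").astype(dt) if dt is str else df[col].astype(dt)
    df["pop_freq"] = pd.to_numeric(df["pop_freq"], errors="coerce")
    return df[VARIANT_COLUMNS]


def write_variant_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df[VARIANT_COLUMNS].copy()
    out["pop_freq"] = out["pop_freq"].map(
        lambda f: "." if pd.isna(f) else format(f, ".6g")
    )
    for col in ("context5", "context3"):
        out[col] = out[col].replace("", ".")
    out.to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table {path} lacks columns: {missing}")
    df["chrom"] = df["chrom"].astype(str)
    for col in ("start", "end"):
        df[col] = df[col].astype(np.int64)
    df["depth"] = df["depth"].astype(float)
    return df[COVERAGE_COLUMNS]


def write_coverage_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df[COVERAGE_COLUMNS].copy()
    out["depth"] = out["depth"].map(lambda d: format(d, ".4f"))
    out.to_csv(path, sep="\t", index=False)


def read_germline_catalog(path: str | os.PathLike) -> dict[tuple[str, int, str, str], float]:
    """Read a germline catalog TSV into an allele-keyed frequency map.

    Keys are ``(chrom, pos, ref, alt)``; matching downstream is exact by
    allele, never position-only.  Malformed rows raise
    :class:`CatalogFormatError` naming the offending line number.
    """
    catalog: dict[tuple[str, int, str, str], float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CATALOG_COLUMNS:
            raise CatalogFormatError(
                f"{path}: expected header {CATALOG_COLUMNS}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise CatalogFormatError(
                    f"{path}:{lineno}: expected 5 fields, found {len(fields)}"
                )
            chrom, pos_s, ref, alt, freq_s = fields
            try:
                pos = int(pos_s)
                freq = float(freq_s)
            except ValueError as exc:
                raise CatalogFormatError(f"{path}:{lineno}: {exc}") from exc
            catalog[(chrom, pos, ref, alt)] = freq
    return catalog


def write_germline_catalog(
    catalog: Mapping[tuple[str, int, str, str], float], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for (chrom, pos, ref, alt), freq in catalog.items():
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{freq:.6g}\n")


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene symbol per line (header optional: a first line 'gene' is skipped)."""
    genes: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh):
            sym = line.strip()
            if not sym or (i == 0 and sym.lower() == "gene"):
                continue
            genes.add(sym)
    return genes


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\n")
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_domain_table(path: str | os.PathLike) -> pd.DataFrame:
    """Protein-domain annotation: gene, domain, start_aa, end_aa (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "domain", "start_aa", "end_aa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"domain table {path} lacks columns: {missing}")
    df["start_aa"] = df["start_aa"].astype(np.int64)
    df["end_aa"] = df["end_aa"].astype(np.int64)
    return df[required]


def read_vcf_variants(path: str | os.PathLike, sample: str | None = None) -> pd.DataFrame:
    """Optional reader for standard VCF (uncompressed or bgzipped).

    Maps ``INFO/DP`` or ``FORMAT/DP`` to depth, ``FORMAT/AD`` to
    alt_reads and ``QUAL`` to qphred.  Annotation columns (gene,
    consequence, pop_freq, contexts) are left empty; fill them from an
    external annotation step.  Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # deferred: only needed for real-data input

    records = []
    vcf = VCF(str(path))
    sample_name = sample or (vcf.samples[0] if vcf.samples else "sample")
    sidx = vcf.samples.index(sample_name) if vcf.samples else None
    for rec in vcf:
        depths = rec.format("DP")
        ads = rec.format("AD")
        depth = int(depths[sidx][0]) if depths is not None else int(rec.INFO.get("DP", 0))
        for ai, alt in enumerate(rec.ALT):
            alt_reads = int(ads[sidx][ai + 1]) if ads is not None else 0
            vclass = "SNV" if len(rec.REF) == 1 and len(alt) == 1 else "indel"
            records.append(
                {
                    "sample": sample_name,
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "depth": depth,
                    "alt_reads": alt_reads,
                    "qphred": float(rec.QUAL or 0.0),
                    "vclass": vclass,
                    "gene": "",
                    "consequence": "other",
                    "pop_freq": np.nan,
                    "context5": "",
                    "context3": "",
                }
            )
    return pd.DataFrame(records, columns=VARIANT_COLUMNS)
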