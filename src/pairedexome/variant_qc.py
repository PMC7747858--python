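"""Reliability filters and germline exclusion for unmatched tumor calls.

Without a matched normal sample, somatic status is approximated in two
steps: (1) read-evidence quality filters (depth, variant-supporting
reads, variant allele fraction, phred-scaled call quality), and
(2) exclusion of any variant present in a population germline catalog
(1000 Genomes / EVS / ExAC-style) at frequency >= 1e-5.  What survives
is "putatively somatic".

All fraction thresholds are compared with exact integer arithmetic
(``alt_reads * q >= p * depth`` for a threshold ``p/q``) so that calls
sitting exactly on a boundary resolve with the intended inclusive
sense rather than by float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QcThresholds:
    """Quality-control thresholds; defaults are the study's published values.

    min_vaf is the minimum variant allele fraction (inclusive);
    max_pop_freq is an *exclusive* upper bound for retention — a variant
    catalogued at exactly this frequency is excluded as germline.
    """

    min_depth: int = 10
    min_alt_reads: int = 3
    min_vaf: Fraction = field(default_factory=lambda: Fraction(15, 100))
    min_qphred_snv: float = 20.0
    min_qphred_indel: float = 30.0
    max_pop_freq: float = 1e-5

    def __post_init__(self) -> None:
        object.__setattr__(self, "min_vaf", Fraction(self.min_vaf))
        if not (0 < self.min_vaf <= 1):
            raise ValueError("min_vaf must be in (0, 1]")
        if min(self.min_depth, self.min_alt_reads, self.min_qphred_snv,
               self.min_qphred_indel, self.max_pop_freq) < 0:
            raise ValueError("thresholds must be non-negative")


DEFAULT_THRESHOLDS = QcThresholds()


def passes_quality(
    depth: int,
    alt_reads: int,
    qphred: float,
    vclass: str,
    thresholds: QcThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Return True iff the call clears every read-evidence filter.

    A call must be covered by >= min_depth reads, be supported by
    >= min_alt_reads variant reads forming >= min_vaf of the coverage,
    and carry quality >= min_qphred_snv (SNV) or min_qphred_indel
    (indel).  depth == 0 returns False without raising.
    """
    if depth <= 0:
        return False
    t = thresholds
    min_q = t.min_qphred_indel if vclass == "indel" else t.min_qphred_snv
    vaf = t.min_vaf
    return (
        depth >= t.min_depth
        and alt_reads >= t.min_alt_reads
        and alt_reads * vaf.denominator >= vaf.numerator * depth
        and qphred >= min_q
    )


def exclude_germline(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    catalog: Mapping[tuple[str, int, str, str], float],
    max_pop_freq: float = 1e-5,
) -> bool:
    """True = retain as putatively somatic.

    A variant is dropped iff the exact allele (chrom, pos, ref, alt)
    appears in the germline catalog with frequency >= max_pop_freq.
    Absent alleles, and catalogued alleles below the bound, are kept.
    """
    freq = catalog.get((chrom, pos, ref, alt))
    return freq is None or freq < max_pop_freq


def _quality_mask(df: pd.DataFrame, t: QcThresholds) -> np.ndarray:
    depth = df["depth"].to_numpy(np.int64)
    alt = df["alt_reads"].to_numpy(np.int64)
    qp = df["qphred"].to_numpy(float)
    is_indel = df["vclass"].to_numpy() == "indel"
    min_q = np.where(is_indel, t.min_qphred_indel, t.min_qphred_snv)
    vaf = t.min_vaf
    return (
        (depth >= t.min_depth)
        & (alt >= t.min_alt_reads)
        & (alt * vaf.denominator >= vaf.numerator * depth)
        & (qp >= min_q)
        & (depth > 0)
    )


def _germline_mask(
    df: pd.DataFrame,
    catalog: Mapping[tuple[str, int, str, str], float],
    max_pop_freq: float,
) -> np.ndarray:
    """Boolean retain mask by exact-allele catalog lookup."""
    keys = zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    return np.fromiter(
        (catalog.get(k) is None or catalog[k] < max_pop_freq for k in keys),
        dtype=bool,
        count=len(df),
    )


def qc_pipeline(
    table: pd.DataFrame,
    thresholds: QcThresholds = DEFAULT_THRESHOLDS,
    catalog: Mapping[tuple[str, int, str, str], float] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply quality filters then germline exclusion to a variant table.

    Returns the retained rows and an attrition report counting removals
    per rule, in application order (quality first, then germline: a row
    failing both is charged to quality).
    """
    if table.empty:
        return table.copy(), {"quality": 0, "germline": 0}
    qmask = _quality_mask(table, thresholds)
    after_quality = table[qmask]
    if catalog is not None and len(after_quality):
        gmask = _germline_mask(after_quality, catalog, thresholds.max_pop_freq)
    else:
        gmask = np.ones(len(after_quality), dtype=bool)
    retained = after_quality[gmask].reset_index(drop=True)
    attrition = {
        "quality": int((~qmask).sum()),
        "germline": int((~gmask).sum()),
    }
    return retained, attrition
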