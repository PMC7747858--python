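"""Three-way classification of variants across a tumor/metastasis pair.

Every putatively somatic variant in a patient is assigned exactly one
status:

* ``shared`` — called in the primary tumor and supported in the
  metastasis by >= 2 variant reads forming >= 5% of metastasis coverage
  at the site (the truncal clone carried it to the metastasis);
* ``primary_specific`` — called in the primary but failing the sharing
  rule in the metastasis;
* ``met_specific`` — called in the metastasis with >= 3 variant reads
  forming >= 15% of coverage, while the primary shows <= 1 variant read
  forming < 5% of its coverage (acquired after dissemination);
* ``unresolved`` — called only in the metastasis but failing the
  met-specific evidence rule; kept for audit, excluded from counts.

Sharing is decided from the primary's viewpoint whenever the variant
passes QC in the primary; met-specificity is only evaluated for
variants that do not.  Fraction thresholds use exact integer
comparisons, matching the inclusive (>=) and strict (<) senses of the
rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

STATUSES = ("shared", "primary_specific", "met_specific", "unresolved")

# sharing rule: met_alt >= 2 and met_alt/met_depth >= 5%
MIN_SHARED_ALT = 2
SHARED_VAF = (1, 20)
# met-specific rule: met_alt >= 3, met VAF >= 15%, primary_alt <= 1, primary VAF < 5%
MIN_MET_ALT = 3
MET_VAF = (3, 20)
MAX_PRIMARY_ALT = 1
PRIMARY_VAF_CEIL = (1, 20)

VariantKey = tuple[str, int, str, str]


@dataclass
class PairedVariant:
    """One genomic variant aligned across a patient's two compartments."""

    patient_id: str
    key: VariantKey
    primary_depth: int
    primary_alt_reads: int
    met_depth: int
    met_alt_reads: int
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.primary_alt_reads > self.primary_depth or self.met_alt_reads > self.met_depth:
            raise ValueError(f"{self.key}: alt reads exceed depth")


def classify_from_primary(pv: PairedVariant) -> str:
    """Classify a primary-called variant as shared or primary-specific.

    Shared iff the metastasis shows >= 2 variant reads forming >= 5% of
    its coverage at the site; zero metastasis coverage makes the
    proportion condition unsatisfiable, hence primary-specific.
    """
    if pv.met_depth == 0:
        logger.debug("%s: zero metastasis coverage, primary_specific", pv.key)
        return "primary_specific"
    num, den = SHARED_VAF
    if pv.met_alt_reads >= MIN_SHARED_ALT and pv.met_alt_reads * den >= num * pv.met_depth:
        return "shared"
    return "primary_specific"


def classify_met_specific(pv: PairedVariant) -> bool:
    """True iff a metastasis-called variant qualifies as metastasis-specific.

    Requires strong metastasis evidence (>= 3 variant reads, >= 15% of
    coverage) and near-absence in the primary (<= 1 variant read,
    < 5% of coverage).  An uncovered primary site with zero variant
    reads counts as 0% primary fraction.
    """
    m_num, m_den = MET_VAF
    if not (pv.met_alt_reads >= MIN_MET_ALT and pv.met_alt_reads * m_den >= m_num * pv.met_depth):
        return False
    if pv.primary_alt_reads > MAX_PRIMARY_ALT:
        return False
    if pv.primary_depth == 0:
        if pv.primary_alt_reads == 0:
            logger.debug("%s: zero primary coverage, fraction treated as 0", pv.key)
            return True
        return False
    p_num, p_den = PRIMARY_VAF_CEIL
    return pv.primary_alt_reads * p_den < p_num * pv.primary_depth


def _evidence_map(table: pd.DataFrame | None) -> dict[VariantKey, tuple[int, int]]:
    if table is None or table.empty:
        return {}
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): (int(r.depth), int(r.alt_reads))
        for r in table.itertuples(index=False)
    }


def _check_duplicates(table: pd.DataFrame, label: str) -> None:
    if table.empty:
        return
    dup = table.duplicated(subset=["chrom", "pos", "ref", "alt"], keep=False)
    if dup.any():
        keys = (
            table.loc[dup, ["chrom", "pos", "ref", "alt"]]
            .apply(lambda r: f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}", axis=1)
            .unique()
            .tolist()
        )
        raise ValueError(f"duplicate variant keys in {label} table: {keys}")


def classify_patient(
    primary_table: pd.DataFrame,
    met_table: pd.DataFrame,
    primary_evidence: pd.DataFrame | None = None,
    met_evidence: pd.DataFrame | None = None,
    patient_id: str = "patient",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every QC-passing variant of one patient.

    ``primary_table`` / ``met_table`` are the QC-filtered variant tables
    of each compartment.  ``primary_evidence`` / ``met_evidence`` are
    optional pre-filter tables supplying read depth at sites where the
    compartment has no retained call (e.g. pileup depth at a site called
    only in the metastasis); they default to the filtered tables, with
    absent sites treated as depth 0.

    Returns a paired table (one row per variant key with both
    compartments' evidence and a ``status`` column) and per-status
    counts.
    """
    _check_duplicates(primary_table, "primary")
    _check_duplicates(met_table, "metastasis")

    p_calls = _evidence_map(primary_table)
    m_calls = _evidence_map(met_table)
    p_depth = _evidence_map(primary_evidence) if primary_evidence is not None else p_calls
    m_depth = _evidence_map(met_evidence) if met_evidence is not None else m_calls

    ann_cols = ["vclass", "gene", "consequence", "context5", "context3"]
    annotations: dict[VariantKey, dict] = {}
    for table in (met_table, primary_table):  # primary wins on overlap
        if not table.empty:
            for r in table.itertuples(index=False):
                key = (r.chrom, int(r.pos), r.ref, r.alt)
                annotations[key] = {c: getattr(r, c) for c in ann_cols}

    rows = []
    counts = dict.fromkeys(STATUSES, 0)
    keys = list(p_calls) + [k for k in m_calls if k not in p_calls]
    for key in keys:
        pd_, pa = p_calls.get(key, p_depth.get(key, (0, 0)))
        md, ma = m_calls.get(key, m_depth.get(key, (0, 0)))
        pv = PairedVariant(patient_id, key, pd_, pa, md, ma)
        if key in p_calls:
            status = classify_from_primary(pv)
        else:
            status = "met_specific" if classify_met_specific(pv) else "unresolved"
        counts[status] += 1
        chrom, pos, ref, alt = key
        rows.append(
            {
                "patient": patient_id,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "primary_depth": pd_,
                "primary_alt_reads": pa,
                "met_depth": md,
                "met_alt_reads": ma,
                "status": status,
                **annotations.get(key, dict.fromkeys(ann_cols, "")),
            }
        )
    columns = [
        "patient", "chrom", "pos", "ref", "alt",
        "primary_depth", "primary_alt_reads", "met_depth", "met_alt_reads",
        "status", *ann_cols,
    ]
    pairs = pd.DataFrame(rows, columns=columns)
    return pairs, counts
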