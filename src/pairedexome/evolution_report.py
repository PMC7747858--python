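"""Per-patient trunk/branch trees and cross-patient recurrence reports.

A two-sample tumor/metastasis pair supports only one tree topology:
a trunk (mutations shared by both compartments, attributed to the
common precursor clone) splitting into a primary branch and a
metastasis branch (compartment-private mutations).  Branch lengths are
mutation counts.  Across patients, genes hit by metastasis-private
non-synonymous mutations in several patients are tallied, flagged
against a cancer-gene list (Cancer Gene Census-style), and joined to
protein-domain annotations to make lollipop-plot-ready tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

NONSYNONYMOUS = {"missense", "nonsense", "splice", "frameshift", "inframe_indel"}


@dataclass
class PatientTree:
    """Trunk/branch mutation counts for one patient pair."""

    patient_id: str
    n_shared: int
    n_primary_private: int
    n_met_private: int
    flagged_genes: list[tuple[str, str, bool]] = field(default_factory=list)

    def to_newick(self) -> str:
        return (
            f"((primary:{self.n_primary_private},met:{self.n_met_private})"
            f"trunk:{self.n_shared});"
        )


_NEWICK_RE = re.compile(
    r"^\(\(primary:(\d+),met:(\d+)\)trunk:(\d+)\);$"
)


def tree_from_newick(newick: str, patient_id: str = "patient") -> PatientTree:
    """Parse a trunk/branch Newick string back into counts (round-trip aid)."""
    m = _NEWICK_RE.match(newick.replace(" ", ""))
    if not m:
        raise ValueError(f"not a trunk/branch tree: {newick!r}")
    n_p, n_m, n_s = (int(g) for g in m.groups())
    return PatientTree(patient_id, n_s, n_p, n_m)


def build_tree(
    patient_id: str,
    counts: dict[str, int],
    flagged_genes: list[tuple[str, str, bool]] | None = None,
) -> PatientTree:
    """Build a patient tree from a paired-classification count summary.

    ``counts`` carries the per-status totals; unresolved variants do
    not contribute to any branch.
    """
    return PatientTree(
        patient_id=patient_id,
        n_shared=int(counts.get("shared", 0)),
        n_primary_private=int(counts.get("primary_specific", 0)),
        n_met_private=int(counts.get("met_specific", 0)),
        flagged_genes=flagged_genes or [],
    )


def recurrent_genes(
    pairs_by_patient: dict[str, pd.DataFrame],
    min_patients: int = 2,
    nonsynonymous_only: bool = True,
) -> pd.DataFrame:
    """Genes carrying metastasis-private mutations in >= min_patients patients.

    Counts distinct patients, not variants: two metastasis-private hits
    in one gene in the same patient count once.  By default only
    non-synonymous consequences contribute.  Rows sort by descending
    patient count, then gene symbol.
    """
    if len(pairs_by_patient) < 2:
        raise ValueError("recurrent_genes requires >= 2 patients")
    hits: dict[str, set[str]] = {}
    for patient, pairs in pairs_by_patient.items():
        sel = pairs[pairs["status"] == "met_specific"]
        if nonsynonymous_only:
            sel = sel[sel["consequence"].isin(NONSYNONYMOUS)]
        for gene in sel["gene"].unique():
            if gene:
                hits.setdefault(gene, set()).add(patient)
    rows = [
        {"gene": g, "n_patients": len(p), "patients": ",".join(sorted(p))}
        for g, p in hits.items()
        if len(p) >= min_patients
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_patients", "patients"])
    return df.sort_values(
        ["n_patients", "gene"], ascending=[False, True], ignore_index=True
    )


def annotate_cancer_genes(
    variants: pd.DataFrame, gene_list: set[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag variants lying in cancer-census genes and summarize counts.

    Returns the table with an ``in_cancer_list`` column plus a summary:
    flagged non-synonymous SNVs and flagged indels (any consequence),
    mirroring how such tallies are reported for exome cohorts.
    """
    if not gene_list:
        logger.warning("empty cancer-gene list: nothing will be flagged")
    out = variants.copy()
    out["in_cancer_list"] = out["gene"].isin(gene_list)
    flagged = out[out["in_cancer_list"]]
    summary = {
        "nonsynonymous_snvs": int(
            (
                (flagged["vclass"] == "SNV")
                & flagged["consequence"].isin(NONSYNONYMOUS)
            ).sum()
        ),
        "indels": int((flagged["vclass"] == "indel").sum()),
    }
    return out, summary


@dataclass
class DomainHit:
    gene: str
    protein_pos: int | None
    consequence: str
    domain: str | None

    @property
    def in_functional_domain(self) -> bool:
        return self.domain is not None


def domain_overlap(
    variants: pd.DataFrame, domain_table: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join variants to covering protein domains (lollipop-ready rows).

    ``variants`` needs gene, protein_pos and consequence columns;
    domain spans are 1-based inclusive.  A variant lacking a protein
    position gets domain ``None`` and is counted separately.  The
    summary reports how many distinct genes have >= 1 variant inside an
    annotated domain, and how many variant rows lacked a position.
    """
    rows = []
    no_pos = 0
    for r in variants.itertuples(index=False):
        pos = getattr(r, "protein_pos", None)
        if pos is None or pd.isna(pos):
            no_pos += 1
            rows.append(
                {"gene": r.gene, "protein_pos": None, "consequence": r.consequence,
                 "domain": None, "in_functional_domain": False}
            )
            continue
        pos = int(pos)
        spans = domain_table[domain_table["gene"] == r.gene]
        cover = spans[(spans["start_aa"] <= pos) & (pos <= spans["end_aa"])]
        domain = str(cover["domain"].iloc[0]) if len(cover) else None
        rows.append(
            {"gene": r.gene, "protein_pos": pos, "consequence": r.consequence,
             "domain": domain, "in_functional_domain": domain is not None}
        )
    hits = pd.DataFrame(
        rows, columns=["gene", "protein_pos", "consequence", "domain", "in_functional_domain"]
    )
    summary = {
        "genes_with_domain_hit": int(
            hits.loc[hits["in_functional_domain"], "gene"].nunique()
        ),
        "variants_without_position": no_pos,
    }
    return hits, summary
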