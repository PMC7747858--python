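"""Synthetic paired tumor/metastasis cohorts with known ground truth.

The generator emulates the design of a paired whole-exome study: for
each patient, one primary lung tumor sample and one brain metastasis
sample, both sequenced to a configurable median depth (default 135X).
It plants four origins of variants —

* ``germline``   — present in both compartments at VAF 0.5 and listed
  in the population catalog with frequency >= 1e-5 (so the germline
  exclusion step must remove them);
* ``truncal``    — somatic, shared by both compartments (the common
  precursor clone);
* ``primary_private`` / ``met_private`` — somatic, confined to one
  compartment —

plus copy-number segments planted in the metastasis coverage, and a
recurrent metastasis-private missense mutation planted in one gene
across several patients (emulating a gene hit in multiple metastases).
Both compartments' variant tables carry a row for every site of the
patient (with zero variant reads where the allele is absent), so
downstream classification always has per-site depth available.

Per-site depth is Poisson around the median depth (floor 1); variant
reads are Binomial(depth, VAF).  Sequencing error (background variant
reads at wild-type sites) is not modeled, nor is tumor purity: each
origin class has a single VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import VARIANT_COLUMNS
from .variant_qc import DEFAULT_THRESHOLDS, passes_quality

ORIGINS = ("germline", "truncal", "primary_private", "met_private")

#: substitution-type weights skewed toward C>A, the dominant type in
#: tobacco-exposed lung tumors (order: C>A, C>G, C>T, T>A, T>C, T>G)
TOBACCO_LIKE_WEIGHTS = (0.40, 0.10, 0.20, 0.08, 0.15, 0.07)

_SUBS = (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    Counts are per patient.  ``planted_segments`` are
    ``(chrom, start_bin, end_bin, log2_ratio)`` with inclusive bin
    indices, applied to the metastasis coverage of every patient.
    """

    n_patients: int = 7
    median_depth: int = 135
    n_truncal: int = 119
    n_primary_private: int = 19
    n_met_private: int = 52
    n_germline: int = 200
    germline_freq_range: tuple[float, float] = (1e-4, 0.5)
    vaf_truncal: float = 0.4
    vaf_private: float = 0.4
    qphred_mean: float = 60.0
    planted_segments: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("chr1", 100, 149, 0.6), ("chr2", 40, 99, -0.8)]
    )
    n_bins: int = 300  # per chromosome
    bin_noise_sd: float = 0.1  # log2 units
    seed: int = 0
    # layout / composition (defaults chosen once as realistic, see docs)
    n_chroms: int = 4
    bin_size: int = 100_000
    indel_fraction: float = 0.2
    substitution_weights: Sequence[float] = TOBACCO_LIKE_WEIGHTS
    recurrent_gene: str = "GENE_MET_R"
    n_recurrent_patients: int = 3
    n_cancer_genes: int = 20

    def validate(self) -> None:
        counts = (
            self.n_patients, self.n_truncal, self.n_primary_private,
            self.n_met_private, self.n_germline,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for vaf in (self.vaf_truncal, self.vaf_private):
            if not (0 < vaf <= 1):
                raise ValueError("VAFs must be in (0, 1]")
        if self.bin_noise_sd < 0:
            raise ValueError("bin_noise_sd must be >= 0")
        if self.n_truncal and self.median_depth * self.vaf_truncal < 1:
            raise ValueError("expected truncal variant reads < 1: unobservable")
        if (self.n_primary_private or self.n_met_private) and (
            self.median_depth * self.vaf_private < 1
        ):
            raise ValueError("expected private variant reads < 1: unobservable")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, lo, hi, _ in self.planted_segments:
            if not (0 <= lo <= hi < self.n_bins):
                raise ValueError(f"planted segment {chrom}:{lo}-{hi} outside bin range")
            for a, b in seen.get(chrom, []):
                if lo <= b and a <= hi:
                    raise ValueError(f"overlapping planted segments on {chrom}")
            seen.setdefault(chrom, []).append((lo, hi))
        if abs(sum(self.substitution_weights) - 1.0) > 1e-6:
            raise ValueError("substitution_weights must sum to 1")


@dataclass
class TruthLabel:
    variant_id: str
    origin: str
    passes_qc_by_construction: bool


@dataclass
class Cohort:
    """All artifacts of one generated cohort."""

    config: CohortConfig
    variant_tables: dict[str, pd.DataFrame]  # sample id -> variant table
    coverage_tables: dict[str, pd.DataFrame]  # sample id -> chrom/start/end/depth
    germline_catalog: dict[tuple[str, int, str, str], float]
    truth: pd.DataFrame  # variant_id, origin, passes_qc_by_construction
    cancer_genes: set[str]
    domain_table: pd.DataFrame

    def patients(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.config.n_patients)]

    @staticmethod
    def sample_ids(patient: str) -> tuple[str, str]:
        return f"{patient}_primary", f"{patient}_met"


def _draw_snv(rng: np.random.Generator, weights: Sequence[float]) -> tuple[str, str, str, str]:
    """One SNV as (ref, alt, context5, context3), random strand."""
    ref, alt = _SUBS[rng.choice(6, p=np.asarray(weights, dtype=float))]
    c5, c3 = rng.choice(list(_BASES)), rng.choice(list(_BASES))
    if rng.random() < 0.5:  # present on the purine strand
        ref, alt = _COMP[ref], _COMP[alt]
        c5, c3 = _COMP[c3], _COMP[c5]
    return ref, alt, c5, c3


def _draw_indel(rng: np.random.Generator) -> tuple[str, str, str]:
    base = rng.choice(list(_BASES))
    ins = base + "".join(rng.choice(list(_BASES), size=rng.integers(1, 4)))
    if rng.random() < 0.5:
        return base, ins, "frameshift" if (len(ins) - 1) % 3 else "inframe_indel"
    return ins, base, "frameshift" if (len(ins) - 1) % 3 else "inframe_indel"


_SNV_CONSEQUENCES = ("synonymous", "missense", "nonsense", "splice", "other")
_SNV_CONSEQUENCE_P = (0.30, 0.55, 0.05, 0.05, 0.05)


def _depth(rng: np.random.Generator, median_depth: int) -> int:
    return max(1, int(rng.poisson(median_depth)))


def _qphred(rng: np.random.Generator, mean: float) -> float:
    return float(round(max(0.0, rng.normal(mean, 5.0))))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one paired cohort; byte-identical under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_len = config.n_bins * config.bin_size

    gene_pool = [f"G{i:05d}" for i in range(1, 5001)]
    cancer_genes = {config.recurrent_gene} | {
        gene_pool[i] for i in rng.choice(len(gene_pool), size=config.n_cancer_genes - 1, replace=False)
    }

    catalog: dict[tuple[str, int, str, str], float] = {}
    variant_tables: dict[str, pd.DataFrame] = {}
    coverage_tables: dict[str, pd.DataFrame] = {}
    truth_rows: list[TruthLabel] = []

    n_per_patient = (
        config.n_germline + config.n_truncal
        + config.n_primary_private + config.n_met_private
    )
    origin_plan = (
        ["germline"] * config.n_germline
        + ["truncal"] * config.n_truncal
        + ["primary_private"] * config.n_primary_private
        + ["met_private"] * config.n_met_private
    )

    for p_idx in range(config.n_patients):
        patient = f"P{p_idx + 1}"
        s_primary, s_met = f"{patient}_primary", f"{patient}_met"

        # distinct sites for this patient
        sites: set[tuple[str, int]] = set()
        while len(sites) < n_per_patient:
            sites.add((chroms[rng.integers(len(chroms))], int(rng.integers(1, chrom_len + 1))))
        site_list = sorted(sites)
        order = rng.permutation(n_per_patient)

        plant_recurrent = (
            p_idx < config.n_recurrent_patients and config.n_met_private > 0
        )
        recurrent_done = False

        rows_primary, rows_met = [], []
        for origin, site_i in zip(origin_plan, order):
            chrom, pos = site_list[site_i]
            gene = gene_pool[rng.integers(len(gene_pool))]
            is_indel = origin != "germline" and rng.random() < config.indel_fraction
            if origin == "met_private" and plant_recurrent and not recurrent_done:
                gene = config.recurrent_gene
                consequence = "missense"
                ref, alt, c5, c3 = _draw_snv(rng, config.substitution_weights)
                vclass = "SNV"
                recurrent_done = True
            elif is_indel:
                ref, alt, consequence = _draw_indel(rng)
                c5 = c3 = ""
                vclass = "indel"
            else:
                ref, alt, c5, c3 = _draw_snv(rng, config.substitution_weights)
                consequence = _SNV_CONSEQUENCES[
                    rng.choice(len(_SNV_CONSEQUENCES), p=_SNV_CONSEQUENCE_P)
                ]
                vclass = "SNV"

            if origin == "germline":
                freq = float(rng.uniform(*config.germline_freq_range))
                catalog.setdefault((chrom, pos, ref, alt), freq)
                pop_freq = catalog[(chrom, pos, ref, alt)]
                vaf_primary = vaf_met = 0.5
            else:
                pop_freq = np.nan
                vaf = config.vaf_truncal if origin == "truncal" else config.vaf_private
                vaf_primary = vaf if origin in ("truncal", "primary_private") else 0.0
                vaf_met = vaf if origin in ("truncal", "met_private") else 0.0

            d_p, d_m = _depth(rng, config.median_depth), _depth(rng, config.median_depth)
            a_p = int(rng.binomial(d_p, vaf_primary)) if vaf_primary else 0
            a_m = int(rng.binomial(d_m, vaf_met)) if vaf_met else 0
            q_p, q_m = _qphred(rng, config.qphred_mean), _qphred(rng, config.qphred_mean)

            common = dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, vclass=vclass,
                gene=gene, consequence=consequence, pop_freq=pop_freq,
                context5=c5, context3=c3,
            )
            rows_primary.append(
                dict(sample=s_primary, depth=d_p, alt_reads=a_p, qphred=q_p, **common)
            )
            rows_met.append(
                dict(sample=s_met, depth=d_m, alt_reads=a_m, qphred=q_m, **common)
            )

            carrying = []
            if vaf_primary:
                carrying.append((d_p, a_p, q_p))
            if vaf_met:
                carrying.append((d_m, a_m, q_m))
            passes = all(
                passes_quality(d, a, q, vclass, DEFAULT_THRESHOLDS)
                for d, a, q in carrying
            )
            truth_rows.append(
                TruthLabel(f"{patient}:{chrom}:{pos}:{ref}>{alt}", origin, passes)
            )

        variant_tables[s_primary] = pd.DataFrame(rows_primary, columns=VARIANT_COLUMNS)
        variant_tables[s_met] = pd.DataFrame(rows_met, columns=VARIANT_COLUMNS)

        # coverage: planted segments scale the metastasis depth
        cov_p_rows, cov_m_rows = [], []
        for chrom in chroms:
            lr = np.zeros(config.n_bins)
            for seg_chrom, lo, hi, value in config.planted_segments:
                if seg_chrom == chrom:
                    lr[lo : hi + 1] = value
            e_p = rng.normal(0.0, config.bin_noise_sd, config.n_bins) if config.bin_noise_sd else 0.0
            e_m = rng.normal(0.0, config.bin_noise_sd, config.n_bins) if config.bin_noise_sd else 0.0
            depth_p = config.median_depth * np.power(2.0, e_p) * np.ones(config.n_bins)
            depth_m = config.median_depth * np.power(2.0, lr + e_m)
            starts = np.arange(config.n_bins) * config.bin_size
            for b in range(config.n_bins):
                cov_p_rows.append(
                    dict(chrom=chrom, start=int(starts[b]), end=int(starts[b] + config.bin_size),
                         depth=float(depth_p[b]))
                )
                cov_m_rows.append(
                    dict(chrom=chrom, start=int(starts[b]), end=int(starts[b] + config.bin_size),
                         depth=float(depth_m[b]))
                )
        coverage_tables[s_primary] = pd.DataFrame(cov_p_rows)
        coverage_tables[s_met] = pd.DataFrame(cov_m_rows)

    truth = pd.DataFrame(
        [(t.variant_id, t.origin, t.passes_qc_by_construction) for t in truth_rows],
        columns=["variant_id", "origin", "passes_qc_by_construction"],
    )

    # domains for the recurrent gene and a few cancer genes
    domain_rows = [
        {"gene": config.recurrent_gene, "domain": "DUF_A", "start_aa": 100, "end_aa": 200}
    ]
    for i, gene in enumerate(sorted(cancer_genes - {config.recurrent_gene})[:5]):
        domain_rows.append(
            {"gene": gene, "domain": f"DOM_{i}", "start_aa": 50, "end_aa": 150}
        )
    domain_table = pd.DataFrame(domain_rows, columns=["gene", "domain", "start_aa", "end_aa"])

    return Cohort(
        config=config,
        variant_tables=variant_tables,
        coverage_tables=coverage_tables,
        germline_catalog=catalog,
        truth=truth,
        cancer_genes=cancer_genes,
        domain_table=domain_table,
    )


def variant_ids(table: pd.DataFrame, patient: str) -> pd.Series:
    """Ground-truth keys for a classified paired table."""
    return (
        patient + ":" + table["chrom"].astype(str) + ":" + table["pos"].astype(str)
        + ":" + table["ref"] + ">" + table["alt"]
    )


def truth_confusion(truth: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate planted origin against assigned sharing status.

    ``calls`` must carry ``variant_id`` and ``status`` columns for the
    variants that survived QC; keys absent from the truth table raise
    an error naming the orphans.  Rows (origins) and columns (statuses)
    are complete even when empty, so row sums equal the number of
    generated variants of each origin that reached classification.
    """
    orphans = sorted(set(calls["variant_id"]) - set(truth["variant_id"]))
    if orphans:
        raise ValueError(f"call keys absent from truth labels: {orphans[:10]}")
    merged = calls.merge(truth[["variant_id", "origin"]], on="variant_id", how="left")
    table = pd.crosstab(merged["origin"], merged["status"])
    from .paired_classification import STATUSES

    table = table.reindex(index=list(ORIGINS), columns=list(STATUSES), fill_value=0)
    table.index.name = "origin"
    table.columns.name = "status"
    return table


def random_snv_table(
    n: int,
    substitution_weights: Sequence[float],
    sample_id: str = "S",
    seed: int | None = None,
) -> pd.DataFrame:
    """A bare SNV table drawn from a substitution-type profile.

    Convenience generator for spectrum/clustering studies where read
    evidence is irrelevant; contexts are uniform, strand random.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        ref, alt, c5, c3 = _draw_snv(rng, substitution_weights)
        rows.append(
            dict(
                sample=sample_id, chrom="chr1", pos=i + 1, ref=ref, alt=alt,
                depth=100, alt_reads=40, qphred=60.0, vclass="SNV", gene="",
                consequence="missense", pop_freq=np.nan, context5=c5, context3=c3,
            )
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
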