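"""End-to-end driver: qc -> classify -> cna -> spectrum -> report.

Runs the full paired-cohort analysis from on-disk tables (or an
in-memory synthetic cohort) and writes per-stage outputs plus a
machine-readable run manifest recording parameters, seeds and counts.
Threshold defaults that come from the published filtering rules are
labeled ``published`` in the manifest; every other default is labeled
``assumed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .cna_segmentation import (
    call_states,
    log_ratio,
    recurrent_regions,
    segment_chromosomes,
    segments_to_frame,
    states_per_bin,
    zero_level,
)
from .evolution_report import annotate_cancer_genes, build_tree, recurrent_genes
from .mutational_spectrum import cluster_samples, spectrum, spectrum_matrix
from .paired_classification import classify_patient
from .synthetic_cohort import Cohort, CohortConfig, generate_cohort, truth_confusion, variant_ids
from .variant_qc import QcThresholds, qc_pipeline

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (CLI flags mirror these fields)."""

    qc: QcThresholds = field(default_factory=QcThresholds)
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_seed: int = 0
    min_recurrence_patients: int = 2
    min_region_patients: int = 2
    spectrum_components: int = 2

    def manifest_parameters(self) -> dict:
        qc = asdict(self.qc)
        qc["min_vaf"] = float(self.qc.min_vaf)
        return {
            "qc_thresholds": {"values": qc, "provenance": "published"},
            "cna_offsets": {"values": {"gain": 0.15, "amplification": 2.0},
                            "provenance": "published"},
            "cbs": {
                "values": {"alpha": self.cbs_alpha, "n_perm": self.cbs_n_perm,
                           "seed": self.cbs_seed, "min_width": 3},
                "provenance": "assumed",
            },
            "zero_level_bin_width": {"values": 0.05, "provenance": "assumed"},
            "recurrence": {
                "values": {"min_patients": self.min_recurrence_patients},
                "provenance": "assumed",
            },
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_cohort(
    cohort: Cohort,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage on an in-memory cohort; return the manifest.

    When ``outdir`` is given, all stage outputs (paired tables, SEG
    tables, recurrence reports, spectra, Newick trees, manifest) are
    written beneath it as plain-text files.
    """
    cfg = config or RunConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "parameters": cfg.manifest_parameters(),
        "cohort_seed": cohort.config.seed,
        "patients": {},
    }

    pairs_by_patient: dict[str, pd.DataFrame] = {}
    state_tables: dict[str, pd.DataFrame] = {}
    spectra = []
    all_calls = []

    for patient in cohort.patients():
        s_p, s_m = Cohort.sample_ids(patient)
        entry: dict = {}

        # --- qc
        try:
            qc_p, att_p = qc_pipeline(
                cohort.variant_tables[s_p], cfg.qc, cohort.germline_catalog
            )
            qc_m, att_m = qc_pipeline(
                cohort.variant_tables[s_m], cfg.qc, cohort.germline_catalog
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("qc", f"{patient}: {exc}") from exc
        entry["qc"] = {
            "primary": {"retained": len(qc_p), **att_p},
            "met": {"retained": len(qc_m), **att_m},
        }

        # --- classify
        try:
            pairs, counts = classify_patient(
                qc_p, qc_m,
                primary_evidence=cohort.variant_tables[s_p],
                met_evidence=cohort.variant_tables[s_m],
                patient_id=patient,
            )
        except Exception as exc:
            raise StageError("classify", f"{patient}: {exc}") from exc
        pairs_by_patient[patient] = pairs
        entry["classification"] = counts

        calls = pairs[["status"]].copy()
        calls["variant_id"] = variant_ids(pairs, patient)
        all_calls.append(calls)

        # --- cna
        try:
            ratios = log_ratio(cohort.coverage_tables[s_p], cohort.coverage_tables[s_m])
            segs = segment_chromosomes(
                ratios, alpha=cfg.cbs_alpha, n_perm=cfg.cbs_n_perm, seed=cfg.cbs_seed
            )
            zero = zero_level(segs)
            segs = call_states(segs, zero)
        except Exception as exc:
            raise StageError("cna", f"{patient}: {exc}") from exc
        state_tables[patient] = states_per_bin(ratios, segs)
        entry["cna"] = {
            "zero_level": zero,
            "n_segments": len(segs),
            "n_altered": sum(s.state != "neutral" for s in segs),
        }

        # --- spectrum (metastasis-acquired mutations)
        met_private = pairs[pairs["status"] == "met_specific"]
        spectra.append(spectrum(met_private.assign(sample=s_m), sample_id=s_m))

        # --- evolution report
        flagged, cancer_summary = annotate_cancer_genes(pairs, cohort.cancer_genes)
        tree = build_tree(patient, counts)
        entry["tree"] = tree.to_newick()
        entry["cancer_gene_summary"] = cancer_summary

        manifest["patients"][patient] = entry
        if out is not None:
            pairs.to_csv(out / f"{patient}_pairs.tsv", sep="\t", index=False)
            segframe = segments_to_frame(segs, s_m)
            segframe.to_csv(out / f"{patient}_segments.tsv", sep="\t", index=False)
            (out / f"{patient}_tree.nwk").write_text(tree.to_newick() + "\n")

    # --- cross-patient reports
    try:
        recurrence = recurrent_genes(pairs_by_patient, cfg.min_recurrence_patients)
        regions = recurrent_regions(state_tables, cfg.min_region_patients)
    except Exception as exc:
        raise StageError("report", str(exc)) from exc
    manifest["recurrent_genes"] = recurrence.to_dict("records")
    manifest["recurrent_regions"] = regions.to_dict("records")

    nonzero = [s for s in spectra if s.total() > 0]
    if len(nonzero) >= 2:
        clustering = cluster_samples(nonzero, cfg.spectrum_components)
        manifest["spectrum_clusters"] = clustering.cluster_labels
        if out is not None:
            (out / "spectrum_dendrogram.nwk").write_text(clustering.newick + "\n")
            clustering.pca_coordinates.to_csv(out / "spectrum_pca.tsv", sep="\t")

    confusion = truth_confusion(cohort.truth, pd.concat(all_calls, ignore_index=True))
    manifest["truth_confusion"] = {
        origin: row.to_dict() for origin, row in confusion.iterrows()
    }

    if out is not None:
        recurrence.to_csv(out / "recurrent_genes.tsv", sep="\t", index=False)
        regions.to_csv(out / "recurrent_regions.tsv", sep="\t", index=False)
        if nonzero:
            spectrum_matrix(nonzero).to_csv(out / "spectra.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_demo(seed: int = 7, outdir: str | Path | None = None, n_patients: int = 7) -> dict:
    """Generate a synthetic cohort and run the whole pipeline on it."""
    cohort = generate_cohort(CohortConfig(n_patients=n_patients, seed=seed))
    run_cfg = RunConfig(cbs_seed=seed, cbs_n_perm=200)
    return run_cohort(cohort, run_cfg, outdir)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a generated cohort to disk in the plain-text dialects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, table in cohort.variant_tables.items():
        pio.write_variant_table(table, out / f"{sample}.variants.tsv")
    for sample, table in cohort.coverage_tables.items():
        pio.write_coverage_table(table, out / f"{sample}.coverage.tsv")
    pio.write_germline_catalog(cohort.germline_catalog, out / "germline_catalog.tsv")
    cohort.truth.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    pio.write_gene_list(cohort.cancer_genes, out / "cancer_genes.tsv")
    cohort.domain_table.to_csv(out / "domains.tsv", sep="\t", index=False)
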