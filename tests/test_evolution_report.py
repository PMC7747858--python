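"""Trunk/branch trees, recurrence tallies, cancer-gene and domain annotation."""

import io as _io

import pandas as pd
import pytest
from Bio import Phylo

from pairedexome.evolution_report import (
    annotate_cancer_genes,
    build_tree,
    domain_overlap,
    recurrent_genes,
    tree_from_newick,
)
from pairedexome.paired_classification import classify_patient
from pairedexome.synthetic_cohort import Cohort
from pairedexome.variant_qc import qc_pipeline

from conftest import make_variant, variant_frame


class TestPatientTree:
    def test_newick_roundtrip(self):
        tree = build_tree("P1", {"shared": 50, "primary_specific": 10, "met_specific": 10})
        newick = tree.to_newick()
        back = tree_from_newick(newick, "P1")
        assert (back.n_shared, back.n_primary_private, back.n_met_private) == (50, 10, 10)

    def test_newick_parses_with_external_parser(self):
        tree = build_tree("P1", {"shared": 7, "primary_specific": 2, "met_specific": 12})
        parsed = Phylo.read(_io.StringIO(tree.to_newick()), "newick")
        lengths = {leaf.name: leaf.branch_length for leaf in parsed.get_terminals()}
        assert lengths == {"primary": 2, "met": 12}
        trunk = parsed.common_ancestor(["primary", "met"])
        assert trunk.branch_length == 7

    def test_all_zero_counts_still_valid_newick(self):
        tree = build_tree("P1", {})
        parsed = Phylo.read(_io.StringIO(tree.to_newick()), "newick")
        assert len(parsed.get_terminals()) == 2

    def test_longer_met_branch(self):
        tree = build_tree("P1", {"shared": 5, "primary_specific": 1, "met_specific": 30})
        assert tree.n_met_private > tree.n_primary_private


def _pairs(patient, rows):
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "consequence", "status"],
    )
    df["patient"] = patient
    return df


class TestRecurrentGenes:
    def test_counts_patients_not_variants(self):
        # P1 has two met-private hits in GENEX -> counts once
        pairs = {
            "P1": _pairs("P1", [
                ("chr1", 1, "C", "A", "GENEX", "missense", "met_specific"),
                ("chr1", 9, "C", "T", "GENEX", "missense", "met_specific"),
            ]),
            "P2": _pairs("P2", [
                ("chr1", 2, "C", "A", "GENEX", "nonsense", "met_specific"),
            ]),
            "P3": _pairs("P3", [
                ("chr1", 3, "C", "A", "GENEX", "missense", "primary_specific"),
            ]),
        }
        out = recurrent_genes(pairs, min_patients=2)
        assert len(out) == 1
        assert out.iloc[0]["gene"] == "GENEX"
        assert out.iloc[0]["n_patients"] == 2  # P3's hit is not met-specific

    def test_three_patient_recurrence(self):
        pairs = {
            f"P{i}": _pairs(f"P{i}", [
                ("chr1", i, "C", "A", "GENEX", "missense", "met_specific")
            ])
            for i in range(1, 4)
        }
        out = recurrent_genes(pairs, min_patients=2)
        assert out.iloc[0].tolist() == ["GENEX", 3, "P1,P2,P3"]

    def test_private_genes_give_empty_report(self):
        pairs = {
            "P1": _pairs("P1", [("chr1", 1, "C", "A", "G1", "missense", "met_specific")]),
            "P2": _pairs("P2", [("chr1", 2, "C", "A", "G2", "missense", "met_specific")]),
        }
        assert recurrent_genes(pairs, min_patients=2).empty

    def test_synonymous_toggle(self):
        pairs = {
            "P1": _pairs("P1", [("chr1", 1, "C", "A", "GS", "synonymous", "met_specific")]),
            "P2": _pairs("P2", [("chr1", 2, "C", "T", "GS", "synonymous", "met_specific")]),
        }
        assert recurrent_genes(pairs, min_patients=2).empty
        relaxed = recurrent_genes(pairs, min_patients=2, nonsynonymous_only=False)
        assert relaxed.iloc[0]["gene"] == "GS"

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            recurrent_genes({"P1": _pairs("P1", [])})


class TestCancerGenes:
    def _variants(self):
        return variant_frame([
            make_variant(pos=1, gene="CANCER1", consequence="missense"),
            make_variant(pos=2, gene="CANCER1", consequence="synonymous"),
            make_variant(pos=3, gene="OTHER", consequence="missense"),
            make_variant(pos=4, gene="CANCER2", vclass="indel",
                         consequence="frameshift", ref="A", alt="AT",
                         context5="", context3=""),
        ])

    def test_flag_and_counts(self):
        flagged, summary = annotate_cancer_genes(self._variants(), {"CANCER1", "CANCER2"})
        assert flagged["in_cancer_list"].tolist() == [True, True, False, True]
        # synonymous SNV is flagged but excluded from the non-synonymous tally
        assert summary == {"nonsynonymous_snvs": 1, "indels": 1}

    def test_empty_gene_list_flags_nothing(self):
        flagged, summary = annotate_cancer_genes(self._variants(), set())
        assert not flagged["in_cancer_list"].any()
        assert summary == {"nonsynonymous_snvs": 0, "indels": 0}


class TestDomainOverlap:
    domains = pd.DataFrame(
        {"gene": ["G1", "G1", "G2"], "domain": ["kinase", "SH2", "DUF"],
         "start_aa": [100, 300, 10], "end_aa": [200, 350, 50]}
    )

    def _var(self, gene, pos):
        return pd.DataFrame(
            {"gene": [gene], "protein_pos": [pos], "consequence": ["missense"]}
        )

    @pytest.mark.parametrize("pos,inside", [(150, True), (100, True), (200, True),
                                            (99, False), (201, False)])
    def test_boundary_inclusive(self, pos, inside):
        hits, _ = domain_overlap(self._var("G1", pos), self.domains)
        assert bool(hits["in_functional_domain"].item()) is inside

    def test_missing_position_counted_separately(self):
        hits, summary = domain_overlap(self._var("G1", None), self.domains)
        assert not hits["in_functional_domain"].item()
        assert summary["variants_without_position"] == 1

    def test_gene_level_summary(self):
        variants = pd.concat(
            [self._var("G1", 150), self._var("G1", 250), self._var("G2", 20),
             self._var("G3", 5)],
            ignore_index=True,
        )
        hits, summary = domain_overlap(variants, self.domains)
        assert summary["genes_with_domain_hit"] == 2  # G1 and G2, not G3

    def test_planted_three_of_thirteen(self):
        """13 recurrent genes, exactly 3 with an in-domain hit."""
        genes = [f"R{i:02d}" for i in range(13)]
        domains = pd.DataFrame(
            {"gene": genes[:3], "domain": ["D"] * 3, "start_aa": [1] * 3,
             "end_aa": [100] * 3}
        )
        variants = pd.DataFrame(
            {"gene": genes, "protein_pos": [50] * 13, "consequence": ["missense"] * 13}
        )
        _, summary = domain_overlap(variants, domains)
        assert summary["genes_with_domain_hit"] == 3


def test_tree_counts_reconcile_with_classification(small_cohort):
    """Cross-module consistency: tree branch lengths equal classifier counts."""
    patient = "P1"
    s_p, s_m = Cohort.sample_ids(patient)
    qc_p, _ = qc_pipeline(
        small_cohort.variant_tables[s_p], catalog=small_cohort.germline_catalog
    )
    qc_m, _ = qc_pipeline(
        small_cohort.variant_tables[s_m], catalog=small_cohort.germline_catalog
    )
    pairs, counts = classify_patient(
        qc_p, qc_m,
        primary_evidence=small_cohort.variant_tables[s_p],
        met_evidence=small_cohort.variant_tables[s_m],
        patient_id=patient,
    )
    tree = build_tree(patient, counts)
    assert tree.n_shared == (pairs["status"] == "shared").sum()
    assert tree.n_primary_private == (pairs["status"] == "primary_specific").sum()
    assert tree.n_met_private == (pairs["status"] == "met_specific").sum()
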