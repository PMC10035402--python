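import itertools

import pytest

from mrith.annotation import (AnnotationResources, CNVEvent,
                              classify_pathogenic, druggable_summary,
                              long_gene_threshold, normalized_gene_burden,
                              recurrence_table)
from mrith.clonality import MergedVariant


def mv(patient, gene, effect, clonality, pos=100, alt="T"):
    return MergedVariant(
        chrom="chr1", pos=pos, ref="A", alt=alt, patient_id=patient,
        biopsy_order=("B1", "B2"), presence=[True, True],
        rescued=[False, False], alt_reads=[10, 10], depth=[100, 100],
        gene=gene, effect=effect, clonality=clonality,
    )


class TestClassifyPathogenic:
    def test_lof_fires_with_empty_resources(self):
        v = mv("P1", "GENE001", "nonsense", "CLONAL")
        verdict = classify_pathogenic(v, AnnotationResources())
        assert verdict.is_likely_pathogenic and verdict.reasons == {"LOF"}

    def test_plain_missense_not_pathogenic(self):
        v = mv("P1", "GENE001", "missense", "CLONAL")
        assert not classify_pathogenic(v, AnnotationResources()).is_likely_pathogenic

    def test_oncogene_amplification(self):
        res = AnnotationResources(oncogene_set={"ERBB2"})
        ev = CNVEvent(gene="ERBB2", call="gain")
        verdict = classify_pathogenic(ev, res)
        assert verdict.reasons == {"ONCOGENE_AMP"}

    def test_complete_deletion_needs_upstream_flag(self):
        res = AnnotationResources()
        assert not classify_pathogenic(
            CNVEvent(gene="X", call="deletion"), res).is_likely_pathogenic
        assert classify_pathogenic(
            CNVEvent(gene="X", call="deletion", full_gene_or_wt_loss=True),
            res).reasons == {"COMPLETE_DELETION"}

    def test_matches_disjunction_truth_table(self):
        """The verdict equals a brute-force OR over the five clauses for
        every combination of firing clauses."""
        for lof, hotspot, clinvar, amp, deletion in itertools.product(
                [False, True], repeat=5):
            res = AnnotationResources(
                hotspot_set={("chr1", 100, "A", "T")} if hotspot else set(),
                clinvar_pathogenic_set={("chr1", 100, "A", "T")} if clinvar else set(),
                oncogene_set={"G"} if amp else set(),
            )
            v = mv("P1", "G", "frameshift" if lof else "missense", "CLONAL")
            verdict = classify_pathogenic(v, res)
            expected_snv = lof or hotspot or clinvar
            assert verdict.is_likely_pathogenic == expected_snv
            cn_gain = classify_pathogenic(CNVEvent("G", "gain"), res)
            assert cn_gain.is_likely_pathogenic == amp
            cn_del = classify_pathogenic(
                CNVEvent("G", "deletion", full_gene_or_wt_loss=deletion), res)
            assert cn_del.is_likely_pathogenic == deletion


class TestLongGene:
    def test_interpolated_quartile(self):
        thr, flags = long_gene_threshold({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        assert thr == pytest.approx(3.25)
        assert flags == {"A": False, "B": False, "C": False, "D": True}

    def test_equal_lengths_flag_none(self):
        _, flags = long_gene_threshold({g: 2.0 for g in "ABCDE"})
        assert not any(flags.values())

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            long_gene_threshold({"A": 1.0})

    def test_permutation_invariant(self):
        lengths = {"A": 5.0, "B": 1.0, "C": 9.0, "D": 2.0, "E": 7.0}
        thr1, _ = long_gene_threshold(lengths)
        thr2, _ = long_gene_threshold(dict(reversed(list(lengths.items()))))
        assert thr1 == thr2


class TestGeneBurden:
    def test_count_over_cds(self):
        out = normalized_gene_burden({"G1": 12}, {"G1": 3.0})
        assert out["G1"] == pytest.approx(4.0)

    def test_zero_counts_on_request(self):
        out = normalized_gene_burden({}, {"G1": 3.0}, include_zero=True)
        assert out == {"G1": 0.0}

    def test_unknown_gene_named_in_error(self):
        with pytest.raises(ValueError, match="MYSTERY"):
            normalized_gene_burden({"MYSTERY": 1}, {"G1": 3.0})


class TestRecurrence:
    def variants(self):
        return [
            mv("P1", "TP53", "missense", "CLONAL"),
            mv("P2", "TP53", "nonsense", "CLONAL"),
            mv("P3", "TP53", "missense", "CLONAL"),
            mv("P3", "TP53", "missense", "CLONAL", pos=200),  # same patient twice
            mv("P1", "CDH1", "missense", "SUBCLONAL"),
            mv("P2", "MUC16", "silent", "CLONAL"),
            mv("P9", "ARID1A", "frameshift", "CLONAL"),       # MSI patient
        ]

    MSI = {"P9": True, "P1": False, "P2": False, "P3": False}

    def test_counts_patients_once(self):
        rows = recurrence_table(self.variants(), self.MSI, clonal_only=True,
                                min_patients=3, population="MSS")
        assert rows == [("TP53", 3)]

    def test_subclonal_excluded_under_clonal_only(self):
        rows = recurrence_table(self.variants(), self.MSI, clonal_only=True,
                                min_patients=1, population="MSS")
        genes = [g for g, _ in rows]
        assert "CDH1" not in genes and "MUC16" not in genes  # silent excluded

    def test_msi_population_filter(self):
        rows = recurrence_table(self.variants(), self.MSI, clonal_only=True,
                                min_patients=1, population="MSI")
        assert rows == [("ARID1A", 1)]

    def test_removing_patient_never_increases_counts(self):
        full = dict(recurrence_table(self.variants(), self.MSI,
                                     min_patients=1, population="all"))
        reduced = [v for v in self.variants() if v.patient_id != "P3"]
        smaller = dict(recurrence_table(reduced, self.MSI,
                                        min_patients=1, population="all"))
        for gene, count in smaller.items():
            assert count <= full[gene]


class TestDruggableSummary:
    def test_constructed_cohort_percentages(self):
        res = AnnotationResources(druggable_set={"ERBB2", "PIK3CA"})
        subtype_of = {f"M{i}": "MSI" for i in range(4)}
        subtype_of.update({f"C{i}": "CIN" for i in range(12)})
        variants = [mv(f"M{i}", "PIK3CA", "nonsense", "CLONAL") for i in range(4)]
        variants += [mv(f"C{i}", "ERBB2", "frameshift", "CLONAL") for i in range(5)]
        variants += [mv("C5", "ERBB2", "missense", "CLONAL")]       # not pathogenic
        variants += [mv("C6", "ERBB2", "nonsense", "SUBCLONAL")]    # not clonal
        out = druggable_summary(variants, res, subtype_of)
        assert out["MSI"] == (4, 4, 100)
        assert out["CIN"] == (5, 12, 42)

    def test_subtype_without_hits_is_zero(self):
        res = AnnotationResources(druggable_set={"ERBB2"})
        out = druggable_summary([], res, {"P1": "GS"})
        assert out["GS"] == (0, 1, 0)

    def test_cnv_events_count(self):
        res = AnnotationResources(druggable_set={"ERBB2"},
                                  oncogene_set={"ERBB2"})
        out = druggable_summary(
            [], res, {"P1": "CIN"},
            cnv_events={"P1": [CNVEvent("ERBB2", "gain")]})
        assert out["CIN"] == (1, 1, 100)
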