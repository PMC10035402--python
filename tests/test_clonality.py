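import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from mrith.clonality import (CLONAL, NONE, PRIVATE, SUBCLONAL, MergedVariant,
                             RescueParams, binomial_upper_tail, classify_clonality,
                             classify_merged, clonality_summary,
                             forced_call_rescue, merge_patient_variants)
from mrith.io import VariantCall
from tests.conftest import classify_cohort


def call(biopsy, pos=100, alt="T", alt_reads=40, depth=100, called=True, **kw):
    return VariantCall(biopsy_id=biopsy, patient_id="P1", chrom="chr1",
                       pos=pos, ref="A", alt=alt, alt_reads=alt_reads,
                       depth=depth, called=called, **kw)


class TestMerge:
    def test_presence_across_biopsies(self):
        merged = merge_patient_variants(
            [call("B1"), call("B2")], ["B1", "B2", "B3"])
        assert len(merged) == 1
        assert merged[0].presence == [True, True, False]
        assert merged[0].alt_reads == [40, 40, -1]

    def test_different_alt_distinct_records(self):
        merged = merge_patient_variants(
            [call("B1", alt="T"), call("B2", alt="G")], ["B1", "B2"])
        assert len(merged) == 2

    def test_duplicate_rows_collapse_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            merged = merge_patient_variants(
                [call("B1"), call("B1")], ["B1", "B2"])
        assert len(merged) == 1 and merged[0].presence == [True, False]
        assert any("duplicate" in r.message for r in caplog.records)

    def test_unknown_biopsy_rejected(self):
        with pytest.raises(ValueError, match="biopsy_order"):
            merge_patient_variants([call("B9")], ["B1"])

    def test_mixed_patients_rejected(self):
        other = VariantCall(biopsy_id="B1", patient_id="P2", chrom="chr1",
                            pos=5, ref="A", alt="T", alt_reads=1, depth=10)
        with pytest.raises(ValueError, match="patients"):
            merge_patient_variants([call("B1"), other], ["B1"])


def merged_record(presence, alt_reads, depth, rescued=None):
    n = len(presence)
    return MergedVariant(
        chrom="chr1", pos=1, ref="A", alt="T", patient_id="P1",
        biopsy_order=tuple(f"B{i}" for i in range(n)),
        presence=list(presence), rescued=rescued or [False] * n,
        alt_reads=list(alt_reads), depth=list(depth),
    )


class TestRescue:
    def test_low_vaf_sister_rescued(self):
        # 4 alt reads of 200 (VAF 2%): error-only tail prob ~5.7e-5
        assert binomial_upper_tail(4, 200, 0.001) == pytest.approx(
            float(binom.sf(3, 200, 0.001)))
        assert binomial_upper_tail(4, 200, 0.001) < 1e-4
        m = merged_record([True, False], [50, 4], [120, 200])
        out = forced_call_rescue(m)
        assert out.presence == [True, True]
        assert out.rescued == [False, True]

    def test_min_alt_reads_gate(self):
        m = merged_record([True, False], [50, 1], [120, 300])
        assert forced_call_rescue(m).presence == [True, False]

    def test_low_depth_unevaluable(self):
        m = merged_record([True, False], [50, 5], [120, 10])
        out = forced_call_rescue(m)
        assert out.presence == [True, False]
        assert out.unevaluable == [False, True]

    def test_no_presence_returned_unchanged(self, caplog):
        m = merged_record([False, False], [0, 0], [100, 100])
        with caplog.at_level("WARNING"):
            out = forced_call_rescue(m)
        assert out.presence == [False, False]
        assert any("no called biopsy" in r.message for r in caplog.records)

    def test_never_removes_called_presence(self):
        m = merged_record([True, True], [50, 0], [120, 100])
        assert forced_call_rescue(m).presence == [True, True]

    @given(
        alt=st.integers(0, 30), depth=st.integers(20, 400),
        stricter_alt=st.integers(0, 5), p_factor=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_stringency(self, alt, depth, stricter_alt, p_factor):
        """Raising thresholds never adds a rescued presence."""
        alt = min(alt, depth)
        m = merged_record([True, False], [50, alt], [120, depth])
        base = RescueParams()
        strict = RescueParams(
            min_alt_reads=base.min_alt_reads + stricter_alt,
            max_binomial_p=base.max_binomial_p * p_factor,
        )
        loose_presence = forced_call_rescue(m, base).presence[1]
        strict_presence = forced_call_rescue(m, strict).presence[1]
        assert not (strict_presence and not loose_presence)


class TestClassify:
    @pytest.mark.parametrize("presence,expected", [
        ((1, 1, 1), CLONAL),
        ((1, 0, 0, 0), PRIVATE),
        ((1, 1, 0), SUBCLONAL),
        ((0, 0), NONE),
        ((1,), NONE),       # single-biopsy patient: clonality unassessable
    ])
    def test_examples(self, presence, expected):
        assert classify_clonality([bool(b) for b in presence]) == expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            classify_clonality([])

    def test_matches_exhaustive_definition_oracle(self):
        """Agreement with brute-force label rules over all vectors, n <= 6."""
        for n in range(1, 7):
            for bits in itertools.product([False, True], repeat=n):
                k = sum(bits)
                if n == 1 or k == 0:
                    expected = NONE
                elif k == n:
                    expected = CLONAL
                elif k == 1:
                    expected = PRIVATE
                else:
                    expected = SUBCLONAL
                assert classify_clonality(list(bits)) == expected


class TestSummary:
    def make_variants(self, counts):
        out = []
        for label, n in counts.items():
            presence = {CLONAL: [True, True], SUBCLONAL: [True, True, False],
                        PRIVATE: [True, False]}[label]
            for i in range(n):
                m = merged_record(presence, [10] * len(presence), [100] * len(presence))
                m.clonality = label
                out.append(m)
        return out

    def test_printed_cohort_percentages(self):
        """428/213/685 of 1,326 give 32% / 16% / 52%."""
        variants = self.make_variants({CLONAL: 428, SUBCLONAL: 213, PRIVATE: 685})
        subtypes = {f"P{i}": "GS" for i in range(32)}
        for i, m in enumerate(variants):
            m.patient_id = f"P{i % 32}"
        s = clonality_summary(variants, subtypes)
        assert s.counts[CLONAL] == 428 and s.n_classified == 1326
        assert s.percents == {CLONAL: 32, SUBCLONAL: 16, PRIVATE: 52}
        assert round(s.mean_per_patient[CLONAL], 1) == 13.4
        assert round(s.mean_per_patient[SUBCLONAL]) == 7
        assert round(s.mean_per_patient[PRIVATE]) == 21

    def test_empty_cohort_all_zero(self):
        s = clonality_summary([], {})
        assert s.counts[CLONAL] == 0
        assert s.percents == {CLONAL: 0, SUBCLONAL: 0, PRIVATE: 0}

    def test_unclassified_variant_rejected(self):
        m = merged_record([True, True], [10, 10], [100, 100])
        with pytest.raises(ValueError, match="unclassified"):
            clonality_summary([m])


class TestSyntheticRecovery:
    def test_no_censoring_recovers_truth_exactly(self, uncensored_cohort,
                                                 truth_lookup):
        merged = classify_cohort(uncensored_cohort, rescue=None)
        truth = truth_lookup(uncensored_cohort)
        multi = [m for m in merged if len(m.biopsy_order) > 1]
        assert multi
        assert all(m.clonality == truth[(m.patient_id,) + m.key] for m in multi)

    def test_rescue_recovers_censored_clonal_labels(self, censored_cohort,
                                                    truth_lookup):
        truth = truth_lookup(censored_cohort)

        def clonal_recovery(rescue):
            merged = classify_cohort(censored_cohort, rescue=rescue)
            hits = total = 0
            for m in merged:
                if truth[(m.patient_id,) + m.key] == CLONAL and len(m.biopsy_order) > 1:
                    total += 1
                    hits += m.clonality == CLONAL
            return hits / total

        without = clonal_recovery(None)
        with_rescue = clonal_recovery(RescueParams())
        assert with_rescue > without

    def test_rescue_never_promotes_private_without_error(self, truth_lookup):
        from mrith.simulate import SimulationConfig, simulate_cohort

        cohort = simulate_cohort(SimulationConfig(
            seed=23, purity_range=(0.03, 0.25), error_rate=0.0, n_patients=16))
        truth = truth_lookup(cohort)
        merged = classify_cohort(cohort, rescue=RescueParams())
        for m in merged:
            if truth[(m.patient_id,) + m.key] == PRIVATE:
                assert m.clonality != CLONAL
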