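import numpy as np
import pytest

from mrith.contexts import CONTEXT_LABELS, LABEL_INDEX, substitution_class
from mrith.io import VariantCall
from mrith.signatures import (SignatureCatalog, SpectrumVector, count_contexts,
                              refit_signatures, stratified_signatures,
                              synthetic_catalog)
from mrith.simulate import SimulationConfig, simulate_cohort, simulate_spectrum
from tests.conftest import classify_cohort


def snv(ref, alt, ctx, biopsy="B1"):
    return VariantCall(biopsy_id=biopsy, patient_id="P1", chrom="chr1", pos=10,
                       ref=ref, alt=alt, trinucleotide_context=ctx,
                       alt_reads=10, depth=100)


class TestContexts:
    def test_pyrimidine_reference_binned_directly(self):
        assert substitution_class("C", "A", "ACA") == "A[C>A]A"

    def test_purine_reference_reverse_complemented(self):
        # G>T at TGT is A[C>A]A on the pyrimidine strand
        assert substitution_class("G", "T", "TGT") == "A[C>A]A"

    def test_labels_are_96_lexicographic(self):
        assert len(CONTEXT_LABELS) == 96
        assert list(CONTEXT_LABELS) == sorted(CONTEXT_LABELS)

    def test_middle_base_mismatch_rejected(self):
        with pytest.raises(ValueError, match="middle"):
            substitution_class("C", "A", "AAA")


class TestCountContexts:
    def test_binning_and_reverse_complement(self):
        spectrum, skipped = count_contexts(
            [snv("C", "A", "ACA"), snv("G", "T", "TGT")])
        assert skipped == 0
        assert spectrum.counts[LABEL_INDEX["A[C>A]A"]] == 2
        assert spectrum.n_mutations == 2

    def test_indels_and_missing_context_skipped(self):
        ins = VariantCall(biopsy_id="B1", patient_id="P1", chrom="chr1", pos=5,
                          ref="A", alt="AT", alt_reads=5, depth=50)
        no_ctx = VariantCall(biopsy_id="B1", patient_id="P1", chrom="chr1",
                             pos=6, ref="C", alt="T", alt_reads=5, depth=50)
        spectrum, skipped = count_contexts([ins, no_ctx, snv("C", "T", "GCG")])
        assert skipped == 2
        assert spectrum.n_mutations == 1

    def test_totals_conserved(self):
        variants = [snv("C", "A", "ACA")] * 5 + [
            VariantCall(biopsy_id="B1", patient_id="P1", chrom="chr1", pos=5,
                        ref="A", alt="AT", alt_reads=5, depth=50)] * 2
        spectrum, skipped = count_contexts(variants)
        assert spectrum.n_mutations + skipped == 7

    def test_mismatched_context_is_error(self):
        with pytest.raises(ValueError):
            count_contexts([snv("C", "A", "ATA")])


class TestCatalog:
    def test_columns_stochastic(self, catalog):
        assert catalog.matrix.shape == (96, 11)
        assert np.allclose(catalog.matrix.sum(axis=0), 1.0)
        assert (catalog.matrix >= 0).all()

    def test_deterministic(self):
        a, b = synthetic_catalog(), synthetic_catalog()
        assert np.array_equal(a.matrix, b.matrix)

    def test_tsv_round_trip(self, catalog, tmp_path):
        from mrith.io import read_signature_catalog, write_signature_catalog

        path = tmp_path / "cat.tsv"
        write_signature_catalog(catalog, path)
        back = read_signature_catalog(path)
        assert back.names == catalog.names
        assert np.allclose(back.matrix, catalog.matrix)


class TestSimulateSpectrum:
    def test_single_signature_matches_expectation(self, catalog):
        n = 100_000
        sp = simulate_spectrum({"SBS1": 1.0}, n, catalog, seed=1)
        expected = catalog.column("SBS1") * n
        se = np.sqrt(expected * (1 - catalog.column("SBS1")))
        assert (np.abs(sp.counts - expected) <= 4 * se + 1).all()

    def test_zero_mutations_rejected(self, catalog):
        with pytest.raises(ValueError):
            simulate_spectrum({"SBS1": 1.0}, 0, catalog)

    def test_length_mismatch_rejected(self, catalog):
        with pytest.raises(ValueError, match="length"):
            simulate_spectrum([0.5, 0.5], 100, catalog)

    def test_disjoint_mixture_splits_mass(self):
        # two toy signatures with disjoint supports, equal weights
        m = np.zeros((96, 2))
        m[:48, 0] = 1 / 48
        m[48:, 1] = 1 / 48
        toy = SignatureCatalog(names=("S1", "S2"), matrix=m)
        sp = simulate_spectrum({"S1": 0.5, "S2": 0.5}, 40_000, toy, seed=2)
        half = sp.counts[:48].sum()
        assert abs(half - 20_000) < 4 * np.sqrt(40_000 * 0.25)


class TestRefit:
    def test_exact_column_recovered(self, catalog):
        sp = SpectrumVector(np.round(catalog.column("SBS18") * 1e5).astype(int))
        fit = refit_signatures(sp, catalog)
        assert fit.as_dict() == {"SBS18": 1.0}
        assert fit.residual_sse < 1e-6

    def test_two_component_recovery(self, catalog):
        sp = simulate_spectrum({"SBS1": 0.7, "SBS4": 0.3}, 10_000, catalog, seed=3)
        fit = refit_signatures(sp, catalog).as_dict()
        assert set(fit) == {"SBS1", "SBS4"}
        assert fit["SBS1"] == pytest.approx(0.7, abs=0.03)
        assert fit["SBS4"] == pytest.approx(0.3, abs=0.03)

    def test_minor_component_below_cutoff_dropped(self, catalog):
        sp = simulate_spectrum({"SBS1": 0.95, "SBS3": 0.05}, 10_000, catalog, seed=4)
        assert refit_signatures(sp, catalog).as_dict() == {"SBS1": 1.0}

    def test_asymptotic_three_component_consistency(self, catalog):
        # noiseless large-n mixture; tight tol isolates estimator bias from
        # the early-stopping rule
        truth = {"SBS1": 0.5, "SBS21": 0.3, "SBS24": 0.2}
        expected = catalog.mixture(truth) * 100_000
        sp = SpectrumVector(np.round(expected).astype(int))
        fit = refit_signatures(sp, catalog, tol=1e-8).as_dict()
        for name, w in truth.items():
            assert fit[name] == pytest.approx(w, abs=0.02)

    def test_weights_sum_to_one_and_respect_cutoff(self, catalog):
        rng = np.random.default_rng(6)
        for _ in range(5):
            w = rng.dirichlet(np.ones(3))
            truth = dict(zip(("SBS1", "SBS5", "SBS15"), w))
            sp = simulate_spectrum(truth, 5000, catalog, seed=int(rng.integers(1e6)))
            fit = refit_signatures(sp, catalog)
            nz = fit.weights[fit.weights > 0]
            assert nz.sum() == pytest.approx(1.0)
            assert (nz >= 0.06).all()

    def test_too_few_mutations_rejected(self, catalog):
        sp = SpectrumVector(np.eye(96, dtype=int)[:, 0] * 5)
        with pytest.raises(ValueError, match="at least 20"):
            refit_signatures(sp, catalog)


@pytest.fixture(scope="module")
def big_mss_cohort():
    # one MSS subtype only, enough patients to pool >= 2,000 clonal SNVs
    cfg = SimulationConfig(
        seed=29, n_patients=400, msi_n_loci=25,
        subtype_probs={"EBV": 0.0, "MSI": 0.0, "CIN": 0.0, "GS": 1.0},
    )
    return simulate_cohort(cfg)


class TestStratified:
    def test_recovers_generator_mixtures(self, big_mss_cohort):
        merged = classify_cohort(big_mss_cohort, rescue=None)
        fits = {(f.group, f.stratum): f
                for f in stratified_signatures(merged, big_mss_cohort.catalog,
                                               tol=1e-5)}
        cfg = big_mss_cohort.config
        for stratum, table in (("clonal", cfg.signature_weights_clonal),
                               ("nonclonal", cfg.signature_weights_nonclonal)):
            fit = fits[("all", stratum)]
            assert fit.status == "fitted" and fit.n_mutations >= 2000
            recovered = fit.weights.as_dict()
            for name, w in table["GS"].items():
                assert recovered.get(name, 0.0) == pytest.approx(w, abs=0.05)

    def test_all_in_one_stratum_marks_other_insufficient(self, catalog):
        sp_variants = []
        for i in range(50):
            v = snv("C", "T", "ACG")
            m = type("M", (), {})()
            m.patient_id = "P1"
            m.clonality = "CLONAL"
            m.ref, m.alt = v.ref, v.alt
            m.trinucleotide_context = v.trinucleotide_context
            sp_variants.append(m)
        fits = {f.stratum: f for f in stratified_signatures(sp_variants, catalog)}
        assert fits["clonal"].status == "fitted"
        assert fits["nonclonal"].status == "insufficient"

    def test_one_row_per_group_and_stratum(self, default_cohort):
        merged = classify_cohort(default_cohort, rescue=None)
        subtype_of = default_cohort.true_subtypes
        fits = stratified_signatures(merged, default_cohort.catalog,
                                     group_of=subtype_of)
        seen = {(f.group, f.stratum) for f in fits}
        for st in set(subtype_of.values()):
            assert (st, "clonal") in seen and (st, "nonclonal") in seen
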