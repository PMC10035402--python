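import pytest

import mrith
from mrith.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort_patients():
    """The bundled 32-patient clinical cohort table."""
    return mrith.read_cohort_table(mrith.example_cohort_path())


@pytest.fixture(scope="session")
def catalog():
    return mrith.synthetic_catalog()


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size synthetic cohort under default study conditions."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def uncensored_cohort():
    """No caller threshold: the observed presence equals the truth."""
    return simulate_cohort(SimulationConfig(seed=13, caller_min_alt=0))


@pytest.fixture(scope="session")
def censored_cohort():
    """Low purity pushes clonal VAFs under the caller threshold, creating
    the pseudoheterogeneity the forced-call rescue targets."""
    return simulate_cohort(
        SimulationConfig(seed=17, purity_range=(0.03, 0.25))
    )


def classify_cohort(cohort, rescue):
    """Merge + (optional rescue) + classify every patient of a cohort."""
    from mrith.clonality import classify_merged, merge_patient_variants

    merged = []
    for pid in sorted(cohort.variant_calls):
        m = merge_patient_variants(cohort.variant_calls[pid], cohort.biopsies[pid])
        merged.extend(classify_merged(m, rescue=rescue))
    return merged


@pytest.fixture(scope="session")
def truth_lookup():
    def build(cohort):
        return {(t.patient_id,) + t.key: t.true_label for t in cohort.truth}
    return build
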