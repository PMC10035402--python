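"""Classify clonality across biopsies, with and without forced-call rescue.

Simulates a low-purity cohort where clonal mutations drop below the caller
threshold in some biopsies (pseudoheterogeneity), then compares clonal-label
recovery before and after rescuing censored read evidence.
"""

from mrith.clonality import (RescueParams, classify_merged, clonality_summary,
                             merge_patient_variants)
from mrith.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=5, n_patients=12,
                                          purity_range=(0.03, 0.25)))
truth = {(t.patient_id,) + t.key: t.true_label for t in cohort.truth}

for rescue, tag in ((None, "no rescue "), (RescueParams(), "with rescue")):
    merged = []
    for pid in sorted(cohort.variant_calls):
        m = merge_patient_variants(cohort.variant_calls[pid], cohort.biopsies[pid])
        merged.extend(classify_merged(m, rescue=rescue))
    summary = clonality_summary(merged)
    clonal_truth = [m for m in merged
                    if truth[(m.patient_id,) + m.key] == "CLONAL"]
    hit = sum(m.clonality == "CLONAL" for m in clonal_truth)
    print(f"{tag}: labels {summary.percents}  "
          f"truth-clonal recovered {hit}/{len(clonal_truth)}")

# The rescued run recovers substantially more of the truly clonal mutations:
# apparent subclonality caused by censored low-VAF reads, not true absence.
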