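"""mrith: multiregional intratumoral-heterogeneity analysis of tumor panels.

Per-variant clonality classification across spatially separated biopsies
(with forced-call rescue of censored low-VAF evidence), TCGA gastric
molecular subtype assignment, per-patient clonal phylogenies, clonality-
stratified mutational-signature refitting, rule-based pathogenicity and
druggability summaries, and cohort statistics — plus a ground-truth
synthetic cohort generator used throughout the test suite.
"""

from importlib import resources as _resources
from pathlib import Path

__version__ = "0.1.0"

from .clonality import (CLONAL, NONE, PRIVATE, SUBCLONAL, MergedVariant,
                        RescueParams, classify_clonality, classify_merged,
                        clonality_summary, forced_call_rescue,
                        merge_patient_variants)
from .io import (PanelDefinition, ParseError, PatientRecord, ValidationError,
                 VariantCall, read_cohort_table, read_variant_table,
                 write_newick)
from .phylogeny import (ClonalTree, PresencePattern, build_presence_patterns,
                        build_tree, patient_tree, resolve_conflicts)
from .signatures import (SignatureCatalog, SignatureWeights, SpectrumVector,
                         count_contexts, refit_signatures,
                         stratified_signatures, synthetic_catalog)
from .simulate import (SimulationConfig, SyntheticCohort, TruthRecord,
                       simulate_cohort, simulate_spectrum)
from .subtyping import (CNVSegment, MSILocus, SubtypeCall, SubtypeEvidence,
                        SubtypeThresholds, assign_subtype,
                        cnv_altered_fraction, msi_score, subtype_frequencies)


def example_cohort_path() -> Path:
    """Path to the bundled 32-patient clinical cohort table."""
    return Path(str(_resources.files("mrith").joinpath("data/gastric_cohort.tsv")))
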