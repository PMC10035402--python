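"""Synthetic multiregion gastric-tumor cohorts with known ground truth.

The generator emulates the shape of a multiregion panel study: each patient
carries 2-6 spatially separated tumor biopsies sequenced at ~336x; the
patient's molecular subtype sets a Poisson mutation burden (MSI tumors
hypermutated) and a clonal fraction; each mutation is truly CLONAL (all
biopsies), SUBCLONAL (a uniform random proper subset of >= 2 biopsies) or
PRIVATE (one biopsy); observed read counts follow a diploid VAF model
(expected VAF = purity x CCF / 2) with binomial sampling over
Poisson-distributed depths, and a simple caller threshold on mutant reads
reproduces the low-VAF censoring ("pseudoheterogeneity") the forced-call
rescue targets.  Trinucleotide contexts are drawn from clonality-stratum
signature mixtures; MSI patients get shifted microsatellite length
histograms, CIN patients amplified/deleted segments, EBV patients elevated
EBV read fractions.

All randomness flows from a single NumPy generator seeded by
``SimulationConfig.seed``; draws are consumed in a fixed documented order
(patient loop: demographics, biopsies, purities, mutations, evidence), so
equal configs give identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from . import contexts
from .io import PanelDefinition, PatientRecord, VariantCall
from .signatures import SignatureCatalog, SpectrumVector, synthetic_catalog
from .subtyping import CNVSegment, MSILocus

SUBTYPES = ("EBV", "MSI", "CIN", "GS")


class ConfigError(ValueError):
    pass


def _default_subtype_probs() -> dict[str, float]:
    # observed cohort composition: 2/4/12/14 of 32
    return {"EBV": 2 / 32, "MSI": 4 / 32, "CIN": 12 / 32, "GS": 14 / 32}


def _default_burden() -> dict[str, float]:
    return {"MSI": 170.0, "EBV": 25.0, "CIN": 26.0, "GS": 22.0}


def _default_clonal_fraction() -> dict[str, float]:
    return {"EBV": 0.34, "MSI": 0.36, "CIN": 0.27, "GS": 0.27}


def _default_clonal_weights() -> dict[str, dict[str, float]]:
    mss_clonal = {"SBS1": 0.30, "SBS3": 0.20, "SBS4": 0.15, "SBS5": 0.25, "SBS10b": 0.10}
    return {
        "EBV": dict(mss_clonal),
        "CIN": {"SBS1": 0.35, "SBS3": 0.25, "SBS4": 0.15, "SBS5": 0.25},
        "GS": {"SBS1": 0.30, "SBS3": 0.20, "SBS5": 0.25, "SBS10b": 0.25},
        "MSI": {"SBS1": 0.30, "SBS15": 0.40, "SBS26": 0.30},
    }


def _default_nonclonal_weights() -> dict[str, dict[str, float]]:
    mss_nonclonal = {
        "SBS3": 0.15, "SBS4": 0.15, "SBS5": 0.20, "SBS6": 0.10,
        "SBS15": 0.10, "SBS18": 0.15, "SBS24": 0.15,
    }
    return {
        "EBV": dict(mss_nonclonal),
        "CIN": dict(mss_nonclonal),
        "GS": dict(mss_nonclonal),
        "MSI": {"SBS1": 0.20, "SBS4": 0.15, "SBS6": 0.15,
                "SBS15": 0.20, "SBS21": 0.15, "SBS26": 0.15},
    }


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort (defaults mirror the cohort
    shape of a 32-patient multiregion gastric panel study)."""

    n_patients: int = 32
    biopsies_per_patient: tuple[int, int] = (2, 6)
    subtype_probs: dict[str, float] = field(default_factory=_default_subtype_probs)
    burden_per_subtype: dict[str, float] = field(default_factory=_default_burden)
    clonal_fraction_per_subtype: dict[str, float] = field(
        default_factory=_default_clonal_fraction)
    # remainder of non-clonal mass split subclonal:private as observed cohort-wide
    subclonal_private_split: tuple[float, float] = (16.0, 52.0)
    purity_range: tuple[float, float] = (0.3, 0.7)
    mean_depth: float = 336.0
    error_rate: float = 0.001
    caller_min_alt: int = 8
    signature_weights_clonal: dict[str, dict[str, float]] = field(
        default_factory=_default_clonal_weights)
    signature_weights_nonclonal: dict[str, dict[str, float]] = field(
        default_factory=_default_nonclonal_weights)
    indel_fraction: float = 0.10
    snv_silent_prob: float = 0.45
    msi_n_loci: int = 100
    msi_locus_reads: int = 200
    msi_unstable_fraction: float = 0.20
    msi_shift: int = 3
    cin_altered_fraction: float = 0.35
    cin_min_log2: float = 0.58
    ebv_fraction_range: tuple[float, float] = (0.005, 0.02)
    ebv_background_max: float = 2e-5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        lo, hi = self.biopsies_per_patient
        if lo < 1 or hi < lo:
            raise ConfigError(f"bad biopsies_per_patient range ({lo}, {hi})")
        total = sum(self.subtype_probs.get(s, 0.0) for s in SUBTYPES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"subtype_probs sum to {total}, not 1")
        if not (0 < self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ConfigError(f"purity_range {self.purity_range} outside (0, 1]")
        for s in SUBTYPES:
            if self.burden_per_subtype[s] <= 0:
                raise ConfigError(f"non-positive burden for {s}")
            f = self.clonal_fraction_per_subtype[s]
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"clonal fraction for {s} outside [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated variant (for recovery-based tests)."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    true_label: str                     # CLONAL / SUBCLONAL / PRIVATE
    stratum: str                        # "clonal" / "nonclonal"
    true_stratum_weights: tuple[tuple[str, float], ...]
    true_ccf: tuple[tuple[str, float], ...]   # biopsy_id -> CCF

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus ground truth."""

    config: SimulationConfig
    catalog: SignatureCatalog
    panel: PanelDefinition
    patients: list[PatientRecord]
    biopsies: dict[str, list[str]]
    variant_calls: dict[str, list[VariantCall]]
    cnv_segments: dict[str, list[CNVSegment]]
    msi_loci: dict[str, list[MSILocus]]
    ebv_fractions: dict[str, dict[str, float]]
    truth: list[TruthRecord]

    @property
    def true_subtypes(self) -> dict[str, str]:
        return {p.patient_id: p.subtype_assigned for p in self.patients}


def make_panel(n_genes: int = 150, region_bp: int = 25_000,
               seed: int = 4242) -> PanelDefinition:
    """A synthetic capture panel: ``n_genes`` single-interval genes totalling
    ``n_genes * region_bp`` bases (defaults give 3.75 Mbp), with lognormal
    CDS lengths."""
    rng = np.random.default_rng(seed)
    regions = []
    cds: dict[str, float] = {}
    pos = 1_000_000
    for i in range(n_genes):
        chrom = f"chr{(i % 22) + 1}"
        gene = f"GENE{i + 1:03d}"
        regions.append((chrom, pos + i * 10 * region_bp,
                        pos + i * 10 * region_bp + region_bp))
        cds[gene] = float(np.round(rng.lognormal(mean=0.7, sigma=0.6), 3))
    return PanelDefinition(target_regions=tuple(regions), gene_cds_kbp=cds)


def _proper_subsets(n: int) -> list[tuple[int, ...]]:
    """All biopsy-index subsets of size >= 2 and < n."""
    out = []
    for size in range(2, n):
        out.extend(combinations(range(n), size))
    return out


def _draw_demographics(rng: np.random.Generator, pid: str, subtype: str) -> PatientRecord:
    country = rng.choice(["Colombia", "Mexico", "USA"], p=[0.6, 0.28, 0.12])
    ethnicity = "Latino" if country != "USA" else rng.choice(["Latino", "White"])
    sex = "M" if rng.random() < 0.59 else "F"
    age = int(np.clip(rng.normal(60, 13), 25, 95))
    histology = rng.choice(["intestinal", "diffuse", "mixed"], p=[0.45, 0.40, 0.15])
    stage = rng.choice(["IB", "IIB", "IIIA", "IIIB", "IIIC", "IV"],
                       p=[0.08, 0.16, 0.12, 0.24, 0.12, 0.28])
    return PatientRecord(
        patient_id=pid, subtype_assigned=subtype,
        hpylori="yes" if rng.random() < 0.2 else "no",
        country=str(country), ethnicity=str(ethnicity), sex=str(sex),
        age=age, histology=str(histology), anatomic_site=None, stage=str(stage),
    )


def _draw_variant_identity(rng: np.random.Generator, panel: PanelDefinition,
                           genes: list[str], mixture: np.ndarray,
                           is_indel: bool, used: set) -> tuple:
    """(chrom, pos, ref, alt, gene, context) with a patient-unique key."""
    for _ in range(1000):
        gi = int(rng.integers(len(genes)))
        chrom, start, end = panel.target_regions[gi]
        pos = int(rng.integers(start + 2, end - 2)) + 1   # 1-based
        if is_indel:
            ref_base = "ACGT"[int(rng.integers(4))]
            ins = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + ins
            else:
                ref, alt = ref_base + ins, ref_base
            ctx = None
        else:
            ci = int(rng.choice(contexts.N_CONTEXTS, p=mixture))
            label = contexts.CONTEXT_LABELS[ci]
            five, ref, alt, three = contexts.label_parts(label)
            ctx = five + ref + three
            if rng.random() < 0.5:       # record on the purine strand
                ctx = contexts.revcomp(ctx)
                ref = contexts.revcomp(ref)
                alt = contexts.revcomp(alt)
        key = (chrom, pos, ref, alt)
        if key not in used:
            used.add(key)
            return chrom, pos, ref, alt, genes[gi], ctx
    raise RuntimeError("could not draw a unique variant key")


def _draw_effect(rng: np.random.Generator, is_indel: bool, silent_prob: float) -> str:
    if is_indel:
        return "frameshift" if rng.random() < 0.8 else "inframe_indel"
    if rng.random() < silent_prob:
        return "silent"
    r = rng.random()
    if r < 0.85:
        return "missense"
    if r < 0.95:
        return "nonsense"
    return "splice"


def simulate_cohort(config: SimulationConfig,
                    catalog: SignatureCatalog | None = None,
                    panel: PanelDefinition | None = None) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort under ``config``.

    See the module docstring for the generative model.  Raises
    :class:`ConfigError` on invalid configuration.
    """
    config.validate()
    catalog = catalog or synthetic_catalog()
    panel = panel or make_panel()
    genes = list(panel.gene_cds_kbp)
    rng = np.random.default_rng(config.seed)

    sub_p = np.array([config.subtype_probs[s] for s in SUBTYPES])
    sc, pv = config.subclonal_private_split
    split = np.array([sc, pv]) / (sc + pv)

    mixtures: dict[tuple[str, str], np.ndarray] = {}
    weight_items: dict[tuple[str, str], tuple[tuple[str, float], ...]] = {}
    for st in SUBTYPES:
        for stratum, table in (("clonal", config.signature_weights_clonal),
                               ("nonclonal", config.signature_weights_nonclonal)):
            w = table[st]
            mixtures[(st, stratum)] = catalog.mixture(w)
            weight_items[(st, stratum)] = tuple(sorted(w.items()))

    patients: list[PatientRecord] = []
    biopsies: dict[str, list[str]] = {}
    variant_calls: dict[str, list[VariantCall]] = {}
    cnv: dict[str, list[CNVSegment]] = {}
    msi: dict[str, list[MSILocus]] = {}
    ebv: dict[str, dict[str, float]] = {}
    truth: list[TruthRecord] = []

    lo, hi = config.biopsies_per_patient
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        subtype = str(rng.choice(SUBTYPES, p=sub_p))
        patients.append(_draw_demographics(rng, pid, subtype))
        n_biop = int(rng.integers(lo, hi + 1))
        bids = [f"{pid}_T{k + 1}" for k in range(n_biop)]
        biopsies[pid] = bids
        purity = rng.uniform(*config.purity_range, size=n_biop)

        n_mut = int(rng.poisson(config.burden_per_subtype[subtype]))
        cf = config.clonal_fraction_per_subtype[subtype]
        label_p = np.array([cf, (1 - cf) * split[0], (1 - cf) * split[1]])
        subsets = _proper_subsets(n_biop)
        used: set = set()
        calls: list[VariantCall] = []
        for _ in range(n_mut):
            label = ("CLONAL", "SUBCLONAL", "PRIVATE")[
                int(rng.choice(3, p=label_p))]
            if label == "CLONAL":
                carrier = set(range(n_biop))
            elif label == "SUBCLONAL" and subsets:
                carrier = set(subsets[int(rng.integers(len(subsets)))])
            else:
                label = "PRIVATE" if n_biop > 1 else "CLONAL"
                carrier = {int(rng.integers(n_biop))}
                if n_biop == 1:
                    carrier = {0}
            stratum = "clonal" if label == "CLONAL" else "nonclonal"
            is_indel = rng.random() < config.indel_fraction
            chrom, pos, ref, alt, gene, ctx = _draw_variant_identity(
                rng, panel, genes, mixtures[(subtype, stratum)], is_indel, used)
            effect = _draw_effect(rng, is_indel, config.snv_silent_prob)
            ccf = {bids[b]: (1.0 if b in carrier else 0.0) for b in range(n_biop)}
            truth.append(TruthRecord(
                patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                true_label=label, stratum=stratum,
                true_stratum_weights=weight_items[(subtype, stratum)],
                true_ccf=tuple(ccf.items()),
            ))
            for b in range(n_biop):
                depth = max(1, int(rng.poisson(config.mean_depth)))
                if b in carrier:
                    vaf = purity[b] * 1.0 / 2.0
                    alt_reads = int(rng.binomial(depth, min(vaf, 1.0)))
                else:
                    alt_reads = int(rng.binomial(depth, config.error_rate))
                called = (b in carrier) and alt_reads >= config.caller_min_alt
                calls.append(VariantCall(
                    biopsy_id=bids[b], patient_id=pid, chrom=chrom, pos=pos,
                    ref=ref, alt=alt, gene=gene, effect=effect,
                    trinucleotide_context=ctx, alt_reads=alt_reads,
                    depth=depth, called=called,
                ))
        variant_calls[pid] = calls

        # --- subtype evidence ---------------------------------------------
        # CNV segments: CIN patients get clonal +-log2 >= cin_min_log2
        # segments over randomly chosen panel regions until the target
        # altered fraction is covered; others get small sub-threshold noise.
        segs: list[CNVSegment] = []
        region_order = rng.permutation(len(panel.target_regions))
        if subtype == "CIN":
            covered = 0
            target = config.cin_altered_fraction * panel.target_bases
            for ri in region_order:
                if covered >= target:
                    break
                chrom, s, e = panel.target_regions[ri]
                mag = config.cin_min_log2 + rng.uniform(0.0, 0.9)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                for bid in bids:
                    segs.append(CNVSegment(chrom=chrom, start=s, end=e,
                                           log2_ratio=sign * mag, biopsy_id=bid))
                covered += e - s
        else:
            for ri in region_order[:3]:
                chrom, s, e = panel.target_regions[ri]
                small = rng.uniform(-0.15, 0.15)
                for bid in bids:
                    segs.append(CNVSegment(chrom=chrom, start=s, end=e,
                                           log2_ratio=float(small), biopsy_id=bid))
        cnv[pid] = segs

        # MSI locus histograms: multinomial reads over a 3-length normal
        # profile; unstable loci of MSI patients shift the tumor mass.
        base_profile = np.array([0.2, 0.5, 0.3])
        base_lengths = np.array([14, 15, 16])
        n_unstable = (round(config.msi_unstable_fraction * config.msi_n_loci)
                      if subtype == "MSI" else 0)
        loci: list[MSILocus] = []
        for li in range(config.msi_n_loci):
            normal_counts = rng.multinomial(config.msi_locus_reads, base_profile)
            tumor_lengths = (base_lengths - config.msi_shift
                             if li < n_unstable else base_lengths)
            tumor_counts = rng.multinomial(config.msi_locus_reads, base_profile)
            tumor = {int(l): int(c) for l, c in zip(tumor_lengths, tumor_counts)}
            normal = {int(l): int(c) for l, c in zip(base_lengths, normal_counts)}
            loci.append(MSILocus(locus_id=f"MS{li + 1:04d}",
                                 tumor_hist=tumor, normal_hist=normal))
        msi[pid] = loci

        # EBV on-target read fractions
        if subtype == "EBV":
            ebv[pid] = {bid: float(rng.uniform(*config.ebv_fraction_range))
                        for bid in bids}
        else:
            ebv[pid] = {bid: float(rng.uniform(0.0, config.ebv_background_max))
                        for bid in bids}

    return SyntheticCohort(
        config=config, catalog=catalog, panel=panel, patients=patients,
        biopsies=biopsies, variant_calls=variant_calls, cnv_segments=cnv,
        msi_loci=msi, ebv_fractions=ebv, truth=truth,
    )


def simulate_spectrum(weights: Mapping[str, float] | Sequence[float],
                      n_mutations: int, catalog: SignatureCatalog,
                      seed: int | np.random.Generator = 0) -> SpectrumVector:
    """Multinomial spectrum of ``n_mutations`` draws from a signature mixture."""
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    if not isinstance(weights, Mapping):
        w = np.asarray(weights, dtype=float)
        if w.shape != (catalog.n_signatures,):
            raise ValueError(
                f"weight vector length {w.shape} does not match catalog "
                f"({catalog.n_signatures} signatures)"
            )
        weights = dict(zip(catalog.names, w))
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {total}, not 1")
    probs = catalog.mixture(weights)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SpectrumVector(rng.multinomial(n_mutations, probs))


def truth_label_fractions(truth: Sequence[TruthRecord]) -> dict[str, float]:
    """Empirical CLONAL/SUBCLONAL/PRIVATE fractions of a truth set."""
    n = len(truth)
    out = {"CLONAL": 0, "SUBCLONAL": 0, "PRIVATE": 0}
    for t in truth:
        out[t.true_label] += 1
    return {k: (v / n if n else 0.0) for k, v in out.items()}


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a config from a plain (YAML/JSON-loaded) mapping."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("biopsies_per_patient", "purity_range", "ebv_fraction_range",
                "subclonal_private_split"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)
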