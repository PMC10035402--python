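"""Rule-based pathogenicity, druggability, and gene-burden summaries.

A change is "likely pathogenic" when any of five clauses fires: it is a
loss-of-function mutation (nonsense, frameshift, or splice), a known cancer
hotspot, annotated pathogenic in ClinVar, an amplification of a known
oncogene, or a complete deletion of the gene or of its wild-type allele.
Hotspot/ClinVar/oncogene/druggable membership arrives as user-supplied
resource files; nothing is downloaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

LOF_EFFECTS = frozenset({"nonsense", "frameshift", "splice"})

LOF = "LOF"
HOTSPOT = "HOTSPOT"
CLINVAR = "CLINVAR"
ONCOGENE_AMP = "ONCOGENE_AMP"
COMPLETE_DELETION = "COMPLETE_DELETION"


@dataclass
class AnnotationResources:
    """Exact-match lookup sets used by the pathogenicity rules."""

    hotspot_set: set = field(default_factory=set)           # (gene, pchange) or variant keys
    clinvar_pathogenic_set: set = field(default_factory=set)  # variant keys
    oncogene_set: set = field(default_factory=set)          # gene symbols
    druggable_set: set = field(default_factory=set)         # gene symbols
    driver_sets: dict[str, set] = field(default_factory=dict)

    @staticmethod
    def load_gene_list(path: str | Path) -> set[str]:
        """One gene symbol per line; blank lines and '#' comments ignored."""
        out = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
        return out


@dataclass(frozen=True)
class CNVEvent:
    """A gene-level copy-number event for pathogenicity classification."""

    gene: str
    call: str                        # "gain" | "loss" | "deletion"
    full_gene_or_wt_loss: bool = False   # upstream LOH/whole-gene flag


@dataclass(frozen=True)
class PathogenicityVerdict:
    is_likely_pathogenic: bool
    reasons: frozenset[str]

    def __post_init__(self) -> None:
        if self.is_likely_pathogenic != bool(self.reasons):
            raise ValueError("verdict must be true iff reasons are nonempty")


def classify_pathogenic(event, resources: AnnotationResources) -> PathogenicityVerdict:
    """Evaluate the five-clause likely-pathogenic rule on a variant or CNV event.

    ``event`` is either a variant-like object with ``gene``/``effect``/``key``
    attributes or a :class:`CNVEvent`.
    """
    reasons: set[str] = set()
    if isinstance(event, CNVEvent):
        if event.call == "gain" and event.gene in resources.oncogene_set:
            reasons.add(ONCOGENE_AMP)
        if event.call == "deletion" and event.full_gene_or_wt_loss:
            reasons.add(COMPLETE_DELETION)
    else:
        if event.effect in LOF_EFFECTS:
            reasons.add(LOF)
        key = getattr(event, "key", None)
        if key is not None and key in resources.hotspot_set:
            reasons.add(HOTSPOT)
        gene = getattr(event, "gene", None)
        pchange = getattr(event, "protein_change", None)
        if gene is not None and pchange is not None and (gene, pchange) in resources.hotspot_set:
            reasons.add(HOTSPOT)
        if key is not None and key in resources.clinvar_pathogenic_set:
            reasons.add(CLINVAR)
    return PathogenicityVerdict(
        is_likely_pathogenic=bool(reasons), reasons=frozenset(reasons)
    )


def long_gene_threshold(gene_cds_kbp: Mapping[str, float]
                        ) -> tuple[float, dict[str, bool]]:
    """75th-percentile CDS-length cutoff and per-gene long flags.

    The threshold is the linearly interpolated (type-7) 75th percentile of
    the panel's CDS lengths; a gene is flagged long iff strictly above it.
    Requires at least 4 genes.
    """
    if len(gene_cds_kbp) < 4:
        raise ValueError(f"need >= 4 genes for a quartile cutoff, got {len(gene_cds_kbp)}")
    lengths = np.array(list(gene_cds_kbp.values()), dtype=float)
    threshold = float(np.percentile(lengths, 75, method="linear"))
    flags = {g: l > threshold for g, l in gene_cds_kbp.items()}
    return threshold, flags


def normalized_gene_burden(snv_counts: Mapping[str, int],
                           gene_cds_kbp: Mapping[str, float],
                           include_zero: bool = False) -> dict[str, float]:
    """Per-gene SNV count divided by CDS length in kbp."""
    out: dict[str, float] = {}
    for gene, count in snv_counts.items():
        if gene not in gene_cds_kbp:
            raise ValueError(f"no CDS length for gene {gene!r}")
        out[gene] = count / gene_cds_kbp[gene]
    if include_zero:
        for gene in gene_cds_kbp:
            out.setdefault(gene, 0.0)
    return out


def recurrence_table(merged: Iterable, msi_status: Mapping[str, bool],
                     clonal_only: bool = True, min_patients: int = 3,
                     population: str = "all") -> list[tuple[str, int]]:
    """Genes (non)clonally mutated in at least ``min_patients`` patients.

    Silent effects are excluded; a gene counts each patient once regardless
    of mutation multiplicity.  ``population`` restricts patients to "MSS",
    "MSI", or "all" using ``msi_status`` (patient_id -> True if MSI).
    Output is sorted by descending patient count then gene name.
    """
    if population not in ("MSS", "MSI", "all"):
        raise ValueError(f"unknown population {population!r}")
    patients_by_gene: dict[str, set[str]] = {}
    for m in merged:
        if m.gene is None or m.effect == "silent" or m.clonality in (None, "NONE"):
            continue
        if clonal_only and m.clonality != "CLONAL":
            continue
        if population != "all":
            is_msi = msi_status.get(m.patient_id, False)
            if (population == "MSI") != is_msi:
                continue
        patients_by_gene.setdefault(m.gene, set()).add(m.patient_id)
    rows = [
        (gene, len(pats)) for gene, pats in patients_by_gene.items()
        if len(pats) >= min_patients
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def druggable_summary(merged: Iterable, resources: AnnotationResources,
                      subtype_of: Mapping[str, str],
                      cnv_events: Mapping[str, Sequence[CNVEvent]] | None = None
                      ) -> dict[str, tuple[int, int, int]]:
    """Per subtype: patients with >= 1 clonal likely-pathogenic druggable change.

    Returns subtype -> (qualifying patients, patients of that subtype,
    integer percent).  ``cnv_events`` optionally maps patient_id to
    clonal gene-level CNV events that also count.
    """
    qualifying: set[str] = set()
    for m in merged:
        if m.clonality != "CLONAL" or m.gene not in resources.druggable_set:
            continue
        if classify_pathogenic(m, resources).is_likely_pathogenic:
            qualifying.add(m.patient_id)
    if cnv_events:
        for pid, events in cnv_events.items():
            for ev in events:
                if ev.gene in resources.druggable_set and \
                        classify_pathogenic(ev, resources).is_likely_pathogenic:
                    qualifying.add(pid)
    out: dict[str, tuple[int, int, int]] = {}
    for st in sorted(set(subtype_of.values())):
        members = [p for p, s in subtype_of.items() if s == st]
        num = sum(1 for p in members if p in qualifying)
        pct = _round_half_away(100.0 * num / len(members)) if members else 0
        out[st] = (num, len(members), pct)
    return out
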