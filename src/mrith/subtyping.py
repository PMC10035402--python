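"""TCGA gastric molecular subtype assignment (EBV / MSI / CIN / GS).

Each patient is placed in one of the four TCGA gastric subtypes by a
decision cascade: Epstein-Barr-virus-positive tumors first (on-target EBV
read fraction), then microsatellite-instable tumors (percent of unstable
microsatellite loci), then chromosomal-instability tumors (fraction of the
panel in amplified/deleted segments), with genomically-stable as the
fall-through.

The MSI score is a simplified per-locus test: at each assessable locus the
tumor and normal repeat-length read histograms are compared with a
chi-square homogeneity test (length bins pooled so every expected cell is
at least 1), p-values are Benjamini-Hochberg adjusted across loci, and the
score is the percentage of assessable loci called unstable.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .io import PanelDefinition, ValidationError

SUBTYPE_ORDER = ("EBV", "MSI", "CIN", "GS")


@dataclass
class MSILocus:
    """Tumor and normal repeat-length read histograms at one microsatellite."""

    locus_id: str
    tumor_hist: dict[int, int]
    normal_hist: dict[int, int]
    assessable: bool | None = None   # set during scoring

    def __post_init__(self) -> None:
        for hist in (self.tumor_hist, self.normal_hist):
            for length, count in hist.items():
                if count < 0:
                    raise ValidationError(
                        f"{self.locus_id}: negative read count at length {length}"
                    )

    def totals(self) -> tuple[int, int]:
        return sum(self.tumor_hist.values()), sum(self.normal_hist.values())


@dataclass(frozen=True)
class CNVSegment:
    """One copy-number segment of one biopsy (half-open 0-based)."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    biopsy_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has end <= start"
            )


@dataclass(frozen=True)
class SubtypeEvidence:
    """Patient-level evidence triple feeding the subtype cascade."""

    ebv_read_fraction: float
    msi_score: float                 # percent of unstable assessable loci
    cnv_altered_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ebv_read_fraction <= 1.0):
            raise ValidationError(f"ebv_read_fraction {self.ebv_read_fraction} not in [0,1]")
        if not (0.0 <= self.msi_score <= 100.0):
            raise ValidationError(f"msi_score {self.msi_score} not in [0,100]")
        if not (0.0 <= self.cnv_altered_fraction <= 1.0):
            raise ValidationError(
                f"cnv_altered_fraction {self.cnv_altered_fraction} not in [0,1]"
            )


@dataclass(frozen=True)
class SubtypeThresholds:
    ebv_min: float = 1e-4
    msi_min: float = 3.5
    cin_min: float = 0.20


@dataclass(frozen=True)
class SubtypeCall:
    patient_id: str
    subtype: str
    evidence: SubtypeEvidence
    thresholds: SubtypeThresholds = field(default_factory=SubtypeThresholds)


def _pool_low_expected(table: np.ndarray) -> np.ndarray:
    """Merge adjacent length columns of a 2xL table until expected cells >= 1.

    Greedy: repeatedly merge the column with the smallest total into its
    lower-total neighbor.  Deterministic; returns a 2xL' table, L' >= 1.
    """
    table = table.astype(float)
    while table.shape[1] > 1:
        colsum = table.sum(axis=0)
        rowsum = table.sum(axis=1)
        expected = np.outer(rowsum, colsum) / table.sum()
        if (expected >= 1.0).all():
            break
        j = int(colsum.argmin())
        if j == 0:
            k = 1
        elif j == table.shape[1] - 1:
            k = j - 1
        else:
            k = j - 1 if colsum[j - 1] <= colsum[j + 1] else j + 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def locus_instability_p(locus: MSILocus) -> float:
    """Chi-square homogeneity p-value for tumor vs normal length histograms."""
    lengths = sorted(set(locus.tumor_hist) | set(locus.normal_hist))
    table = np.array(
        [[locus.tumor_hist.get(l, 0) for l in lengths],
         [locus.normal_hist.get(l, 0) for l in lengths]],
        dtype=float,
    )
    # drop all-zero columns, then pool sparse ones
    table = table[:, table.sum(axis=0) > 0]
    if table.size == 0 or table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    table = _pool_low_expected(table)
    if table.shape[1] < 2:
        return 1.0
    _, p, _, _ = chi2_contingency(table, correction=False)
    return float(p)


def msi_score(loci: Sequence[MSILocus], alpha: float = 0.05,
              min_locus_coverage: int = 20, min_assessable_loci: int = 20) -> float:
    """Percent of assessable microsatellite loci whose tumor histogram differs.

    A locus is assessable when both tumor and normal histograms carry at
    least ``min_locus_coverage`` reads.  Instability is a BH-adjusted
    chi-square p below ``alpha``.  Raises ``ValueError`` when fewer than
    ``min_assessable_loci`` loci are assessable.
    """
    assessable: list[MSILocus] = []
    for locus in loci:
        t, n = locus.totals()
        locus.assessable = t >= min_locus_coverage and n >= min_locus_coverage
        if locus.assessable:
            assessable.append(locus)
    if len(assessable) < min_assessable_loci:
        raise ValueError(
            f"only {len(assessable)} assessable loci "
            f"(< {min_assessable_loci} required)"
        )
    pvals = np.array([locus_instability_p(l) for l in assessable])
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return 100.0 * float(reject.sum()) / len(assessable)


def _interval_union_bases(intervals: Iterable[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, s, e in intervals:
        by_chrom[chrom].append((s, e))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def cnv_altered_fraction(segments: Sequence[CNVSegment], panel: PanelDefinition,
                         amp_del_log2: float = 0.3) -> float:
    """Fraction of panel bases inside amplified/deleted segments.

    A segment qualifies when |log2 ratio| >= ``amp_del_log2``; overlapping
    qualifying segments are counted once (interval union), and only the
    overlap with the panel's target regions counts.
    """
    qualifying = [
        (s.chrom, s.start, s.end) for s in segments
        if abs(s.log2_ratio) >= amp_del_log2
    ]
    if not qualifying:
        return 0.0
    seg_union = _interval_union_bases(qualifying)
    panel_union = _interval_union_bases(panel.target_regions)
    covered = 0
    for chrom, panel_ivs in panel_union.items():
        segs = seg_union.get(chrom, [])
        for ps, pe in panel_ivs:
            for ss, se in segs:
                lo, hi = max(ps, ss), min(pe, se)
                if hi > lo:
                    covered += hi - lo
    return covered / panel.target_bases


def assign_subtype(evidence: SubtypeEvidence, patient_id: str = "",
                   thresholds: SubtypeThresholds | None = None) -> SubtypeCall:
    """Run the EBV -> MSI -> CIN -> GS decision cascade on one patient."""
    th = thresholds or SubtypeThresholds()
    if evidence.ebv_read_fraction >= th.ebv_min:
        subtype = "EBV"
    elif evidence.msi_score >= th.msi_min:
        subtype = "MSI"
    elif evidence.cnv_altered_fraction >= th.cin_min:
        subtype = "CIN"
    else:
        subtype = "GS"
    return SubtypeCall(patient_id=patient_id, subtype=subtype,
                       evidence=evidence, thresholds=th)


def patient_evidence(ebv_fractions: Mapping[str, float],
                     msi_score_value: float,
                     per_biopsy_altered: Sequence[float]) -> SubtypeEvidence:
    """Aggregate per-biopsy evidence to the patient level.

    Maximum EBV fraction across biopsies, the (patient-level) MSI score, and
    the mean CNV-altered fraction across biopsies.
    """
    ebv = max(ebv_fractions.values()) if ebv_fractions else 0.0
    cnv = float(np.mean(per_biopsy_altered)) if len(per_biopsy_altered) else 0.0
    return SubtypeEvidence(ebv_read_fraction=ebv, msi_score=msi_score_value,
                           cnv_altered_fraction=cnv)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def subtype_frequencies(subtypes_by_patient: Mapping[str, str],
                        patients: Sequence["object"] | None = None,
                        ethnicity: str | None = None,
                        country: str | None = None) -> dict[str, int]:
    """Percent of patients per subtype, optionally filtered by demographics.

    ``subtypes_by_patient`` maps patient_id -> subtype; ``patients`` (a list
    of :class:`~mrith.io.PatientRecord`) is required when filtering by
    ethnicity or country.  Percentages are rounded half-away-from-zero.
    """
    ids = list(subtypes_by_patient)
    if ethnicity is not None or country is not None:
        if patients is None:
            raise ValueError("patient records required for demographic filtering")
        by_id = {p.patient_id: p for p in patients}
        ids = [
            pid for pid in ids
            if pid in by_id
            and (ethnicity is None or by_id[pid].ethnicity == ethnicity)
            and (country is None or by_id[pid].country == country)
        ]
    if not ids:
        raise ValueError("no patients left after filtering")
    counts = {st: 0 for st in SUBTYPE_ORDER}
    for pid in ids:
        counts[subtypes_by_patient[pid]] += 1
    return {st: _round_half_away(100.0 * counts[st] / len(ids)) for st in SUBTYPE_ORDER}
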