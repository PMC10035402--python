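"""Clonality classification of somatic variants across multiregional biopsies.

A variant found in every tumor biopsy of a patient is CLONAL, in more than
one but not all biopsies SUBCLONAL, in exactly one PRIVATE; aberrant cases
(no presence after merging, or a patient with a single tumor biopsy, where
clonality is unassessable) are NONE.

Apparent absence of a truly clonal mutation in one biopsy can be an artifact
of censoring — allele-specific imbalance, heterogeneous amplification, or
low purity pushing the variant allele fraction below the caller's limit
("pseudoheterogeneity").  :func:`forced_call_rescue` re-examines the raw
read counts of biopsies where a sister biopsy carries the call and marks the
variant present when the mutant-read evidence is inconsistent with
sequencing error alone.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import binom

from .io import VariantCall

logger = logging.getLogger(__name__)

CLONAL = "CLONAL"
SUBCLONAL = "SUBCLONAL"
PRIVATE = "PRIVATE"
NONE = "NONE"
LABELS = (CLONAL, SUBCLONAL, PRIVATE, NONE)


@dataclass
class RescueParams:
    """Thresholds for heuristic forced-call rescue.

    A biopsy absent for a variant called in a sister biopsy is rescued when
    it has at least ``min_depth`` coverage and its mutant reads satisfy all
    of: count >= ``min_alt_reads``, VAF >= ``min_vaf``, and the upper-tail
    binomial probability of that many mutant reads arising from sequencing
    error at ``error_rate`` is <= ``max_binomial_p``.
    """

    min_alt_reads: int = 3
    min_vaf: float = 0.01
    min_depth: int = 20
    max_binomial_p: float = 0.01
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.min_alt_reads < 0 or self.min_depth < 0:
            raise ValueError("read thresholds must be nonnegative")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf must be in [0, 1]")
        if not (0.0 <= self.max_binomial_p <= 1.0) or not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")


@dataclass
class MergedVariant:
    """One distinct variant of one patient, merged across tumor biopsies."""

    chrom: str
    pos: int
    ref: str
    alt: str
    patient_id: str
    biopsy_order: tuple[str, ...]
    presence: list[bool]
    rescued: list[bool]
    alt_reads: list[int]            # -1 where no read data for that biopsy
    depth: list[int]                # -1 where no read data
    gene: str | None = None
    effect: str | None = None
    trinucleotide_context: str | None = None
    clonality: str | None = None
    unevaluable: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.biopsy_order)
        if not (len(self.presence) == len(self.rescued) == len(self.alt_reads)
                == len(self.depth) == n):
            raise ValueError("per-biopsy vectors must match biopsy_order length")
        if not self.unevaluable:
            self.unevaluable = [False] * n
        for i, r in enumerate(self.rescued):
            if r and not self.presence[i]:
                raise ValueError("rescued flag at an absent biopsy")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_present(self) -> int:
        return sum(self.presence)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def presence_mask(self) -> int:
        """Presence vector as a bitmask (bit i = biopsy_order[i])."""
        return sum(1 << i for i, p in enumerate(self.presence) if p)


def merge_patient_variants(calls: Sequence[VariantCall],
                           biopsy_order: Sequence[str]) -> list[MergedVariant]:
    """Merge one patient's per-biopsy calls into per-variant records.

    One :class:`MergedVariant` is produced per distinct ``(chrom, pos, ref,
    alt)`` key, with presence set where the caller emitted the variant and
    read counts carried per biopsy.  Exact duplicates within one biopsy
    collapse to a single presence with a logged warning.
    """
    patient_ids = {c.patient_id for c in calls}
    if len(patient_ids) > 1:
        raise ValueError(f"calls span multiple patients: {sorted(patient_ids)}")
    order = tuple(biopsy_order)
    index = {b: i for i, b in enumerate(order)}
    by_key: dict[tuple[str, int, str, str], list[VariantCall]] = defaultdict(list)
    for c in calls:
        if c.biopsy_id not in index:
            raise ValueError(
                f"call at {c.chrom}:{c.pos} has biopsy_id {c.biopsy_id!r} "
                f"not in biopsy_order"
            )
        by_key[c.key].append(c)

    merged: list[MergedVariant] = []
    for key in sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3])):
        group = by_key[key]
        n = len(order)
        presence = [False] * n
        alt_reads = [-1] * n
        depth = [-1] * n
        seen_biopsies: set[str] = set()
        for c in group:
            i = index[c.biopsy_id]
            if c.biopsy_id in seen_biopsies and c.called:
                logger.warning(
                    "duplicate call for %s:%s %s>%s in biopsy %s; collapsed",
                    c.chrom, c.pos, c.ref, c.alt, c.biopsy_id,
                )
            seen_biopsies.add(c.biopsy_id)
            if c.called:
                presence[i] = True
            alt_reads[i] = c.alt_reads
            depth[i] = c.depth
        first = group[0]
        merged.append(
            MergedVariant(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                patient_id=first.patient_id, biopsy_order=order,
                presence=presence, rescued=[False] * n,
                alt_reads=alt_reads, depth=depth,
                gene=first.gene, effect=first.effect,
                trinucleotide_context=first.trinucleotide_context,
            )
        )
    return merged


def binomial_upper_tail(alt_reads: int, depth: int, error_rate: float) -> float:
    """P(X >= alt_reads) for X ~ Binomial(depth, error_rate)."""
    if alt_reads <= 0:
        return 1.0
    return float(binom.sf(alt_reads - 1, depth, error_rate))


def forced_call_rescue(merged: MergedVariant,
                       params: RescueParams | None = None) -> MergedVariant:
    """Rescue censored presences of a variant called in a sister biopsy.

    Returns a new record; the input is not modified.  Biopsies with depth
    below ``params.min_depth`` (or no read data) are flagged unevaluable and
    left absent.  If no biopsy is present the record is returned unchanged
    with a warning (rescue needs a called sister biopsy).
    """
    params = params or RescueParams()
    if merged.n_present == 0:
        logger.warning(
            "variant %s:%s %s>%s has no called biopsy; rescue skipped",
            merged.chrom, merged.pos, merged.ref, merged.alt,
        )
        return merged
    presence = list(merged.presence)
    rescued = list(merged.rescued)
    unevaluable = list(merged.unevaluable)
    for i in range(len(presence)):
        if presence[i]:
            continue
        d = merged.depth[i]
        a = merged.alt_reads[i]
        if d < params.min_depth or d <= 0:
            unevaluable[i] = True
            continue
        unevaluable[i] = False
        if a < params.min_alt_reads:
            continue
        if a / d < params.min_vaf:
            continue
        if binomial_upper_tail(a, d, params.error_rate) > params.max_binomial_p:
            continue
        presence[i] = True
        rescued[i] = True
    return replace(merged, presence=presence, rescued=rescued, unevaluable=unevaluable)


def classify_clonality(presence: Sequence[bool], n_biopsies: int | None = None) -> str:
    """Assign CLONAL / SUBCLONAL / PRIVATE / NONE from a presence vector.

    With ``k`` present biopsies of ``n``: all present (n >= 2) is CLONAL;
    1 < k < n is SUBCLONAL; k = 1 with n >= 2 is PRIVATE; k = 0 or a
    single-biopsy patient (n = 1) is NONE.
    """
    n = len(presence) if n_biopsies is None else n_biopsies
    if n < 1 or len(presence) != n:
        raise ValueError(f"presence length {len(presence)} != n_biopsies {n} or n < 1")
    k = sum(bool(p) for p in presence)
    if n == 1 or k == 0:
        return NONE
    if k == n:
        return CLONAL
    if k == 1:
        return PRIVATE
    return SUBCLONAL


def classify_merged(merged: Iterable[MergedVariant],
                    rescue: RescueParams | None = None) -> list[MergedVariant]:
    """Rescue (optional) then classify a list of merged variants in place-order.

    Pass ``rescue=None`` to classify the called presence vectors as-is.
    """
    out = []
    for m in merged:
        if rescue is not None and m.n_present > 0:
            m = forced_call_rescue(m, rescue)
        m.clonality = classify_clonality(m.presence)
        out.append(m)
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ClonalitySummary:
    """Cohort-level clonality tallies.

    ``counts`` are per label; ``percents`` are of classified variants (NONE
    excluded from the denominator), rounded half-away-from-zero;
    ``mean_per_patient`` divides by the number of patients.  ``by_subtype``
    maps subtype -> an inner summary of its patients' variants.
    """

    n_patients: int
    counts: dict[str, int]
    percents: dict[str, int]
    fractions: dict[str, float]
    mean_per_patient: dict[str, float]
    by_subtype: dict[str, "ClonalitySummary"] = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return sum(self.counts[l] for l in (CLONAL, SUBCLONAL, PRIVATE))


def _summarize(variants: Sequence[MergedVariant], n_patients: int) -> ClonalitySummary:
    counts = {l: 0 for l in LABELS}
    for m in variants:
        if m.clonality is None:
            raise ValueError(f"unclassified variant {m.key}")
        counts[m.clonality] += 1
    total = sum(counts[l] for l in (CLONAL, SUBCLONAL, PRIVATE))
    fractions = {
        l: (counts[l] / total if total else 0.0) for l in (CLONAL, SUBCLONAL, PRIVATE)
    }
    percents = {l: _round_half_away(100 * fractions[l]) for l in fractions}
    means = {
        l: (counts[l] / n_patients if n_patients else 0.0)
        for l in (CLONAL, SUBCLONAL, PRIVATE)
    }
    return ClonalitySummary(
        n_patients=n_patients, counts=counts, percents=percents,
        fractions=fractions, mean_per_patient=means,
    )


def clonality_summary(variants: Sequence[MergedVariant],
                      patient_subtypes: Mapping[str, str | None] | None = None
                      ) -> ClonalitySummary:
    """Tally clonality labels overall and, if subtypes are given, per subtype.

    ``patient_subtypes`` maps every patient id in the cohort (including
    patients with zero variants) to a subtype or ``None``; it defines the
    per-patient-mean denominators.
    """
    if patient_subtypes is not None:
        patients = set(patient_subtypes)
    else:
        patients = {m.patient_id for m in variants}
    overall = _summarize(variants, len(patients))
    if patient_subtypes is not None:
        groups: dict[str, list[MergedVariant]] = defaultdict(list)
        for m in variants:
            st = patient_subtypes.get(m.patient_id)
            if st is not None:
                groups[st].append(m)
        for st in sorted({s for s in patient_subtypes.values() if s is not None}):
            n_pat = sum(1 for s in patient_subtypes.values() if s == st)
            overall.by_subtype[st] = _summarize(groups.get(st, []), n_pat)
    return overall
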