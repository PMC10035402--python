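"""Cohort-level descriptive and inferential statistics.

Covers the quantities a multiregion panel study reports: per-biopsy
mutation rates over the capture region, demographic summaries (percent
male, mean ages, percent advanced-stage), two-sample Student/Welch t-tests,
and exact tests on r x c contingency tables (the Freeman-Halton extension
of Fisher's exact test, by full enumeration for small tables or Monte Carlo
otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .io import PanelDefinition, PatientRecord


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("contingency counts must be integers")
            object.__setattr__(self, "counts", counts.astype(int))
        if (np.asarray(self.counts) < 0).any() or int(np.asarray(self.counts).sum()) < 1:
            raise ValueError("counts must be nonnegative with total >= 1")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def mutation_rate_per_biopsy(nonsilent_count: int, silent_count: int,
                             panel: PanelDefinition) -> tuple[float, float, float]:
    """(nonsilent, silent, total) mutations per Mbp of the panel target."""
    if nonsilent_count < 0 or silent_count < 0:
        raise ValueError("mutation counts must be nonnegative")
    mbp = panel.target_mbp
    return (nonsilent_count / mbp, silent_count / mbp,
            (nonsilent_count + silent_count) / mbp)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_dropped: int


def two_sample_t(group_a: Sequence[float | None], group_b: Sequence[float | None],
                 variant: str = "pooled") -> TTestResult:
    """Two-sided two-sample t-test, pooled-variance (Student) or Welch.

    Missing values (None/NaN) are dropped and counted; each group must keep
    at least 2 values.
    """
    def clean(g: Sequence) -> np.ndarray:
        return np.array([x for x in g if x is not None and not (
            isinstance(x, float) and math.isnan(x))], dtype=float)

    a, b = clean(group_a), clean(group_b)
    dropped = (len(group_a) - len(a)) + (len(group_b) - len(b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if variant == "pooled":
        t, p = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = float(res.df)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return TTestResult(t=float(t), df=float(df), p=float(p),
                       mean_a=float(a.mean()), mean_b=float(b.mean()),
                       n_dropped=dropped)


def _log_table_prob(counts: np.ndarray) -> float:
    """Log conditional probability of a table given its margins."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
        - gammaln(n + 1) - gammaln(counts + 1).sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(rows), len(cols)
    table = np.zeros((r, c), dtype=int)

    def fill(i: int, remaining_cols: np.ndarray):
        if i == r - 1:
            table[i] = remaining_cols
            yield table
            return
        def fill_row(j: int, row_left: int, cols_left: np.ndarray):
            if j == c - 1:
                if row_left <= cols_left[j]:
                    table[i, j] = row_left
                    new_cols = cols_left.copy()
                    new_cols[j] -= row_left
                    yield from fill(i + 1, new_cols)
                return
            for v in range(min(row_left, cols_left[j]) + 1):
                table[i, j] = v
                new_cols = cols_left.copy()
                new_cols[j] -= v
                yield from fill_row(j + 1, row_left - v, new_cols)
        yield from fill_row(0, rows[i], remaining_cols)

    yield from fill(0, cols.copy())


def fisher_exact(table: ContingencyTable, method: str = "enumerate",
                 seed: int | None = None, n_draws: int = 1_000_000,
                 max_enumerate_n: int = 40) -> float:
    """Two-sided Fisher / Freeman-Halton exact p for an r x c table.

    Probability-ordering rule: p is the total conditional probability of all
    tables with the observed margins whose probability is <= the observed
    table's (with 1e-12 relative slack for ties).  ``method="enumerate"``
    sums over all tables (permitted up to ``max_enumerate_n`` total counts);
    ``method="monte_carlo"`` samples tables with fixed margins by random
    permutation (``n_draws`` draws, seeded).
    """
    counts = np.asarray(table.counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    log_p_obs = _log_table_prob(counts)
    slack = 1e-12

    if method == "enumerate":
        if table.total > max_enumerate_n:
            raise ValueError(
                f"total {table.total} > {max_enumerate_n}: use method='monte_carlo'"
            )
        p = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _log_table_prob(t)
            if lp <= log_p_obs + slack:
                p += math.exp(lp)
        return min(p, 1.0)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        # one categorical row label per observation; columns fixed by position
        row_of = np.repeat(np.arange(len(rows)), rows)
        col_of = np.repeat(np.arange(len(cols)), cols)
        hits = 0
        batch = 10_000
        done = 0
        r, c = len(rows), len(cols)
        while done < n_draws:
            m = min(batch, n_draws - done)
            for _ in range(m):
                perm = rng.permutation(row_of)
                t = np.zeros((r, c), dtype=int)
                np.add.at(t, (perm, col_of), 1)
                if _log_table_prob(t) <= log_p_obs + slack:
                    hits += 1
            done += m
        return hits / n_draws
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CohortSummary:
    n_patients: int
    percent_male: int
    mean_age: float
    mean_age_by_country: dict[str, float]
    percent_advanced_stage: int
    subtype_percents: dict[str, int]
    subtype_percents_latino: dict[str, int] | None = None
    mean_mutations_per_patient: float | None = None
    mean_mutations_per_biopsy: float | None = None
    clonality_percents: dict[str, int] = field(default_factory=dict)


def summarize_cohort(patients: Sequence[PatientRecord],
                     advanced_denominator: str = "known_stage") -> CohortSummary:
    """Demographic and subtype summary of a cohort table.

    "Advanced" means AJCC stage III or IV; the denominator is patients with
    a known stage (``advanced_denominator="known_stage"``) or all patients
    (``"all"``).  Means are over non-missing values; percents are rounded
    half-away-from-zero.
    """
    if not patients:
        raise ValueError("empty cohort")
    n = len(patients)
    males = sum(1 for p in patients if p.sex == "M")
    ages = [p.age for p in patients if p.age is not None]
    mean_age = float(np.mean(ages)) if ages else float("nan")
    by_country: dict[str, list[int]] = {}
    for p in patients:
        if p.age is not None and p.country is not None:
            by_country.setdefault(p.country, []).append(p.age)
    staged = [p for p in patients if p.stage is not None]
    advanced = sum(1 for p in staged if p.stage.startswith(("III", "IV")))
    denom = len(staged) if advanced_denominator == "known_stage" else n
    assigned = {p.patient_id: p.subtype_assigned for p in patients
                if p.subtype_assigned is not None}
    from .subtyping import subtype_frequencies
    subtype_pct = subtype_frequencies(assigned) if assigned else {}
    latino_assigned = {
        p.patient_id: p.subtype_assigned for p in patients
        if p.subtype_assigned is not None and p.ethnicity == "Latino"
    }
    latino_pct = subtype_frequencies(latino_assigned) if latino_assigned else None
    return CohortSummary(
        n_patients=n,
        percent_male=_round_half_away(100.0 * males / n),
        mean_age=mean_age,
        mean_age_by_country={c: float(np.mean(a)) for c, a in by_country.items()},
        percent_advanced_stage=_round_half_away(100.0 * advanced / denom) if denom else 0,
        subtype_percents=subtype_pct,
        subtype_percents_latino=latino_pct,
    )


def country_subtype_table(patients: Sequence[PatientRecord],
                          countries: Sequence[str] = ("Colombia", "Mexico"),
                          ethnicity: str | None = "Latino") -> ContingencyTable:
    """Subtype x country contingency table (rows = EBV/MSI/CIN/GS)."""
    from .subtyping import SUBTYPE_ORDER

    counts = np.zeros((len(SUBTYPE_ORDER), len(countries)), dtype=int)
    for p in patients:
        if p.subtype_assigned is None or p.country not in countries:
            continue
        if ethnicity is not None and p.ethnicity != ethnicity:
            continue
        counts[SUBTYPE_ORDER.index(p.subtype_assigned), countries.index(p.country)] += 1
    return ContingencyTable(
        row_labels=tuple(SUBTYPE_ORDER), col_labels=tuple(countries), counts=counts
    )


def age_groups_by_country(patients: Sequence[PatientRecord],
                          reference: str = "Colombia") -> tuple[list[int], list[int]]:
    """Ages of the reference-country patients vs all other-country patients."""
    a = [p.age for p in patients if p.country == reference and p.age is not None]
    b = [p.age for p in patients
         if p.country not in (None, reference) and p.age is not None]
    return a, b
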