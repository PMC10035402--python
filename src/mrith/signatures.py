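"""Mutational-spectrum counting and nonnegative signature refitting.

The refit follows the forward-selection scheme popularized for single-sample
signature decomposition: starting from all-zero weights, each iteration
tunes one signature's weight by golden-section search to minimize the
sum-of-squared-error between the renormalized weighted reconstruction and
the observed 96-context frequency vector, adopts the signature giving the
largest error decrease, and stops when no candidate improves the error by
more than ``tol``.  Weights below ``cutoff`` (default 6%) are zeroed and the
survivors renormalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import contexts
from .contexts import CONTEXT_LABELS, N_CONTEXTS


@dataclass
class SpectrumVector:
    """Counts over the 96 substitution classes (lexicographic label order)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_CONTEXTS,):
            raise ValueError(f"spectrum must have {N_CONTEXTS} bins")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        n = self.counts.sum()
        if n == 0:
            raise ValueError("empty spectrum has no frequency vector")
        return self.counts / n

    def __add__(self, other: "SpectrumVector") -> "SpectrumVector":
        return SpectrumVector(self.counts + other.counts)


@dataclass
class SignatureCatalog:
    """A 96 x K column-stochastic matrix of signature profiles."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_CONTEXTS, len(self.names)):
            raise ValueError(
                f"catalog matrix shape {self.matrix.shape} does not match "
                f"{N_CONTEXTS} contexts x {len(self.names)} signatures"
            )
        if (self.matrix < 0).any():
            raise ValueError("catalog entries must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"catalog columns must sum to 1 (got {sums})")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(names=tuple(names), matrix=self.matrix[:, idx])

    def mixture(self, weights: Mapping[str, float] | np.ndarray) -> np.ndarray:
        """Probability vector of a weighted mixture of the columns."""
        if isinstance(weights, Mapping):
            w = np.array([weights.get(n, 0.0) for n in self.names])
        else:
            w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("mixture weights must have positive sum")
        return self.matrix @ (w / w.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CONTEXT_LABELS),
                            columns=list(self.names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureCatalog":
        if list(df.index) != list(CONTEXT_LABELS):
            df = df.reindex(list(CONTEXT_LABELS))
            if df.isna().any().any():
                raise ValueError("catalog rows do not cover the 96 context labels")
        return cls(names=tuple(df.columns), matrix=df.to_numpy())


@dataclass
class SignatureWeights:
    """Fitted nonnegative signature weights for one spectrum."""

    names: tuple[str, ...]
    weights: np.ndarray
    residual_sse: float
    n_mutations: int

    def as_dict(self, nonzero_only: bool = True) -> dict[str, float]:
        return {
            n: float(w) for n, w in zip(self.names, self.weights)
            if not nonzero_only or w > 0
        }


# Default synthetic catalog: COSMIC SBS names relevant to gastric tumors.
DEFAULT_SIGNATURE_NAMES = (
    "SBS1", "SBS3", "SBS4", "SBS5", "SBS6",
    "SBS10b", "SBS15", "SBS18", "SBS21", "SBS24", "SBS26",
)


def synthetic_catalog(names: Sequence[str] = DEFAULT_SIGNATURE_NAMES
                      ) -> SignatureCatalog:
    """Deterministic synthetic signature catalog (a COSMIC stand-in).

    Each signature concentrates 85% of its mass on eight exclusive peak
    contexts (a fixed pseudorandom partition of the 96 classes) over a 15%
    uniform background.  The names follow COSMIC SBS naming so outputs read
    naturally, but the probability values are synthetic: swap in a real
    COSMIC v3.2 TSV via :func:`mrith.io.read_signature_catalog` for real
    data.
    """
    k = len(names)
    if k * 8 > N_CONTEXTS:
        raise ValueError("too many signatures for disjoint 8-context peaks")
    rng = np.random.default_rng(90210)
    perm = rng.permutation(N_CONTEXTS)
    matrix = np.full((N_CONTEXTS, k), 0.15 / N_CONTEXTS)
    for j in range(k):
        peaks = perm[j * 8:(j + 1) * 8]
        raw = rng.gamma(shape=2.0, scale=1.0, size=8)
        matrix[peaks, j] += 0.85 * raw / raw.sum()
    matrix /= matrix.sum(axis=0, keepdims=True)
    return SignatureCatalog(names=tuple(names), matrix=matrix)


def count_contexts(variants: Iterable) -> tuple[SpectrumVector, int]:
    """Bin SNVs with trinucleotide contexts into a 96-class spectrum.

    Non-SNV records and records lacking a context are skipped; the skip
    count is returned alongside the spectrum.  A context whose middle base
    disagrees with the record's reference allele raises ``ValueError``.
    """
    counts = np.zeros(N_CONTEXTS, dtype=int)
    skipped = 0
    for v in variants:
        ctx = getattr(v, "trinucleotide_context", None)
        if ctx is None or len(v.ref) != 1 or len(v.alt) != 1:
            skipped += 1
            continue
        counts[contexts.class_index(v.ref, v.alt, ctx)] += 1
    return SpectrumVector(counts), skipped


def _golden_section(f, lo: float, hi: float, xtol: float = 1e-5) -> float:
    """Minimize a scalar function on [lo, hi] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > xtol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _sse(weights: np.ndarray, matrix: np.ndarray, target: np.ndarray) -> float:
    total = weights.sum()
    if total <= 0:
        recon = np.zeros_like(target)
    else:
        recon = matrix @ (weights / total)
    diff = recon - target
    return float(diff @ diff)


def refit_signatures(spectrum: SpectrumVector, catalog: SignatureCatalog,
                     cutoff: float = 0.06, tol: float = 1e-3,
                     min_mutations: int = 20,
                     max_iter: int = 200) -> SignatureWeights:
    """Fit nonnegative signature weights to a spectrum by forward selection.

    See the module docstring for the algorithm.  Raises ``ValueError`` when
    the spectrum holds fewer than ``min_mutations`` mutations (too few for a
    meaningful decomposition) or its length mismatches the catalog.
    """
    if spectrum.n_mutations < min_mutations:
        raise ValueError(
            f"spectrum has {spectrum.n_mutations} mutations; "
            f"at least {min_mutations} required for refitting"
        )
    target = spectrum.frequencies()
    matrix = catalog.matrix
    k = catalog.n_signatures
    weights = np.zeros(k)
    current_sse = np.inf        # the empty model is not a valid reconstruction
    for _ in range(max_iter):
        best_j = -1
        best_w = 0.0
        best_sse = current_sse
        for j in range(k):
            def f(w: float, j: int = j) -> float:
                trial = weights.copy()
                trial[j] = w
                return _sse(trial, matrix, target)
            w_star = _golden_section(f, 0.0, 1.0)
            sse_star = f(w_star)
            if sse_star < best_sse - 1e-15:
                best_sse, best_j, best_w = sse_star, j, w_star
        if best_j < 0 or (current_sse - best_sse) < tol:
            break
        weights[best_j] = best_w
        assert best_sse <= current_sse + 1e-12, "SSE must be non-increasing"
        current_sse = best_sse
        # renormalizing leaves the reconstruction unchanged but keeps the
        # [0, 1] single-weight search on a meaningful relative scale
        if weights.sum() > 0:
            weights /= weights.sum()
    total = weights.sum()
    if total > 0:
        norm = weights / total
        norm[norm < cutoff] = 0.0
        if norm.sum() > 0:
            norm = norm / norm.sum()
        weights = norm
    residual = _sse(weights, matrix, target) if weights.sum() > 0 else float(target @ target)
    return SignatureWeights(
        names=catalog.names, weights=weights,
        residual_sse=residual, n_mutations=spectrum.n_mutations,
    )


CLONAL_STRATUM = "clonal"
NONCLONAL_STRATUM = "nonclonal"


@dataclass
class StratumFit:
    group: str
    stratum: str
    n_mutations: int
    status: str                      # "fitted" or "insufficient"
    weights: SignatureWeights | None = None


def stratified_signatures(merged: Iterable, catalog: SignatureCatalog,
                          group_of: Mapping[str, str] | None = None,
                          cutoff: float = 0.06, tol: float = 1e-3,
                          min_mutations: int = 20) -> list[StratumFit]:
    """Pooled signature refits per (patient group, clonality stratum).

    Variants labeled CLONAL form the ``clonal`` stratum; SUBCLONAL and
    PRIVATE together form ``nonclonal``; NONE-labeled variants are excluded.
    ``group_of`` maps patient_id -> group label (e.g. molecular subtype or
    histology); omit it for a single cohort-wide group.  Groups/strata below
    the mutation floor are reported with status ``"insufficient"``.
    """
    pools: dict[tuple[str, str], list] = {}
    for m in merged:
        if m.clonality in (None, "NONE"):
            continue
        group = group_of.get(m.patient_id, "?") if group_of is not None else "all"
        stratum = CLONAL_STRATUM if m.clonality == "CLONAL" else NONCLONAL_STRATUM
        pools.setdefault((group, stratum), []).append(m)
    groups = sorted({g for g, _ in pools})
    fits: list[StratumFit] = []
    for group in groups:
        for stratum in (CLONAL_STRATUM, NONCLONAL_STRATUM):
            variants = pools.get((group, stratum), [])
            spectrum, _ = count_contexts(variants)
            n = spectrum.n_mutations
            if n < min_mutations:
                fits.append(StratumFit(group, stratum, n, "insufficient"))
                continue
            w = refit_signatures(spectrum, catalog, cutoff=cutoff, tol=tol,
                                 min_mutations=min_mutations)
            fits.append(StratumFit(group, stratum, n, "fitted", w))
    return fits


def fits_to_frame(fits: Sequence[StratumFit]) -> pd.DataFrame:
    """Tabulate stratified fits (one row per group/stratum)."""
    rows = []
    for f in fits:
        row: dict[str, object] = {
            "group": f.group, "stratum": f.stratum,
            "n_mutations": f.n_mutations, "status": f.status,
        }
        if f.weights is not None:
            row.update({n: float(w) for n, w in zip(f.weights.names, f.weights.weights)})
        rows.append(row)
    return pd.DataFrame(rows)
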