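"""Pyrimidine-centered trinucleotide substitution classes (the 96 SBS contexts).

Single-base substitutions are binned into 96 classes: 6 pyrimidine-centered
substitutions (C>A, C>G, C>T, T>A, T>C, T>G) times 16 flanking-base
combinations.  Substitutions with a purine reference are reverse-complemented
onto the pyrimidine strand before binning.  Class labels follow the COSMIC
convention, e.g. ``A[C>A]A``, and the canonical ordering used throughout this
package is the lexicographic order of those labels.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = ("C", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 96 class labels in lexicographic order.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    sorted(
        f"{five}[{ref}>{alt}]{three}"
        for ref in PYRIMIDINES
        for alt in BASES
        if alt != ref
        for five in BASES
        for three in BASES
    )
)

LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

N_CONTEXTS = 96


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def substitution_class(ref: str, alt: str, context: str) -> str:
    """Map an SNV plus its reference-strand trinucleotide context to a class label.

    ``context`` is the 3-base reference-strand sequence centered on the variant
    position; its middle base must equal ``ref``.  Purine references are
    reverse-complemented to the pyrimidine-centered class.

    Raises
    ------
    ValueError
        If the alleles are not single bases, the context is not a 3-mer over
        ACGT, or the context middle base disagrees with ``ref``.
    """
    ref = ref.upper()
    alt = alt.upper()
    context = context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: ref={ref!r} alt={alt!r}")
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValueError(f"malformed trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = context[1]
        alt = revcomp(alt)
    return f"{context[0]}[{context[1]}>{alt}]{context[2]}"


def class_index(ref: str, alt: str, context: str) -> int:
    """Index of the substitution class in :data:`CONTEXT_LABELS`."""
    return LABEL_INDEX[substitution_class(ref, alt, context)]


def label_parts(label: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into (five_prime, ref, alt, three_prime)."""
    return label[0], label[2], label[4], label[6]
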