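"""The 96-subtype taxonomy of single-base substitutions.

Single nucleotide variants are classified into 96 canonical subtypes
defined by the base change and the trinucleotide context of the mutated
site.  Because a substitution and its reverse-strand description denote
the same event, mutations are collapsed onto the pyrimidine strand: a
purine reference (A or G) is reverse-complemented together with its
context before lookup, so every subtype has a C or T reference base.

The canonical ordering is change-major (C>A, C>G, C>T, T>A, T>C, T>G),
then 5' flanking base, then 3' flanking base, each in A, C, G, T order.
Subtype ``index`` is therefore ``16*change_rank + 4*rank(5') + rank(3')``
and ranges over [0, 95].  Column labels use the bracket grammar
``5'[REF>ALT]3'`` (e.g. ``A[C>A]A`` for index 0), compatible with
COSMIC-style signature tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

BASES = "ACGT"
_BASE_RANK = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-centered base changes in canonical order.
BASE_CHANGES: tuple[tuple[str, str], ...] = (
    ("C", "A"),
    ("C", "G"),
    ("C", "T"),
    ("T", "A"),
    ("T", "C"),
    ("T", "G"),
)
_CHANGE_RANK = {c: i for i, c in enumerate(BASE_CHANGES)}

N_SUBTYPES = 96


class SubtypeError(ValueError):
    """Malformed input to the subtype classifier (distinct from the
    ``None`` result returned for ambiguous bases)."""


@dataclass(frozen=True, order=True)
class MutationClass:
    """One of the 96 canonical pyrimidine-centered SNV subtypes."""

    ref: str
    alt: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if (self.ref, self.alt) not in _CHANGE_RANK:
            raise SubtypeError(
                f"{self.ref}>{self.alt} is not a canonical pyrimidine base change"
            )
        for b in (self.five_prime, self.three_prime):
            if b not in _BASE_RANK:
                raise SubtypeError(f"flanking base {b!r} is not one of A/C/G/T")

    @property
    def index(self) -> int:
        return (
            16 * _CHANGE_RANK[(self.ref, self.alt)]
            + 4 * _BASE_RANK[self.five_prime]
            + _BASE_RANK[self.three_prime]
        )

    @property
    def label(self) -> str:
        """COSMIC-style bracket label, e.g. ``A[C>A]A``."""
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"

    @property
    def context(self) -> str:
        return self.five_prime + self.ref + self.three_prime

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


@lru_cache(maxsize=1)
def canonical_classes() -> tuple[MutationClass, ...]:
    """Return the 96 subtypes in canonical index order (stable)."""
    classes = []
    for ref, alt in BASE_CHANGES:
        for five in BASES:
            for three in BASES:
                classes.append(MutationClass(ref, alt, five, three))
    return tuple(classes)


def class_from_index(index: int) -> MutationClass:
    if not 0 <= index < N_SUBTYPES:
        raise SubtypeError(f"subtype index {index} outside [0, 95]")
    return canonical_classes()[index]


@lru_cache(maxsize=1)
def subtype_labels() -> tuple[str, ...]:
    """The 96 canonical column labels, in index order."""
    return tuple(c.label for c in canonical_classes())


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise SubtypeError(f"cannot complement non-nucleotide character {base!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N only)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError:
        bad = sorted(set(seq) - set(_COMPLEMENT))
        raise SubtypeError(f"non-nucleotide character(s) {bad} in sequence")


def classify(context: str, ref: str, alt: str) -> MutationClass | None:
    """Map (trinucleotide context, ref, alt) to its canonical subtype.

    A purine reference is collapsed onto the pyrimidine strand by
    reverse-complementing the context and complementing both alleles.
    Lowercase (soft-masked) bases are uppercased first.

    Returns ``None`` when any involved base is ambiguous (N or any
    other non-ACGT IUPAC code); raises :class:`SubtypeError` for
    structurally malformed input (wrong context length, middle base not
    matching ``ref``, or ``ref == alt``).
    """
    context = context.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(context) != 3:
        raise SubtypeError(f"context {context!r} must have length 3")
    if len(ref) != 1 or len(alt) != 1:
        raise SubtypeError("ref and alt must be single bases")
    if context[1] != ref:
        raise SubtypeError(
            f"middle base of context {context!r} does not match ref {ref!r}"
        )
    if ref == alt:
        raise SubtypeError(f"ref and alt are both {ref!r}")
    if any(b not in BASES for b in context) or alt not in BASES:
        return None
    if ref in "AG":  # purine reference: collapse to the pyrimidine strand
        context = reverse_complement(context)
        ref = complement(ref)
        alt = complement(alt)
    return MutationClass(ref, alt, context[0], context[2])
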