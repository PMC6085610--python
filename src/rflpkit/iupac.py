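"""IUPAC nucleotide alphabet: degeneracy sets, complements, compatibility.

The fifteen one-letter codes cover every nonempty subset of {A, C, G, T}
except the empty set.  A *degenerate* letter denotes more than one base
(R = A/G, Y = C/T, ..., N = any); the four concrete letters denote
themselves.  Pattern matching throughout the package uses compatibility:
a concrete text base ``t`` matches a pattern letter ``p`` iff
``t in bases(p)``.
"""

from __future__ import annotations

from .errors import AlphabetError

IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse table: base set -> unique IUPAC letter.
LETTER_FOR_BASES: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_BASES.items()
}

CONCRETE = frozenset("ACGT")
DEGENERATE = frozenset(IUPAC_BASES) - CONCRETE

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def bases(letter: str) -> frozenset[str]:
    """Degeneracy set of one IUPAC letter."""
    try:
        return IUPAC_BASES[letter]
    except KeyError:
        raise AlphabetError(letter, 0, "IUPAC letter") from None


def letter_for(base_set: frozenset[str] | set[str] | str) -> str:
    """The unique IUPAC letter whose degeneracy set equals ``base_set``."""
    key = frozenset(base_set)
    try:
        return LETTER_FOR_BASES[key]
    except KeyError:
        raise AlphabetError("".join(sorted(key)), 0, "base set") from None


def compatible(text_char: str, pattern_char: str) -> bool:
    """True iff concrete base ``text_char`` lies in ``pattern_char``'s set."""
    return text_char in IUPAC_BASES[pattern_char]


def is_concrete(seq: str) -> bool:
    """True iff every letter of ``seq`` is one of A/C/G/T."""
    return all(c in CONCRETE for c in seq)


def validate(seq: str, alphabet: frozenset[str] = frozenset(IUPAC_BASES),
             context: str = "sequence") -> None:
    """Raise :class:`AlphabetError` at the first letter outside ``alphabet``."""
    for i, c in enumerate(seq):
        if c not in alphabet:
            raise AlphabetError(c, i, context)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, IUPAC-aware.

    Degenerate letters map to the letter of the complemented base set
    (R<->Y, K<->M, B<->V, D<->H; S, W, N are self-complementary), so
    ``bases(reverse_complement(p)[i]) == {complement(b) for b in bases(p[-1-i])}``
    and the operation is an involution.
    """
    out = []
    for i, c in enumerate(seq):
        try:
            out.append(COMPLEMENT[c])
        except KeyError:
            raise AlphabetError(c, i) from None
    return "".join(reversed(out))
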