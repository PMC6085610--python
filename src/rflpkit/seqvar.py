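"""Variation-bearing DNA templates.

A template is a plain-DNA backbone plus zero or more variation sites.
Three input dialects are accepted:

``plain``
    A/C/G/T only — no variation.
``iupac``
    Degenerate letters mark substitution sites; ``ACGGMTTT`` has a site
    with alleles A and C (M = A/C).
``bracket``
    Alleles are written out: ``ACGG[A/C]TTTTTT`` for a di-allelic SNP,
    up to ``[w/x/y/z]`` for tetra-allelic sites, and ``[-/G]`` or
    ``[GAT/-]`` for indels (``-`` is the deletion allele).

Internally a site occupies one placeholder character in the backbone;
coordinates are 0-based half-open, while user-facing reports are
1-based.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from Bio import SeqIO

from . import iupac
from .errors import (
    AlphabetError,
    BracketParseError,
    CombinatorialLimitError,
    SpecificationError,
    TransformUnsupportedError,
)
from .iupac import reverse_complement  # noqa: F401  (re-exported)

__all__ = [
    "PLACEHOLDER",
    "VariationSite",
    "VariantTemplate",
    "AlleleSequence",
    "parse_input",
    "detect_variations",
    "bracket_to_iupac",
    "iupac_to_bracket",
    "expand_alleles",
    "flanking",
    "reverse_complement",
    "reverse_complement_template",
    "read_fasta_templates",
    "read_template_lines",
    "synthesize_template",
]

#: Backbone character standing in for one variation site.
PLACEHOLDER = "*"

DELETION = "-"

DEFAULT_EXPANSION_CAP = 256

_CANONICAL = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class VariationSite:
    """One variation: its backbone position and ordered allele strings."""

    position: int
    alleles: tuple[str, ...]

    def is_indel(self) -> bool:
        return DELETION in self.alleles

    def canonical_alleles(self) -> tuple[str, ...]:
        """Alleles sorted A<C<G<T with the deletion allele last."""
        return tuple(sorted(
            self.alleles,
            key=lambda a: (a == DELETION, [_CANONICAL.get(c, 4) for c in a])))


@dataclass(frozen=True)
class VariantTemplate:
    """DNA backbone with one placeholder per variation site."""

    backbone: str
    sites: tuple[VariationSite, ...]
    dialect: str = "plain"

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if positions != sorted(set(positions)):
            raise ValueError("site positions must be strictly increasing")
        for p in positions:
            if not (0 <= p < len(self.backbone)) or self.backbone[p] != PLACEHOLDER:
                raise ValueError(f"site position {p} does not hold a placeholder")
        if self.backbone.count(PLACEHOLDER) != len(self.sites):
            raise ValueError("placeholder count must equal site count")

    def is_plain(self) -> bool:
        return not self.sites

    def to_bracket(self) -> str:
        """Render as a bracket-dialect string."""
        out, sites = [], {s.position: s for s in self.sites}
        for i, c in enumerate(self.backbone):
            if c == PLACEHOLDER:
                out.append("[" + "/".join(sites[i].alleles) + "]")
            else:
                out.append(c)
        return "".join(out)


@dataclass(frozen=True)
class AlleleSequence:
    """One concrete realization of a template.

    ``alleles`` holds the allele chosen per site; ``site_spans`` the
    realized 0-based half-open span of each site in ``sequence``
    (empty span at the insertion point for deletion alleles).
    """

    alleles: tuple[str, ...]
    sequence: str
    site_spans: tuple[tuple[int, int], ...]

    @property
    def label(self) -> str:
        return "|".join(self.alleles) if self.alleles else "."


_ALLELE_RE = re.compile(r"^[ACGT]+$")


def _clean(text: str) -> str:
    # digits and whitespace (sequence-editor line numbers) are noise
    return re.sub(r"[\s\d]", "", text).upper()


def _validate_group(inner: str, position: int) -> tuple[str, ...]:
    alleles = tuple(inner.split("/"))
    if len(alleles) < 2:
        raise BracketParseError(
            f"variation group [{inner}] at position {position + 1} needs "
            "at least 2 alleles")
    if len(alleles) > 4:
        raise BracketParseError(
            f"variation group [{inner}] at position {position + 1} has "
            f"{len(alleles)} alleles (max 4)")
    if len(set(alleles)) != len(alleles):
        raise BracketParseError(
            f"duplicate alleles in group [{inner}] at position {position + 1}")
    for a in alleles:
        if a != DELETION and not _ALLELE_RE.match(a):
            raise BracketParseError(
                f"invalid allele {a!r} in group [{inner}] at "
                f"position {position + 1}")
    if DELETION in alleles and len(alleles) != 2:
        raise BracketParseError(
            f"indel group [{inner}] at position {position + 1} must have "
            "exactly two alleles, [-/dNTPn] or [dNTPn/-]")
    return alleles


def _parse_bracket(text: str) -> VariantTemplate:
    backbone: list[str] = []
    sites: list[VariationSite] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "[":
            end = text.find("]", i)
            if end < 0:
                raise BracketParseError(
                    f"unclosed variation group at position {i + 1}")
            alleles = _validate_group(text[i + 1:end], i)
            sites.append(VariationSite(len(backbone), alleles))
            backbone.append(PLACEHOLDER)
            i = end + 1
        elif c in iupac.CONCRETE:
            backbone.append(c)
            i += 1
        else:
            raise SpecificationError(
                f"invalid character {c!r} at position {i + 1} for the "
                "bracket dialect")
    return VariantTemplate("".join(backbone), tuple(sites), "bracket")


def _parse_iupac(text: str) -> VariantTemplate:
    backbone: list[str] = []
    sites: list[VariationSite] = []
    for i, c in enumerate(text):
        if c in iupac.CONCRETE:
            backbone.append(c)
        elif c in iupac.DEGENERATE:
            alleles = tuple(sorted(iupac.bases(c), key=_CANONICAL.__getitem__))
            sites.append(VariationSite(len(backbone), alleles))
            backbone.append(PLACEHOLDER)
        else:
            raise SpecificationError(
                f"invalid character {c!r} at position {i + 1} for the "
                "IUPAC dialect")
    return VariantTemplate("".join(backbone), tuple(sites), "iupac")


def parse_input(text: str, dialect: str = "auto") -> VariantTemplate:
    """Parse an input sequence in the given dialect into a template.

    ``auto`` picks ``bracket`` if a ``[`` is present, else ``iupac`` if
    any degenerate letter is present, else ``plain``.  Whitespace and
    digits are stripped and case is folded before validation; any other
    character outside the dialect's alphabet raises
    :class:`SpecificationError` naming position and character.
    """
    cleaned = _clean(text)
    if not cleaned:
        raise SpecificationError("empty input sequence")
    if dialect == "auto":
        if "[" in cleaned:
            dialect = "bracket"
        elif any(c in iupac.DEGENERATE for c in cleaned):
            dialect = "iupac"
        else:
            dialect = "plain"
    if dialect == "bracket":
        return _parse_bracket(cleaned)
    if dialect == "iupac":
        return _parse_iupac(cleaned)
    if dialect == "plain":
        for i, c in enumerate(cleaned):
            if c not in iupac.CONCRETE:
                raise SpecificationError(
                    f"invalid character {c!r} at position {i + 1} for the "
                    "plain dialect")
        return VariantTemplate(cleaned, (), "plain")
    raise ValueError(f"unknown dialect {dialect!r}")


def detect_variations(template: VariantTemplate) -> list[tuple[int, list[str]]]:
    """Positions and alleles of all variation sites, in backbone order."""
    return [(s.position, list(s.alleles)) for s in template.sites]


def bracket_to_iupac(template: VariantTemplate) -> str:
    """Render a template as a composite-IUPAC string.

    Works only when every site is a substitution of single bases; indels
    and multi-base alleles have no IUPAC representation.
    """
    sites = {s.position: s for s in template.sites}
    out = []
    for i, c in enumerate(template.backbone):
        if c != PLACEHOLDER:
            out.append(c)
            continue
        site = sites[i]
        if site.is_indel() or any(len(a) != 1 for a in site.alleles):
            raise TransformUnsupportedError(
                f"site at position {i + 1} ({'/'.join(site.alleles)}) has no "
                "IUPAC representation (indel or multi-base allele)")
        out.append(iupac.letter_for(set(site.alleles)))
    return "".join(out)


def iupac_to_bracket(text: str) -> VariantTemplate:
    """Parse a composite-IUPAC string into a bracket-dialect template
    with alleles in canonical A<C<G<T order."""
    return replace(_parse_iupac(_clean(text)), dialect="bracket")


def expand_alleles(template: VariantTemplate,
                   cap: int = DEFAULT_EXPANSION_CAP) -> list[AlleleSequence]:
    """All concrete sequences realizing the template, one per element of
    the Cartesian product of site alleles (product order).

    A template without sites yields itself.  Raises
    :class:`CombinatorialLimitError` when the product exceeds ``cap``.
    """
    count = 1
    for s in template.sites:
        count *= len(s.alleles)
    if count > cap:
        raise CombinatorialLimitError(count, cap, "allele expansion")
    out: list[AlleleSequence] = []
    site_positions = [s.position for s in template.sites]
    for choice in itertools.product(*(s.alleles for s in template.sites)):
        parts: list[str] = []
        spans: list[tuple[int, int]] = []
        cursor = 0
        next_site = 0
        for i, c in enumerate(template.backbone):
            if next_site < len(site_positions) and i == site_positions[next_site]:
                allele = choice[next_site]
                realized = "" if allele == DELETION else allele
                spans.append((cursor, cursor + len(realized)))
                parts.append(realized)
                cursor += len(realized)
                next_site += 1
            else:
                parts.append(c)
                cursor += 1
        out.append(AlleleSequence(choice, "".join(parts), tuple(spans)))
    return out


def flanking(template: VariantTemplate, radius: int,
             site_index: int = 0) -> VariantTemplate:
    """Sub-template covering ``radius`` backbone bases on each side of
    the chosen site, truncated at the sequence ends.

    All sites falling inside the window are retained with positions
    re-indexed from the window start.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not (0 <= site_index < len(template.sites)):
        raise IndexError(f"site_index {site_index} out of range")
    center = template.sites[site_index].position
    lo = max(0, center - radius)
    hi = min(len(template.backbone), center + radius + 1)
    kept = tuple(
        VariationSite(s.position - lo, s.alleles)
        for s in template.sites if lo <= s.position < hi)
    return VariantTemplate(template.backbone[lo:hi], kept, template.dialect)


def reverse_complement_template(template: VariantTemplate) -> VariantTemplate:
    """Reverse-complement a whole template: backbone mirrored, each
    site's alleles complemented (deletion allele unchanged)."""
    n = len(template.backbone)
    backbone = "".join(
        c if c == PLACEHOLDER else iupac.COMPLEMENT[c]
        for c in reversed(template.backbone))
    sites = tuple(sorted(
        (VariationSite(
            n - 1 - s.position,
            tuple(a if a == DELETION else reverse_complement(a)
                  for a in s.alleles))
         for s in template.sites),
        key=lambda s: s.position))
    return VariantTemplate(backbone, sites, template.dialect)


def read_fasta_templates(path, dialect: str = "auto"
                         ) -> list[tuple[str, VariantTemplate]]:
    """Read templates from FASTA; bracket groups may appear inside
    sequence lines.  Returns (header description, template) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.description, parse_input(str(rec.seq), dialect)))
    return out


def read_template_lines(path, dialect: str = "auto") -> list[VariantTemplate]:
    """Read one template per non-blank line of a plain-text file."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(parse_input(line, dialect))
    return out


def synthesize_template(rng, flank_length: int = 500, n_alleles: int = 2,
                        indel: bool = False) -> VariantTemplate:
    """Random single-site template: uniform-random flanks around one
    substitution (or indel) site.  ``rng`` is a ``random.Random``."""
    left = "".join(rng.choice("ACGT") for _ in range(flank_length))
    right = "".join(rng.choice("ACGT") for _ in range(flank_length))
    if indel:
        ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
        alleles: tuple[str, ...] = (DELETION, ins)
    else:
        alleles = tuple(rng.sample("ACGT", n_alleles))
    site = VariationSite(flank_length, alleles)
    return VariantTemplate(left + PLACEHOLDER + right, (site,), "bracket")
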