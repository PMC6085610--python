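"""Recognition-site search: Boyer-Moore over DNA with IUPAC-degenerate
patterns.

The matcher aligns the pattern right-to-left against the text and, on a
mismatch, advances by the larger of the bad-character and good-suffix
shifts.  The bad-character rule realigns the rightmost pattern position
compatible with the mismatched text letter; good-suffix shift 1
realigns the rightmost earlier occurrence of the matched suffix whose
preceding letter differs, and shift 2 falls back to the longest pattern
prefix that is a suffix of the matched suffix.

Degenerate patterns match by compatibility: text base ``t`` matches
pattern letter ``p`` iff ``t ∈ bases(p)``.  Compatibility is not an
equivalence relation, so for degenerate patterns the good-suffix rule
is unsound and only the bad-character rule (computed over degeneracy
sets) is applied; correctness is preserved, only the skip distance
shrinks.  :func:`naive_search` is the permanent brute-force oracle with
the identical contract.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, TextIO

from . import iupac
from .errors import AlphabetError, CombinatorialLimitError
from .rebase_io import EnzymeRecord

__all__ = [
    "SearchTables",
    "MatchHit",
    "build_tables",
    "bm_search",
    "naive_search",
    "expand_iupac_pattern",
    "find_sites",
    "hits_to_tsv",
    "hits_to_json",
    "hits_to_bed",
]

DEFAULT_PATTERN_CAP = 4096

HIT_COLUMNS = ("enzyme_name", "strand", "start", "end", "matched_text", "pattern")


@dataclass(frozen=True)
class SearchTables:
    """Preprocessed shift tables for one pattern (text-independent).

    ``bad_character`` maps each concrete text letter to the shift used
    when it mismatches at the last pattern position (range 1..M);
    ``good_suffix`` is the strong good-suffix shift array, ``None`` for
    degenerate patterns where the rule is disabled.
    """

    pattern: str
    bad_character: dict[str, int]
    good_suffix: Optional[tuple[int, ...]]
    last_compatible: dict[str, int]

    @property
    def degenerate(self) -> bool:
        return self.good_suffix is None


@dataclass(frozen=True)
class MatchHit:
    """One recognition-site occurrence, in + strand coordinates
    (0-based half-open)."""

    enzyme_name: str
    strand: str
    start: int
    end: int
    matched_text: str
    pattern: str


def _good_suffix_table(pattern: str) -> tuple[int, ...]:
    # strong good-suffix preprocessing via border positions; shift[j] is
    # the advance after a mismatch at pattern index j-1 (shift[0]: full match)
    m = len(pattern)
    shift = [0] * (m + 1)
    border = [0] * (m + 2)
    i, j = m, m + 1
    border[i] = j
    while i > 0:
        while j <= m and pattern[i - 1] != pattern[j - 1]:
            if shift[j] == 0:
                shift[j] = j - i
            j = border[j]
        i -= 1
        j -= 1
        border[i] = j
    j = border[0]
    for i in range(m + 1):
        if shift[i] == 0:
            shift[i] = j
        if i == j:
            j = border[j]
    return tuple(shift)


def build_tables(pattern: str) -> SearchTables:
    """Build Boyer-Moore shift tables for an IUPAC pattern.

    ``last_compatible[c]`` is the rightmost pattern index whose
    degeneracy set contains concrete base ``c`` (absent letters shift
    the full pattern length).  Good-suffix tables are built only for
    concrete patterns.
    """
    if not pattern:
        raise ValueError("pattern must be nonempty")
    iupac.validate(pattern, context="pattern")
    m = len(pattern)
    last: dict[str, int] = {}
    for j, p in enumerate(pattern):
        for c in iupac.bases(p):
            last[c] = j
    # Horspool-style shift keyed on the last-position text letter;
    # occurrences at the final position are excluded so shifts stay >= 1
    last_but_final: dict[str, int] = {}
    for j, p in enumerate(pattern[:-1]):
        for c in iupac.bases(p):
            last_but_final[c] = j
    bad_character = {
        c: m - 1 - last_but_final[c] if c in last_but_final else m
        for c in "ACGT"
    }
    degenerate = any(c in iupac.DEGENERATE for c in pattern)
    good_suffix = None if degenerate else _good_suffix_table(pattern)
    return SearchTables(pattern, bad_character, good_suffix, last)


def _check_text(text: str) -> None:
    for i, c in enumerate(text):
        if c not in iupac.CONCRETE:
            raise AlphabetError(c, i, "search text (expand alleles first)")


def bm_search(text: str, pattern: str,
              tables: Optional[SearchTables] = None,
              trace: Optional[list] = None) -> list[int]:
    """All 0-based start positions of ``pattern`` in concrete ``text``.

    Overlapping occurrences are all reported.  ``trace``, if given,
    collects the (alignment_start, shift) pairs taken — used to verify
    shift behaviour and termination bounds.
    """
    if tables is None:
        tables = build_tables(pattern)
    elif tables.pattern != pattern:
        raise ValueError("tables were built for a different pattern")
    _check_text(text)
    m = len(pattern)
    n = len(text)
    hits: list[int] = []
    if m > n:
        return hits
    last = tables.last_compatible
    gs = tables.good_suffix
    sets = [iupac.IUPAC_BASES[p] for p in pattern]
    s = 0
    while s <= n - m:
        j = m - 1
        while j >= 0 and text[s + j] in sets[j]:
            j -= 1
        if j < 0:
            hits.append(s)
            shift = gs[0] if gs is not None else 1
        else:
            bad = j - last.get(text[s + j], -1)
            good = gs[j + 1] if gs is not None else 1
            shift = max(bad, good, 1)
        if trace is not None:
            trace.append((s, shift))
        s += shift
    return hits


def naive_search(text: str, pattern: str) -> list[int]:
    """Brute-force position-by-position scan; the reference oracle for
    :func:`bm_search` and the benchmark baseline."""
    iupac.validate(pattern, context="pattern")
    _check_text(text)
    m = len(pattern)
    sets = [iupac.IUPAC_BASES[p] for p in pattern]
    return [
        s for s in range(len(text) - m + 1)
        if all(text[s + j] in sets[j] for j in range(m))
    ]


def expand_iupac_pattern(pattern: str,
                         cap: int = DEFAULT_PATTERN_CAP) -> list[str]:
    """All concrete sequences covered by a degenerate pattern, in
    lexicographic order; count equals the product of per-position
    degeneracies."""
    iupac.validate(pattern, context="pattern")
    count = 1
    for c in pattern:
        count *= len(iupac.bases(c))
    if count > cap:
        raise CombinatorialLimitError(count, cap, "pattern expansion")
    choices = [sorted(iupac.bases(c)) for c in pattern]
    return ["".join(p) for p in itertools.product(*choices)]


def find_sites(text: str, enzymes: Iterable[EnzymeRecord],
               min_len: int = 1, max_len: Optional[int] = None,
               commercial_only: bool = False,
               include_iupac: bool = True) -> list[MatchHit]:
    """All recognition sites of the surviving enzymes in ``text``, on
    both strands.

    Enzymes are filtered before the search by recognition length,
    commercial availability and (when ``include_iupac`` is false)
    degenerate patterns.  Minus-strand sites are found by searching the
    reverse complement of the pattern and reported in + strand
    coordinates.  Hits are sorted by (start, enzyme_name, strand).
    """
    _check_text(text)
    hits: list[MatchHit] = []
    for enz in enzymes:
        m = len(enz.pattern)
        if m < min_len or (max_len is not None and m > max_len):
            continue
        if commercial_only and not enz.is_commercial():
            continue
        if not include_iupac and enz.is_iupac():
            continue
        if m > len(text):
            continue
        for start in bm_search(text, enz.pattern):
            hits.append(MatchHit(enz.name, "+", start, start + m,
                                 text[start:start + m], enz.pattern))
        rc = iupac.reverse_complement(enz.pattern)
        for start in bm_search(text, rc):
            hits.append(MatchHit(enz.name, "-", start, start + m,
                                 text[start:start + m], enz.pattern))
    hits.sort(key=lambda h: (h.start, h.enzyme_name, h.strand))
    return hits


def _hit_row(h: MatchHit) -> dict:
    return {
        "enzyme_name": h.enzyme_name,
        "strand": h.strand,
        "start": h.start + 1,   # 1-based inclusive for reports
        "end": h.end,
        "matched_text": h.matched_text,
        "pattern": h.pattern,
    }


def hits_to_tsv(hits: Sequence[MatchHit], fh: TextIO) -> None:
    """Hit table as TSV with 1-based inclusive coordinates."""
    fh.write("\t".join(HIT_COLUMNS) + "\n")
    for h in hits:
        row = _hit_row(h)
        fh.write("\t".join(str(row[c]) for c in HIT_COLUMNS) + "\n")


def hits_to_json(hits: Sequence[MatchHit], fh: TextIO) -> None:
    """Hit table as a JSON array with 1-based inclusive coordinates."""
    json.dump([_hit_row(h) for h in hits], fh, indent=2)
    fh.write("\n")


def hits_to_bed(hits: Sequence[MatchHit], fh: TextIO,
                chrom: str = "seq") -> None:
    """Hit table as BED6 (0-based half-open, strand column)."""
    for h in hits:
        fh.write(f"{chrom}\t{h.start}\t{h.end}\t{h.enzyme_name}\t0\t{h.strand}\n")
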