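"""Enzyme catalog I/O: parse flat-text catalogs in the REBASE
"parsed references" dialect, strip cut-site notation, and generate
synthetic fixture catalogs for testing.

A catalog entry carries the seven fields a wet-lab user needs to pick an
enzyme: name, microorganism, source, recognition sequence, methylation,
commercial availability (supplier codes) and references, plus the
prototype enzyme.  The recognition sequence may embed cut-site notation
(``G^AATTC`` or ``GGTCTC(1/5)``); :func:`strip_cut_notation` separates
the IUPAC pattern from the cut offsets.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, TextIO

from . import iupac
from .errors import RebaseParseError, RecognitionParseError

__all__ = [
    "EnzymeRecord",
    "RebaseDialect",
    "ParseWarning",
    "ParseResult",
    "DEFAULT_DIALECT",
    "parse_rebase",
    "parse_rebase_file",
    "strip_cut_notation",
    "generate_fixture",
    "format_records",
    "make_record",
    "write_tsv",
    "write_jsonl",
]

TSV_COLUMNS = (
    "name", "prototype", "microorganism", "source", "recognition_raw",
    "pattern", "cut_top", "cut_bottom", "methylation", "suppliers",
    "references",
)


@dataclass(frozen=True)
class EnzymeRecord:
    """One parsed catalog entry.

    ``pattern`` is the uppercase IUPAC recognition sequence with all cut
    notation removed.  ``cut_top``/``cut_bottom`` are cut offsets in
    bases from the pattern start (top/bottom strand); ``None`` when the
    entry carries no cut notation.  Offsets upstream of the pattern
    (two-sided cutters) are kept in ``cut_top_upstream``/
    ``cut_bottom_upstream`` but play no role in site matching.
    ``index`` is the 0-based position in the source file, which also
    disambiguates duplicate names.
    """

    name: str
    prototype: str = ""
    microorganism: str = ""
    source: str = ""
    recognition_raw: str = ""
    pattern: str = ""
    cut_top: Optional[int] = None
    cut_bottom: Optional[int] = None
    cut_top_upstream: Optional[int] = None
    cut_bottom_upstream: Optional[int] = None
    methylation: str = ""
    suppliers: frozenset[str] = frozenset()
    references: tuple[str, ...] = ()
    index: int = 0

    def is_commercial(self) -> bool:
        """True iff at least one supplier sells the enzyme."""
        return bool(self.suppliers)

    def is_iupac(self) -> bool:
        """True iff the recognition pattern contains a degenerate letter."""
        return any(c in iupac.DEGENERATE for c in self.pattern)


@dataclass(frozen=True)
class RebaseDialect:
    """Field-tag conventions of a flat-text catalog.

    ``field_tags`` marks, in order: name, prototype, microorganism,
    source, recognition sequence, methylation, commercial availability,
    references.  Records are separated by blank lines; lines starting
    with a ``comment_prefixes`` entry are skipped.
    """

    field_tags: tuple[str, ...] = (
        "<1>", "<2>", "<3>", "<4>", "<5>", "<6>", "<7>", "<8>",
    )
    record_separator: str = "blank-line"
    comment_prefixes: tuple[str, ...] = ("#",)

    def __post_init__(self) -> None:
        if len(self.field_tags) != 8:
            raise ValueError("dialect needs exactly 8 field tags")
        if len(set(self.field_tags)) != 8:
            raise ValueError("field tags must be unique")


DEFAULT_DIALECT = RebaseDialect()

_FIELD_NAMES = (
    "name", "prototype", "microorganism", "source", "recognition",
    "methylation", "commercial", "references",
)


@dataclass(frozen=True)
class ParseWarning:
    """A skipped or suspect catalog entry."""

    line: int
    name: str
    message: str


@dataclass
class ParseResult:
    """Outcome of a catalog parse: records in file order plus diagnostics."""

    records: list[EnzymeRecord] = field(default_factory=list)
    warnings: list[ParseWarning] = field(default_factory=list)
    skipped_noncutting: int = 0


_RECOGNITION_RE = re.compile(
    r"^(?:\((-?\d+)/(-?\d+)\))?"      # optional upstream (a/b)
    r"([A-Za-z^]+)"                    # letters with optional caret
    r"(?:\((-?\d+)/(-?\d+)\))?$"       # optional downstream (n/m)
)


def strip_cut_notation(recognition_raw: str):
    """Split a printed recognition sequence into (pattern, cut_top, cut_bottom).

    A caret marks the top-strand cut within the site: ``G^AATTC`` ->
    (``GAATTC``, 1, None).  A trailing ``(n/m)`` marks cuts downstream of
    the site: ``GGTCTC(1/5)`` -> (``GGTCTC``, 7, 11), i.e. pattern length
    plus the printed offset.  Sequences without notation yield
    (pattern, None, None).
    """
    pattern, cut_top, cut_bottom, _, _ = _parse_recognition(recognition_raw)
    return pattern, cut_top, cut_bottom


def _parse_recognition(raw: str, entry: str = "?"):
    raw = raw.strip()
    if not raw:
        raise RecognitionParseError(f"empty recognition sequence in entry {entry}")
    m = _RECOGNITION_RE.match(raw)
    if m is None:
        bad = re.sub(r"[A-Za-z^()/\d-]", "", raw)
        raise RecognitionParseError(
            f"unparsable recognition sequence {raw!r} in entry {entry}"
            + (f" (offending characters {bad!r})" if bad else "")
        )
    up_a, up_b, body, down_n, down_m = m.groups()
    caret_count = body.count("^")
    if caret_count > 1:
        raise RecognitionParseError(
            f"multiple carets in recognition {raw!r} (entry {entry})"
        )
    pattern = body.replace("^", "").upper()
    for i, c in enumerate(pattern):
        if c not in iupac.IUPAC_BASES:
            raise RecognitionParseError(
                f"non-IUPAC letter {c!r} at position {i + 1} of "
                f"recognition {raw!r} (entry {entry})"
            )
    cut_top = cut_bottom = None
    if caret_count:
        cut_top = body.index("^")
    if down_n is not None:
        if caret_count:
            raise RecognitionParseError(
                f"both caret and (n/m) notation in {raw!r} (entry {entry})"
            )
        cut_top = len(pattern) + int(down_n)
        cut_bottom = len(pattern) + int(down_m)
    up_top = up_bottom = None
    if up_a is not None:
        up_top, up_bottom = int(up_a), int(up_b)
    return pattern, cut_top, cut_bottom, up_top, up_bottom


_TAGLIKE_RE = re.compile(r"^<[^>]{1,8}>")


def parse_rebase(text: str, dialect: RebaseDialect = DEFAULT_DIALECT) -> ParseResult:
    """Parse flat-file catalog text into :class:`EnzymeRecord` objects.

    Blank lines separate entries; within an entry each line starts with
    a dialect field tag, and untagged lines continue the previous field
    (wrapped references).  Entries missing a name or recognition field
    are skipped with a warning; non-cutting entries (recognition ``?``)
    are skipped and counted.  Leading text that contains no field tag is
    treated as file header and ignored.
    """
    tag_for = dict(zip(dialect.field_tags, _FIELD_NAMES))
    result = ParseResult()
    # split into blocks of (line_number, line) separated by blank lines
    blocks: list[list[tuple[int, str]]] = [[]]
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            if blocks[-1]:
                blocks.append([])
            continue
        if any(line.startswith(p) for p in dialect.comment_prefixes):
            continue
        blocks[-1].append((lineno, line))
    index = 0
    for block in blocks:
        if not block:
            continue
        if not any(line.startswith(t) for _, line in block for t in tag_for):
            continue  # header / prose block
        fields: dict[str, list[str]] = {}
        current: Optional[str] = None
        first_line = block[0][0]
        for lineno, line in block:
            matched = next((t for t in tag_for if line.startswith(t)), None)
            if matched is not None:
                current = tag_for[matched]
                fields.setdefault(current, []).append(line[len(matched):].strip())
            elif _TAGLIKE_RE.match(line):
                raise RebaseParseError(
                    f"line {lineno}: unrecognized field tag in {line!r}"
                )
            elif current is not None:
                fields[current].append(line.strip())
            else:
                raise RebaseParseError(
                    f"line {lineno}: expected a field tag, got {line!r}"
                )
        name = " ".join(fields.get("name", [])).strip()
        recognition = " ".join(fields.get("recognition", [])).strip()
        if not name:
            result.warnings.append(
                ParseWarning(first_line, "?", "entry missing name field; skipped"))
            continue
        if not recognition:
            result.warnings.append(
                ParseWarning(first_line, name, "entry missing recognition field; skipped"))
            continue
        if recognition == "?":
            result.skipped_noncutting += 1
            result.warnings.append(
                ParseWarning(first_line, name,
                             "non-cutting entry (recognition '?'); skipped"))
            continue
        pattern, cut_top, cut_bottom, up_top, up_bottom = _parse_recognition(
            recognition, entry=name)
        suppliers = frozenset(
            c for c in " ".join(fields.get("commercial", [])) if c.isalpha())
        result.records.append(EnzymeRecord(
            name=name,
            prototype=" ".join(fields.get("prototype", [])).strip(),
            microorganism=" ".join(fields.get("microorganism", [])).strip(),
            source=" ".join(fields.get("source", [])).strip(),
            recognition_raw=recognition,
            pattern=pattern,
            cut_top=cut_top,
            cut_bottom=cut_bottom,
            cut_top_upstream=up_top,
            cut_bottom_upstream=up_bottom,
            methylation=" ".join(fields.get("methylation", [])).strip(),
            suppliers=suppliers,
            references=tuple(fields.get("references", [])),
            index=index,
        ))
        index += 1
    return result


def parse_rebase_file(path, dialect: RebaseDialect = DEFAULT_DIALECT) -> ParseResult:
    """Parse a catalog file by path."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_rebase(fh.read(), dialect)


def format_records(records: Iterable[EnzymeRecord],
                   dialect: RebaseDialect = DEFAULT_DIALECT) -> str:
    """Render records back into the flat-file dialect (inverse of parsing)."""
    tags = dialect.field_tags
    out: list[str] = []
    for rec in records:
        out.append(f"{tags[0]}{rec.name}")
        out.append(f"{tags[1]}{rec.prototype}")
        out.append(f"{tags[2]}{rec.microorganism}")
        out.append(f"{tags[3]}{rec.source}")
        out.append(f"{tags[4]}{rec.recognition_raw}")
        out.append(f"{tags[5]}{rec.methylation}")
        out.append(f"{tags[6]}{''.join(sorted(rec.suppliers))}")
        refs = rec.references or ("",)
        out.append(f"{tags[7]}{refs[0]}")
        out.extend(refs[1:])
        out.append("")
    return "\n".join(out)


def make_record(name: str, recognition_raw: str, *, prototype: str = "",
                microorganism: str = "synthetic construct",
                source: str = "synthetic", methylation: str = "",
                suppliers: Iterable[str] = (), references: Iterable[str] = (),
                index: int = 0) -> EnzymeRecord:
    """Convenience constructor deriving pattern/cut fields from the
    printed recognition sequence."""
    pattern, cut_top, cut_bottom, up_top, up_bottom = _parse_recognition(
        recognition_raw, entry=name)
    return EnzymeRecord(
        name=name, prototype=prototype, microorganism=microorganism,
        source=source, recognition_raw=recognition_raw, pattern=pattern,
        cut_top=cut_top, cut_bottom=cut_bottom, cut_top_upstream=up_top,
        cut_bottom_upstream=up_bottom, methylation=methylation,
        suppliers=frozenset(suppliers), references=tuple(references),
        index=index,
    )


@dataclass(frozen=True)
class Fixture:
    """A synthetic catalog: the flat-file text and the records it encodes."""

    text: str
    records: tuple[EnzymeRecord, ...]


#: Supplier code pool used by the fixture generator (REBASE-style letters).
_SUPPLIER_POOL = "BCEIJKMNOQRSVXY"

# Two real, commercially listed enzymes anchor every fixture so worked
# examples run against any generated catalog: TspGWI cuts ACGGA
# downstream of the site; BspGI cuts within CTGGAC.
_TSPGWI = make_record(
    "TspGWI", "ACGGA(11/9)",
    microorganism="Thermus sp. GW", source="A. Gowher",
    suppliers="Q", references=("Zylicz-Stachula, A., unpublished observations.",),
)
_BSPGI = make_record(
    "BspGI", "CTGGAC",
    microorganism="Bacillus sphaericus G", source="V.E. Repin",
    suppliers="I", references=("Repin, V.E., unpublished observations.",),
)


def generate_fixture(n_enzymes: int, seed: int, iupac_fraction: float = 0.3,
                     commercial_fraction: float = 0.7,
                     dialect: RebaseDialect = DEFAULT_DIALECT) -> Fixture:
    """Generate a deterministic synthetic catalog of ``n_enzymes`` entries.

    The first one or two entries are always the anchor enzymes TspGWI
    (ACGGA) and BspGI (CTGGAC); the rest are synthetic, with recognition
    lengths 4-8, a degenerate letter in roughly ``iupac_fraction`` of
    entries and a nonempty supplier set in roughly
    ``commercial_fraction``.  Identical arguments give byte-identical
    text, and ``parse_rebase(fixture.text)`` returns ``fixture.records``
    field for field.
    """
    if n_enzymes < 1:
        raise ValueError("n_enzymes must be >= 1")
    if not (0 <= iupac_fraction <= 1 and 0 <= commercial_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = random.Random(seed)
    records: list[EnzymeRecord] = [_TSPGWI]
    if n_enzymes >= 2:
        records.append(_BSPGI)
    for i in range(len(records), n_enzymes):
        length = rng.randint(4, 8)
        letters = [rng.choice("ACGT") for _ in range(length)]
        if rng.random() < iupac_fraction:
            for pos in rng.sample(range(length), rng.randint(1, 2)):
                letters[pos] = rng.choice(sorted(iupac.DEGENERATE))
        pattern = "".join(letters)
        style = rng.random()
        if style < 0.4:
            cut = rng.randint(0, length)
            raw = pattern[:cut] + "^" + pattern[cut:]
        elif style < 0.6:
            n_off = rng.randint(1, 12)
            raw = f"{pattern}({n_off}/{max(n_off - 2, 0)})"
        else:
            raw = pattern
        if rng.random() < commercial_fraction:
            suppliers = frozenset(
                rng.sample(_SUPPLIER_POOL, rng.randint(1, 3)))
        else:
            suppliers = frozenset()
        methylation = f"{rng.randint(1, len(pattern))}(6)" if rng.random() < 0.3 else ""
        refs = [f"Author{rng.randint(1, 99)}, A., ({rng.randint(1990, 2017)}) "
                f"Nucleic Acids Res. {rng.randint(10, 45)}."]
        if rng.random() < 0.3:
            refs.append(f"Author{rng.randint(1, 99)}, B., unpublished observations.")
        records.append(make_record(
            f"Zsy{i}I", raw,
            microorganism=f"Synthetica fictiva {i}",
            source=f"collection {rng.randint(100, 999)}",
            methylation=methylation,
            suppliers=suppliers,
            references=refs,
        ))
    records = [replace(rec, index=i) for i, rec in enumerate(records)]
    return Fixture(format_records(records, dialect), tuple(records))


def _row(rec: EnzymeRecord) -> dict:
    return {
        "name": rec.name,
        "prototype": rec.prototype,
        "microorganism": rec.microorganism,
        "source": rec.source,
        "recognition_raw": rec.recognition_raw,
        "pattern": rec.pattern,
        "cut_top": rec.cut_top,
        "cut_bottom": rec.cut_bottom,
        "methylation": rec.methylation,
        "suppliers": "".join(sorted(rec.suppliers)),
        "references": "; ".join(rec.references),
    }


def write_tsv(records: Iterable[EnzymeRecord], fh: TextIO) -> None:
    """Write one TSV row per record, columns in field order."""
    fh.write("\t".join(TSV_COLUMNS) + "\n")
    for rec in records:
        row = _row(rec)
        fh.write("\t".join(
            "" if row[c] is None else str(row[c]) for c in TSV_COLUMNS) + "\n")


def write_jsonl(records: Iterable[EnzymeRecord], fh: TextIO) -> None:
    """Write one JSON object per line per record."""
    for rec in records:
        fh.write(json.dumps(_row(rec)) + "\n")
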