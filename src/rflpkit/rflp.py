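"""PCR-RFLP judgment: which enzymes discriminate the alleles of a
variation.

For each allele of the judged variation site a concrete sequence is
realized and searched on both strands.  A hit *discriminates* when its
span intersects the realized allele span (for deletion alleles: when
the insertion point lies strictly inside the hit); all other hits are
*background*.  An enzyme is **specific** — usable for PCR-RFLP
genotyping — iff it cuts some but not all alleles at the variation and
has no background hit in any allele: a background site would cut every
genotype and destroy the diagnostic fragment pattern (an enzyme whose
site reappears elsewhere in the amplicon is excluded outright).
"""

from __future__ import annotations

import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from .errors import NoVariationError, ReportJoinError
from .matcher import MatchHit, find_sites
from .rebase_io import EnzymeRecord
from .seqvar import (
    DELETION,
    PLACEHOLDER,
    VariantTemplate,
    VariationSite,
    expand_alleles,
    flanking,
)

__all__ = [
    "JudgeOptions",
    "RflpVerdict",
    "ClassifiedVerdicts",
    "BatchResult",
    "judge_rflp",
    "enzymes_without_hits",
    "classify_results",
    "report",
    "report_to_tsv",
    "report_to_json",
    "judge_rflp_batch",
]

REPORT_COLUMNS = (
    "enzyme_name", "recognition", "pattern", "strand", "specific",
    "cut_alleles", "uncut_alleles", "variation_hits", "background_hits",
    "enzyme_class", "availability", "microorganism", "source",
    "methylation", "suppliers", "references",
)


@dataclass(frozen=True)
class JudgeOptions:
    """Filters and windowing applied before judgment.

    ``include_iupac_enzymes`` admits enzymes with degenerate
    recognition patterns; ``min_len``/``max_len`` bound recognition
    length; ``commercial_only`` keeps only supplier-listed enzymes;
    ``flank_radius`` trims the template to a window around the judged
    site before searching; ``site_index`` selects which variation to
    judge when several exist (the others are held at their first
    allele).
    """

    include_iupac_enzymes: bool = True
    min_len: int = 1
    max_len: Optional[int] = None
    commercial_only: bool = False
    flank_radius: Optional[int] = None
    site_index: int = 0

    def __post_init__(self) -> None:
        if self.max_len is not None and self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.flank_radius is not None and self.flank_radius < 1:
            raise ValueError("flank_radius must be >= 1 when present")


@dataclass(frozen=True)
class RflpVerdict:
    """Per-enzyme judgment for one variation site."""

    enzyme_name: str
    pattern: str
    strand: str
    cut_alleles: frozenset[str]
    uncut_alleles: frozenset[str]
    variation_hits: dict[str, tuple[MatchHit, ...]]
    background_hits: tuple[MatchHit, ...]
    specific: bool
    classification: tuple[str, str]


@dataclass
class ClassifiedVerdicts:
    """Verdicts split along the two classification axes."""

    iupac: list[RflpVerdict] = field(default_factory=list)
    general: list[RflpVerdict] = field(default_factory=list)
    commercial: list[RflpVerdict] = field(default_factory=list)
    non_commercial: list[RflpVerdict] = field(default_factory=list)


@dataclass(frozen=True)
class BatchResult:
    """One slot of a batch run: verdicts, or the error that replaced them."""

    ok: bool
    verdicts: Optional[list[RflpVerdict]]
    error: Optional[str]


def _passes_filters(enz: EnzymeRecord, options: JudgeOptions) -> bool:
    m = len(enz.pattern)
    if m < options.min_len:
        return False
    if options.max_len is not None and m > options.max_len:
        return False
    if options.commercial_only and not enz.is_commercial():
        return False
    if not options.include_iupac_enzymes and enz.is_iupac():
        return False
    return True


def _freeze_other_sites(template: VariantTemplate,
                        site_index: int) -> VariantTemplate:
    """Reduce to a single-site template: every other site realizes its
    first allele."""
    judged = template.sites[site_index]
    parts: list[str] = []
    new_pos = -1
    site_iter = iter(template.sites)
    current = next(site_iter, None)
    for i, c in enumerate(template.backbone):
        if c != PLACEHOLDER:
            parts.append(c)
            continue
        assert current is not None and current.position == i
        if current is judged:
            new_pos = sum(len(p) for p in parts)
            parts.append(PLACEHOLDER)
        else:
            first = current.alleles[0]
            parts.append("" if first == DELETION else first)
        current = next(site_iter, None)
    backbone = "".join(parts)
    return VariantTemplate(
        backbone, (VariationSite(new_pos, judged.alleles),), template.dialect)


def _overlaps(hit: MatchHit, span: tuple[int, int]) -> bool:
    lo, hi = span
    if lo == hi:  # deletion allele: insertion point strictly inside the hit
        return hit.start < lo < hit.end
    return hit.start < hi and hit.end > lo


def judge_rflp(template: VariantTemplate, enzymes: Sequence[EnzymeRecord],
               options: JudgeOptions = JudgeOptions()) -> list[RflpVerdict]:
    """Judge every enzyme against the alleles of one variation site.

    Returns one verdict per enzyme with at least one hit in any allele,
    sorted specific-first then by name.  Use
    :func:`enzymes_without_hits` for the complementary summary.
    """
    if not template.sites:
        raise NoVariationError("template carries no variation site")
    enzymes = [e for e in enzymes]
    if not enzymes:
        raise ValueError("enzyme catalog is empty")
    site_index = options.site_index
    if not (0 <= site_index < len(template.sites)):
        raise IndexError(f"site_index {site_index} out of range")
    if options.flank_radius is not None:
        center = template.sites[site_index].position
        lo = max(0, center - options.flank_radius)
        site_index = sum(
            1 for s in template.sites if lo <= s.position < center)
        template = flanking(template, options.flank_radius, options.site_index)
    reduced = _freeze_other_sites(template, site_index)
    allele_seqs = expand_alleles(reduced)
    all_labels = frozenset(a.alleles[0] for a in allele_seqs)
    records = {e.name: e for e in reversed(enzymes)}  # first occurrence wins

    var_hits: dict[str, dict[str, list[MatchHit]]] = {}
    bg_hits: dict[str, list[MatchHit]] = {}
    for aseq in allele_seqs:
        label = aseq.alleles[0]
        span = aseq.site_spans[0]
        hits = find_sites(
            aseq.sequence, enzymes,
            min_len=options.min_len, max_len=options.max_len,
            commercial_only=options.commercial_only,
            include_iupac=options.include_iupac_enzymes)
        for h in hits:
            if _overlaps(h, span):
                var_hits.setdefault(h.enzyme_name, {}).setdefault(
                    label, []).append(h)
            else:
                bg_hits.setdefault(h.enzyme_name, []).append(h)

    verdicts: list[RflpVerdict] = []
    for name in set(var_hits) | set(bg_hits):
        enz = records[name]
        per_allele = {
            lab: tuple(hs) for lab, hs in var_hits.get(name, {}).items()}
        cut = frozenset(per_allele)
        background = []
        seen = set()
        for h in bg_hits.get(name, []):
            key = (h.strand, h.start, h.end)
            if key not in seen:
                seen.add(key)
                background.append(h)
        strands = {h.strand for hs in per_allele.values() for h in hs}
        if not strands:
            strands = {h.strand for h in background}
        strand = "both" if len(strands) > 1 else next(iter(strands), "")
        specific = bool(cut) and cut != all_labels and not background
        verdicts.append(RflpVerdict(
            enzyme_name=name,
            pattern=enz.pattern,
            strand=strand,
            cut_alleles=cut,
            uncut_alleles=all_labels - cut,
            variation_hits=per_allele,
            background_hits=tuple(background),
            specific=specific,
            classification=(
                "iupac" if enz.is_iupac() else "general",
                "commercial" if enz.is_commercial() else "non-commercial"),
        ))
    verdicts.sort(key=lambda v: (not v.specific, v.enzyme_name))
    return verdicts


def enzymes_without_hits(verdicts: Sequence[RflpVerdict],
                         enzymes: Sequence[EnzymeRecord],
                         options: JudgeOptions = JudgeOptions()) -> list[str]:
    """Names of filter-surviving enzymes that produced no hit at all."""
    hit_names = {v.enzyme_name for v in verdicts}
    return [e.name for e in enzymes
            if _passes_filters(e, options) and e.name not in hit_names]


def classify_results(verdicts: Sequence[RflpVerdict]) -> ClassifiedVerdicts:
    """Split verdicts into composite-IUPAC vs general and commercial vs
    non-commercial (each verdict lands in exactly one bucket per axis)."""
    out = ClassifiedVerdicts()
    for v in verdicts:
        (out.iupac if v.classification[0] == "iupac" else out.general).append(v)
        (out.commercial if v.classification[1] == "commercial"
         else out.non_commercial).append(v)
    return out


def _fmt_hits(hits: Iterable[MatchHit]) -> str:
    # 1-based inclusive spans for reports
    return ",".join(f"{h.start + 1}-{h.end}{h.strand}" for h in hits)


def report(verdicts: Sequence[RflpVerdict],
           enzymes: Sequence[EnzymeRecord]) -> list[dict[str, str]]:
    """Join verdicts with full catalog records into flat string records
    (1-based coordinates, deterministic order)."""
    by_name = {e.name: e for e in reversed(enzymes)}
    out: list[dict[str, str]] = []
    for v in verdicts:
        if v.enzyme_name not in by_name:
            raise ReportJoinError(
                f"enzyme {v.enzyme_name!r} not found in the catalog")
        enz = by_name[v.enzyme_name]
        var = ";".join(
            f"{lab}:{_fmt_hits(v.variation_hits[lab])}"
            for lab in sorted(v.variation_hits))
        out.append({
            "enzyme_name": v.enzyme_name,
            "recognition": enz.recognition_raw,
            "pattern": v.pattern,
            "strand": v.strand,
            "specific": "yes" if v.specific else "no",
            "cut_alleles": "/".join(sorted(v.cut_alleles)),
            "uncut_alleles": "/".join(sorted(v.uncut_alleles)),
            "variation_hits": var,
            "background_hits": _fmt_hits(v.background_hits),
            "enzyme_class": v.classification[0],
            "availability": v.classification[1],
            "microorganism": enz.microorganism,
            "source": enz.source,
            "methylation": enz.methylation,
            "suppliers": "".join(sorted(enz.suppliers)),
            "references": "; ".join(enz.references),
        })
    return out


def report_to_tsv(records: Sequence[dict[str, str]], fh: TextIO) -> None:
    fh.write("\t".join(REPORT_COLUMNS) + "\n")
    for rec in records:
        fh.write("\t".join(rec[c] for c in REPORT_COLUMNS) + "\n")


def report_to_json(records: Sequence[dict[str, str]], fh: TextIO) -> None:
    json.dump(list(records), fh, indent=2)
    fh.write("\n")


def judge_rflp_batch(templates: Sequence[VariantTemplate],
                     enzymes: Sequence[EnzymeRecord],
                     options: JudgeOptions = JudgeOptions(),
                     workers: int = 1) -> list[BatchResult]:
    """Judge many templates; slot *i* of the output corresponds to
    ``templates[i]`` for any worker count.

    Per-template failures are captured as error slots without aborting
    the rest of the batch.
    """
    if not templates:
        raise ValueError("batch requires at least one template")
    if workers < 1:
        raise ValueError("workers must be >= 1")

    def one(template: VariantTemplate) -> BatchResult:
        try:
            return BatchResult(True, judge_rflp(template, enzymes, options), None)
        except Exception as exc:  # captured per slot, batch continues
            return BatchResult(False, None, f"{type(exc).__name__}: {exc}")

    if workers == 1:
        return [one(t) for t in templates]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(one, templates))
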