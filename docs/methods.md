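# Methods

## The judgment model

A *variant template* is a DNA backbone over {A,C,G,T} with variation
sites, each an ordered list of 2–4 distinct alleles; an allele is a run
of dNTPs or the deletion symbol `-`. For the judged site, one concrete
sequence per allele is realized (any other sites in the template are
held at their first allele, so exactly one variation is interrogated at
a time) and every catalog enzyme surviving the filters is searched in
each realization on both strands, the minus strand by searching the
reverse complement of the recognition pattern and reporting plus-strand
coordinates.

Hits are split by interval intersection on 0-based half-open spans:

- a **variation hit** intersects the realized allele span; for a
  deletion allele (empty span) the insertion point must lie *strictly*
  inside the hit, so a site merely abutting the junction does not
  count;
- every other hit is **background**.

An enzyme is **specific** — usable for PCR-RFLP — iff its set of cut
alleles is a nonempty proper subset of all alleles *and* it has no
background hit in any allele. Cutting all alleles gives identical
digests for every genotype; a background site cuts every genotype
outside the variation. Both conditions therefore disqualify. An enzyme
with a background hit is excluded outright even when the background
lies on the opposite strand from its discriminating hit: strandedness
does not rescue a restriction site, since the enzyme cleaves
double-stranded DNA wherever the site occurs. A hit on either strand
counts as cutting.

Two classification axes label each verdict: *composite-IUPAC* vs
*general* (whether the recognition pattern contains a degenerate
letter) and *commercial* vs *non-commercial* (whether the supplier set
is nonempty).

## Matching

Recognition patterns use the 15 IUPAC letters. Matching is by
compatibility: text base `t` matches pattern letter `p` iff
`t ∈ bases(p)`. This avoids expanding a degenerate pattern into its
(possibly exponential) concrete set; expansion is still exposed as an
operation and serves in tests as the equivalence oracle (matching a
degenerate pattern must equal the union over all its expansions).

The search is Boyer-Moore: right-to-left comparison, advance by the
larger of

- the **bad-character shift** — realign the rightmost pattern position
  whose degeneracy set contains the mismatched text letter (full
  pattern length when none exists);
- the **strong good-suffix shift** — realign the rightmost earlier
  occurrence of the matched suffix preceded by a different letter, or
  failing that the longest pattern prefix that is a suffix of the
  matched suffix (computed with the standard border-array
  preprocessing).

For degenerate patterns compatibility is not transitive (`R` "equals"
both `A` and `G` while `A ≠ G`), which breaks the reasoning behind the
good-suffix rule, so there the matcher uses bad-character shifts only —
a correctness-over-speed choice; every shift remains ≥ 1 and the
number of alignments is bounded by N − M + 1. Overlapping occurrences
are all reported (the repeat-exclusion rule needs them), and enzymes
whose pattern exceeds the text are skipped silently. The brute-force
scanner `naive_search` shares the exact contract and is retained
permanently as test oracle and benchmark baseline; a second,
independent step-by-step simulation of the shift rules (brute-force
strong-good-suffix computation) verifies not just the hit positions
but the entire shift sequence the matcher takes.

## Input dialects and coordinates

`plain` admits A/C/G/T only; `iupac` turns *every* degenerate letter
into a substitution site (whether an IUPAC letter may denote mere
ambiguity rather than variation is input-dependent, so the dialect is
explicit instead of guessed, and `auto` picks bracket/iupac/plain by
inspection); `bracket` writes alleles out, `[-/dNTPn]` for indels with
any n ≥ 1 under the expansion cap. Input is uppercased with whitespace
and digits stripped before validation, so pasted sequence-editor text
parses; any other nonconforming character is a typed error naming
position and character (the CLI maps it to exit code 3).

Internally all coordinates are 0-based half-open; user-facing reports
are 1-based inclusive, and BED output stays 0-based half-open.
Canonical allele order is A<C<G<T with `-` last. Bracket→IUPAC
transformation refuses indels and multi-base alleles, since no IUPAC
code encodes length polymorphism.

## Catalog handling

The flat-file dialect (field tags `<1>`…`<8>`, blank-line record
separation) is configurable because different catalog exports vary;
untagged lines continue the previous field so wrapped reference lists
parse. Cut notation: a caret inside the site gives the top-strand cut
offset; trailing `(n/m)` gives pattern length + n / + m; upstream
`(a/b)` on two-sided cutters is stored but unused — judgment needs
site presence, not fragment maps. Non-cutting entries (recognition
`?`) and entries missing name or recognition are skipped with
warnings; enzyme names are not assumed unique (file order
disambiguates). The supplier field is a set of single letters; any
nonempty set means commercially available. Methylation and
isoschizomer information are carried as opaque strings. Catalog
updates are manual: point the tools at a newer file.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| allele expansion cap | 256 | max product of per-site allele counts in `expand_alleles` |
| pattern expansion cap | 4096 | max concrete expansions of a degenerate pattern |
| `min_len` / `max_len` | 1 / none | recognition-length filter (bases) |
| `include_iupac_enzymes` | true | admit degenerate-pattern enzymes |
| `commercial_only` | false | require a nonempty supplier set |
| `flank_radius` | none | trim to ±radius backbone bases around the judged site before searching |
| `site_index` | 0 | which variation to judge in multi-site templates |
| batch `workers` | 1 | thread count; output is worker-count invariant |

`flank_radius` trades sensitivity for speed and locality: a smaller
window searches faster and ignores distant background sites, which is
the intended behaviour when the assay amplicon is short, but widening
it can legitimately flip a verdict by revealing a background hit.

## Synthetic data

The fixture generator emits catalogs in the same flat-file dialect the
real parser reads, so tests exercise the production code path. Entries
have recognition lengths 4–8 (the bulk of real catalog entries),
degenerate letters in a configurable fraction (default 0.3), supplier
sets in a configurable fraction (default 0.7), and a mix of caret,
`(n/m)` and bare notation; output is byte-deterministic per seed. Two
real enzymes anchor every fixture — TspGWI (ACGGA) and BspGI (CTGGAC) —
so the worked examples run against any generated catalog. Synthetic
batch templates are uniform-random flanks (default 500 bases per side,
matching a typical variant-flank retrieval) around one site. What this
does *not* emulate: real base composition and repeat structure, the
length tail of real catalogs (up to ~35 bases), isoschizomer clusters,
or methylation sensitivity — so passing tests demonstrate algorithmic
correctness, not performance or yield on genomic sequence.

Problem sizes used by the acceptance script: 10,000 random search
instances (text ≤ 200 nt, pattern ≤ 12 nt), 1,000 degenerate patterns
capped at 64 expansions, 500 strand-symmetry templates at 40-base
flanks, 100 catalog round-trip seeds, and one 381-template batch at
500-base flanks run with 1 and 4 workers.

## Numerical and degenerate-input choices

- Duplicate alleles, >4 alleles, malformed indel groups and unclosed
  brackets are parse errors, not warnings.
- A degenerate "variation" whose alleles are identical strings can be
  constructed programmatically; no enzyme is ever specific for it
  (the allele label set collapses, so no proper subset exists).
- Judging a template without variation raises; an empty catalog
  raises; in batch mode per-template failures are captured in their
  output slot and the batch continues.
- Verdict order is specific-first, then enzyme name; hits are ordered
  by (start, enzyme, strand) — all outputs are byte-reproducible.

## Known limitations

- No fragment-length or digest-map computation: cut offsets are parsed
  and stored, but judgment is by site presence, and gel patterns are
  not simulated.
- One variation is judged at a time; joint judgment of co-occurring
  variants is out of scope.
- No methylation-sensitivity filtering, isoschizomer cross-referencing,
  primer design, or catalog downloading.
- Threads provide ordering/robustness semantics for batch runs, not
  CPU parallelism under the GIL; the batch exists for throughput
  plumbing and determinism guarantees.
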