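# rflpkit

Restriction-enzyme site hunting and PCR-RFLP enzyme selection for DNA
sequences carrying variations.

## The problem

PCR-RFLP genotypes a variant by amplifying the region and digesting the
amplicon with a restriction enzyme whose recognition site exists in one
allele but not the other: the alleles then separate by fragment length
on a gel. Picking that enzyme by hand means scanning thousands of
catalog entries — many with degenerate (IUPAC) recognition sequences —
against every allele, on both strands, while rejecting enzymes whose
site also occurs elsewhere in the amplicon (such an enzyme cuts every
genotype and destroys the diagnostic pattern). `rflpkit` automates the
whole selection for molecular biologists and pipeline authors doing SNP
genotyping, mutation screening, or marker-assisted breeding.

## What it does

- **Catalog parsing** (`rflpkit.rebase_io`) — reads flat-text enzyme
  catalogs in the REBASE "parsed references" field-tag dialect
  (name, prototype, microorganism, source, recognition sequence,
  methylation, supplier codes, references), strips cut-site notation
  (`G^AATTC`, `GGTCTC(1/5)`), and can generate deterministic synthetic
  catalogs for testing.
- **Variation-aware input** (`rflpkit.seqvar`) — three sequence
  dialects: plain DNA, variation-by-IUPAC-code (`ACGGMTTT`), and
  bracketed alleles (`ACGG[A/C]TTTTTT`, up to tetra-allelic, indels as
  `[-/dNTPn]`); conversion between them, allele expansion, flanking
  windows, IUPAC-aware reverse complement, FASTA and line-per-template
  readers.
- **Site search** (`rflpkit.matcher`) — Boyer-Moore matching with
  bad-character and good-suffix shift rules, generalized to degenerate
  patterns via compatibility sets (text base `t` matches pattern letter
  `p` iff `t ∈ bases(p)`); a brute-force scanner with the identical
  contract is kept permanently as oracle and baseline; search runs on
  both strands.
- **RFLP judgment** (`rflpkit.rflp`) — an enzyme is *specific* for a
  variation iff it cuts some but not all alleles at the variant
  position and has no background site anywhere else in any allele.
  Verdicts are classified along two axes (composite-IUPAC vs general
  pattern; commercial vs non-commercial) and joined with full catalog
  records for reporting. A batch mode judges many templates with any
  worker count, deterministically.
- **CLI** (`rflpkit`) — `fixture`, `parse`, `search`, `judge`, `batch`
  subcommands writing TSV, JSON, or BED.

## Worked example

Judge the di-allelic variant `ACGG[A/C]TTTTTT` against a small catalog
containing TspGWI, whose recognition sequence is `ACGGA`:

```sh
$ rflpkit fixture 2 --seed 0 --out enzymes.txt
$ rflpkit judge "ACGG[A/C]TTTTTT" --rebase enzymes.txt
enzyme_name  recognition  pattern  strand  specific  cut_alleles  uncut_alleles  variation_hits  background_hits
TspGWI       ACGGA(11/9)  ACGGA    +       yes       A            C              A:1-5+
```

TspGWI's site spans bases 1–5 of the A allele only, so digestion
distinguishes the genotypes: `specific` is `yes`, the A allele is cut,
the C allele is not, and there is no background site. Appending a
second copy of the recognition sequence flips the verdict:

```sh
$ rflpkit judge "ACGG[A/C]TTTTTTACGGATTT" --rebase enzymes.txt
enzyme_name  recognition  pattern  strand  specific  cut_alleles  uncut_alleles  variation_hits  background_hits
TspGWI       ACGGA(11/9)  ACGGA    +       no        A            C              A:1-5+          12-16+
```

The background hit at bases 12–16 appears in both alleles, so the
enzyme would cut every genotype and is excluded (`specific` is `no`).

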