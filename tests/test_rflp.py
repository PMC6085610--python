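"""RFLP judgment: allele discrimination, background exclusion,
classification, reporting and batch mode."""

import csv
import io
import itertools
import json
import random

import pytest

from rflpkit.errors import NoVariationError, ReportJoinError
from rflpkit.rebase_io import generate_fixture, make_record
from rflpkit.rflp import (
    JudgeOptions,
    classify_results,
    enzymes_without_hits,
    judge_rflp,
    judge_rflp_batch,
    report,
    report_to_json,
    report_to_tsv,
)
from rflpkit.seqvar import (
    VariantTemplate,
    VariationSite,
    parse_input,
    reverse_complement_template,
    synthesize_template,
)


def specific_names(verdicts):
    return {v.enzyme_name for v in verdicts if v.specific}


class TestWorkedExamples:
    def test_snp_discriminated_by_tspgwi(self, anchor_catalog):
        verdicts = judge_rflp(parse_input("ACGG[A/C]TTTTTT"), anchor_catalog)
        (v,) = [v for v in verdicts if v.enzyme_name == "TspGWI"]
        assert v.specific
        assert v.cut_alleles == {"A"} and v.uncut_alleles == {"C"}
        assert v.background_hits == ()
        assert v.strand == "+"

    def test_repeat_site_excludes_enzyme(self, anchor_catalog):
        # the recognition sequence reappears downstream in both alleles
        verdicts = judge_rflp(
            parse_input("ACGG[A/C]TTTTTTACGGATTT"), anchor_catalog)
        (v,) = [v for v in verdicts if v.enzyme_name == "TspGWI"]
        assert not v.specific
        assert v.cut_alleles == {"A"}
        assert len(v.background_hits) == 1

    def test_flanking_window_can_drop_the_background(self, anchor_catalog):
        options = JudgeOptions(flank_radius=4)
        verdicts = judge_rflp(
            parse_input("ACGG[A/C]TTTTTTACGGATTT"), anchor_catalog, options)
        assert specific_names(verdicts) == {"TspGWI"}

    def test_general_only_judgment(self, snp_catalog):
        template = parse_input("AATTTCTGG[A/G]CCCTAACGGT")
        verdicts = judge_rflp(
            template, snp_catalog, JudgeOptions(include_iupac_enzymes=False))
        assert specific_names(verdicts) == {"BspGI"}
        (v,) = [v for v in verdicts if v.enzyme_name == "BspGI"]
        assert v.cut_alleles == {"A"}

    def test_iupac_judgment_is_strict_superset(self, snp_catalog):
        template = parse_input("AATTTCTGG[A/G]CCCTAACGGT")
        general = specific_names(judge_rflp(
            template, snp_catalog, JudgeOptions(include_iupac_enzymes=False)))
        full = specific_names(judge_rflp(template, snp_catalog))
        assert general < full
        assert full == {"BspGI", "ZdgAI", "ZdgBI", "ZdgCI"}


class TestJudgmentRules:
    def test_verdict_partitions_alleles(self, snp_catalog):
        for v in judge_rflp(parse_input("AATTTCTGG[A/G]CCCTAACGGT"),
                            snp_catalog):
            assert v.cut_alleles | v.uncut_alleles == {"A", "G"}
            assert not (v.cut_alleles & v.uncut_alleles)
            if v.specific:
                assert v.cut_alleles and v.cut_alleles != {"A", "G"}
                assert v.background_hits == ()

    def test_enzyme_cutting_all_alleles_not_specific(self):
        # variant position falls on the N of the pattern: both alleles cut
        enz = make_record("AnyI", "CGNAT")
        verdicts = judge_rflp(parse_input("TTACG[A/C]ATT"), [enz])
        (v,) = verdicts
        assert v.cut_alleles == {"A", "C"} and not v.specific

    def test_deletion_allele_insertion_point(self):
        enz = make_record("TspGWI", "ACGGA(11/9)")
        verdicts = judge_rflp(parse_input("ACG[-/T]GATC"), [enz])
        (v,) = verdicts
        assert v.specific
        assert v.cut_alleles == {"-"} and v.uncut_alleles == {"T"}

    def test_multisite_others_frozen_at_first_allele(self):
        # judging site 0: site 1 must realize its first allele G
        enz = make_record("ProbeI", "GGATTG")
        template = parse_input("ACG[G/T]ATT[G/C]AC")
        verdicts = judge_rflp(template, [enz], JudgeOptions(site_index=0))
        (v,) = verdicts
        assert v.cut_alleles == {"G"} and v.specific

    def test_site_index_selects_the_judged_variation(self):
        enz = make_record("ProbeI", "GGATTG")
        template = parse_input("ACG[G/T]ATT[G/C]AC")
        verdicts = judge_rflp(template, [enz], JudgeOptions(site_index=1))
        (v,) = verdicts
        assert v.cut_alleles == {"G"} and v.uncut_alleles == {"C"}

    def test_no_variation_and_empty_catalog_error(self, anchor_catalog):
        with pytest.raises(NoVariationError):
            judge_rflp(parse_input("ACGT"), anchor_catalog)
        with pytest.raises(ValueError):
            judge_rflp(parse_input("ACG[A/C]T"), [])

    def test_identical_alleles_never_specific(self, anchor_catalog):
        template = VariantTemplate(
            "ACGG*TTTTTT", (VariationSite(4, ("A", "A")),), "bracket")
        assert specific_names(judge_rflp(template, anchor_catalog)) == set()


class TestJudgmentProperties:
    def test_allele_permutation_invariance(self, snp_catalog):
        fwd = parse_input("AATTTCTGG[A/G]CCCTAACGGT")
        rev = parse_input("AATTTCTGG[G/A]CCCTAACGGT")
        assert specific_names(judge_rflp(fwd, snp_catalog)) == \
               specific_names(judge_rflp(rev, snp_catalog))

    def test_adding_enzymes_is_monotone(self, snp_catalog):
        template = parse_input("AATTTCTGG[A/G]CCCTAACGGT")
        before = specific_names(judge_rflp(template, snp_catalog[:2]))
        after = specific_names(judge_rflp(template, snp_catalog))
        assert before <= after

    def test_general_judgment_subset_of_full(self):
        catalog = list(generate_fixture(40, seed=21).records)
        rng = random.Random(3)
        for _ in range(10):
            template = synthesize_template(rng, flank_length=30)
            restricted = judge_rflp(
                template, catalog, JudgeOptions(include_iupac_enzymes=False))
            full = judge_rflp(template, catalog)
            assert specific_names(restricted) <= specific_names(full)
            assert all(v.classification[0] == "general" for v in restricted)

    def test_strand_symmetry(self):
        catalog = list(generate_fixture(30, seed=13).records)
        rng = random.Random(17)
        for _ in range(20):
            template = synthesize_template(rng, flank_length=40)
            mirrored = reverse_complement_template(template)
            fwd = specific_names(judge_rflp(template, catalog))
            rev = specific_names(judge_rflp(mirrored, catalog))
            assert fwd == rev


class TestClassification:
    def test_axes(self, snp_catalog):
        verdicts = judge_rflp(
            parse_input("AATTTCTGG[A/G]CCCTAACGGT"), snp_catalog)
        buckets = classify_results(verdicts)
        names = {v.enzyme_name: v for v in verdicts}
        assert names["BspGI"] in buckets.general
        assert names["BspGI"] in buckets.commercial
        assert names["ZdgAI"] in buckets.iupac
        assert names["ZdgBI"] in buckets.non_commercial
        assert len(buckets.iupac) + len(buckets.general) == len(verdicts)
        assert len(buckets.commercial) + len(buckets.non_commercial) == \
               len(verdicts)

    def test_degenerate_pattern_always_iupac_bucket(self):
        enz = make_record("ZnI", "GGTNACC", suppliers="N")
        verdicts = judge_rflp(parse_input("AAGGT[A/C]ACCTT"), [enz])
        assert classify_results(verdicts).iupac == verdicts

    def test_empty_verdicts(self):
        buckets = classify_results([])
        assert buckets.iupac == buckets.general == [] \
            and buckets.commercial == buckets.non_commercial == []


class TestReport:
    def test_joined_record_carries_catalog_fields(self, anchor_catalog):
        verdicts = judge_rflp(parse_input("ACGG[A/C]TTTTTT"), anchor_catalog)
        records = report(verdicts, anchor_catalog)
        row = records[0]
        assert row["enzyme_name"] == "TspGWI"
        for field in ("microorganism", "source", "recognition",
                      "methylation", "suppliers", "references"):
            assert field in row
        assert row["variation_hits"] == "A:1-5+"  # 1-based inclusive

    def test_empty_verdicts_empty_report(self, anchor_catalog):
        assert report([], anchor_catalog) == []

    def test_unknown_enzyme_raises(self, anchor_catalog):
        verdicts = judge_rflp(parse_input("ACGG[A/C]TTTTTT"), anchor_catalog)
        with pytest.raises(ReportJoinError):
            report(verdicts, anchor_catalog[1:])

    def test_tsv_and_json_renderings_field_equal(self, snp_catalog):
        verdicts = judge_rflp(
            parse_input("AATTTCTGG[A/G]CCCTAACGGT"), snp_catalog)
        records = report(verdicts, snp_catalog)
        tsv, js = io.StringIO(), io.StringIO()
        report_to_tsv(records, tsv)
        report_to_json(records, js)
        tsv.seek(0)
        from_tsv = list(csv.DictReader(tsv, delimiter="\t"))
        from_json = json.loads(js.getvalue())
        assert from_tsv == from_json == records

    def test_enzymes_without_hits_summary(self, snp_catalog):
        verdicts = judge_rflp(
            parse_input("AATTTCTGG[A/G]CCCTAACGGT"), snp_catalog)
        assert enzymes_without_hits(verdicts, snp_catalog) == ["TspGWI"]
        general = JudgeOptions(include_iupac_enzymes=False)
        verdicts_g = judge_rflp(
            parse_input("AATTTCTGG[A/G]CCCTAACGGT"), snp_catalog, general)
        assert enzymes_without_hits(verdicts_g, snp_catalog, general) == \
               ["TspGWI"]


class TestBatch:
    def test_batch_of_one_wraps_single_judgment(self, anchor_catalog):
        template = parse_input("ACGG[A/C]TTTTTT")
        (slot,) = judge_rflp_batch([template], anchor_catalog)
        assert slot.ok
        assert slot.verdicts == judge_rflp(template, anchor_catalog)

    def test_worker_counts_agree(self, snp_catalog):
        templates = [
            parse_input("ACGG[A/C]TTTTTT"),
            parse_input("ACGG[A/C]TTTTTTACGGATTT"),
            parse_input("AATTTCTGG[A/G]CCCTAACGGT"),
        ]
        seq = judge_rflp_batch(templates, snp_catalog, workers=1)
        par = judge_rflp_batch(templates, snp_catalog, workers=4)
        assert seq == par

    def test_failures_captured_in_place(self, anchor_catalog):
        templates = [parse_input("ACGG[A/C]TTTTTT"), parse_input("ACGT")]
        results = judge_rflp_batch(templates, anchor_catalog, workers=2)
        assert results[0].ok and not results[1].ok
        assert "NoVariationError" in results[1].error

    def test_empty_batch_rejected(self, anchor_catalog):
        with pytest.raises(ValueError):
            judge_rflp_batch([], anchor_catalog)
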