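"""Variant model, filter cascade, and tabular I/O."""

import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from nsclc_biomarkers import FilterProfile, filter_variants, read_variants, write_variants
from nsclc_biomarkers.variants import VariantIOError

from conftest import make_variant


class TestVariantModel:
    def test_amplification_must_have_empty_alleles(self):
        with pytest.raises(ValidationError):
            make_variant(consequence="amplification", ref="A", alt="T")
        v = make_variant(consequence="amplification", ref="", alt="", hgvs_p="")
        assert v.max_pop_freq() == 0.0

    def test_unknown_consequence_rejected(self):
        with pytest.raises(ValidationError):
            make_variant(consequence="nonsense_mediated_decay")

    def test_out_of_range_af_rejected(self):
        with pytest.raises(ValidationError):
            make_variant(allele_frequency=1.5)


class TestFilterCascade:
    def test_low_af_missense_removed_under_reporting(self):
        # calls below the 5% allele-fraction floor are dropped
        kept = filter_variants(
            [make_variant(allele_frequency=0.04)], FilterProfile.reporting()
        )
        assert kept == []

    def test_af_boundary_inclusive(self):
        kept = filter_variants(
            [make_variant(allele_frequency=0.05)], FilterProfile.reporting()
        )
        assert len(kept) == 1

    def test_common_population_variant_removed(self):
        # >1.5% in any population database is treated as germline/common
        v = make_variant(pop_freqs={"1kg": 0.02, "esp6500": 0.0})
        assert filter_variants([v], FilterProfile.reporting()) == []
        boundary = make_variant(pop_freqs={"1kg": 0.015, "esp6500": 0.0})
        assert len(filter_variants([boundary], FilterProfile.reporting())) == 1

    def test_empty_input_identity(self):
        assert filter_variants([], FilterProfile.reporting()) == []

    def test_six_row_toy_table_reporting_vs_tmb(self):
        # enumerated by hand: reporting drops both silents, the low-AF missense
        # and the common variant, keeping 2; tmb keeps the passing silent too.
        variants = [
            make_variant(hgvs_p="p.K100K", consequence="silent", allele_frequency=0.2),
            make_variant(hgvs_p="p.K200K", consequence="silent", allele_frequency=0.02),
            make_variant(hgvs_p="p.A300T", allele_frequency=0.02),
            make_variant(hgvs_p="p.A400T", pop_freqs={"1kg": 0.02, "esp6500": 0.0}),
            make_variant(hgvs_p="p.A500T"),
            make_variant(hgvs_p="p.A600T"),
        ]
        reporting = filter_variants(variants, FilterProfile.reporting())
        assert [v.hgvs_p for v in reporting] == ["p.A500T", "p.A600T"]
        tmb = filter_variants(variants, FilterProfile.tmb())
        assert [v.hgvs_p for v in tmb] == ["p.K100K", "p.A500T", "p.A600T"]

    def test_amplification_af_exemption_only_for_reporting(self):
        amp = make_variant(
            consequence="amplification", ref="", alt="", hgvs_p="", allele_frequency=0.0
        )
        assert len(filter_variants([amp], FilterProfile.reporting())) == 1
        assert filter_variants([amp], FilterProfile.tmb()) == []

    def test_reporting_never_keeps_silent(self):
        silent = make_variant(consequence="silent", allele_frequency=0.5)
        assert filter_variants([silent], FilterProfile.reporting()) == []

    @settings(deadline=None, max_examples=50)
    @given(
        afs=st.lists(st.floats(0, 1, allow_nan=False), min_size=0, max_size=20),
        conseq=st.sampled_from(["missense", "silent", "stopgain", "frameshift_indel"]),
    )
    def test_filter_idempotent_subset_order_preserving(self, afs, conseq):
        variants = [
            make_variant(hgvs_p=f"p.A{i+1}T", consequence=conseq, allele_frequency=af)
            for i, af in enumerate(afs)
        ]
        profile = FilterProfile.tmb()
        once = filter_variants(variants, profile)
        assert filter_variants(once, profile) == once
        assert all(v in variants for v in once)
        positions = [variants.index(v) for v in once]
        assert positions == sorted(positions)


class TestTabularIO:
    def test_maf_round_trip(self, tmp_path):
        variants = [
            make_variant(sample_id=f"S{i}", pos=100 + i, allele_frequency=0.05 + 0.01 * i)
            for i in range(10)
        ]
        path = tmp_path / "variants.tsv"
        write_variants(variants, path)
        assert read_variants(path, format="maf-tsv") == variants

    def test_one_based_position_preserved(self, tmp_path):
        v = make_variant(pos=1)
        path = tmp_path / "v.tsv"
        write_variants([v], path)
        assert read_variants(path)[0].pos == 1

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tgene\nS1\tEGFR\n")
        with pytest.raises(VariantIOError, match="chrom"):
            read_variants(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_variants([make_variant()], path)
        with open(path, "a") as fh:
            fh.write("S2\tEGFR\t7\tnot_an_int\tA\tT\tp.L858R\tmissense\t0.3\t500\t0\t0\tfalse\n")
        with pytest.raises(VariantIOError, match="line 3"):
            read_variants(path)

    def test_vcf_read_and_missing_annotation(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=HGVSP,Number=1,Type=String,Description="p">\n'
            '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="c">\n'
            '##INFO=<ID=AF,Number=1,Type=Float,Description="af">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "##contig=<ID=7>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        ok = tmp_path / "ok.vcf"
        ok.write_text(
            header
            + "7\t55191822\t.\tT\tG\t.\t.\tGENE=EGFR;HGVSP=p.L858R;CONSEQ=missense;AF=0.31;DP=420\n"
        )
        calls = read_variants(ok, format="vcf")
        assert calls[0].hgvs_p == "p.L858R"
        assert calls[0].pos == 55191822
        assert calls[0].allele_frequency == pytest.approx(0.31)

        bad = tmp_path / "bad.vcf"
        bad.write_text(header + "7\t55191822\t.\tT\tG\t.\t.\tGENE=EGFR;AF=0.3\n")
        with pytest.raises(VariantIOError, match="CONSEQ"):
            read_variants(bad, format="vcf")
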