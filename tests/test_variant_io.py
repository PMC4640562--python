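"""Input/output contracts: mutation tables, VCF trios, reports."""

import json

import pytest

from clstest.exceptions import FormatError, InputError, ValidationError
from clstest.hc_filter import HCProfile
from clstest.cls_test import run_cls_test
from clstest.simulate import generate_fixture_trio
from clstest.variant_io import (
    LocusKey,
    SampleEvidence,
    read_mutation_table,
    read_report,
    read_trio_vcfs,
    write_mutation_table,
    write_report,
    write_trio_vcfs,
)

HEADER = (
    "chrom\tpos\tref\talt\tgermline_depth\tgermline_alt\tgermline_hq_depth\t"
    "tumor_a_depth\ttumor_a_alt\ttumor_a_hq_depth\ttumor_a_called\t"
    "tumor_b_depth\ttumor_b_alt\ttumor_b_hq_depth\ttumor_b_called\tdbsnp\n"
)


class TestMutationTable:
    def test_rows_map_to_records(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            HEADER
            + "chr1\t100\tA\tT\t30\t0\t30\t60\t40\t60\t1\t80\t30\t80\t1\t0\n"
            + "chr2\t5\tC\tG\t20\t1\t18\t50\t0\t50\t0\t45\t20\t45\t1\t1\n"
            + "chrX\t7\tG\tA\t25\t0\t25\t41\t15\t41\t1\t42\t0\t42\t0\t0\n"
        )
        records = read_mutation_table(path)
        assert len(records) == 3
        first = records[0]
        assert first.key == LocusKey("chr1", 100, "A", "T")
        assert first.germline == SampleEvidence(30, 0, 30, called=False)
        assert first.tumor_a.alt_count == 40 and first.tumor_a.called
        assert records[1].in_dbsnp and not records[2].in_dbsnp

    def test_header_only_table_is_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(HEADER)
        assert read_mutation_table(path) == []

    def test_zero_position_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(HEADER + "chr1\t0\tA\tT\t30\t0\t30\t60\t40\t60\t1\t80\t30\t80\t1\t0\n")
        with pytest.raises(ValidationError, match="1-based"):
            read_mutation_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tref\talt\nchr1\t1\tA\tT\n")
        with pytest.raises(FormatError, match="germline_depth"):
            read_mutation_table(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError, match="nope.tsv"):
            read_mutation_table(tmp_path / "nope.tsv")

    def test_write_read_round_trip(self, tmp_path):
        records = generate_fixture_trio(5, 2, 3, {"dbsnp": 2, "tumor_coverage": 1}, seed=11)
        path = tmp_path / "rt.tsv"
        write_mutation_table(records, path)
        assert read_mutation_table(path) == records


class TestVcfTrio:
    def test_fixture_round_trip_100_loci(self, tmp_path):
        records = sorted(
            generate_fixture_trio(60, 20, 15, {"dbsnp": 3, "germline_coverage": 2}, seed=1),
            key=lambda r: r.key,
        )
        assert len(records) == 100
        paths = [tmp_path / f"{s}.vcf" for s in ("g", "a", "b")]
        write_trio_vcfs(records, *paths)
        assert read_trio_vcfs(*paths) == records

    def test_deterministic_parse(self, tmp_path):
        records = generate_fixture_trio(4, 2, 1, seed=5)
        paths = [tmp_path / f"{s}.vcf" for s in ("g", "a", "b")]
        write_trio_vcfs(records, *paths)
        assert read_trio_vcfs(*paths) == read_trio_vcfs(*paths)

    def test_absent_tumor_record_encoded_as_uncalled(self, tmp_path):
        """A locus called only in tumor A yields tumor_b.called False (zero depth)."""
        head = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
        )
        (tmp_path / "a.vcf").write_text(head + "chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP:AD\t0/1:100:60,40\n")
        (tmp_path / "b.vcf").write_text(head)
        (tmp_path / "g.vcf").write_text(head + "chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP:AD\t0/0:30:30,0\n")
        records = read_trio_vcfs(tmp_path / "g.vcf", tmp_path / "a.vcf", tmp_path / "b.vcf")
        assert len(records) == 1
        rec = records[0]
        assert rec.tumor_a.called and rec.tumor_a.alt_count == 40
        assert not rec.tumor_b.called and rec.tumor_b.total_depth == 0
        assert rec.germline.total_depth == 30

    def test_multiallelic_record_split_per_alt(self, tmp_path):
        head = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
        )
        (tmp_path / "a.vcf").write_text(
            head + "chr1\t50\t.\tA\tT,C\t.\t.\t.\tGT:DP:AD\t1/2:90:10,45,35\n"
        )
        (tmp_path / "b.vcf").write_text(head)
        (tmp_path / "g.vcf").write_text(head + "chr1\t50\t.\tA\tT\t.\t.\t.\tGT:DP:AD\t0/0:30:30,0\n")
        records = read_trio_vcfs(tmp_path / "g.vcf", tmp_path / "a.vcf", tmp_path / "b.vcf")
        assert {r.key.alt for r in records} == {"T", "C"}
        by_alt = {r.key.alt: r for r in records}
        assert by_alt["T"].tumor_a.alt_count == 45
        assert by_alt["C"].tumor_a.alt_count == 35

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError, match="a.vcf"):
            read_trio_vcfs(tmp_path / "g.vcf", tmp_path / "a.vcf", tmp_path / "b.vcf")

    def test_cross_format_equivalence(self, tmp_path):
        """VCF trio and mutation table carry identical evidence for the same content."""
        records = sorted(
            generate_fixture_trio(10, 4, 6, {"dbsnp": 2}, seed=9), key=lambda r: r.key
        )
        vcfs = [tmp_path / f"{s}.vcf" for s in ("g", "a", "b")]
        write_trio_vcfs(records, *vcfs)
        table = tmp_path / "t.tsv"
        write_mutation_table(records, table)
        assert read_trio_vcfs(*vcfs) == sorted(read_mutation_table(table), key=lambda r: r.key)


class TestReports:
    def test_json_report_fields(self, tmp_path):
        result = run_cls_test(HCProfile.from_counts(50, 62))
        path = tmp_path / "r.json"
        write_report(result, path, "json")
        payload = read_report(path)
        assert payload["cls_display"] == "81"
        assert round(payload["cls"], 1) == 80.6
        assert payload["decision"] == "clonal"
        assert payload["params"]["p0"] == 0.04
        # full precision preserved through the round trip
        assert payload["p_value"] == result.p_value
        assert payload["ci_low"] == result.ci_low

    def test_tsv_report_single_row(self, tmp_path):
        import pandas as pd

        result = run_cls_test(HCProfile.from_counts(2, 184))
        path = tmp_path / "r.tsv"
        write_report(result, path, "tsv")
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 1
        assert df.loc[0, "decision"] == "independence_not_rejected"

    def test_bad_format_rejected(self, tmp_path):
        result = run_cls_test(HCProfile.from_counts(1, 50))
        with pytest.raises(ValidationError):
            write_report(result, tmp_path / "r.xml", "xml")
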