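"""Upstream-dialect parsing, structured CSV determinism, lossless round-trips."""

import io

import pytest

from genovault import datastore, etl
from genovault.etl import EtlError
from genovault.records import FusionRecord, GeneCountRecord

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=20000000>
##contig=<ID=2,length=16000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="d">
##INFO=<ID=GENE,Number=1,Type=String,Description="g">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
"""


def write_vcf(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestParseVcf:
    def test_depth_and_alt_from_format_ad_dp(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "1\t12345\t.\tA\tT\t50\tPASS\tDP=100;GENE=SG1\tGT:AD:DP\t"
            "0/1:70,30:100\n",
        )
        (rec,) = etl.parse_vcf(p, "S1", "dna_panel")
        assert (rec.pos, rec.depth, rec.alt_count) == (12345, 100, 30)
        assert rec.vaf == pytest.approx(0.3)
        assert rec.filter_status == "PASS"
        assert rec.gene_symbol == "SG1"

    def test_multiallelic_line_split_per_alt(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "1\t500\t.\tA\tT,G\t50\tPASS\tDP=90\tGT:AD:DP\t"
            "1/2:30,40,20:90\n",
        )
        recs = etl.parse_vcf(p, "S1", "dna_panel")
        assert [r.alt_allele for r in recs] == ["T", "G"]
        assert [r.pos for r in recs] == [500, 500]
        assert [r.alt_count for r in recs] == [40, 20]

    def test_missing_depth_fields_annotated_nodepth(self, tmp_path):
        p = write_vcf(tmp_path, "1\t500\t.\tA\tT\t50\tPASS\t.\tGT\t0/1\n")
        (rec,) = etl.parse_vcf(p, "S1", "rna_expressed")
        assert (rec.depth, rec.alt_count, rec.vaf) == (0, 0, 0.0)
        assert "nodepth" in rec.filter_status

    def test_info_dp_fallback(self, tmp_path):
        p = write_vcf(tmp_path, "1\t500\t.\tA\tT\t50\tPASS\tDP=77\tGT\t0/1\n")
        (rec,) = etl.parse_vcf(p, "S1", "dna_panel")
        assert rec.depth == 77 and rec.alt_count == 0

    def test_short_data_line_error_names_line_number(self, tmp_path):
        p = write_vcf(tmp_path, "1\t500\t.\tA\n")
        with pytest.raises(EtlError, match="line 10"):
            etl.parse_vcf(p, "S1", "dna_panel")

    def test_missing_header_is_an_error(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("##fileformat=VCFv4.2\n1\t1\t.\tA\tT\t.\t.\tDP=1\n")
        with pytest.raises(EtlError, match="#CHROM"):
            etl.parse_vcf(p, "S1", "dna_panel")

    def test_synthetic_vcfs_match_planted_truth(self, study):
        truth = study["truth"]
        for sid, planted in truth.mutations.items():
            recs = etl.parse_vcf(
                study["dir"] / "dna" / f"{sid}.vcf", sid, "dna_panel"
            )
            assert len(recs) == len(planted)
            for rec, t in zip(recs, planted):
                assert (rec.chrom, rec.pos) == (t["chrom"], t["pos"])
                assert (rec.ref_allele, rec.alt_allele) == (t["ref"], t["alt"])
                assert (rec.depth, rec.alt_count) == (t["depth"], t["alt_count"])
                assert rec.vaf == pytest.approx(t["vaf"])


class TestParseSegments:
    SEG = (
        "ID\tchrom\tstart\tend\tnum.mark\tmedian.logR\tcopy.number\tcall\t"
        "subclone.status\n"
    )

    def test_neutral_row_maps_to_normal(self):
        stream = io.StringIO(
            self.SEG + "S\t1\t1000\t5000\t4\t0.0\t2\tNEUT\tFALSE\n"
        )
        (seg,) = etl.parse_cnv_segments(stream, "S1")
        assert seg.cn_type == "normal"
        assert (seg.start, seg.end, seg.median_logR) == (1000, 5000, 0.0)

    @pytest.mark.parametrize(
        "cn,expected",
        [(0, "deletion"), (1, "deletion"), (2, "normal"),
         (3, "amplification"), (5, "amplification")],
    )
    def test_cn_type_rule(self, cn, expected):
        stream = io.StringIO(
            self.SEG + f"S\t1\t1\t10\t1\t0.1\t{cn}\tX\tFALSE\n"
        )
        (seg,) = etl.parse_cnv_segments(stream, "S1")
        assert seg.cn_type == expected

    def test_start_after_end_is_an_error(self):
        stream = io.StringIO(self.SEG + "S\t1\t50\t10\t1\t0.0\t2\tN\tF\n")
        with pytest.raises(EtlError, match="start 50 > end 10"):
            etl.parse_cnv_segments(stream, "S1")

    def test_unknown_header_lists_expected_names(self):
        stream = io.StringIO("a\tb\tc\n1\t2\t3\n")
        with pytest.raises(EtlError, match="lacks required columns"):
            etl.parse_cnv_segments(stream, "S1")

    def test_synthetic_profile_matches_planted_segments(self, study):
        truth = study["truth"]
        sid = "T1R1"
        segs = etl.parse_cnv_segments(study["dir"] / "cnv" / f"{sid}.seg", sid)
        planted = sorted(
            truth.cnv[sid], key=lambda r: (r["chrom"], r["start"])
        )
        assert len(segs) == study["config"].n_cnv_segments
        for seg, t in zip(segs, planted):
            assert (seg.chrom, seg.start, seg.end) == (
                t["chrom"], t["start"], t["end"]
            )
            assert seg.copy_number == t["copy_number"]
            assert seg.median_logR == pytest.approx(t["median_logR"])
            assert seg.subclone == t["subclone"]


class TestParseCounts:
    def test_two_genes_three_samples_gives_six_records(self):
        stream = io.StringIO(
            "gene_id\tA\tB\tC\nG1\t1\t2\t3\nG2\t0\t5\t6\n"
        )
        recs = etl.parse_gene_counts(stream)
        assert len(recs) == 6
        zero = [r for r in recs if r.count == 0]
        assert len(zero) == 1 and zero[0].gene_id == "G2"

    def test_negative_count_rejected(self):
        stream = io.StringIO("gene_id\tA\nG1\t-1\n")
        with pytest.raises(EtlError, match="negative count"):
            etl.parse_gene_counts(stream)

    def test_duplicate_gene_rejected(self):
        stream = io.StringIO("gene_id\tA\nG1\t1\nG1\t2\n")
        with pytest.raises(EtlError, match="duplicated id"):
            etl.parse_gene_counts(stream)

    def test_isoform_matrix_requires_gene_id_column(self):
        stream = io.StringIO("isoform_id\tA\nI1\t1\n")
        with pytest.raises(EtlError, match="gene_id"):
            etl.parse_isoform_counts(stream)


class TestParseFusions:
    TSV = (
        "#FusionName\tJunctionReadCount\tSpanningFragCount\t"
        "LeftBreakpoint\tRightBreakpoint\n"
    )

    def test_field_mapping(self):
        stream = io.StringIO(
            self.TSV + "BCR--ABL1\t10\t5\t22:23632600:+\t9:133729451:+\n"
        )
        (rec,) = etl.parse_fusions(stream, "S1")
        assert rec == FusionRecord(
            "S1", "BCR", "ABL1", "22:23632600:+", "9:133729451:+", 10, 5
        )

    def test_zero_support_rejected(self):
        stream = io.StringIO(self.TSV + "A--B\t0\t0\t1:1:+\t2:2:-\n")
        with pytest.raises(EtlError, match="no\\s+supporting reads"):
            etl.parse_fusions(stream, "S1")

    def test_name_without_separator_rejected(self):
        stream = io.StringIO(self.TSV + "AB\t1\t0\t1:1:+\t2:2:-\n")
        with pytest.raises(EtlError, match="lacks '--'"):
            etl.parse_fusions(stream, "S1")

    def test_synthetic_table_row_count(self, study):
        sid = "T2R2"
        recs = etl.parse_fusions(
            study["dir"] / "rna" / "fusions" / f"{sid}.fusions.tsv", sid
        )
        assert len(recs) == study["config"].n_fusions


class TestStructuredCsv:
    def test_empty_batch_writes_header_only(self, tmp_path):
        p = etl.write_structured_csv_kind("gene_counts", [], tmp_path / "g.csv")
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("sample_id,gene_id")

    def test_rewriting_same_records_is_byte_identical(self, tmp_path):
        recs = [
            GeneCountRecord("S2", "G2", "", "", 1.5),
            GeneCountRecord("S1", "G1", "sym", "1:5-10", 2.0),
        ]
        a = etl.write_structured_csv(recs, tmp_path / "a.csv").read_bytes()
        b = etl.write_structured_csv(
            list(reversed(recs)), tmp_path / "b.csv"
        ).read_bytes()
        assert a == b
        assert b"\r" not in a  # LF only

    def test_header_mismatch_on_import_names_columns(self, tmp_path, fresh_db):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,gene_id,count\n")
        with pytest.raises(EtlError, match="missing.*extra"):
            etl.import_structured_csv(fresh_db, "gene_counts", p)

    def test_parse_write_import_query_is_lossless(self, tmp_path, seeded_db):
        stream = io.StringIO(
            "gene_id\tgene_symbol\tlocus\tS1\tS2\n"
            "G1\tA\t1:1-10\t5\t0\nG2\tB\t2:5-9\t1.5\t2\n"
        )
        recs = etl.parse_gene_counts(stream)
        p = etl.write_structured_csv(recs, tmp_path / "g.csv")
        n = etl.import_structured_csv(seeded_db, "gene_counts", p)
        assert n == 4
        back = datastore.query_table(seeded_db, "gene_counts")
        assert sorted(map(repr, back)) == sorted(map(repr, recs))


class TestEndToEnd:
    def test_full_study_etl_counts(self, study):
        db, config = study["db"], study["config"]
        n_samples = len(config.rna_samples)
        assert db.count("study_metadata") == 21
        assert db.count("gene_counts") == config.n_genes * n_samples
        assert db.count("cnv_segments") == config.n_cnv_segments * n_samples
        assert db.count("fusions") == config.n_fusions * n_samples
        n_panel = len(config.panel_samples) * config.n_mutations
        n_rna = int(config.expressed_fraction * config.n_mutations) * len(
            config.panel_samples
        )
        assert db.count("mutations") == n_panel + n_rna

    def test_gene_counts_match_emitted_matrix(self, study):
        recs = datastore.query_table(
            study["db"], "gene_counts", filter={"sample_id": "T1R1"}
        )
        text = (study["dir"] / "rna" / "counts_gene.tsv").read_text()
        lines = text.splitlines()
        col = lines[0].split("\t").index("T1R1")
        from_file = {
            ln.split("\t")[0]: float(ln.split("\t")[col])
            for ln in lines[1:]
        }
        assert {r.gene_id: r.count for r in recs} == from_file
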