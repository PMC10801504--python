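"""Domain-type invariants and file ingestion (GTF / bedGraph / BED)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dogscan.discovery import DoGRecord
from dogscan.io import (
    ParseError,
    read_annotation,
    read_coverage,
    read_dogs_bed,
    read_peaks,
    read_sample_sheet,
    write_dogs_bed,
)
from dogscan.model import CoverageTrack, DoGParams, GeneModel, GenomicInterval, PeakSet


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
    def test_rejects_degenerate_coordinates(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    @given(st.integers(0, 10**8), st.integers(1, 10**6))
    @settings(max_examples=50, derandomize=True)
    def test_length_is_end_minus_start(self, start, span):
        iv = GenomicInterval("chr1", start, start + span)
        assert iv.length() == span

    def test_overlap_requires_shared_base_and_chromosome(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # half-open abutment
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestGeneModel:
    def test_tss_tes_follow_strand(self):
        plus = GeneModel("G1", GenomicInterval("chr1", 100, 500, "+"))
        minus = GeneModel("G2", GenomicInterval("chr1", 100, 500, "-"))
        assert (plus.tss, plus.tes) == (100, 500)
        assert (minus.tss, minus.tes) == (500, 100)


class TestReadAnnotation:
    def test_gtf_coordinates_become_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\t.\tgene\t1001\t3000\t.\t+\t.\tgene_id "G1";\n')
        (g,) = read_annotation(p)
        assert g.gene_id == "G1"
        assert (g.interval.start, g.interval.end) == (1000, 3000)
        assert (g.tss, g.tes) == (1000, 3000)
        assert g.interval.length() == 2000  # span preserved exactly

    def test_gene_span_is_union_of_transcript_records(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\t.\ttranscript\t501\t2000\t.\t+\t.\tgene_id "G2";\n'
            'chr1\t.\ttranscript\t801\t2600\t.\t+\t.\tgene_id "G2";\n'
        )
        (g,) = read_annotation(p)
        assert (g.interval.start, g.interval.end) == (500, 2600)

    def test_empty_file_yields_empty_set_with_warning(self, tmp_path, caplog):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_annotation(p) == []
        assert any("no records" in r.message for r in caplog.records)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\t.\tgene\t1\t100\t.\t+\t.\tgene_id "G1";\n'
            "chr1\tgarbage\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_annotation(p)

    def test_conflicting_strand_drops_gene(self, tmp_path, caplog):
        p = tmp_path / "conflict.gtf"
        p.write_text(
            'chr1\t.\tgene\t1\t100\t.\t+\t.\tgene_id "G1";\n'
            'chr1\t.\tgene\t200\t300\t.\t-\t.\tgene_id "G1";\n'
            'chr1\t.\tgene\t400\t500\t.\t+\t.\tgene_id "G2";\n'
        )
        with caplog.at_level("WARNING"):
            genes = read_annotation(p)
        assert [g.gene_id for g in genes] == ["G2"]


class TestReadCoverage:
    def test_depth_reconstructed_with_zero_elsewhere(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t10\t5\n")
        t = read_coverage(p, library_size=1000)
        assert t.depth_sum("chr1", 0, 10) == 50
        assert t.depth_sum("chr1", 10, 100) == 0
        assert t.depth_sum("chr2", 0, 100) == 0

    def test_empty_file_is_all_zero_track(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("")
        t = read_coverage(p, library_size=1000)
        assert t.depth_sum("chr1", 0, 10**6) == 0

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t5\t3\t1\n")
        with pytest.raises(ParseError, match="line 1"):
            read_coverage(p, library_size=1000)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t10\t-2\n")
        with pytest.raises(ParseError, match="negative"):
            read_coverage(p, library_size=1000)

    def test_overlapping_intervals_rejected_naming_lines(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t10\t1\nchr1\t5\t20\t2\n")
        with pytest.raises(ParseError, match="lines 1 and 2"):
            read_coverage(p, library_size=1000)


class TestReadPeaks:
    def test_disjoint_records_loaded_and_sorted(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t500\t800\nchr1\t0\t100\nchr2\t10\t50\n")
        ps = read_peaks(p)
        assert len(ps) == 3
        starts = [(pk.chrom, pk.start) for pk in ps]
        assert starts == sorted(starts)

    def test_unknown_chromosome_retained(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chrUn_gl000220\t5\t10\n")
        assert len(read_peaks(p)) == 1

    def test_overlap_query(self):
        ps = PeakSet([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 500, 600)])
        assert ps.any_overlap(GenomicInterval("chr1", 150, 160))
        assert not ps.any_overlap(GenomicInterval("chr1", 200, 500))  # half-open

    @given(
        st.lists(
            st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
            min_size=0,
            max_size=20,
        )
    )
    @settings(max_examples=30, derandomize=True)
    def test_dog_bed_round_trip_preserves_intervals(self, raw):
        import tempfile
        from pathlib import Path

        dogs = [
            DoGRecord(f"G{i}", GenomicInterval("chr1", s, s + w), mean_fpkm=0.5)
            for i, (s, w) in enumerate(raw)
        ]
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "dogs.bed"
            write_dogs_bed(dogs, path)
            back = read_dogs_bed(path)
        assert {(d.region.chrom, d.region.start, d.region.end, d.gene_id) for d in back} == {
            (d.region.chrom, d.region.start, d.region.end, d.gene_id) for d in dogs
        }


class TestSampleSheet:
    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_id\tcondition\ns1\tctl\n")
        with pytest.raises(ParseError, match="missing columns"):
            read_sample_sheet(p)

    def test_read_length_defaults_to_50(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "sample_id\tcondition\treplicate\tcoverage_path\tlibrary_size\n"
            "s1\tctl\t1\ts1.bedGraph\t1000000\n"
        )
        df = read_sample_sheet(p)
        assert int(df["read_length"].iloc[0]) == 50


class TestDoGParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_length_bp": 100, "window_bp": 500},
            {"window_bp": 0},
            {"min_fpkm": -0.1},
            {"p_threshold": 0.0},
            {"fc_threshold": 0.0},
        ],
    )
    def test_invalid_parameter_combinations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DoGParams(**kwargs)
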