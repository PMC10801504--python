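"""Windowed DoG caller: unit examples, brute-force oracle equivalence,
and monotonicity properties."""

import numpy as np
import pytest

from dogscan.discovery import (
    DoGRecord,
    call_dog,
    call_dogs_all,
    fpkm,
    merge_replicates,
    window_reads,
)
from dogscan.model import CoverageTrack, DoGParams, GenomicInterval

from conftest import brute_force_dog, gene, make_track, random_instance


class TestFpkm:
    @pytest.mark.parametrize(
        "reads,length,lib,expected",
        [
            (0, 500, 10**6, 0.0),
            (10, 500, 10**6, 20.0),
            (1, 1000, 10**7, 0.1),  # below the 0.2 discovery floor
        ],
    )
    def test_direct_formula(self, reads, length, lib, expected):
        assert fpkm(reads, length, lib) == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            fpkm(1, 500, 0)


class TestWindowReads:
    def test_uniform_depth(self):
        track = make_track([(1000, 1500, 4)])
        assert window_reads(track, GenomicInterval("chr1", 1000, 1500), 50) == 40.0

    def test_zero_window_and_beyond_extent(self):
        track = make_track([(0, 100, 1)])
        assert window_reads(track, GenomicInterval("chr1", 200, 700), 50) == 0.0
        assert window_reads(track, GenomicInterval("chr1", 10**6, 10**6 + 500), 50) == 0.0

    def test_partial_coverage(self):
        track = make_track([(100, 150, 1)], chrom_len=1000)
        assert window_reads(track, GenomicInterval("chr1", 0, 1000), 50) == 1.0


def high_depth_track(tes, n_bases, chrom_len=None, depth=5):
    """depth 5 over [tes, tes+n_bases): window FPKM = 5*500/50/(0.5*1) = 100."""
    return make_track([(0, tes, depth), (tes, tes + n_bases, depth)], chrom_len=chrom_len)


class TestCallDog:
    def test_zero_downstream_coverage_gives_none(self, default_params):
        g = gene("G1", 1000, 3000)
        track = make_track([(1000, 3000, 5)], chrom_len=50_000)
        assert call_dog(g, track, [], default_params) is None

    def test_twelve_high_windows_give_6kb_dog(self, default_params):
        g = gene("G1", 1000, 3000)
        track = high_depth_track(3000, 6000, chrom_len=50_000)
        rec = call_dog(g, track, [], default_params)
        assert rec is not None
        assert (rec.region.start, rec.region.end) == (3000, 9000)
        assert rec.length_bp == 6000
        assert brute_force_dog(g, track, [g], default_params) == (3000, 9000)

    def test_seven_windows_fall_short_of_min_length(self, default_params):
        g = gene("G1", 1000, 3000)
        track = high_depth_track(3000, 3500, chrom_len=50_000)
        assert call_dog(g, track, [], default_params) is None
        assert brute_force_dog(g, track, [g], default_params) is None

    def test_downstream_gene_truncates_extension(self, default_params):
        g = gene("G1", 1000, 3000)
        blocker = gene("G2", 7500, 9000)
        track = high_depth_track(3000, 10_000, chrom_len=50_000)
        rec = call_dog(g, track, [blocker], default_params)
        assert rec is not None
        assert rec.length_bp == 4500  # truncated at the downstream TSS
        assert (rec.region.start, rec.region.end) == (3000, 7500)
        assert brute_force_dog(g, track, [g, blocker], default_params) == (3000, 7500)

    def test_antisense_downstream_gene_blocks_at_its_far_tss(self, default_params):
        # antisense gene body lies inside the readthrough path; its TSS faces
        # away, so the DoG may run across the body up to the TSS boundary
        g = gene("G1", 1000, 3000)
        anti = gene("G2", 5000, 9000, strand="-")
        track = high_depth_track(3000, 20_000, chrom_len=50_000)
        rec = call_dog(g, track, [anti], default_params)
        assert rec is not None
        assert (rec.region.start, rec.region.end) == (3000, 9000)
        assert rec.region.overlaps(anti.interval)

    def test_minus_strand_gene_extends_leftward(self, default_params):
        g = gene("G1", 20_000, 22_000, strand="-")
        track = make_track([(14_000, 22_000, 5)], chrom_len=50_000)
        rec = call_dog(g, track, [], default_params)
        assert rec is not None
        assert (rec.region.start, rec.region.end) == (14_000, 20_000)
        assert brute_force_dog(g, track, [g], default_params) == (14_000, 20_000)

    def test_minus_strand_gene_at_contig_edge_gives_none(self, default_params):
        g = gene("G1", 0, 2000, strand="-")
        track = make_track([(0, 2000, 5)])
        assert call_dog(g, track, [], default_params) is None

    def test_exact_4kb_passes_inclusive_minimum(self, default_params):
        g = gene("G1", 1000, 3000)
        track = high_depth_track(3000, 4000, chrom_len=50_000)
        rec = call_dog(g, track, [], default_params)
        assert rec is not None and rec.length_bp == 4000


@pytest.mark.parametrize("seed", range(40))
def test_caller_matches_per_base_brute_force_oracle(seed, default_params):
    """Fast caller output equals an independent per-base re-scan, every gene."""
    genes, track = random_instance(seed)
    called = {
        d.gene_id: (d.region.start, d.region.end)
        for d in call_dogs_all(genes, track, default_params)
    }
    expected = {}
    for g in genes:
        res = brute_force_dog(g, track, genes, default_params)
        if res is not None:
            expected[g.gene_id] = res
    assert called == expected


class TestCallDogsAll:
    def test_recovers_exactly_planted_readthrough_genes(self, default_params):
        genes = []
        segs = []
        planted = []
        pos = 1000
        for i in range(10):
            g = gene(f"G{i}", pos, pos + 2000)
            genes.append(g)
            segs.append((pos, pos + 2000, 5.0))
            if i % 3 == 0:  # 4 planted readthroughs >= 4 kb
                segs.append((pos + 2000, pos + 2000 + 5000, 2.0))
                planted.append(f"G{i}")
            pos += 2000 + 12_000
        track = make_track(segs, chrom_len=pos)
        dogs = call_dogs_all(genes, track, default_params)
        assert {d.gene_id for d in dogs} == set(planted)

    def test_empty_annotation_and_determinism(self, default_params):
        _, track = random_instance(3)
        assert call_dogs_all([], track, default_params) == []
        genes, track = random_instance(4)
        a = call_dogs_all(genes, track, default_params)
        b = call_dogs_all(genes, track, default_params)
        assert a == b

    def test_every_dog_starts_at_parent_tes_and_meets_min_length(self, default_params):
        for seed in range(10):
            genes, track = random_instance(seed + 100)
            by_id = {g.gene_id: g for g in genes}
            for d in call_dogs_all(genes, track, default_params):
                parent = by_id[d.gene_id]
                assert d.length_bp >= default_params.min_length_bp
                anchor = d.region.start if parent.strand != "-" else d.region.end
                assert anchor == parent.tes
                assert not d.region.overlaps(parent.interval)

    def test_raising_min_fpkm_never_adds_or_lengthens_dogs(self):
        genes, track = random_instance(11)
        lo = call_dogs_all(genes, track, DoGParams(min_fpkm=0.2))
        hi = call_dogs_all(genes, track, DoGParams(min_fpkm=0.8))
        lo_by = {d.gene_id: d.length_bp for d in lo}
        assert {d.gene_id for d in hi} <= set(lo_by)
        for d in hi:
            assert d.length_bp <= lo_by[d.gene_id]

    def test_lowering_min_length_never_decreases_count(self):
        genes, track = random_instance(12)
        strict = call_dogs_all(genes, track, DoGParams(min_length_bp=5000))
        lax = call_dogs_all(genes, track, DoGParams(min_length_bp=4000))
        assert {d.gene_id for d in strict} <= {d.gene_id for d in lax}


class TestMergeReplicates:
    def _dog(self, gid, start, end, strand="+", fpkm_=1.0):
        return DoGRecord(gid, GenomicInterval("chr1", start, end, strand), fpkm_)

    def test_union_keeps_farthest_downstream_end(self):
        a = [self._dog("G1", 3000, 8000)]
        b = [self._dog("G1", 3000, 10_000)]
        (m,) = merge_replicates([a, b])
        assert (m.region.start, m.region.end) == (3000, 10_000)
        assert m.length_bp == 7000

    def test_minus_strand_union_extends_leftward(self):
        a = [self._dog("G1", 5000, 9000, strand="-")]
        b = [self._dog("G1", 3000, 9000, strand="-")]
        (m,) = merge_replicates([a, b])
        assert (m.region.start, m.region.end) == (3000, 9000)

    def test_disjoint_sets_concatenate_and_empty_is_identity(self):
        a = [self._dog("G1", 0, 5000), self._dog("G2", 9000, 14_000)]
        merged = merge_replicates([a, []])
        assert {d.gene_id for d in merged} == {"G1", "G2"}

    def test_conflicting_strand_rejected(self):
        a = [self._dog("G1", 3000, 8000, strand="+")]
        b = [self._dog("G1", 3000, 8000, strand="-")]
        with pytest.raises(ValueError, match="G1"):
            merge_replicates([a, b])
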