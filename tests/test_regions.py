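"""Region algebra: GFF parsing, flank extension, interval merging, stats, I/O."""

import io
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transgeno import simulate as S
from transgeno.regions import (
    GenomicInterval,
    GeneLocus,
    GffParseError,
    build_transcribed_regions,
    extend_locus,
    extract_region_fasta,
    merge_intervals,
    read_gene_models,
    read_regions_bed,
    region_stats,
    write_regions_bed,
)

GFF_LINE = "chr1H\tHC\tgene\t{start}\t{end}\t.\t+\t.\tID={lid}\n"


def mask_union(intervals, chrom_len=100_000):
    """Independent per-base oracle: union of intervals as a boolean mask."""
    masks = {}
    for iv in intervals:
        m = masks.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))
        m[iv.start : iv.end] = True
    return masks


def regions_mask(regions, chrom_len=100_000):
    return mask_union([r.interval for r in regions], chrom_len)


class TestReadGeneModels:
    def test_coordinate_convention(self):
        loci = read_gene_models(io.StringIO(GFF_LINE.format(start=1001, end=2000, lid="g1")))
        iv = loci[0].interval
        assert (iv.start, iv.end, iv.length) == (1000, 2000, 1000)

    def test_empty_body(self):
        assert read_gene_models(io.StringIO("##gff-version 3\n")) == []

    def test_fixture_matches_manifest(self, clean_bundle):
        cfg = clean_bundle.truth.config
        expected = S.simulate_annotation(cfg, S.simulate_genome(cfg))
        loci = read_gene_models(clean_bundle.gff3)
        assert len(loci) == cfg.n_loci
        assert [l.locus_id for l in loci] == [e.locus_id for e in expected]
        assert [(l.interval.start, l.interval.end) for l in loci] == [
            (e.start0, e.end0) for e in expected
        ]
        assert {l.source for l in loci} <= {"HC", "novel"}

    def test_malformed_line_reports_line_number(self):
        text = "##gff-version 3\nchr1H\tHC\tgene\tnope\n"
        with pytest.raises(GffParseError, match="line 2"):
            read_gene_models(io.StringIO(text))

    def test_inverted_record_rejected(self):
        with pytest.raises(GffParseError, match="end 100 < start 200"):
            read_gene_models(io.StringIO(GFF_LINE.format(start=200, end=100, lid="g1")))

    def test_duplicate_id_rejected(self):
        text = GFF_LINE.format(start=1, end=10, lid="g1") + GFF_LINE.format(
            start=100, end=200, lid="g1"
        )
        with pytest.raises(GffParseError, match="duplicate"):
            read_gene_models(io.StringIO(text))


class TestExtendLocus:
    @pytest.mark.parametrize(
        "span, flank, chrom_len, expected",
        [
            ((10_000, 12_000), 3_000, 100_000, (7_000, 15_000)),
            ((1_000, 2_000), 3_000, 100_000, (0, 5_000)),  # left clip at origin
            ((98_000, 99_000), 3_000, 100_000, (95_000, 100_000)),  # right clip
        ],
    )
    def test_symmetric_flanks_with_clipping(self, span, flank, chrom_len, expected):
        locus = GeneLocus("g", GenomicInterval("c", *span))
        iv = extend_locus(locus, flank, chrom_len)
        assert (iv.start, iv.end) == expected

    def test_strand_does_not_change_flanks(self):
        fwd = GeneLocus("g", GenomicInterval("c", 10_000, 12_000), strand="+")
        rev = GeneLocus("g", GenomicInterval("c", 10_000, 12_000), strand="-")
        assert extend_locus(fwd, 3000, 10**6) == extend_locus(rev, 3000, 10**6)

    def test_chromosome_shorter_than_locus_rejected(self):
        locus = GeneLocus("g", GenomicInterval("c", 0, 5_000))
        with pytest.raises(ValueError, match="shorter than locus end"):
            extend_locus(locus, 100, 4_000)


class TestMergeIntervals:
    def test_overlap_merges_with_members(self):
        regions = merge_intervals(
            [GenomicInterval("c", 0, 5000), GenomicInterval("c", 4000, 9000)],
            ["a", "b"],
        )
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 9000)
        assert set(regions[0].member_locus_ids) == {"a", "b"}

    def test_no_cross_chromosome_merge(self):
        regions = merge_intervals(
            [GenomicInterval("A", 0, 100), GenomicInterval("B", 0, 100)]
        )
        assert len(regions) == 2

    def test_book_ended_intervals_merge(self):
        regions = merge_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 100, 200)]
        )
        assert len(regions) == 1
        assert regions[0].interval.end == 200

    def test_random_union_equals_per_base_oracle(self):
        rng = random.Random(42)
        intervals = []
        for _ in range(200):
            start = rng.randrange(0, 99_000)
            intervals.append(
                GenomicInterval(rng.choice("AB"), start, start + rng.randrange(1, 2000))
            )
        merged = merge_intervals(intervals)
        expect = mask_union(intervals)
        got = regions_mask(merged)
        assert set(expect) == set(got)
        for chrom in expect:
            assert np.array_equal(expect[chrom], got[chrom])
        # merged regions are sorted and pairwise non-overlapping
        for a, b in zip(merged, merged[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end < b.interval.start

    def test_idempotent_and_order_invariant(self):
        rng = random.Random(7)
        intervals = [
            GenomicInterval("c", s, s + rng.randrange(1, 500))
            for s in rng.sample(range(0, 50_000), 100)
        ]
        once = merge_intervals(intervals)
        twice = merge_intervals([r.interval for r in once])
        assert [r.interval for r in twice] == [r.interval for r in once]
        shuffled = intervals[:]
        rng.shuffle(shuffled)
        assert [r.interval for r in merge_intervals(shuffled)] == [
            r.interval for r in once
        ]

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5_000), st.integers(1, 500)),
            min_size=1,
            max_size=30,
        )
    )
    def test_total_bp_bounded_by_input_sum(self, raw):
        intervals = [GenomicInterval("c", s, s + l) for s, l in raw]
        merged = merge_intervals(intervals)
        total = sum(r.interval.length for r in merged)
        assert total <= sum(iv.length for iv in intervals)
        assert total == int(mask_union(intervals, 6_000)["c"].sum())


class TestRegionStats:
    def test_reported_ratio_renders_2_64(self):
        # one synthetic region spanning the reported transcribed-region total
        region = merge_intervals([GenomicInterval("c", 0, 590_551_456)])[0]
        stats = region_stats([region], reference_total_bp=223_654_512)
        assert stats.render_ratio() == "2.64"

    def test_single_region(self):
        stats = region_stats(merge_intervals([GenomicInterval("c", 0, 1000)]), 1000)
        assert (stats.n_regions, stats.total_bp) == (1, 1000)

    def test_empty_region_list(self):
        stats = region_stats([], 100)
        assert (stats.n_regions, stats.total_bp) == (0, 0)

    def test_fixture_total_matches_per_base_mask(self, clean_bundle):
        loci = read_gene_models(clean_bundle.gff3)
        sizes = {c: clean_bundle.truth.config.chrom_len for c in {l.interval.chrom for l in loci}}
        regions = build_transcribed_regions(loci, 3000, sizes)
        stats = region_stats(regions, sum(l.interval.length for l in loci))
        masks = regions_mask(regions, clean_bundle.truth.config.chrom_len)
        assert stats.total_bp == sum(int(m.sum()) for m in masks.values())


class TestRegionIO:
    def test_bed_round_trip(self, tmp_path):
        regions = merge_intervals(
            [GenomicInterval("chr1H", 7000, 15000), GenomicInterval("chr2H", 0, 50)],
            ["gA", "gB"],
        )
        bed = tmp_path / "r.bed"
        write_regions_bed(regions, bed)
        lines = bed.read_text().splitlines()
        assert lines[0] == "chr1H\t7000\t15000\tgA"
        assert read_regions_bed(bed) == regions

    def test_fasta_extraction(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGTAAAA\n")
        regions = merge_intervals([GenomicInterval("chr1", 0, 4)])
        records = extract_region_fasta(regions, fa)
        assert records == [("chr1:0-4", "ACGT")]

    def test_missing_chromosome_named_in_error(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGTAAAA\n")
        regions = merge_intervals([GenomicInterval("chrX", 0, 4)])
        with pytest.raises(ValueError, match="chrX"):
            extract_region_fasta(regions, fa)
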