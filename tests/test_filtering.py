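"""Filter cascade: site classification, per-rule behaviour, and full-VCF runs."""

import random

import pytest

from transgeno.filtering import (
    FilterConfig,
    SampleCall,
    UnsupportedAlleleError,
    VariantSite,
    classify_site,
    conflict_filter,
    depth_filter,
    neighbor_filter,
    run_cascade,
    select_library,
    singleton_filter,
)


def call(strain, gt, depth=10, lib=None):
    return SampleCall(strain, lib or f"{strain}_sr", gt, depth)


class TestClassifySite:
    @pytest.mark.parametrize(
        "ref, alts, expected",
        [
            ("A", ("G",), "SNP"),
            ("A", ("AT",), "INDEL"),
            ("ATC", ("A",), "INDEL"),
            ("A", ("G", "T"), "MULTI"),
            ("a", ("g",), "SNP"),  # case-insensitive
        ],
    )
    def test_classes(self, ref, alts, expected):
        assert classify_site(ref, alts) == expected

    @pytest.mark.parametrize("bad", ["<DEL>", "N", "", "A[chr1:123["])
    def test_symbolic_alleles_rejected(self, bad):
        with pytest.raises((UnsupportedAlleleError, ValueError)):
            classify_site("A", (bad,))


class TestDepthFilter:
    def test_single_read_fails(self):
        assert not depth_filter(call("s", (1, 1), depth=1), min_reads=2)

    def test_two_reads_pass(self):
        assert depth_filter(call("s", (1, 1), depth=2), min_reads=2)

    def test_zero_depth_nonmissing_is_invalid(self):
        with pytest.raises(ValueError):
            depth_filter(call("s", (1, 1), depth=0), min_reads=2)

    def test_negative_depth_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SampleCall("s", "l", (0, 0), depth=-1)


class TestSingletonFilter:
    @pytest.mark.parametrize(
        "n_carriers, passes", [(0, False), (1, False), (2, True), (5, True)]
    )
    def test_carrier_threshold(self, n_carriers, passes):
        calls = [
            call(f"s{i}", (1, 1) if i < n_carriers else (0, 0)) for i in range(10)
        ]
        assert singleton_filter(calls) is passes

    def test_all_missing_fails(self):
        calls = [SampleCall(f"s{i}", f"l{i}", None) for i in range(5)]
        assert not singleton_filter(calls)

    def test_het_counts_as_carrier(self):
        calls = [call("a", (0, 1)), call("b", (1, 1))] + [
            call(f"s{i}", (0, 0)) for i in range(5)
        ]
        assert singleton_filter(calls)


class TestConflictFilter:
    def test_agreeing_replicates_pass(self):
        calls = [call("a", (1, 1), lib="a_sr"), call("a", (1, 1), lib="a_sp")]
        assert conflict_filter(calls)

    def test_disagreeing_replicates_fail(self):
        # cross-checked by scanning all library pairs of the strain
        calls = [call("a", (1, 1), lib="a_sr"), call("a", (0, 0), lib="a_sp")]
        assert not conflict_filter(calls)
        strains = {c.strain_id for c in calls}
        brute = any(
            c1.gt != c2.gt
            for s in strains
            for c1 in calls
            for c2 in calls
            if c1.strain_id == s == c2.strain_id and c1.library_id < c2.library_id
            and c1.gt is not None and c2.gt is not None
        )
        assert brute

    def test_single_library_vacuous(self):
        assert conflict_filter([call("a", (1, 1))])

    def test_missing_replicate_is_not_a_conflict(self):
        calls = [call("a", (1, 1), lib="a_sr"), SampleCall("a", "a_sp", None)]
        assert conflict_filter(calls)


def sites_at(positions, chrom="c"):
    if isinstance(positions, dict):
        return [
            VariantSite(ch, p, "A", ("G",)) for ch, ps in positions.items() for p in ps
        ]
    return [VariantSite(chrom, p, "A", ("G",)) for p in positions]


def neighbor_oracle(sites, window, inclusive=True):
    """All-pairs independent check of the neighbor rule."""
    kept = []
    for s in sites:
        ok = True
        for t in sites:
            if t is s or t.chrom != s.chrom:
                continue
            d = abs(t.pos - s.pos)
            if (d <= window) if inclusive else (d < window):
                ok = False
                break
        if ok:
            kept.append(s)
    return sorted(kept, key=lambda s: (s.chrom, s.pos))


class TestNeighborFilter:
    def test_distance_61_keeps_both(self):
        assert len(neighbor_filter(sites_at([100, 161]), 60)) == 2

    def test_distance_60_drops_both(self):
        assert neighbor_filter(sites_at([100, 160]), 60) == []

    def test_cross_chromosome_independence(self):
        sites = sites_at({"chr1": [100], "chr2": [100]})
        assert len(neighbor_filter(sites, 60)) == 2

    def test_exclusive_boundary_variant(self):
        assert len(neighbor_filter(sites_at([100, 160]), 60, inclusive=False)) == 2
        assert neighbor_filter(sites_at([100, 159]), 60, inclusive=False) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_sweep_equals_all_pairs_oracle(self, seed):
        rng = random.Random(seed)
        positions = rng.sample(range(1, 3000), rng.randint(5, 300))
        sites = sites_at(positions)
        rng.shuffle(sites)
        assert neighbor_filter(sites, 60) == neighbor_oracle(sites, 60)


class TestSelectLibrary:
    def test_preferred_tissue_wins(self):
        libs = {"x_sp": "spike", "x_sr": "shoot_root"}
        assert select_library(libs, ["shoot_root"]) == "x_sr"

    def test_single_library(self):
        assert select_library({"only": "spike"}) == "only"

    def test_lexicographic_tie_break(self):
        assert select_library({"libB": "leaf", "libA": "leaf"}, ["root"]) == "libA"


EMPTY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1H,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tST000_sr\tST001_sr
"""

EMPTY_META = "strain_id\tlibrary_id\ttissue\trow_type\nST000\tST000_sr\tshoot_root\ttwo_row\nST001\tST001_sr\tshoot_root\tsix_row\n"


class TestRunCascade:
    def test_noise_free_recovers_planted_clean_set(self, clean_bundle):
        result = run_cascade(clean_bundle.vcf, str(clean_bundle.metadata))
        got = {(s.chrom, s.pos) for s in result.sites}
        assert got == clean_bundle.truth.clean_keys
        cfg = clean_bundle.truth.config
        assert result.report.n_multi == cfg.n_multiallelic
        assert result.report.n_detected == cfg.n_planted

    def test_stage_counts_monotonic(self, noisy_bundle):
        report = run_cascade(noisy_bundle.vcf, str(noisy_bundle.metadata)).report
        order = ["detected", "after_depth", "after_singleton", "after_conflict",
                 "after_multi", "after_neighbor"]
        counts = [report.stage_counts[k] for k in order]
        assert counts == sorted(counts, reverse=True)
        assert report.n_final == counts[-1]
        assert report.n_final_snp + report.n_final_indel == report.n_final

    def test_idempotent_on_own_output(self, noisy_bundle, tmp_path):
        from transgeno.filtering import read_metadata, write_filtered_vcf

        meta = read_metadata(noisy_bundle.metadata)
        first = run_cascade(noisy_bundle.vcf, meta)
        out = tmp_path / "filtered.vcf"
        write_filtered_vcf(noisy_bundle.vcf, out, first)
        second = run_cascade(out, meta)
        assert {(s.chrom, s.pos) for s in second.sites} == first.surviving_keys
        assert second.report.n_final == first.report.n_final

    def test_empty_vcf_zero_report(self, tmp_path):
        vcf = tmp_path / "e.vcf"
        vcf.write_text(EMPTY_VCF)
        meta = tmp_path / "m.tsv"
        meta.write_text(EMPTY_META)
        result = run_cascade(vcf, str(meta))
        assert result.report.n_detected == 0
        assert result.report.n_final == 0
        assert result.matrix.n_sites == 0

    def test_unmapped_vcf_sample_is_fatal(self, tmp_path):
        vcf = tmp_path / "e.vcf"
        vcf.write_text(EMPTY_VCF)
        meta = tmp_path / "m.tsv"
        meta.write_text(
            "strain_id\tlibrary_id\ttissue\trow_type\nST000\tST000_sr\tshoot_root\ttwo_row\n"
        )
        with pytest.raises(ValueError, match="ST001_sr"):
            run_cascade(vcf, str(meta))

    def test_matrix_calls_match_planted_truth(self, clean_bundle):
        result = run_cascade(clean_bundle.vcf, str(clean_bundle.metadata))
        truth_by_key = {(v.chrom, v.pos): v for v in clean_bundle.truth.variants}
        for i, site in enumerate(result.matrix.sites):
            v = truth_by_key[(site.chrom, site.pos)]
            for strain in result.matrix.strains:
                gt = result.matrix.calls.iloc[i][strain]
                if gt != ".":  # depth noise may mask unprotected calls
                    assert gt == v.true_gt[strain]
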