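"""VCF/BED/FASTA round trips, the site filter cascade, thinning, RAD loci."""

from __future__ import annotations

import numpy as np
import pytest

from partho.genotype_io import (
    DepthTrack,
    FilterConfig,
    GenotypeState,
    RadLocus,
    apply_site_filters,
    derive_rad_loci,
    read_bed,
    read_fasta,
    read_vcf,
    thin_by_window,
    write_bed,
    write_fasta,
    write_vcf,
)

from conftest import M, make_dataset

H0, H1, H2 = int(GenotypeState.HOM_REF), int(GenotypeState.HET), int(GenotypeState.HOM_ALT)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

class TestReadVcf:
    def test_reads_all_records_and_samples(self, trio_vcf):
        data = read_vcf(trio_vcf)
        assert data.n_sites == 5
        assert data.samples == ["momma", "kidA", "kidB"]
        site = data.site(0)
        assert (site.chrom, site.pos, site.ref_allele, site.alt_allele) == ("chr1", 100, "A", "T")
        assert [c.state for c in site.calls] == [GenotypeState.HET, GenotypeState.HOM_REF,
                                                 GenotypeState.HOM_ALT]
        assert [c.depth for c in site.calls] == [30, 22, 18]

    def test_uncalled_genotype_is_missing(self, trio_vcf):
        data = read_vcf(trio_vcf)
        assert data.site(2).calls[1].state is GenotypeState.MISSING

    def test_sample_reordering(self, trio_vcf):
        data = read_vcf(trio_vcf, ["kidB", "momma", "kidA"])
        assert data.samples == ["kidB", "momma", "kidA"]
        assert data.site(0).calls[0].state is GenotypeState.HOM_ALT

    def test_unknown_sample_errors_with_name(self, trio_vcf):
        with pytest.raises(KeyError, match="nonesuch"):
            read_vcf(trio_vcf, ["momma", "nonesuch"])

    def test_multiallelic_record_retained_for_filter_stage(self, trio_vcf):
        data = read_vcf(trio_vcf)
        assert not data.site(3).is_biallelic


class TestVcfRoundTrip:
    def test_write_read_is_identity(self, trio_vcf, tmp_path):
        data = read_vcf(trio_vcf)
        out = tmp_path / "rt.vcf"
        write_vcf(data, out)
        back = read_vcf(out)
        assert back.samples == data.samples
        np.testing.assert_array_equal(back.gt, data.gt)
        np.testing.assert_array_equal(back.depth, data.depth)
        np.testing.assert_array_equal(back.pos, data.pos)
        assert list(back.ref) == list(data.ref)
        assert back.alt == data.alt
        np.testing.assert_allclose(back.qual, data.qual)

    def test_write_is_deterministic(self, trio_vcf, tmp_path):
        data = read_vcf(trio_vcf)
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(data, a)
        write_vcf(data, b)
        assert a.read_bytes() == b.read_bytes()


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

class TestFilterCascade:
    def test_low_qual_site_dropped(self):
        data = make_dataset([[H1, H0, H0], [H1, H0, H0]], qual=[25.0, 60.0])
        out = apply_site_filters(data)
        assert out.n_sites == 1
        assert out.qual[0] == 60.0

    def test_low_depth_call_masked_then_complete_case_drops_site(self):
        depth = [[20, 4, 20], [20, 20, 20]]
        data = make_dataset([[H1, H0, H0], [H1, H0, H0]], depth=depth)
        out = apply_site_filters(data)
        assert out.n_sites == 1
        assert int(out.depth[0, 1]) == 20

    def test_clean_dataset_unchanged(self):
        data = make_dataset([[H1, H0, H2]] * 4)
        out = apply_site_filters(data)
        assert out.n_sites == 4
        np.testing.assert_array_equal(out.gt, data.gt)

    def test_indels_dropped_and_neighbouring_snps_excluded(self):
        # indel at pos 200 (REF "GTT"); SNPs at 197..203 are within 3 bp
        data = make_dataset(
            [[H1, H0, H0]] * 4,
            pos=[150, 199, 200, 206],
            ref=["A", "A", "GTT", "A"],
            alt=[("T",), ("T",), ("G",), ("T",)],
        )
        out = apply_site_filters(data)
        # indel span is [200, 202]; SNP at 199 within 3 bp, SNP at 206 outside (202+3=205)
        assert list(out.pos) == [150, 206]

    def test_info_hard_filter_violation_dropped(self):
        data = make_dataset([[H1, H0, H0]] * 2,
                            info=[{"QD": 1.0}, {"QD": 20.0}])
        out = apply_site_filters(data)
        assert out.n_sites == 1
        assert out.info[0]["QD"] == 20.0

    def test_absent_info_key_skipped(self):
        data = make_dataset([[H1, H0, H0]], info=[{"FS": 10.0}])
        out = apply_site_filters(data)
        assert out.n_sites == 1

    def test_unknown_comparator_rejected(self):
        with pytest.raises(ValueError, match="comparator"):
            FilterConfig(info_filters=(("QD", "!!", 2.0),))

    def test_non_biallelic_dropped(self):
        data = make_dataset([[H1, H0, H0]] * 2, alt=[("T", "G"), ("T",)])
        out = apply_site_filters(data)
        assert out.n_sites == 1
        assert out.alt[0] == ("T",)

    def test_total_depth_outliers_dropped_with_explicit_bounds(self):
        depth = [[10, 10, 10], [100, 100, 100], [5, 5, 5]]
        data = make_dataset([[H1, H0, H0]] * 3, depth=depth)
        cfg = FilterConfig(depth_sum_bounds=(20, 60))
        out = apply_site_filters(data, cfg)
        assert out.n_sites == 1
        assert int(out.depth.sum()) == 30

    def test_filter_log_records_attrition(self):
        data = make_dataset([[H1, H0, H0]] * 2, qual=[25.0, 60.0])
        out = apply_site_filters(data)
        assert any("rule4_qual: removed 1" in line for line in out.provenance)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cascade_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        gt = rng.integers(0, 3, size=(n, 3)).astype(np.int8)
        gt[rng.random((n, 3)) < 0.05] = M
        depth = rng.negative_binomial(5, 5 / 22, size=(n, 3))
        qual = rng.gamma(4, 60, size=n)
        data = make_dataset(gt, depth=depth, qual=qual,
                            pos=sorted(rng.choice(10**6, size=n, replace=False)))
        once = apply_site_filters(data)
        twice = apply_site_filters(once)
        assert twice.n_sites == once.n_sites
        np.testing.assert_array_equal(twice.gt, once.gt)


# ---------------------------------------------------------------------------
# Thinning
# ---------------------------------------------------------------------------

class TestThinning:
    def test_single_window_keeps_one(self):
        data = make_dataset([[H1, H0, H0]] * 3, pos=[10, 20, 30])
        out = thin_by_window(data, 50_000, seed=0)
        assert out.n_sites == 1

    def test_distinct_windows_keep_both(self):
        data = make_dataset([[H1, H0, H0]] * 2, pos=[10, 60_000])
        out = thin_by_window(data, 50_000, seed=0)
        assert list(out.pos) == [10, 60_000]

    def test_deterministic_under_seed(self):
        data = make_dataset([[H1, H0, H0]] * 20, pos=list(range(1000, 21000, 1000)))
        a = thin_by_window(data, 5_000, seed=7)
        b = thin_by_window(data, 5_000, seed=7)
        assert list(a.pos) == list(b.pos)

    def test_kept_sites_are_members_and_bounded_by_windows(self):
        rng = np.random.default_rng(3)
        pos = sorted(rng.choice(10**6, size=200, replace=False))
        data = make_dataset([[H1, H0, H0]] * 200, pos=pos)
        out = thin_by_window(data, 50_000, seed=1)
        assert set(out.pos) <= set(pos)
        occupied = {p // 50_000 for p in pos}
        assert out.n_sites == len(occupied)

    def test_invalid_window_rejected(self):
        data = make_dataset([[H1, H0, H0]])
        with pytest.raises(ValueError):
            thin_by_window(data, 0, seed=0)


# ---------------------------------------------------------------------------
# RAD locus derivation
# ---------------------------------------------------------------------------

def brute_force_rad_loci(tracks, min_depth=5, min_qual=30.0, max_gap=10, min_len=100):
    """Independent per-base oracle: label bases, scan runs, merge gaps."""
    by_chrom = {}
    for t in tracks:
        by_chrom.setdefault(t.chrom, []).append(t)
    loci = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        L = len(group[0].depth)
        start0 = group[0].start
        passing = []
        for b in range(L):
            ok = all(t.depth[b] >= min_depth and
                     (t.quality is None or t.quality[b] >= min_qual)
                     for t in group)
            passing.append(ok)
        intervals = []
        b = 0
        while b < L:
            if passing[b]:
                s = b
                e = b
                while True:
                    # extend over pass bases and gaps of <= max_gap fails
                    nxt = e + 1
                    gap = 0
                    while nxt < L and not passing[nxt] and gap < max_gap:
                        nxt += 1
                        gap += 1
                    if nxt < L and passing[nxt]:
                        e = nxt
                    else:
                        break
                intervals.append((s, e + 1))
                b = e + 1
            else:
                b += 1
        for s, e in intervals:
            if e - s >= min_len:
                loci.append(RadLocus(chrom, start0 + s, start0 + e))
    return loci


class TestRadLoci:
    def make_tracks(self, depths_by_sample, chrom="chr1", quality=None):
        return [DepthTrack(sample=f"s{i}", chrom=chrom, start=0,
                           depth=np.asarray(d), quality=quality)
                for i, d in enumerate(depths_by_sample)]

    def test_simple_block_kept(self):
        d = np.zeros(300, dtype=int)
        d[:120] = 10
        loci = derive_rad_loci(self.make_tracks([d, d, d]))
        assert loci == [RadLocus("chr1", 0, 120)]

    def test_gap_boundary_merge_and_split(self):
        # runs [0,60) and [70,130): gap of 10 -> merged into [0,130)
        d = np.zeros(300, dtype=int)
        d[0:60] = 10
        d[70:130] = 10
        assert derive_rad_loci(self.make_tracks([d])) == [RadLocus("chr1", 0, 130)]
        # runs [0,60) and [71,130): gap of 11 -> two short intervals, both dropped
        d2 = np.zeros(300, dtype=int)
        d2[0:60] = 10
        d2[71:130] = 10
        assert derive_rad_loci(self.make_tracks([d2])) == []

    def test_length_boundary(self):
        d99 = np.zeros(200, dtype=int)
        d99[:99] = 10
        assert derive_rad_loci(self.make_tracks([d99])) == []
        d100 = np.zeros(200, dtype=int)
        d100[:100] = 10
        assert derive_rad_loci(self.make_tracks([d100])) == [RadLocus("chr1", 0, 100)]

    def test_all_zero_depth_empty(self):
        d = np.zeros(500, dtype=int)
        assert derive_rad_loci(self.make_tracks([d, d])) == []

    def test_base_fails_unless_all_samples_pass(self):
        a = np.full(200, 10)
        b = np.full(200, 10)
        b[50] = 0  # one sample dips below depth at base 50
        loci = derive_rad_loci(self.make_tracks([a, b]), max_gap=0)
        assert loci == [RadLocus("chr1", 51, 200)]  # [0,50) is only 50 bp

    def test_quality_track_enforced(self):
        d = np.full(200, 10)
        q = np.full(200, 40.0)
        q[100:] = 10.0
        loci = derive_rad_loci([DepthTrack("s", "chr1", 0, d, q)])
        assert loci == [RadLocus("chr1", 0, 100)]

    def test_mismatched_tracks_rejected(self):
        t1 = DepthTrack("a", "chr1", 0, np.zeros(100, dtype=int))
        t2 = DepthTrack("b", "chr1", 50, np.zeros(100, dtype=int))
        with pytest.raises(ValueError, match="mismatched"):
            derive_rad_loci([t1, t2])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(500, 10_000))
        tracks = []
        for s in range(int(rng.integers(1, 4))):
            # blocky coverage with noise so run/gap boundaries get exercised
            depth = np.zeros(L, dtype=int)
            n_blocks = int(rng.integers(3, 25))
            for _ in range(n_blocks):
                a = int(rng.integers(0, L))
                b = min(L, a + int(rng.integers(20, 400)))
                depth[a:b] = int(rng.integers(4, 30))
            depth[rng.random(L) < 0.01] = 0
            tracks.append(DepthTrack(f"s{s}", "chr1", 0, depth))
        got = derive_rad_loci(tracks)
        expected = brute_force_rad_loci(tracks)
        assert got == expected


# ---------------------------------------------------------------------------
# FASTA / BED plumbing
# ---------------------------------------------------------------------------

class TestFastaBed:
    def test_fasta_round_trip_and_uppercasing(self, tmp_path):
        path = tmp_path / "ref.fa"
        path.write_text(">chr1\nacgtACGT\n>chr2\nGGGGcc\n")
        seqs = read_fasta(path)
        assert seqs == {"chr1": "ACGTACGT", "chr2": "GGGGCC"}
        out = tmp_path / "out.fa"
        write_fasta(seqs, out)
        assert read_fasta(out) == seqs

    def test_bed_convention_and_round_trip(self, tmp_path):
        loci = [RadLocus("chr1", 0, 120), RadLocus("chr2", 55, 200)]
        path = tmp_path / "loci.bed"
        write_bed(loci, path)
        assert path.read_text().splitlines()[0] == "chr1\t0\t120"
        assert read_bed(path) == loci

    def test_malformed_bed_reports_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t120\nchr1\tnope\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(path)
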