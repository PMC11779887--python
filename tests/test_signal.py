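"""Coverage aggregation, normalization, background and size-stratum logic."""

import numpy as np
import pandas as pd
import pytest

from atacbench import (
    CoverageTrack,
    FragmentSet,
    Interval,
    aggregate_coverage,
    build_genome,
    coverage_level_histogram,
    fragment_size_distribution,
    pileup,
    sample_offpeak_regions,
)


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])


@pytest.fixture(scope="module")
def tiny_genome():
    return build_genome(1, 10_000, seed=0)


class TestAggregateCoverage:
    def test_single_fragment_per_base(self, tiny_genome):
        frags = FragmentSet(frame([("chr1", 0, 100, "BC1", 1)]))
        track = aggregate_coverage(frags, genome=tiny_genome)
        arr = track.values("chr1")
        assert (arr[:100] == 1).all()
        assert (arr[100:] == 0).all()

    def test_rpkm_closed_form(self, tiny_genome):
        """RPKM = raw x 1e9 / (total_fragments x bin_size)."""
        frags = FragmentSet(frame([("chr1", 0, 100, "BC1", 1)]))
        track = aggregate_coverage(frags, genome=tiny_genome, normalization="RPKM")
        assert track.values("chr1")[0] == pytest.approx(1e9 / (1 * 1))
        frags4 = FragmentSet(
            frame([("chr1", 0, 100, "a", 1), ("chr1", 0, 100, "b", 3)])
        )
        track4 = aggregate_coverage(
            frags4, genome=tiny_genome, bin_size=10, normalization="RPKM"
        )
        assert track4.values("chr1")[0] == pytest.approx(4 * 1e9 / (4 * 10))

    def test_barcode_selection_identity(self, frags_small, genome_small):
        frags, _ = frags_small
        all_bc = aggregate_coverage(frags, genome=genome_small, barcodes=frags.barcodes())
        none_bc = aggregate_coverage(frags, genome=genome_small)
        for chrom in genome_small.chrom_names:
            assert (all_bc.values(chrom) == none_bc.values(chrom)).all()

    def test_unknown_barcode_warns(self, tiny_genome):
        frags = FragmentSet(frame([("chr1", 0, 10, "BC1", 1)]))
        with pytest.warns(UserWarning, match="unknown barcodes"):
            track = aggregate_coverage(frags, genome=tiny_genome, barcodes=["BC1", "nope"])
        assert track.values("chr1")[0] == 1

    def test_binned_counting_matches_brute_force(self, tiny_genome):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            s = int(rng.integers(0, 9_000))
            rows.append(("chr1", s, s + int(rng.integers(1, 500)), f"b{i}", 1))
        frags = FragmentSet(frame(rows))
        b = 25
        track = aggregate_coverage(frags, genome=tiny_genome, bin_size=b)
        arr = track.values("chr1")
        for bin_idx in rng.integers(0, len(arr), size=20):
            lo, hi = bin_idx * b, (bin_idx + 1) * b
            expected = sum(1 for _, s, e, _, _ in rows if s < hi and e > lo)
            assert arr[bin_idx] == expected

    def test_rpkm_scalar_multiple_of_raw(self, frags_small, genome_small):
        frags, _ = frags_small
        raw = aggregate_coverage(frags, genome=genome_small)
        rpkm = aggregate_coverage(frags, genome=genome_small, normalization="RPKM")
        factor = 1e9 / frags.total_fragments
        for chrom in genome_small.chrom_names:
            assert np.allclose(rpkm.values(chrom), raw.values(chrom) * factor)


class TestCoverageLevelHistogram:
    def test_uniform_coverage_single_row(self, tiny_genome):
        frags = FragmentSet(frame([("chr1", 100, 200, "a", 1)]))
        table = coverage_level_histogram(aggregate_coverage(frags, genome=tiny_genome))
        assert list(table["level"]) == [1]
        assert table["percentage"].iloc[0] == pytest.approx(100.0)

    def test_two_levels_hand_computed(self, tiny_genome):
        # equal-length stretches at coverage 1 and 3: read-bases 1L vs 3L
        frags = FragmentSet(
            frame(
                [("chr1", 0, 100, "a", 1)]
                + [("chr1", 100, 200, x, 1) for x in "bcd"]
            )
        )
        table = coverage_level_histogram(aggregate_coverage(frags, genome=tiny_genome))
        pct = dict(zip(table["level"], table["percentage"]))
        assert pct[1] == pytest.approx(25.0)
        assert pct[3] == pytest.approx(75.0)

    def test_percentages_sum_to_100(self, frags_small, genome_small):
        frags, _ = frags_small
        table = coverage_level_histogram(aggregate_coverage(frags, genome=genome_small))
        assert table["percentage"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_track(self, tiny_genome):
        table = coverage_level_histogram(CoverageTrack.zeros(tiny_genome))
        assert len(table) == 0


class TestSampleOffpeakRegions:
    def test_no_exclusion_within_bounds(self, tiny_genome):
        regions = sample_offpeak_regions(tiny_genome, [], n=10, width=500, seed=1)
        assert len(regions) == 10
        for r in regions:
            assert r.width == 500
            assert 0 <= r.start and r.end <= 10_000

    def test_zero_overlap_with_exclusion_brute_force(self, genome_small):
        rng = np.random.default_rng(5)
        exclusion = []
        for _ in range(40):
            chrom = ["chr1", "chr2"][rng.integers(0, 2)]
            s = int(rng.integers(0, 90_000))
            exclusion.append(Interval(chrom, s, s + int(rng.integers(100, 2_000))))
        regions = sample_offpeak_regions(genome_small, exclusion, n=200, width=1000, seed=2)
        for r in regions:
            for ex in exclusion:
                assert not r.overlaps(ex)

    def test_deterministic(self, tiny_genome):
        a = sample_offpeak_regions(tiny_genome, [], n=5, width=100, seed=3)
        b = sample_offpeak_regions(tiny_genome, [], n=5, width=100, seed=3)
        assert a == b

    def test_capacity_error(self, tiny_genome):
        with pytest.raises(ValueError, match="cannot place"):
            sample_offpeak_regions(tiny_genome, [], n=20_000, width=9_999, seed=1)

    def test_paper_scale_defaults(self):
        import inspect

        sig = inspect.signature(sample_offpeak_regions)
        assert sig.parameters["n"].default == 50_000
        assert sig.parameters["width"].default == 4000


class TestPileup:
    def test_constant_track_flat_profile(self, tiny_genome):
        track = CoverageTrack(tiny_genome, {"chr1": np.full(10_000, 4.0)})
        profile = pileup(track, [Interval("chr1", 4000, 5000)], window=100)
        assert np.allclose(profile.values, 4.0)

    def test_delta_at_center(self, tiny_genome):
        arr = np.zeros(10_000)
        arr[4500] = 7.0
        track = CoverageTrack(tiny_genome, {"chr1": arr})
        profile = pileup(track, [Interval("chr1", 4000, 5000)], window=50)
        assert profile.values[50] == 7.0
        assert profile.values.sum() == 7.0

    def test_matches_brute_force(self, tiny_genome):
        rng = np.random.default_rng(11)
        arr = rng.poisson(2.0, size=10_000).astype(float)
        track = CoverageTrack(tiny_genome, {"chr1": arr})
        regions = [
            Interval("chr1", int(s), int(s) + 200)
            for s in rng.integers(300, 9_500, size=5)
        ]
        window = 150
        profile = pileup(track, regions, window=window)
        for o in (-window, -7, 0, 42, window):
            vals = []
            for r in regions:
                pos = r.center + o
                vals.append(arr[pos] if 0 <= pos < 10_000 else 0.0)
            assert profile.values[o + window] == pytest.approx(np.mean(vals))

    def test_edge_regions_zero_padded(self, tiny_genome):
        track = CoverageTrack(tiny_genome, {"chr1": np.full(10_000, 1.0)})
        profile = pileup(track, [Interval("chr1", 0, 10)], window=50)
        assert profile.values[0] == 0.0  # offset -50 is off-chromosome
        assert profile.values[-1] == 1.0

    def test_empty_regions_error(self, tiny_genome):
        with pytest.raises(ValueError):
            pileup(CoverageTrack.zeros(tiny_genome), [], window=10)

    def test_linearity(self, tiny_genome):
        rng = np.random.default_rng(2)
        a = rng.poisson(3.0, 10_000).astype(float)
        b = rng.poisson(1.0, 10_000).astype(float)
        regions = [Interval("chr1", 2000, 2400), Interval("chr1", 7000, 7500)]
        t_ab = CoverageTrack(tiny_genome, {"chr1": 2 * a + 3 * b})
        p_ab = pileup(t_ab, regions, window=100)
        p_a = pileup(CoverageTrack(tiny_genome, {"chr1": a}), regions, window=100)
        p_b = pileup(CoverageTrack(tiny_genome, {"chr1": b}), regions, window=100)
        assert np.allclose(p_ab.values, 2 * p_a.values + 3 * p_b.values)


class TestFragmentSizeDistribution:
    def test_no_peaks_off_equals_all(self, frags_small):
        frags, _ = frags_small
        h_all = fragment_size_distribution(frags, [], "all")
        h_in = fragment_size_distribution(frags, [], "in_peak")
        h_off = fragment_size_distribution(frags, [], "off_peak")
        assert h_in.total == 0
        assert (h_off.counts == h_all.counts).all()

    def test_strata_partition_all(self, frags_small, elements_small):
        frags, _ = frags_small
        peaks = [e.interval for e in elements_small]
        h_all = fragment_size_distribution(frags, peaks, "all")
        h_in = fragment_size_distribution(frags, peaks, "in_peak")
        h_off = fragment_size_distribution(frags, peaks, "off_peak")
        assert h_in.total + h_off.total == h_all.total == len(frags)
        assert (h_in.counts + h_off.counts == h_all.counts).all()

    def test_peaks_required_for_strata(self, frags_small):
        frags, _ = frags_small
        with pytest.raises(ValueError):
            fragment_size_distribution(frags, None, "in_peak")


class TestBackgroundComparability:
    def test_depth_matched_backgrounds_within_twofold(
        self, genome_small, elements_small
    ):
        """Off-peak pile-up of a depth-matched single-cell track is within 2x
        of the bulk background pile-up on matched simulations."""
        from atacbench import (
            bulk_profile,
            simulate_fragments,
            single_cell_profile,
            thin_fragments,
        )

        sc, _ = simulate_fragments(
            elements_small, genome_small,
            single_cell_profile(n_cells=200, mean_fragments=400.0), seed=31,
        )
        bulk, _ = simulate_fragments(
            elements_small, genome_small,
            bulk_profile(n_cells=200, mean_fragments=100.0), seed=32,
        )
        thinned, _ = thin_fragments(sc, bulk.total_fragments, seed=33)
        exclusion = [e.interval for e in elements_small]
        regions = sample_offpeak_regions(genome_small, exclusion, n=300, width=1000, seed=34)
        p_sc = pileup(aggregate_coverage(thinned, genome=genome_small), regions, window=500)
        p_bulk = pileup(aggregate_coverage(bulk, genome=genome_small), regions, window=500)
        ratio = p_sc.values.mean() / p_bulk.values.mean()
        assert 0.5 < ratio < 2.0
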