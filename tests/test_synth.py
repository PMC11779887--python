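"""Generator contracts: genomes, element placement, ChIP tracks, fragments."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from atacbench import (
    ELEMENT_CLASSES,
    FragmentSizeModel,
    build_genome,
    place_elements,
    simulate_chip_tracks,
    simulate_fragments,
    single_cell_profile,
)
from atacbench.synth import SC_IN_PEAK_SIZES, SC_OFF_PEAK_SIZES


class TestBuildGenome:
    def test_single_chromosome(self):
        g = build_genome(1, 1_000_000, seed=7)
        assert g.chrom_names == ("chr1",)
        assert g.chrom_lengths == (1_000_000,)

    def test_deterministic(self):
        assert build_genome(2, 500_000, 7) == build_genome(2, 500_000, 7)

    @pytest.mark.parametrize("n_chroms,length", [(0, 1_000_000), (1, 1_000)])
    def test_invalid_arguments(self, n_chroms, length):
        with pytest.raises(ValueError):
            build_genome(n_chroms, length, 7)


class TestPlaceElements:
    def test_empty_request(self, genome_small):
        assert place_elements(genome_small, {}, seed=1) == []

    def test_disjoint_by_brute_force(self):
        g = build_genome(1, 1_000_000, seed=7)
        elems = place_elements(
            g, {"promoter": 10, "ctcf": 20}, element_width=300, min_gap=100, seed=5
        )
        assert len(elems) == 30
        ivs = [e.interval for e in elems]
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                assert not ivs[i].overlaps(ivs[j])

    def test_min_gap_and_bounds(self, genome_small):
        elems = place_elements(
            genome_small, {k: 5 for k in ELEMENT_CLASSES},
            element_width=200, min_gap=500, seed=3,
        )
        by_chrom = {}
        for e in elems:
            iv = e.interval
            assert 0 <= iv.start < iv.end <= genome_small.length_of(iv.chrom)
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end >= 500

    def test_strength_passthrough(self, genome_small):
        elems = place_elements(
            genome_small, {"promoter": 5, "ctcf": 5},
            strengths={"promoter": 0.9, "ctcf": 0.15},
            element_width=200, min_gap=500, seed=2,
        )
        p = [e.strength for e in elems if e.klass == "promoter"]
        c = [e.strength for e in elems if e.klass == "ctcf"]
        assert max(c) < min(p)

    def test_infeasible_packing(self):
        g = build_genome(1, 10_000, seed=1)
        with pytest.raises(ValueError, match="pack"):
            place_elements(g, {"promoter": 50}, element_width=400, min_gap=400, seed=1)

    def test_private_round_robin_covers_all_populations(self, genome_small):
        pops = ("a", "b", "c")
        elems = place_elements(
            genome_small, {"promoter": 6, "ctcf": 6}, element_width=200,
            min_gap=500, populations=pops, shared_fraction=0.5, seed=4,
        )
        private = [e for e in elems if len(e.population_mask) == 1]
        assert {next(iter(e.population_mask)) for e in private} == set(pops)


class TestFragmentSizeModel:
    def test_weights_validated(self):
        with pytest.raises(ValueError):
            FragmentSizeModel(weights=(0.5, 0.4, 0.2))

    def test_mode_ordering_validated(self):
        with pytest.raises(ValueError):
            FragmentSizeModel(weights=(0.4, 0.4, 0.2), modes=(200.0, 100.0, 370.0))

    @pytest.mark.parametrize("model", [SC_IN_PEAK_SIZES, SC_OFF_PEAK_SIZES])
    def test_nucleosomal_depletions(self, model):
        """Density has local minima in the mono- and di-nucleosomal troughs."""
        x = np.arange(30, 600)
        d = model.density(x)
        minima = [
            int(x[i])
            for i in range(1, len(x) - 1)
            if d[i] < d[i - 1] and d[i] <= d[i + 1]
        ]
        assert any(120 <= m <= 165 for m in minima)
        assert any(270 <= m <= 320 for m in minima)

    def test_mixture_weight_recovery(self):
        """Weight-only EM on 50k simulated lengths (component shapes known)
        recovers the mixture weights within 0.05."""
        model = SC_IN_PEAK_SIZES
        rng = np.random.default_rng(42)
        lengths = model.sample(50_000, rng).astype(float)
        log_x = np.log(lengths)
        comp_dens = np.stack(
            [
                np.exp(-((log_x - mu) ** 2) / (2 * s * s)) / s
                for mu, s in zip(model.mus, model.sigmas)
            ],
            axis=1,
        )
        w = np.full(3, 1 / 3)
        for _ in range(200):
            resp = comp_dens * w
            resp /= resp.sum(axis=1, keepdims=True)
            w = resp.mean(axis=0)
        assert np.abs(w - np.asarray(model.weights)).max() < 0.05


class TestSimulateChipTracks:
    def test_zero_noise_single_promoter(self):
        g = build_genome(1, 50_000, seed=1)
        elems = place_elements(g, {"promoter": 1}, element_width=400, min_gap=100, seed=1)
        chip, truth = simulate_chip_tracks(elems, g, noise_rate=0.0, seed=9)
        arr = chip["H3K4me3"].values("chr1")
        iv = elems[0].interval
        window = truth["H3K4me3"][0]
        assert arr[iv.start : iv.end].sum() > 0
        pad = 200  # fragment half-length beyond the truth window
        outside = np.concatenate(
            (arr[: max(0, window.start - pad)], arr[window.end + pad :])
        )
        assert (outside == 0).all()

    def test_ctcf_enrichment_by_brute_force(self, genome_small, elements_small):
        chip, _ = simulate_chip_tracks(elements_small, genome_small, seed=9)
        track = chip["CTCF"]
        per_base = np.concatenate([track.values(c) for c in genome_small.chrom_names])
        genome_mean = per_base.mean()
        ctcf_vals = np.concatenate(
            [
                track.values(e.interval.chrom)[e.interval.start : e.interval.end]
                for e in elements_small
                if e.klass == "ctcf"
            ]
        )
        assert ctcf_vals.mean() > 5 * genome_mean

    def test_deterministic(self, genome_small, elements_small):
        a, _ = simulate_chip_tracks(elements_small, genome_small, seed=4)
        b, _ = simulate_chip_tracks(elements_small, genome_small, seed=4)
        for mark in ("H3K4me1", "H3K4me3", "H3K27ac", "CTCF"):
            for chrom in genome_small.chrom_names:
                assert (a[mark].values(chrom) == b[mark].values(chrom)).all()


class TestSimulateFragments:
    def test_single_cell_single_barcode(self, genome_small, elements_small):
        profile = single_cell_profile(n_cells=1, mean_fragments=100.0)
        frags, truth = simulate_fragments(elements_small, genome_small, profile, seed=2)
        assert frags.n_barcodes == 1
        assert list(truth.values()) == ["pop0"]

    def test_bulk_single_pseudobarcode(self, genome_small, elements_small):
        from atacbench import bulk_profile

        frags, _ = simulate_fragments(
            elements_small, genome_small, bulk_profile(n_cells=20, mean_fragments=50.0),
            seed=2,
        )
        assert frags.n_barcodes == 1
        assert frags.barcodes()[0].startswith("BULK")

    def test_in_peak_fraction_binomial_oracle(self, genome_small, elements_small):
        """Observed element-overlap fraction within 3 binomial SDs of 0.5."""
        from atacbench import fragments_in_peaks_mask

        profile = single_cell_profile(
            n_cells=500, mean_fragments=200.0, in_peak_fraction=0.5
        )
        frags, _ = simulate_fragments(elements_small, genome_small, profile, seed=8)
        n = len(frags)
        assert n > 90_000
        observed = fragments_in_peaks_mask(
            frags, [e.interval for e in elements_small]
        ).mean()
        # overlap can only exceed the origin assignment (edge fragments)
        sd = np.sqrt(0.25 / n)
        assert observed > 0.5 - 3 * sd
        assert observed < 0.57  # allows boundary spill-over of in-peak draws

    def test_fragments_within_bounds_and_sorted(self, frags_small, genome_small):
        frags, _ = frags_small
        df = frags.frame
        assert (df["start"] < df["end"]).all()
        for chrom in genome_small.chrom_names:
            sub = df[df["chrom"] == chrom]
            assert (sub["end"] <= genome_small.length_of(chrom)).all()
            assert (np.diff(sub["start"].to_numpy()) >= 0).all()

    def test_fixed_seed_reproducible(self, genome_small, elements_small):
        profile = single_cell_profile(n_cells=10, mean_fragments=50.0)
        a, _ = simulate_fragments(elements_small, genome_small, profile, seed=5)
        b, _ = simulate_fragments(elements_small, genome_small, profile, seed=5)
        assert a.frame.equals(b.frame)

    def test_empty_elements_with_in_peak_fraction_rejected(self, genome_small):
        profile = single_cell_profile(n_cells=5, mean_fragments=10.0)
        with pytest.raises(ValueError):
            simulate_fragments([], genome_small, profile, seed=1)

    def test_strength_monotonicity(self, genome_small, elements_small, frags_small):
        """Mean per-element fragment count increases with element strength."""
        frags, _ = frags_small
        df = frags.frame
        counts, strengths = [], []
        for e in elements_small:
            sub = df[
                (df["chrom"] == e.interval.chrom)
                & (df["start"] < e.interval.end)
                & (df["end"] > e.interval.start)
            ]
            counts.append(len(sub))
            strengths.append(e.strength)
        rho, _ = spearmanr(strengths, counts)
        assert rho > 0.9

    def test_in_peak_subnucleosomal_excess(self, genome_small, elements_small):
        """Single-cell in-peak lengths carry more sub-nucleosomal mass than
        off-peak lengths (fixed seed)."""
        from atacbench import fragment_size_distribution

        profile = single_cell_profile(n_cells=200, mean_fragments=200.0)
        frags, _ = simulate_fragments(elements_small, genome_small, profile, seed=21)
        peaks = [e.interval for e in elements_small]
        h_in = fragment_size_distribution(frags, peaks, "in_peak")
        h_off = fragment_size_distribution(frags, peaks, "off_peak")
        assert h_in.mass_below(147) > h_off.mass_below(147)
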