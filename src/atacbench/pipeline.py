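"""Orchestration of the three benchmark experiments from one flat config.

* ``compare`` — simulate matched bulk and single-cell libraries from one
  element truth; pseudo-bulk, call and filter peaks in both; Venn-partition
  the peak sets; classify peaks by ChIP marks; measure classical-CTCF
  detection sensitivity for the single-cell, depth-matched single-cell and
  bulk tracks; contrast in-peak/off-peak fragment-size composition.
* ``downsample`` — cell-level downsampling grid with per-class detection
  sensitivity curves against the element truth.
* ``dilute`` — spike a homogeneous population into a 7-population background
  at decreasing levels and score cluster recovery.

All randomness flows from a single root seed through
:func:`split_seeds` (numpy SeedSequence, values kept below 2**31).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as io_formats
from .classify import (
    classical_ctcf_set,
    classify_elements,
    detection_sensitivity,
    extend_from_center,
    mark_coverage_matrix,
)
from .clustering import (
    SpikeInReport,
    build_tile_matrix,
    cluster_cells,
    spike_in_evaluation,
    tfidf_lsi,
)
from .core import GenomeModel, Interval
from .peaks import CallerParams, call_peaks, filter_peaks, venn_partition
from .resampling import sensitivity_curve, spike_in, thin_fragments
from .signal import aggregate_coverage, fragment_size_distribution
from .synth import (
    ELEMENT_CLASSES,
    ElementTruth,
    build_genome,
    bulk_profile,
    place_elements,
    simulate_chip_tracks,
    simulate_fragments,
    single_cell_profile,
)

logger = logging.getLogger("atacbench")

#: background population sizes for the dilution experiment (PBMC-like:
#: monocytes, CD4 T, CD8 naive, B, CD8 other, NK, pDC)
PBMC_POPULATIONS = {
    "Monocytes": 842,
    "CD4_T": 758,
    "CD8_naive": 288,
    "B_cells": 198,
    "CD8_other": 129,
    "NK_cells": 106,
    "pDC": 29,
}


@dataclass
class RunConfig:
    """Flat configuration for the benchmark experiments."""

    genome_n_chroms: int = 2
    genome_chrom_length: int = 2_500_000
    elements_per_class: int = 200
    element_width: int = 400
    min_gap: int = 3600
    sc_cells: int = 2000
    bulk_cells: int = 2000
    fragments_per_cell: float = 400.0
    bulk_fragments_per_cell: float = 44.0  # ~11% of single-cell depth
    sc_in_peak_fraction: float = 0.55
    bulk_in_peak_fraction: float = 0.35
    chip_depth: float = 60.0
    chip_noise_rate: float = 0.002
    peak_min_score: float = 0.5
    classify_factor: float = 2.0
    caller_window: int = 300
    caller_local_span: int = 10_000
    caller_min_width: int = 150
    caller_tail: float = 1e-6
    downsample_grid: tuple[int, ...] = (2000, 1000, 500, 100, 50)
    dilution_levels: tuple[int, ...] = (300, 150, 80, 40, 20)
    spike_cells_available: int = 300
    spike_private_weight: float = 0.3
    shared_fraction: float = 0.4
    tile_size: int = 500
    min_frags_per_cell: int = 100
    lsi_components: int = 30
    knn: int = 20
    resolution: float = 1.0
    recall_threshold: float = 0.8
    purity_threshold: float = 0.5
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("downsample_grid", "dilution_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def caller_params(self) -> CallerParams:
        return CallerParams(
            window=self.caller_window,
            local_bg_span=self.caller_local_span,
            min_width=self.caller_min_width,
            tail=self.caller_tail,
        )

    def to_manifest(self) -> dict:
        return dataclasses.asdict(self)


def split_seeds(root_seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2**31) from one root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


# ----------------------------------------------------------------- fixtures


def default_truth(
    config: RunConfig, seed: int, populations: Sequence[str] = ("pop0",)
) -> tuple[GenomeModel, list[ElementTruth]]:
    genome = build_genome(config.genome_n_chroms, config.genome_chrom_length, seed)
    elements = place_elements(
        genome,
        {k: config.elements_per_class for k in ELEMENT_CLASSES},
        element_width=config.element_width,
        min_gap=config.min_gap,
        populations=populations,
        shared_fraction=config.shared_fraction,
        seed=seed,
    )
    return genome, elements


def truth_references(elements: Sequence[ElementTruth]) -> dict[str, list[Interval]]:
    refs: dict[str, list[Interval]] = {k: [] for k in ELEMENT_CLASSES}
    for e in elements:
        refs[e.klass].append(e.interval)
    return refs


# -------------------------------------------------------------- experiments


def run_compare(config: RunConfig, seed: Optional[int] = None) -> dict:
    """Bulk vs single-cell comparison on one simulated truth."""
    seed = config.seed if seed is None else seed
    s_truth, s_chip, s_sc, s_bulk, s_thin = split_seeds(seed, 5)
    genome, elements = default_truth(config, s_truth)
    chip, chip_truth = simulate_chip_tracks(
        elements, genome, depth=config.chip_depth,
        noise_rate=config.chip_noise_rate, seed=s_chip,
    )

    sc_prof = single_cell_profile(
        config.sc_cells, config.fragments_per_cell, config.sc_in_peak_fraction
    )
    bulk_prof = bulk_profile(
        config.bulk_cells, config.bulk_fragments_per_cell, config.bulk_in_peak_fraction
    )
    sc_frags, _ = simulate_fragments(elements, genome, sc_prof, seed=s_sc)
    bulk_frags, _ = simulate_fragments(elements, genome, bulk_prof, seed=s_bulk)

    params = config.caller_params()
    sc_track = aggregate_coverage(sc_frags, genome=genome)
    bulk_track = aggregate_coverage(bulk_frags, genome=genome)
    sc_peaks = filter_peaks(call_peaks(sc_track, params), config.peak_min_score)
    bulk_peaks = filter_peaks(call_peaks(bulk_track, params), config.peak_min_score)

    venn = venn_partition(bulk_peaks, sc_peaks)

    # mark-based classification of the single-cell peak set
    windows = extend_from_center(sc_peaks)
    labels = (
        classify_elements(mark_coverage_matrix(windows, chip), chip, config.classify_factor)
        if sc_peaks
        else []
    )
    label_counts: dict[str, int] = {}
    for lab in labels:
        label_counts[lab] = label_counts.get(lab, 0) + 1

    # classical CTCF sensitivity: sc, depth-matched sc, bulk
    classical = classical_ctcf_set(
        chip_truth["CTCF"], chip_truth["H3K4me1"], chip_truth["H3K4me3"]
    )
    thinned, thin_report = thin_fragments(
        sc_frags, bulk_frags.total_fragments, seed=s_thin
    )
    thin_track = aggregate_coverage(thinned, genome=genome)
    thin_peaks = filter_peaks(call_peaks(thin_track, params), config.peak_min_score)
    sens = {}
    for name, called in (("sc", sc_peaks), ("sc_depth_matched", thin_peaks), ("bulk", bulk_peaks)):
        n_ref, n_det, pct = detection_sensitivity(classical, called)
        sens[name] = {"n_reference": n_ref, "n_detected": n_det, "percentage": pct}

    # fragment-size composition contrast
    hists = {
        "sc_in_peak": fragment_size_distribution(sc_frags, sc_peaks, "in_peak"),
        "sc_off_peak": fragment_size_distribution(sc_frags, sc_peaks, "off_peak"),
        "bulk_off_peak": fragment_size_distribution(bulk_frags, sc_peaks, "off_peak"),
    }
    sub_mass = {k: h.mass_below(147) for k, h in hists.items()}

    return {
        "venn": {
            "only_bulk": venn.n_only_a,
            "only_sc": venn.n_only_b,
            "common": venn.n_common,
            "total": venn.total,
        },
        "n_peaks": {"sc": len(sc_peaks), "bulk": len(bulk_peaks), "sc_depth_matched": len(thin_peaks)},
        "classification": label_counts,
        "classical_ctcf_sensitivity": sens,
        "depth_matching": thin_report,
        "subnucleosomal_mass": sub_mass,
        "n_classical_ctcf": len(classical),
    }


def run_downsample(
    config: RunConfig, seed: Optional[int] = None, include_full: bool = True
) -> dict:
    """Cell-count downsampling with per-class sensitivity vs element truth."""
    seed = config.seed if seed is None else seed
    s_truth, s_sc, s_curve = split_seeds(seed, 3)
    genome, elements = default_truth(config, s_truth)
    profile = single_cell_profile(
        config.sc_cells, config.fragments_per_cell, config.sc_in_peak_fraction
    )
    frags, _ = simulate_fragments(elements, genome, profile, seed=s_sc)
    grid = list(config.downsample_grid)
    if include_full and frags.n_barcodes not in grid:
        grid = [frags.n_barcodes] + grid
    curve = sensitivity_curve(
        frags,
        grid,
        truth_references(elements),
        genome=genome,
        caller_params=config.caller_params(),
        min_score=config.peak_min_score,
        seed=s_curve,
    )
    return {
        "cell_counts": curve.cell_counts,
        "reference_sizes": curve.reference_sizes,
        "percentages": curve.percentages,
        "detected": curve.detected,
        "peak_counts": curve.peak_counts,
        "full_overlap_counts": curve.full_overlap_counts,
    }


def run_dilution(config: RunConfig, seed: Optional[int] = None) -> SpikeInReport:
    """Spike-in dilution series with cluster-recovery scoring."""
    seed = config.seed if seed is None else seed
    seeds = split_seeds(seed, 4 + 2 * len(config.dilution_levels))
    s_truth, s_chip_unused, s_bg, s_spike = seeds[:4]
    level_seeds = seeds[4:]

    populations = list(PBMC_POPULATIONS) + ["spike"]
    genome = build_genome(config.genome_n_chroms, config.genome_chrom_length, s_truth)
    weights = {p: (1 - config.spike_private_weight) / len(PBMC_POPULATIONS) for p in PBMC_POPULATIONS}
    weights["spike"] = config.spike_private_weight
    elements = place_elements(
        genome,
        {k: config.elements_per_class for k in ELEMENT_CLASSES},
        element_width=config.element_width,
        min_gap=config.min_gap,
        populations=populations,
        shared_fraction=config.shared_fraction,
        private_weights=weights,
        seed=s_truth,
    )

    profile = single_cell_profile(
        config.sc_cells, config.fragments_per_cell, config.sc_in_peak_fraction
    )
    bg_frags, bg_truth = simulate_fragments(
        elements, genome, profile,
        populations_cells={**PBMC_POPULATIONS, "spike": 0}, seed=s_bg,
    )
    spike_frags, _ = simulate_fragments(
        elements, genome, profile,
        populations_cells={**{p: 0 for p in PBMC_POPULATIONS},
                           "spike": config.spike_cells_available},
        seed=s_spike,
    )

    entries = []
    for i, level in enumerate(config.dilution_levels):
        merged, truth = spike_in(
            bg_frags, bg_truth, spike_frags, level, seed=level_seeds[2 * i]
        )
        tiles = build_tile_matrix(
            merged, genome=genome, tile_size=config.tile_size,
            min_frags_per_cell=config.min_frags_per_cell,
        )
        emb = tfidf_lsi(tiles, n_components=config.lsi_components, seed=level_seeds[2 * i])
        labels = cluster_cells(
            emb, k_neighbors=config.knn, resolution=config.resolution,
            seed=level_seeds[2 * i + 1],
        )
        entries.append(
            spike_in_evaluation(
                labels, tiles.barcodes, truth,
                recall_threshold=config.recall_threshold,
                purity_threshold=config.purity_threshold,
            )
        )
        logger.info(
            "dilution level %d: recall=%.3f purity=%.3f success=%s",
            level, entries[-1].majority_cluster_recall,
            entries[-1].majority_cluster_purity, entries[-1].success,
        )
    return SpikeInReport(entries=entries)


EXPERIMENTS = ("compare", "downsample", "dilute")


def run_experiment(config: RunConfig, experiment: str, out_dir=None) -> dict:
    """Run one named experiment; write reports + manifest if out_dir given."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")
    logger.info("running experiment %s (seed=%d)", experiment, config.seed)
    if experiment == "compare":
        report = run_compare(config)
    elif experiment == "downsample":
        report = run_downsample(config)
    else:
        report = {"dilution": [dataclasses.asdict(e) for e in run_dilution(config).entries]}

    out_dir = out_dir or config.out_dir
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_manifest(
            {"experiment": experiment, "config": config.to_manifest()},
            out / f"{experiment}.manifest.json",
        )
        io_formats.write_manifest(report, out / f"{experiment}.report.json")
    return report
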