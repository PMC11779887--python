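"""In-silico cell downsampling, read-depth thinning and spike-in dilution.

Downsampling is cell-level everywhere: a uniform random subset of barcodes is
kept and each kept barcode's fragments are carried over exactly (no
fragment-level resampling). A separate Bernoulli fragment-thinning utility
supports depth-matched comparisons between technologies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import detection_sensitivity
from .core import FragmentSet, GenomeModel
from .peaks import CallerParams, call_peaks, filter_peaks
from .signal import aggregate_coverage


@dataclass
class SensitivityCurve:
    """Detection sensitivity per reference class across cell counts."""

    cell_counts: list[int]
    reference_sizes: dict[str, int]
    detected: dict[str, list[int]]  # class -> per cell count
    percentages: dict[str, list[float]]
    peak_counts: list[int]
    full_overlap_counts: list[int]  # peaks overlapping the full-data peak set

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, n in enumerate(self.cell_counts):
            for klass in self.detected:
                rows.append(
                    {
                        "n_cells": n,
                        "class": klass,
                        "n_reference": self.reference_sizes[klass],
                        "n_detected": self.detected[klass][i],
                        "percentage": self.percentages[klass][i],
                    }
                )
        return pd.DataFrame(rows)


def list_barcodes(frags: FragmentSet) -> pd.Series:
    """Exact fragment counts per barcode (duplicate-count weighted)."""
    if not len(frags):
        return pd.Series(dtype=np.int64, name="fragments")
    counts = frags.frame.groupby("barcode")["count"].sum().sort_index()
    counts.name = "fragments"
    return counts


def downsample_cells(frags: FragmentSet, n_cells: int, seed: int = 0) -> FragmentSet:
    """Keep a uniform random subset of n_cells barcodes, fragments intact."""
    barcodes = frags.barcodes()
    if n_cells > len(barcodes):
        raise ValueError(
            f"requested {n_cells} cells but only {len(barcodes)} barcodes present"
        )
    if n_cells == len(barcodes):
        return frags
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(barcodes, dtype=object), size=n_cells, replace=False)
    return frags.subset_barcodes(chosen.tolist())


def thin_fragments(
    frags: FragmentSet, target_fragments: int, seed: int = 0
) -> tuple[FragmentSet, dict]:
    """Bernoulli fragment-level thinning to approximately a target total.

    Returns the thinned set and a report with the retention percentage
    (100 x target / total), the depth-matching statistic used when comparing
    a deeply sequenced single-cell library against a bulk one.
    """
    total = frags.total_fragments
    report = {
        "total_fragments": total,
        "target_fragments": int(target_fragments),
        "retained_percentage": retained_percentage(total, target_fragments),
    }
    if target_fragments >= total:
        return frags, report
    p = target_fragments / total
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frags)) < p
    out = FragmentSet(frags.frame[keep], genome=frags.genome)
    report["fragments_after"] = out.total_fragments
    return out, report


def retained_percentage(total: int, target: int) -> float:
    """Percentage of fragments (or reads) retained by thinning to a target."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * min(target, total) / total


def sensitivity_curve(
    frags: FragmentSet,
    cell_counts: Sequence[int],
    references: Mapping[str, Sequence],
    genome: Optional[GenomeModel] = None,
    caller_params: CallerParams = CallerParams(),
    min_score: float = 0.5,
    blacklist: Optional[Sequence] = None,
    seed: int = 0,
) -> SensitivityCurve:
    """Downsample -> pseudo-bulk -> call/filter peaks -> per-class sensitivity.

    Also reports, per cell count, the number of called peaks and how many of
    them overlap the full-data peak set.
    """
    if not references:
        raise ValueError("references must be non-empty")
    genome = genome or frags.genome
    rng = np.random.default_rng(seed)

    full_track = aggregate_coverage(frags, genome=genome)
    full_peaks = filter_peaks(call_peaks(full_track, caller_params), min_score, blacklist)

    n_available = frags.n_barcodes
    detected: dict[str, list[int]] = {k: [] for k in references}
    percentages: dict[str, list[float]] = {k: [] for k in references}
    peak_counts: list[int] = []
    full_overlaps: list[int] = []
    for n in cell_counts:
        if n == n_available:
            called = full_peaks
        else:
            sub = downsample_cells(frags, n, seed=int(rng.integers(0, 2**31 - 1)))
            track = aggregate_coverage(sub, genome=genome)
            called = filter_peaks(call_peaks(track, caller_params), min_score, blacklist)
        peak_counts.append(len(called))
        if called and full_peaks:
            _, n_ov, _ = detection_sensitivity(called, full_peaks)
        else:
            n_ov = 0
        full_overlaps.append(n_ov)
        for klass, ref in references.items():
            if called:
                _, n_det, pct = detection_sensitivity(ref, called)
            else:
                n_det, pct = 0, 0.0
            detected[klass].append(n_det)
            percentages[klass].append(pct)

    return SensitivityCurve(
        cell_counts=list(cell_counts),
        reference_sizes={k: len(v) for k, v in references.items()},
        detected=detected,
        percentages=percentages,
        peak_counts=peak_counts,
        full_overlap_counts=full_overlaps,
    )


SPIKE_SUFFIX = "::spike"


def spike_in(
    background: FragmentSet,
    background_truth: Mapping[str, str],
    spike: FragmentSet,
    n_spike: int,
    keep_populations: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> tuple[FragmentSet, dict[str, str]]:
    """Dilute n_spike cells of a homogeneous population into a background.

    Spike barcodes are suffix-disambiguated so they can never collide with
    background barcodes; the returned truth table labels them ``spike``.
    """
    if keep_populations is not None:
        keep = set(keep_populations)
        bg_barcodes = [b for b, p in background_truth.items() if p in keep]
        background = background.subset_barcodes(bg_barcodes)
        background_truth = {b: p for b, p in background_truth.items() if p in keep}

    spike_barcodes = spike.barcodes()
    if n_spike > len(spike_barcodes):
        raise ValueError(
            f"requested {n_spike} spike cells but only {len(spike_barcodes)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(
        np.asarray(spike_barcodes, dtype=object), size=n_spike, replace=False
    ).tolist()
    sub = spike.subset_barcodes(chosen)

    renamed = sub.frame.copy()
    renamed["barcode"] = renamed["barcode"].astype(str) + SPIKE_SUFFIX
    bg_set = set(background.frame["barcode"].unique())
    if bg_set & set(renamed["barcode"].unique()):
        raise RuntimeError("barcode collision after suffix disambiguation")

    merged = background.concat(FragmentSet(renamed, genome=spike.genome)).sorted()
    truth = dict(background_truth)
    for bc in chosen:
        truth[f"{bc}{SPIKE_SUFFIX}"] = "spike"
    return merged, truth
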