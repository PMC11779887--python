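"""ChIP-mark-based regulatory-element classification and detection
sensitivity.

Peaks are extended 2 kb each side of their centers; mean coverage of the
four marks (H3K4me1 = primed enhancer, H3K4me3 = promoter, H3K27ac = active
chromatin, CTCF = boundary elements) over those windows drives a rule-based
labelling. A mark is "present" in a window when its mean exceeds a
configurable enrichment factor (default 2x) over the genome-wide mark mean,
or over an input/background track where one is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import Interval, Peak
from .peaks import _build_trees
from .synth import ChipSignalSet

ELEMENT_LABELS = (
    "Promoter",
    "Enhancer",
    "CTCF",
    "Promoter/CTCF",
    "Enhancer/CTCF",
    "Unclassified",
)


@dataclass
class MarkMatrix:
    """Mean mark coverage over peak-centered windows (rows follow input order)."""

    values: np.ndarray  # n_windows x n_marks
    marks: tuple[str, ...]
    windows: list[Interval]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.windows), len(self.marks)):
            raise ValueError("MarkMatrix shape mismatch")
        if (self.values < 0).any():
            raise ValueError("mark coverage must be >= 0")

    def column(self, mark: str) -> np.ndarray:
        return self.values[:, self.marks.index(mark)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.marks))
        df.insert(0, "chrom", [w.chrom for w in self.windows])
        df.insert(1, "start", [w.start for w in self.windows])
        df.insert(2, "end", [w.end for w in self.windows])
        return df


def extend_from_center(
    peaks: Sequence[Union[Peak, Interval]], flank: int = 2000
) -> list[Interval]:
    """Windows [center - flank, center + flank), clipped at chromosome edges
    when the peaks carry no genome the clip is at 0 only."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for p in peaks:
        center = (p.start + p.end) // 2
        out.append(Interval(p.chrom, max(0, center - flank), center + flank))
    return out


def clip_to_genome(windows: Sequence[Interval], genome) -> list[Interval]:
    return [
        Interval(w.chrom, w.start, min(w.end, genome.length_of(w.chrom)))
        for w in windows
    ]


def mark_coverage_matrix(
    windows: Sequence[Interval], chip: ChipSignalSet
) -> MarkMatrix:
    """Mean per-bp coverage of each mark over each window."""
    if not windows:
        raise ValueError("mark_coverage_matrix requires at least one window")
    genome = chip.genome
    values = np.zeros((len(windows), len(ChipSignalSet.MARKS)))
    for j, mark in enumerate(ChipSignalSet.MARKS):
        track = chip[mark]
        b = track.bin_size
        for i, w in enumerate(windows):
            end = min(w.end, genome.length_of(w.chrom))
            if end <= w.start:
                continue
            positions = np.arange(w.start, end) // b
            values[i, j] = float(track.data[w.chrom][positions].mean())
    return MarkMatrix(values=values, marks=ChipSignalSet.MARKS, windows=list(windows))


def sort_by_mark_difference(m: MarkMatrix) -> np.ndarray:
    """Row order: descending H3K4me1 - H3K4me3, genomic coordinate tie-break."""
    diff = m.column("H3K4me1") - m.column("H3K4me3")
    coords = [(w.chrom, w.start, w.end) for w in m.windows]
    order = sorted(range(len(diff)), key=lambda i: coords[i])
    order.sort(key=lambda i: -diff[i])  # stable: ties keep genomic order
    return np.asarray(order)


def genome_mark_means(chip: ChipSignalSet) -> dict[str, float]:
    means = {}
    for mark in ChipSignalSet.MARKS:
        track = chip[mark]
        means[mark] = track.total_signal() / track.genome.total_length
    return means


def classify_elements(
    m: MarkMatrix,
    chip: ChipSignalSet,
    enrichment_factor: float = 2.0,
) -> list[str]:
    """Label each window from its mark presence pattern.

    Presence = window mean > factor x reference level. The reference is the
    genome-wide mean of the input/background track when one is available,
    else the genome-wide mean of the mark itself. Rules: H3K4me3 present ->
    Promoter; else H3K4me1 present -> Enhancer; CTCF present combines to
    Promoter/CTCF or Enhancer/CTCF, or plain CTCF when neither K-mark is
    present; nothing present -> Unclassified.
    """
    if chip.input_track is not None:
        tr = chip.input_track
        ref_level = tr.total_signal() / tr.genome.total_length
        if ref_level == 0:
            raise ValueError("input track is empty; threshold undefined")
        refs = {mark: ref_level for mark in ChipSignalSet.MARKS}
    else:
        refs = genome_mark_means(chip)
        for mark, mean in refs.items():
            if mean == 0:
                raise ValueError(f"genome-wide mean for {mark} is zero; threshold undefined")

    labels = []
    for i in range(len(m.windows)):
        present = {}
        for mark in ChipSignalSet.MARKS:
            present[mark] = m.values[i, m.marks.index(mark)] > enrichment_factor * refs[mark]
        if present["H3K4me3"]:
            base = "Promoter"
        elif present["H3K4me1"]:
            base = "Enhancer"
        else:
            base = None
        if present["CTCF"]:
            labels.append(f"{base}/CTCF" if base else "CTCF")
        else:
            labels.append(base if base else "Unclassified")
    return labels


def classical_ctcf_set(
    ctcf_peaks: Sequence[Union[Interval, Peak]],
    k4me1_peaks: Sequence[Union[Interval, Peak]],
    k4me3_peaks: Sequence[Union[Interval, Peak]],
) -> list:
    """CTCF peaks devoid of any overlap with enhancer or promoter mark peaks."""
    t1, t3 = _build_trees(k4me1_peaks), _build_trees(k4me3_peaks)
    out = []
    for p in ctcf_peaks:
        hit1 = p.chrom in t1 and t1[p.chrom].overlaps(p.start, p.end)
        hit3 = p.chrom in t3 and t3[p.chrom].overlaps(p.start, p.end)
        if not hit1 and not hit3:
            out.append(p)
    return out


def detection_sensitivity(
    reference: Sequence[Union[Interval, Peak]],
    called: Sequence[Union[Interval, Peak]],
) -> tuple[int, int, float]:
    """(n_reference, n_detected, percentage).

    A reference peak is detected when it overlaps >= 1 called peak.
    The percentage is truncated to 2 decimals, matching the printed style of
    published sensitivity figures.
    """
    if not reference:
        raise ValueError("detection_sensitivity: empty reference set")
    trees = _build_trees(called)
    n_det = 0
    for r in reference:
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlaps(r.start, r.end):
            n_det += 1
    pct = (10_000 * n_det // len(reference)) / 100.0
    return len(reference), n_det, pct
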