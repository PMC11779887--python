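"""Synthetic scATAC/bulk-ATAC data generator.

Emulates the statistical structure of barcoded tagmentation-fragment data:

* a fragment-length mixture with sub-nucleosomal (~80 bp), mono-nucleosomal
  (~185 bp) and di-nucleosomal (~370 bp) modes and depletions near 150 and
  300 bp, reflecting nucleosome protection;
* regulatory elements of graded accessibility — strong promoters, medium
  enhancers, weak primed enhancers, weakest CTCF sites — so that weak
  classes vanish first as cells are removed;
* technology-dependent in-peak vs off-peak fragment composition: single-cell
  background is depleted for sub-nucleosomal and enriched for
  mono-nucleosomal fragments relative to bulk background;
* multiple cell populations with population-specific element sets, enabling
  in-silico spike-in dilution experiments;
* ChIP-mark coverage tracks (H3K4me1, H3K4me3, H3K27ac, CTCF) consistent
  with the element truth, for mark-based classification.

Everything is deterministic under an explicit seed; fragment ``count`` is
always 1 (PCR duplication is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CoverageTrack, FragmentSet, GenomeModel, Interval

ELEMENT_CLASSES = ("promoter", "enhancer", "primed_enhancer", "ctcf")

#: default per-cell capture weight by element class; ordered so the weakest
#: classes (CTCF, primed enhancers) are lost first under downsampling
DEFAULT_STRENGTHS = {
    "promoter": 0.9,
    "enhancer": 0.5,
    "primed_enhancer": 0.25,
    "ctcf": 0.12,
}

MIN_FRAGMENT_LENGTH = 20
MAX_FRAGMENT_LENGTH = 1000


@dataclass(frozen=True)
class FragmentSizeModel:
    """Three-component log-normal mixture over fragment lengths.

    Components are parameterised by their mode (bp) and log-scale sigma;
    for a log-normal, ``mu = log(mode) + sigma**2``. Modes must be ordered
    sub < mono < di and weights sum to 1.
    """

    weights: tuple[float, float, float]
    modes: tuple[float, float, float] = (80.0, 185.0, 370.0)
    sigmas: tuple[float, float, float] = (0.38, 0.14, 0.10)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
        if not (self.modes[0] < self.modes[1] < self.modes[2]):
            raise ValueError("component modes must be ordered sub < mono < di")

    @property
    def mus(self) -> tuple[float, float, float]:
        return tuple(
            float(np.log(m) + s * s) for m, s in zip(self.modes, self.sigmas)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(3, size=n, p=np.asarray(self.weights))
        mus = np.asarray(self.mus)
        sigmas = np.asarray(self.sigmas)
        raw = rng.lognormal(mean=mus[comp], sigma=sigmas[comp])
        return np.clip(np.rint(raw), MIN_FRAGMENT_LENGTH, MAX_FRAGMENT_LENGTH).astype(
            np.int64
        )

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        dens = np.zeros_like(x)
        for w, mu, s in zip(self.weights, self.mus, self.sigmas):
            dens += (
                w
                / (x * s * np.sqrt(2 * np.pi))
                * np.exp(-((np.log(x) - mu) ** 2) / (2 * s * s))
            )
        return dens


# default mixtures: single-cell signal is rich in sub-nucleosomal fragments,
# single-cell background shifts to mono-nucleosomal, bulk background shifts
# to sub-nucleosomal
SC_IN_PEAK_SIZES = FragmentSizeModel(weights=(0.55, 0.35, 0.10))
SC_OFF_PEAK_SIZES = FragmentSizeModel(weights=(0.30, 0.55, 0.15))
BULK_IN_PEAK_SIZES = FragmentSizeModel(weights=(0.50, 0.40, 0.10))
BULK_OFF_PEAK_SIZES = FragmentSizeModel(weights=(0.60, 0.30, 0.10))


@dataclass(frozen=True)
class FragmentCountModel:
    """Negative-binomial per-cell fragment count (mean, shape)."""

    mean: float
    shape: float = 10.0  # larger = closer to Poisson

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.shape / (self.shape + self.mean)
        counts = rng.negative_binomial(self.shape, p, size=n)
        return np.maximum(counts, 1)


@dataclass(frozen=True)
class TechnologyProfile:
    """How a technology turns cells into fragments."""

    label: str  # "bulk" or "single_cell"
    n_cells: int
    fragments_per_cell: FragmentCountModel
    in_peak_fraction: float
    in_peak_size_model: FragmentSizeModel
    off_peak_size_model: FragmentSizeModel

    def __post_init__(self) -> None:
        if self.label not in ("bulk", "single_cell"):
            raise ValueError(f"unknown technology label {self.label!r}")
        if not (0.0 <= self.in_peak_fraction <= 1.0):
            raise ValueError("in_peak_fraction outside [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


def single_cell_profile(
    n_cells: int = 2000, mean_fragments: float = 400.0, in_peak_fraction: float = 0.55
) -> TechnologyProfile:
    return TechnologyProfile(
        label="single_cell",
        n_cells=n_cells,
        fragments_per_cell=FragmentCountModel(mean=mean_fragments),
        in_peak_fraction=in_peak_fraction,
        in_peak_size_model=SC_IN_PEAK_SIZES,
        off_peak_size_model=SC_OFF_PEAK_SIZES,
    )


def bulk_profile(
    n_cells: int = 2000, mean_fragments: float = 400.0, in_peak_fraction: float = 0.35
) -> TechnologyProfile:
    """Bulk profile: one pseudo-barcode, noisier background composition."""
    return TechnologyProfile(
        label="bulk",
        n_cells=n_cells,
        fragments_per_cell=FragmentCountModel(mean=mean_fragments),
        in_peak_fraction=in_peak_fraction,
        in_peak_size_model=BULK_IN_PEAK_SIZES,
        off_peak_size_model=BULK_OFF_PEAK_SIZES,
    )


@dataclass(frozen=True)
class ElementTruth:
    """A ground-truth regulatory element with graded accessibility."""

    interval: Interval
    klass: str
    strength: float
    population_mask: frozenset[str]

    def __post_init__(self) -> None:
        if self.klass not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.klass!r}")
        if not (0.0 < self.strength <= 1.0):
            raise ValueError("strength must be in (0, 1]")


@dataclass(frozen=True)
class ChipSignalSet:
    """Coverage tracks for the four classification marks (+ optional input)."""

    tracks: dict[str, CoverageTrack]
    input_track: Optional[CoverageTrack] = None

    MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "CTCF")

    def __post_init__(self) -> None:
        missing = [m for m in self.MARKS if m not in self.tracks]
        if missing:
            raise ValueError(f"missing mark tracks: {missing}")

    def __getitem__(self, mark: str) -> CoverageTrack:
        return self.tracks[mark]

    @property
    def genome(self) -> GenomeModel:
        return next(iter(self.tracks.values())).genome


# ------------------------------------------------------------------ genome


def build_genome(n_chroms: int, chrom_length: int, seed: int = 0) -> GenomeModel:
    """Equal-length chromosomes named chr1..chrN."""
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    return GenomeModel(names, tuple(int(chrom_length) for _ in names))


# ---------------------------------------------------------------- elements


def place_elements(
    genome: GenomeModel,
    counts_per_class: Mapping[str, int],
    strengths: Optional[Mapping[str, float]] = None,
    element_width: int = 400,
    min_gap: int = 3600,
    populations: Sequence[str] = ("pop0",),
    shared_fraction: float = 0.5,
    private_weights: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> list[ElementTruth]:
    """Place non-overlapping elements separated by >= min_gap.

    A ``shared_fraction`` of elements is accessible in every population
    (housekeeping); the rest are each private to one population. Private
    assignment is round-robin by default, or proportional to
    ``private_weights`` when given (e.g. to make a spike-in population's
    element repertoire more distinct).
    """
    strengths = dict(DEFAULT_STRENGTHS, **(strengths or {}))
    for klass in counts_per_class:
        if klass not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {klass!r}")
    n_total = int(sum(counts_per_class.values()))
    if n_total == 0:
        return []
    rng = np.random.default_rng(seed)

    # apportion elements to chromosomes by length, largest remainder
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    quota = n_total * lengths / lengths.sum()
    per_chrom = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - per_chrom))[: n_total - per_chrom.sum()]:
        per_chrom[i] += 1

    starts_all: list[tuple[str, int]] = []
    for chrom, length, k in zip(genome.chrom_names, genome.chrom_lengths, per_chrom):
        if k == 0:
            continue
        span = k * element_width + (k - 1) * min_gap
        if span > length:
            raise ValueError(
                f"cannot pack {k} elements of {element_width} bp with gap "
                f"{min_gap} bp into {chrom} ({length} bp)"
            )
        free = length - span
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        starts = offsets + np.arange(k) * (element_width + min_gap)
        starts_all.extend((chrom, int(s)) for s in starts)

    labels = [k for k, n in sorted(counts_per_class.items()) for _ in range(int(n))]
    rng.shuffle(labels)

    populations = list(populations)
    n_shared = int(round(shared_fraction * n_total)) if len(populations) > 1 else n_total
    shared_idx = set(rng.choice(n_total, size=n_shared, replace=False).tolist())
    if private_weights is not None:
        w = np.array([float(private_weights.get(p, 0.0)) for p in populations])
        if w.sum() <= 0:
            raise ValueError("private_weights must have positive total mass")
        private_probs = w / w.sum()
    else:
        private_probs = None
    elements = []
    private_counter = 0
    for i, ((chrom, start), klass) in enumerate(zip(starts_all, labels)):
        if i in shared_idx or len(populations) == 1:
            mask = frozenset(populations)
        elif private_probs is not None:
            mask = frozenset({populations[int(rng.choice(len(populations), p=private_probs))]})
        else:
            mask = frozenset({populations[private_counter % len(populations)]})
            private_counter += 1
        iv = Interval(chrom, start, start + element_width, name=klass)
        elements.append(
            ElementTruth(iv, klass, float(strengths[klass]), mask)
        )
    return elements


def elements_to_bed(elements: Sequence[ElementTruth]) -> list[Interval]:
    """Element truth as BED6 records (name=class, score=1000 x strength)."""
    return [
        Interval(
            e.interval.chrom,
            e.interval.start,
            e.interval.end,
            name=e.klass,
            score=round(1000 * e.strength),
        )
        for e in elements
    ]


# -------------------------------------------------------------- ChIP tracks

MARK_TO_CLASSES = {
    "H3K4me3": ("promoter",),
    "H3K4me1": ("enhancer", "primed_enhancer"),
    "H3K27ac": ("promoter", "enhancer"),
    "CTCF": ("ctcf",),
}


def _accumulate_fragments(
    arr: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> None:
    """Add +1 coverage over [start, end) ranges via a difference array."""
    np.add.at(arr, starts, 1.0)
    np.add.at(arr, ends, -1.0)


def simulate_chip_tracks(
    elements: Sequence[ElementTruth],
    genome: GenomeModel,
    depth: float = 60.0,
    noise_rate: float = 0.002,
    seed: int = 0,
    flank: int = 200,
    chip_fragment_length: int = 200,
    ctcf_cobinding_fraction: float = 0.25,
) -> tuple[ChipSignalSet, dict[str, list[Interval]]]:
    """Simulate the four mark coverage tracks plus per-mark truth peaks.

    ``depth`` is the mean number of ChIP fragments per bound element;
    ``noise_rate`` is the per-bp rate of uniform background fragments.
    A ``ctcf_cobinding_fraction`` of promoters and enhancers additionally
    receive CTCF signal, producing combined Promoter/CTCF and Enhancer/CTCF
    classes downstream. The returned set carries an input/background track
    (noise only) as the classification reference level.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)

    # CTCF co-binding assignment (deterministic under seed)
    cobound: set[int] = set()
    candidates = [
        i for i, e in enumerate(elements) if e.klass in ("promoter", "enhancer")
    ]
    if candidates and ctcf_cobinding_fraction > 0:
        n_co = int(round(ctcf_cobinding_fraction * len(candidates)))
        if n_co:
            cobound = set(
                rng.choice(np.asarray(candidates), size=n_co, replace=False).tolist()
            )

    tracks: dict[str, CoverageTrack] = {}
    truth_peaks: dict[str, list[Interval]] = {}
    chrom_index = {c: i for i, c in enumerate(genome.chrom_names)}
    half = chip_fragment_length // 2

    for mark in ChipSignalSet.MARKS:
        diff = {
            c: np.zeros(genome.length_of(c) + 1) for c in genome.chrom_names
        }
        bound: list[Interval] = []
        for i, elem in enumerate(elements):
            is_target = elem.klass in MARK_TO_CLASSES[mark] or (
                mark == "CTCF" and i in cobound
            )
            if not is_target:
                continue
            iv = elem.interval
            length = genome.length_of(iv.chrom)
            n_frag = rng.poisson(depth)
            if n_frag:
                centers = rng.integers(iv.start - flank // 2, iv.end + flank // 2, size=n_frag)
                starts = np.clip(centers - half, 0, length)
                ends = np.clip(centers + half, 0, length)
                keep = starts < ends
                _accumulate_fragments(diff[iv.chrom], starts[keep], ends[keep])
            bound.append(
                Interval(
                    iv.chrom,
                    max(0, iv.start - flank),
                    min(length, iv.end + flank),
                    name=mark,
                )
            )
        # uniform Poisson background
        if noise_rate > 0:
            for chrom in genome.chrom_names:
                length = genome.length_of(chrom)
                n_noise = rng.poisson(noise_rate * length)
                if n_noise:
                    starts = rng.integers(0, max(1, length - chip_fragment_length), size=n_noise)
                    ends = np.minimum(starts + chip_fragment_length, length)
                    _accumulate_fragments(diff[chrom], starts, ends)
        data = {c: np.cumsum(d[:-1]) for c, d in diff.items()}
        tracks[mark] = CoverageTrack(genome, data, bin_size=1, normalization="raw")
        bound.sort(key=lambda iv: (chrom_index[iv.chrom], iv.start))
        truth_peaks[mark] = _merge_intervals(bound)

    # input/background: uniform noise at the same rate, no element signal
    input_track = None
    if noise_rate > 0:
        diff = {c: np.zeros(genome.length_of(c) + 1) for c in genome.chrom_names}
        for chrom in genome.chrom_names:
            length = genome.length_of(chrom)
            n_noise = rng.poisson(noise_rate * length)
            if n_noise:
                starts = rng.integers(0, max(1, length - chip_fragment_length), size=n_noise)
                ends = np.minimum(starts + chip_fragment_length, length)
                _accumulate_fragments(diff[chrom], starts, ends)
        input_track = CoverageTrack(
            genome, {c: np.cumsum(d[:-1]) for c, d in diff.items()},
            bin_size=1, normalization="raw",
        )

    return ChipSignalSet(tracks, input_track=input_track), truth_peaks


def _merge_intervals(sorted_ivs: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for iv in sorted_ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(
                Interval(last.chrom, last.start, max(last.end, iv.end), name=last.name)
            )
        else:
            merged.append(iv)
    return merged


# --------------------------------------------------------------- fragments


def simulate_fragments(
    elements: Sequence[ElementTruth],
    genome: GenomeModel,
    profile: TechnologyProfile,
    populations_cells: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> tuple[FragmentSet, dict[str, str]]:
    """Simulate barcoded fragments plus a barcode -> population truth table.

    Each cell draws a fragment count from the profile's count model. A
    fragment is in-peak with probability ``in_peak_fraction``; in-peak
    fragments pick an element accessible in the cell's population with
    probability proportional to element strength, and are centred uniformly
    within it. Off-peak fragments land uniformly on the genome. Lengths come
    from the stratum's size model. Bulk profiles collapse all cells onto a
    single pseudo-barcode.
    """
    if populations_cells is None:
        populations_cells = {"pop0": profile.n_cells}
    elem_pops = set().union(*(e.population_mask for e in elements)) if elements else set()
    unknown = elem_pops - set(populations_cells)
    if unknown:
        raise ValueError(f"element populations {sorted(unknown)} not in populations_cells")
    if not elements and profile.in_peak_fraction > 0:
        raise ValueError("no elements but in_peak_fraction > 0")

    rng = np.random.default_rng(seed)
    chrom_lengths = np.asarray(genome.chrom_lengths, dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()

    frames = []
    truth: dict[str, str] = {}
    for pop in sorted(populations_cells):
        n_cells = int(populations_cells[pop])
        if n_cells <= 0:
            continue
        if profile.label == "bulk":
            barcodes = np.array([f"BULK_{pop}"])
            cell_counts = np.array(
                [int(profile.fragments_per_cell.sample(n_cells, rng).sum())]
            )
        else:
            barcodes = np.array([f"{pop}#{i:05d}" for i in range(n_cells)])
            cell_counts = profile.fragments_per_cell.sample(n_cells, rng)
        for bc in barcodes:
            truth[str(bc)] = pop

        total = int(cell_counts.sum())
        frag_barcodes = np.repeat(barcodes, cell_counts)
        in_peak = rng.random(total) < profile.in_peak_fraction

        acc = [e for e in elements if pop in e.population_mask]
        n_in = int(in_peak.sum())
        if n_in and not acc:
            raise ValueError(f"population {pop!r} has no accessible elements")

        chroms = np.empty(total, dtype=object)
        starts = np.zeros(total, dtype=np.int64)
        ends = np.zeros(total, dtype=np.int64)

        if n_in:
            w = np.array([e.strength for e in acc])
            idx = rng.choice(len(acc), size=n_in, p=w / w.sum())
            lens = profile.in_peak_size_model.sample(n_in, rng)
            e_chrom = np.array([e.interval.chrom for e in acc], dtype=object)
            e_start = np.array([e.interval.start for e in acc])
            e_end = np.array([e.interval.end for e in acc])
            e_cl = np.array([genome.length_of(e.interval.chrom) for e in acc])
            centers = rng.integers(e_start[idx], e_end[idx])
            s = centers - lens // 2
            s = np.clip(s, 0, np.maximum(e_cl[idx] - lens, 0))
            chroms[in_peak] = e_chrom[idx]
            starts[in_peak] = s
            ends[in_peak] = np.minimum(s + lens, e_cl[idx])

        n_off = total - n_in
        if n_off:
            off = ~in_peak
            lens = profile.off_peak_size_model.sample(n_off, rng)
            ci = rng.choice(len(genome.chrom_names), size=n_off, p=chrom_probs)
            cl = chrom_lengths[ci].astype(np.int64)
            s = rng.integers(0, np.maximum(cl - lens, 1))
            chroms[off] = np.array(genome.chrom_names, dtype=object)[ci]
            starts[off] = s
            ends[off] = np.minimum(s + lens, cl)

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chroms.astype(str),
                    "start": starts,
                    "end": np.maximum(ends, starts + 1),
                    "barcode": frag_barcodes.astype(str),
                    "count": np.ones(total, dtype=np.int64),
                }
            )
        )

    if frames:
        frame = pd.concat(frames, ignore_index=True)
    else:
        return FragmentSet.empty(genome=genome), truth
    return FragmentSet(frame, genome=genome).sorted(), truth


# -------------------------------------------------------------- gene model


def make_gene_model(genome: GenomeModel, n_genes: int = 50, seed: int = 0):
    """A random strand-aware gene model for location annotation tests."""
    from .peaks import Gene, GeneModel

    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        ci = int(rng.integers(0, len(genome.chrom_names)))
        chrom = genome.chrom_names[ci]
        length = genome.chrom_lengths[ci]
        gene_len = int(rng.integers(5_000, 30_000))
        start = int(rng.integers(0, max(1, length - gene_len)))
        end = start + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 7))
        cuts = np.sort(rng.choice(np.arange(1, gene_len), size=2 * n_exons, replace=False))
        exons = [
            (start + int(cuts[2 * j]), start + int(cuts[2 * j + 1]))
            for j in range(n_exons)
            if cuts[2 * j] < cuts[2 * j + 1]
        ]
        genes.append(Gene(chrom, start, end, strand, tuple(exons), name=f"gene{i}"))
    return GeneModel(genes)
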