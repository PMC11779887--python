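"""Pseudo-bulk coverage, normalization, background estimation and
fragment-size distributions.

Counting is fragment-level throughout: a fragment contributes once to every
bin it overlaps, weighted by its duplicate ``count``. Where sequencing reads
are discussed elsewhere, the conversion is 2 reads per fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import CoverageTrack, FragmentSet, GenomeModel, Interval, Peak
from .synth import MAX_FRAGMENT_LENGTH


@dataclass
class SizeHistogram:
    """Fragment-length histogram for one stratum (all / in_peak / off_peak)."""

    bin_edges: np.ndarray  # length n_bins + 1, in bp
    counts: np.ndarray
    stratum: str

    def __post_init__(self) -> None:
        if self.stratum not in ("all", "in_peak", "off_peak"):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if (self.counts < 0).any():
            raise ValueError("negative histogram counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def mass_below(self, length_bp: float) -> float:
        """Fraction of fragments strictly shorter than ``length_bp``."""
        if self.total == 0:
            return 0.0
        frac = np.clip((length_bp - self.bin_edges[:-1]) / np.diff(self.bin_edges), 0, 1)
        return float((self.counts * frac).sum() / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "count": self.counts.astype(int),
            }
        )


@dataclass
class PileupProfile:
    """Mean signal at offsets -window..+window around region centers."""

    offsets: np.ndarray
    values: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets/values length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_signal": self.values})


# ------------------------------------------------------------------ coverage


def aggregate_coverage(
    frags: FragmentSet,
    genome: Optional[GenomeModel] = None,
    barcodes: Optional[Sequence[str]] = None,
    bin_size: int = 1,
    normalization: str = "raw",
) -> CoverageTrack:
    """Pseudo-bulk a fragment set into a coverage track.

    Raw bin value = number of fragments overlapping the bin (weighted by the
    duplicate count). RPKM = raw x 1e9 / (total_fragments x bin_size), the
    per-kilobase-per-million convention at single-bin resolution.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if normalization not in ("raw", "RPKM"):
        raise ValueError(f"unknown normalization {normalization!r}")
    genome = genome or frags.genome
    if genome is None:
        raise ValueError("a genome model is required")

    df = frags.frame
    if barcodes is not None:
        present = set(df["barcode"].unique())
        unknown = [b for b in barcodes if b not in present]
        if unknown:
            warnings.warn(f"{len(unknown)} unknown barcodes ignored", stacklevel=2)
        df = df[df["barcode"].isin(set(barcodes))]

    data: dict[str, np.ndarray] = {}
    total_fragments = int(df["count"].sum()) if len(df) else 0
    for chrom in genome.chrom_names:
        length = genome.length_of(chrom)
        n_bins = -(-length // bin_size)
        diff = np.zeros(n_bins + 1)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            starts = sub["start"].to_numpy() // bin_size
            # a fragment overlaps bins floor(start/b) .. floor((end-1)/b)
            ends = (sub["end"].to_numpy() - 1) // bin_size + 1
            weights = sub["count"].to_numpy().astype(np.float64)
            np.add.at(diff, np.clip(starts, 0, n_bins), weights)
            np.add.at(diff, np.clip(ends, 0, n_bins), -weights)
        data[chrom] = np.cumsum(diff[:-1])

    track = CoverageTrack(
        genome, data, bin_size=bin_size, normalization="raw",
        total_fragments=total_fragments,
    )
    if normalization == "RPKM":
        if total_fragments == 0:
            return CoverageTrack(
                genome, data, bin_size=bin_size, normalization="RPKM", total_fragments=0
            )
        factor = 1e9 / (total_fragments * bin_size)
        return track.scaled(factor, normalization="RPKM")
    return track


def coverage_level_histogram(track: CoverageTrack) -> pd.DataFrame:
    """Percentage of total covered read-bases at each integer coverage level.

    For level c > 0 the percentage is 100 * c * bases_at_level_c divided by
    the total signal; percentages sum to 100 over levels.
    """
    if track.normalization != "raw":
        raise ValueError("coverage_level_histogram requires a raw track")
    levels: dict[int, int] = {}
    for chrom in track.genome.chrom_names:
        for start, end, value in track.runs(chrom):
            c = int(round(value))
            if c > 0:
                levels[c] = levels.get(c, 0) + (end - start)
    if not levels:
        return pd.DataFrame({"level": [], "bases": [], "percentage": []})
    total = sum(c * b for c, b in levels.items())
    rows = sorted(levels.items())
    return pd.DataFrame(
        {
            "level": [c for c, _ in rows],
            "bases": [b for _, b in rows],
            "percentage": [100.0 * c * b / total for c, b in rows],
        }
    )


# ------------------------------------------------------------- off-peak bg


def sample_offpeak_regions(
    genome: GenomeModel,
    exclusion: Sequence[Union[Interval, Peak]],
    n: int = 50_000,
    width: int = 4000,
    seed: int = 0,
) -> list[Interval]:
    """Sample ``n`` fixed-width regions uniformly from outside ``exclusion``.

    Start positions are sampled without replacement (distinct starts) by
    rejection with a deterministic retry cap of 1000 x n; sampled regions may
    overlap each other but never the exclusion set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    # allowed start ranges per chromosome: [0, L - width] minus any start
    # whose window would touch an excluded interval
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    for iv in exclusion:
        if iv.chrom in by_chrom:
            by_chrom[iv.chrom].append((iv.start, iv.end))
    ranges: list[tuple[str, int, int]] = []  # (chrom, start, length of range)
    for chrom in genome.chrom_names:
        limit = genome.length_of(chrom) - width
        if limit < 0:
            continue
        blocked = sorted(by_chrom[chrom])
        cursor = 0
        for ex_start, ex_end in blocked:
            lo = max(0, ex_start - width + 1)
            if lo > cursor:
                ranges.append((chrom, cursor, min(lo, limit + 1) - cursor))
            cursor = max(cursor, ex_end)
            if cursor > limit:
                break
        if cursor <= limit:
            ranges.append((chrom, cursor, limit + 1 - cursor))
    ranges = [r for r in ranges if r[2] > 0]
    total = sum(r[2] for r in ranges)
    if total < n:
        raise ValueError(
            f"cannot place {n} regions of {width} bp: only {total} allowed starts"
        )

    cum = np.cumsum([r[2] for r in ranges])
    chosen: set[int] = set()
    attempts = 0
    cap = 1000 * n
    while len(chosen) < n:
        need = n - len(chosen)
        attempts += need
        if attempts > cap:
            raise ValueError("rejection-sampling retry cap exceeded")
        for v in rng.integers(0, total, size=need):
            chosen.add(int(v))
            if len(chosen) == n:
                break

    out = []
    for v in sorted(chosen):
        ri = int(np.searchsorted(cum, v, side="right"))
        chrom, rstart, _ = ranges[ri]
        offset = v - (int(cum[ri - 1]) if ri else 0)
        out.append(Interval(chrom, rstart + offset, rstart + offset + width))
    return out


def pileup(
    track: CoverageTrack,
    regions: Sequence[Union[Interval, Peak]],
    window: int = 2000,
) -> PileupProfile:
    """Mean signal at each bp offset in -window..+window around region centers.

    Regions whose centers are nearer than ``window`` to a chromosome edge are
    zero-padded.
    """
    if not regions:
        raise ValueError("pileup requires at least one region")
    width = 2 * window + 1
    acc = np.zeros(width)
    b = track.bin_size
    for region in regions:
        arr = track.data[region.chrom]
        center = region.center
        lo, hi = center - window, center + window + 1
        src_lo, src_hi = max(lo, 0), min(hi, track.genome.length_of(region.chrom))
        if src_hi > src_lo:
            positions = np.arange(src_lo, src_hi) // b
            acc[src_lo - lo : src_hi - lo] += arr[positions]
    return PileupProfile(
        offsets=np.arange(-window, window + 1),
        values=acc / len(regions),
        n_regions=len(regions),
    )


# ------------------------------------------------------------- size strata


def fragments_in_peaks_mask(
    frags: FragmentSet, peaks: Sequence[Union[Interval, Peak]]
) -> np.ndarray:
    """Boolean mask: fragment overlaps >= 1 peak by >= 1 bp."""
    mask = np.zeros(len(frags), dtype=bool)
    if not peaks:
        return mask
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.asarray(ms), np.asarray(me))
    df = frags.frame
    for chrom, (ms, me) in merged.items():
        rows = df.index[df["chrom"] == chrom].to_numpy()
        if not len(rows):
            continue
        fs = df.loc[rows, "start"].to_numpy()
        fe = df.loc[rows, "end"].to_numpy()
        # first merged peak whose end is > fragment start
        j = np.searchsorted(me, fs, side="right")
        ok = j < len(ms)
        hit = np.zeros(len(rows), dtype=bool)
        hit[ok] = ms[j[ok]] < fe[ok]
        mask[rows] = hit
    return mask


def fragment_size_distribution(
    frags: FragmentSet,
    peaks: Optional[Sequence[Union[Interval, Peak]]] = None,
    stratum: str = "all",
    bin_width: int = 5,
) -> SizeHistogram:
    """Fragment-length histogram for the requested stratum.

    ``in_peak`` means overlapping >= 1 peak by >= 1 bp; in_peak and off_peak
    partition ``all`` exactly.
    """
    if stratum not in ("all", "in_peak", "off_peak"):
        raise ValueError(f"unknown stratum {stratum!r}")
    if stratum != "all" and peaks is None:
        raise ValueError("peaks are required for in_peak/off_peak strata")
    lengths = frags.lengths()
    if stratum != "all":
        mask = fragments_in_peaks_mask(frags, peaks or [])
        lengths = lengths[mask] if stratum == "in_peak" else lengths[~mask]
    edges = np.arange(0, MAX_FRAGMENT_LENGTH + bin_width + 1, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return SizeHistogram(bin_edges=edges.astype(float), counts=counts, stratum=stratum)
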