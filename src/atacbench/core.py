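"""Shared data structures: genomes, intervals, fragments, peaks, coverage tracks.

All genomic coordinates are 0-based, half-open (the 10x fragments / BED
convention). Chromosome order is always the order declared by the
:class:`GenomeModel`, never lexicographic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of named chromosomes with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths must have equal length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True)
class Interval:
    """A genomic interval, optionally named/scored/stranded (BED6 semantics)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A scored open-chromatin interval.

    ``summit`` is the bp offset of maximal signal relative to ``start``.
    Scores live in [0, 1]; the retention convention downstream is strictly
    greater than 0.5.
    """

    chrom: str
    start: int
    end: int
    score: float = 1.0
    summit: int = 0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid peak {self.chrom}:{self.start}-{self.end}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"peak score {self.score} outside [0, 1]")
        if not (0 <= self.summit < self.end - self.start):
            raise ValueError("summit offset outside peak")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit_position(self) -> int:
        return self.start + self.summit

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.name, self.score)


PeakSet = list  # a PeakSet is a plain list of Peak, ordered


def as_peak(iv: Interval, score: float = 1.0) -> Peak:
    summit = (iv.end - iv.start) // 2
    return Peak(iv.chrom, iv.start, iv.end, score=score, summit=summit, name=iv.name)


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "score": [p.score for p in peaks],
            "summit": [p.summit for p in peaks],
        }
    )


class FragmentSet:
    """Barcoded tagmentation fragments: the pipeline's universal currency.

    Thin wrapper over a pandas DataFrame with columns
    (chrom, start, end, barcode, count). ``count`` is the 10x duplicate
    count; the simulator always emits 1.
    """

    def __init__(self, frame: pd.DataFrame, genome: Optional[GenomeModel] = None):
        missing = [c for c in FRAGMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns {missing}")
        df = frame[FRAGMENT_COLUMNS].reset_index(drop=True)
        if len(df):
            if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
                raise ValueError("fragment with start >= end")
            if (df["start"].to_numpy() < 0).any():
                raise ValueError("fragment with negative start")
            if (df["count"].to_numpy() < 1).any():
                raise ValueError("fragment with count < 1")
        self.frame = df
        self.genome = genome

    @classmethod
    def empty(cls, genome: Optional[GenomeModel] = None) -> "FragmentSet":
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "barcode": pd.Series(dtype=str),
                "count": pd.Series(dtype=np.int64),
            }
        )
        return cls(df, genome=genome)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_fragments(self) -> int:
        """Sum of the duplicate-count column (fragments, not rows)."""
        return int(self.frame["count"].sum()) if len(self.frame) else 0

    def barcodes(self) -> list[str]:
        return sorted(self.frame["barcode"].unique().tolist())

    @property
    def n_barcodes(self) -> int:
        return int(self.frame["barcode"].nunique())

    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def sorted(self) -> "FragmentSet":
        """Canonical order: genome chromosome order (if known), then start, end, barcode."""
        df = self.frame
        if self.genome is not None:
            order = {c: i for i, c in enumerate(self.genome.chrom_names)}
            key = df["chrom"].map(lambda c: order.get(c, len(order)))
        else:
            key = df["chrom"]
        df = df.assign(_k=key).sort_values(
            ["_k", "start", "end", "barcode"], kind="mergesort"
        )
        return FragmentSet(df.drop(columns="_k"), genome=self.genome)

    def subset_barcodes(self, barcodes: Iterable[str]) -> "FragmentSet":
        keep = set(barcodes)
        return FragmentSet(
            self.frame[self.frame["barcode"].isin(keep)], genome=self.genome
        )

    def concat(self, other: "FragmentSet") -> "FragmentSet":
        df = pd.concat([self.frame, other.frame], ignore_index=True)
        return FragmentSet(df, genome=self.genome or other.genome)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return self.sorted().frame.reset_index(drop=True).equals(
            other.sorted().frame.reset_index(drop=True)
        )


class CoverageTrack:
    """Per-base (or binned) coverage over a genome.

    Stored densely per chromosome at ``bin_size`` resolution; exposed as
    non-overlapping sorted runs for bedGraph round-trips. ``normalization``
    is either ``raw`` (fragment counts) or ``RPKM``.
    """

    def __init__(
        self,
        genome: GenomeModel,
        data: Mapping[str, np.ndarray],
        bin_size: int = 1,
        normalization: str = "raw",
        total_fragments: Optional[int] = None,
    ):
        if normalization not in ("raw", "RPKM"):
            raise ValueError(f"unknown normalization {normalization!r}")
        self.genome = genome
        self.bin_size = int(bin_size)
        self.normalization = normalization
        self.total_fragments = total_fragments
        self.data: dict[str, np.ndarray] = {}
        for chrom in genome.chrom_names:
            n_bins = math.ceil(genome.length_of(chrom) / self.bin_size)
            arr = np.asarray(
                data.get(chrom, np.zeros(n_bins)), dtype=np.float64
            )
            if len(arr) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, got {len(arr)}"
                )
            if (arr < 0).any():
                raise ValueError("coverage values must be >= 0")
            self.data[chrom] = arr

    @classmethod
    def zeros(
        cls, genome: GenomeModel, bin_size: int = 1, normalization: str = "raw"
    ) -> "CoverageTrack":
        return cls(genome, {}, bin_size=bin_size, normalization=normalization)

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at a bp position (constant within a bin)."""
        arr = self.data[chrom]
        idx = pos // self.bin_size
        if idx < 0 or idx >= len(arr):
            return 0.0
        return float(arr[idx])

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        """Maximal constant-value runs in bp coordinates (zero runs included)."""
        arr = self.data[chrom]
        if len(arr) == 0:
            return []
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        length = self.genome.length_of(chrom)
        out = []
        for s, e in zip(starts, ends):
            out.append(
                (int(s * self.bin_size), min(int(e * self.bin_size), length), float(arr[s]))
            )
        return out

    def total_signal(self) -> float:
        """Sum of value x bp-width over the whole genome."""
        total = 0.0
        for chrom in self.genome.chrom_names:
            length = self.genome.length_of(chrom)
            arr = self.data[chrom]
            widths = np.full(len(arr), self.bin_size, dtype=np.float64)
            if len(arr) and len(arr) * self.bin_size > length:
                widths[-1] = length - (len(arr) - 1) * self.bin_size
            total += float(np.dot(arr, widths))
        return total

    def scaled(self, factor: float, normalization: Optional[str] = None) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            {c: a * factor for c, a in self.data.items()},
            bin_size=self.bin_size,
            normalization=normalization or self.normalization,
            total_fragments=self.total_fragments,
        )

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if self.bin_size != other.bin_size:
            raise ValueError("bin sizes differ")
        return CoverageTrack(
            self.genome,
            {c: self.data[c] + other.data[c] for c in self.data},
            bin_size=self.bin_size,
            normalization=self.normalization,
        )


def iter_chrom_groups(frame: pd.DataFrame) -> Iterator[tuple[str, pd.DataFrame]]:
    for chrom, grp in frame.groupby("chrom", sort=False):
        yield str(chrom), grp
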