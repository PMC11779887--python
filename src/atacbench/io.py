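"""Readers and writers for the plain-text formats the pipeline touches.

One strict dialect per format: 10x-style 5-column fragments TSV (optionally
gzipped), BED3/BED6, bedGraph, 2-column barcode tables, and MTX sparse-matrix
export with row/column sidecars. No UCSC track lines or browser headers;
lines starting with ``#`` are ignored everywhere. Readers report malformed
lines with their line number; writers emit files their readers accept.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import FragmentSet, GenomeModel, Interval

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _data_lines(path: PathLike):
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------- fragments


def read_fragments(path: PathLike, genome: Optional[GenomeModel] = None) -> FragmentSet:
    """Read a 5-column fragments TSV (chrom, start, end, barcode, count)."""
    chroms, starts, ends, barcodes, counts = [], [], [], [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(path, lineno, f"expected 5 columns, got {len(fields)}")
        chrom, start_s, end_s, barcode, count_s = fields
        try:
            start, end, count = int(start_s), int(end_s), int(count_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinate or count") from None
        if start < 0 or start >= end:
            raise ParseError(path, lineno, f"invalid interval {start}-{end}")
        if count < 1:
            raise ParseError(path, lineno, f"count {count} < 1")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        barcodes.append(barcode)
        counts.append(count)
    frame = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
            "barcode": pd.Series(barcodes, dtype=str),
            "count": pd.Series(counts, dtype=np.int64),
        }
    )
    return FragmentSet(frame, genome=genome)


def write_fragments(frags: FragmentSet, path: PathLike) -> None:
    """Write fragments in canonical (sorted) order."""
    df = frags.sorted().frame
    with _open_text(path, "wt") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.barcode}\t{row.count}\n")


# ---------------------------------------------------------------------- BED


def read_bed(path: PathLike) -> list[Interval]:
    """Read BED3 or BED6 intervals."""
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (3, 6):
            raise ParseError(path, lineno, f"expected 3 or 6 columns, got {len(fields)}")
        chrom, start_s, end_s = fields[:3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        name = score = strand = None
        if len(fields) == 6:
            name = fields[3]
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
            strand = fields[5]
            if strand not in ("+", "-", "."):
                raise ParseError(path, lineno, f"invalid strand {strand!r}")
        try:
            out.append(Interval(chrom, start, end, name=name, score=score, strand=strand))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def write_bed(
    intervals: Sequence[Interval], path: PathLike, genome: Optional[GenomeModel] = None
) -> None:
    """Write BED6 when any interval carries name/score/strand, else BED3."""
    ivs = list(intervals)
    if genome is not None:
        order = {c: i for i, c in enumerate(genome.chrom_names)}
        ivs.sort(key=lambda iv: (order.get(iv.chrom, len(order)), iv.start, iv.end))
    bed6 = any(iv.name is not None or iv.score is not None or iv.strand is not None for iv in ivs)
    with _open_text(path, "wt") as fh:
        for iv in ivs:
            if bed6:
                name = iv.name if iv.name is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "0"
                strand = iv.strand if iv.strand is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ----------------------------------------------------------------- bedGraph


def read_bedgraph(path: PathLike) -> dict[str, list[tuple[int, int, float]]]:
    """Read bedGraph runs per chromosome; rejects overlapping runs.

    Adjacent runs with equal value are merged (canonical form).
    """
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        chrom, start_s, end_s, value_s = fields
        try:
            start, end, value = int(start_s), int(end_s), float(value_s)
        except ValueError:
            raise ParseError(path, lineno, "malformed run") from None
        if start < 0 or start >= end:
            raise ParseError(path, lineno, f"invalid run {start}-{end}")
        runs.setdefault(chrom, []).append((start, end, value))
    out = {}
    for chrom, rr in runs.items():
        rr.sort(key=lambda r: r[0])
        merged: list[tuple[int, int, float]] = []
        for s, e, v in rr:
            if merged and s < merged[-1][1]:
                raise ParseError(path, 0, f"overlapping bedGraph runs on {chrom}")
            if merged and s == merged[-1][1] and v == merged[-1][2]:
                merged[-1] = (merged[-1][0], e, v)
            else:
                merged.append((s, e, v))
        out[chrom] = merged
    return out


def write_bedgraph(
    runs_by_chrom: dict[str, list[tuple[int, int, float]]],
    path: PathLike,
    genome: Optional[GenomeModel] = None,
    skip_zero: bool = True,
) -> None:
    """Write canonical bedGraph (adjacent equal-value runs merged)."""
    chrom_order = (
        [c for c in genome.chrom_names if c in runs_by_chrom]
        if genome is not None
        else list(runs_by_chrom)
    )
    with _open_text(path, "wt") as fh:
        for chrom in chrom_order:
            merged: list[tuple[int, int, float]] = []
            for s, e, v in sorted(runs_by_chrom[chrom]):
                if merged and s == merged[-1][1] and v == merged[-1][2]:
                    merged[-1] = (merged[-1][0], e, v)
                else:
                    merged.append((s, e, v))
            for s, e, v in merged:
                if skip_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def track_to_bedgraph(track, path: PathLike, skip_zero: bool = True) -> None:
    runs = {c: track.runs(c) for c in track.genome.chrom_names}
    write_bedgraph(runs, path, genome=track.genome, skip_zero=skip_zero)


def read_bedgraph_track(
    path: PathLike, genome: GenomeModel, normalization: str = "raw"
):
    """Load a bedGraph into a per-bp CoverageTrack over the given genome."""
    from .core import CoverageTrack

    runs = read_bedgraph(path)
    data = {}
    for chrom in genome.chrom_names:
        arr = np.zeros(genome.length_of(chrom))
        for start, end, value in runs.get(chrom, []):
            arr[start : min(end, len(arr))] = value
        data[chrom] = arr
    return CoverageTrack(genome, data, bin_size=1, normalization=normalization)


def read_chrom_sizes(path: PathLike) -> GenomeModel:
    """Read a 2-column (chrom, length) TSV into a GenomeModel."""
    names, lengths = [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        names.append(fields[0])
        try:
            lengths.append(int(fields[1]))
        except ValueError:
            raise ParseError(path, lineno, "non-integer length") from None
    return GenomeModel(tuple(names), tuple(lengths))


# ------------------------------------------------------- tables and exports


def read_barcode_table(path: PathLike) -> dict[str, str]:
    """Read a 2-column (barcode, label) TSV."""
    out = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        out[fields[0]] = fields[1]
    return out


def write_barcode_table(table: dict[str, str], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for barcode in sorted(table):
            fh.write(f"{barcode}\t{table[barcode]}\n")


def write_mtx(
    matrix: scipy.sparse.spmatrix,
    row_names: Sequence[str],
    col_names: Sequence[str],
    prefix: PathLike,
) -> None:
    """Write an MTX file plus ``.rows.txt`` / ``.cols.txt`` name sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), matrix)
    prefix.with_suffix(".rows.txt").write_text("\n".join(row_names) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(col_names) + "\n")


def write_manifest(manifest: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
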