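"""Readers and writers for the text formats the pipeline consumes and emits.

Supported formats: UCSC two-column chrom.sizes, BED3/BED4, bedGraph, and TSV
result tables. All readers and writers are gzip-transparent (a ``.gz``
suffix triggers compression). Coordinates are 0-based half-open throughout,
including bedGraph input. bigWig inputs are supported by prior conversion to
bedGraph (e.g. ``bigWigToBedGraph``); no binary format is read or written here.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterable, Literal, Union

import numpy as np
import pandas as pd

from .errors import CoordinateError, FormatError
from .genome import BinGrid, GenomeLayout
from .intervals import IntervalSet
from .tracks import BinnedTrack

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "read_bedgraph_track",
    "read_read_positions",
    "read_gene_table",
    "write_bedgraph",
    "write_bed",
    "write_table",
]


def _open(path: PathLike, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# readers


def read_chrom_sizes(path: PathLike) -> GenomeLayout:
    """Parse a UCSC two-column name/length table into a :class:`GenomeLayout`.

    Chromosome order in the file is preserved and defines genome-wide bin
    ordering. Duplicate names, non-integer or non-positive lengths are
    rejected.
    """
    pairs: list[tuple[str, int]] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r} for {name!r}"
                ) from None
            if length < 1:
                raise FormatError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            pairs.append((name, length))
    if not pairs:
        raise FormatError(f"{path}: empty chrom.sizes file")
    return GenomeLayout.from_pairs(pairs)


def _read_bed_frame(path: PathLike, min_cols: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str},
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=range(min_cols))
    if df.shape[1] < min_cols:
        raise FormatError(f"{path}: expected >= {min_cols} tab-separated columns")
    return df


UnknownChromPolicy = Literal["skip", "error"]


def _apply_unknown_policy(
    df: pd.DataFrame, layout: GenomeLayout, policy: UnknownChromPolicy, path: PathLike
) -> pd.DataFrame:
    known = df[0].isin(layout.names)
    if known.all():
        return df
    unknown = sorted(df.loc[~known, 0].unique())
    if policy == "error":
        raise CoordinateError(f"{path}: unknown chromosome(s): {', '.join(map(str, unknown))}")
    logger.warning(
        "%s: skipping %d record(s) on unknown chromosome(s): %s",
        path,
        int((~known).sum()),
        ", ".join(map(str, unknown)),
    )
    return df[known]


def read_bed(
    path: PathLike,
    layout: GenomeLayout | None = None,
    unknown_chrom: UnknownChromPolicy = "skip",
) -> IntervalSet:
    """Read BED3/BED4 intervals; the name column is kept when present."""
    df = _read_bed_frame(path, 3)
    if len(df) == 0:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
    if layout is not None:
        df = _apply_unknown_policy(df, layout, unknown_chrom, path)
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
            "name": df[3] if df.shape[1] > 3 else None,
        }
    )
    ivals = IntervalSet(out)
    if layout is not None:
        ivals.check_layout(layout)
    return ivals


def read_bedgraph_track(
    path: PathLike,
    grid: BinGrid,
    unknown_chrom: UnknownChromPolicy = "skip",
) -> BinnedTrack:
    """Reduce a bedGraph file onto ``grid``.

    Each grid bin receives the coverage-weighted mean of all bedGraph
    intervals overlapping it (weights are overlap lengths in bases); bins
    touched by no interval are invalid. Intervals extending beyond their
    chromosome end raise; unknown chromosomes are skipped with a warning by
    default (``unknown_chrom='error'`` to reject).
    """
    df = _read_bed_frame(path, 4)
    wsum = np.zeros(grid.total_bins)
    vsum = np.zeros(grid.total_bins)
    if len(df):
        df = _apply_unknown_policy(df, grid.layout, unknown_chrom, path)
    if len(df):
        chroms = df[0].to_numpy(dtype=str)
        starts = df[1].to_numpy(dtype=np.int64)
        ends = df[2].to_numpy(dtype=np.int64)
        values = df[3].to_numpy(dtype=float)
        if (starts < 0).any() or (starts >= ends).any():
            raise FormatError(f"{path}: malformed bedGraph interval (start >= end or negative)")
        bs = grid.bin_size
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            length = grid.layout.length_of(chrom)
            s, e, v = starts[sel], ends[sel], values[sel]
            if e.max() > length:
                raise CoordinateError(
                    f"{path}: interval beyond {chrom!r} end ({e.max()} > {length})"
                )
            off = grid.chrom_offset(chrom)
            lo = s // bs
            hi = (e - 1) // bs  # last bin touched
            single = lo == hi
            # fast path: interval within one bin
            np.add.at(wsum, off + lo[single], (e - s)[single].astype(float))
            np.add.at(vsum, off + lo[single], ((e - s)[single] * v[single]).astype(float))
            # general path: spread across bins
            for si, ei, vi, li, hi_ in zip(s[~single], e[~single], v[~single], lo[~single], hi[~single]):
                edges = np.arange(li, hi_ + 2, dtype=np.int64) * bs
                edges[0] = si
                edges[-1] = ei
                w = np.diff(edges).astype(float)
                idx = off + np.arange(li, hi_ + 1)
                wsum[idx] += w
                vsum[idx] += w * vi
    valid = wsum > 0
    out = np.full(grid.total_bins, np.nan)
    out[valid] = vsum[valid] / wsum[valid]
    return BinnedTrack(grid, out, valid)


def read_read_positions(path: PathLike, layout: GenomeLayout | None = None,
                        unknown_chrom: UnknownChromPolicy = "skip") -> tuple[np.ndarray, np.ndarray]:
    """Read single-position reads from BED3 (the start coordinate is used).

    Returns (chromosome array, position array).
    """
    df = _read_bed_frame(path, 3)
    if len(df) == 0:
        return np.array([], dtype=str), np.array([], dtype=np.int64)
    if layout is not None:
        df = _apply_unknown_policy(df, layout, unknown_chrom, path)
    return df[0].to_numpy(dtype=str), df[1].to_numpy(dtype=np.int64)


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "fold_change", "padj", "rpkm"]


def read_gene_table(path: PathLike) -> pd.DataFrame:
    """Read a gene expression TSV with the documented header.

    Required columns: gene_id, chrom, start, end, fold_change (linear scale
    unless declared otherwise downstream), padj, rpkm.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene table missing column(s): {', '.join(missing)}")
    if (df["rpkm"] < 0).any():
        raise FormatError(f"{path}: negative rpkm values")
    return df


# ---------------------------------------------------------------------------
# writers


def write_bedgraph(track: BinnedTrack, path: PathLike, precision: int = 12) -> None:
    """Write one bedGraph line per valid bin (values at 12 significant digits,
    so a read/write round trip reproduces the track)."""
    grid = track.grid
    with _open(path, "wt") as fh:
        for chrom, sl in grid.iter_chromosomes():
            vals = track.values[sl]
            ok = track.valid[sl]
            length = grid.layout.length_of(chrom)
            bs = grid.bin_size
            for k in np.flatnonzero(ok):
                start = int(k) * bs
                end = min(start + bs, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[k]:.{precision}g}\n")


def write_bed(intervals: Iterable[tuple], path: PathLike) -> None:
    """Write (chrom, start, end[, name]) tuples as BED."""
    with _open(path, "wt") as fh:
        for rec in intervals:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            name = rec[3] if len(rec) > 3 and rec[3] is not None else None
            if name is None:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_table(frame: pd.DataFrame, path: PathLike) -> None:
    """Write a result table as TSV with header."""
    frame.to_csv(path, sep="\t", index=False)
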