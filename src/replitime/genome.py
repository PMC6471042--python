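"""Genome coordinate model: chromosome layouts and fixed-width bin grids.

All coordinates are 0-based, half-open (BED convention). A :class:`BinGrid`
tiles each chromosome with ``[k*size, (k+1)*size)`` windows, truncating the
last window at the chromosome end, and assigns every bin a *global index* so
genome-wide tracks can live in flat numpy arrays. Chromosome order in the
layout is stable and defines the global bin ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator

import numpy as np

from .errors import CoordinateError, FormatError

__all__ = ["GenomeLayout", "BinGrid"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered list of (chromosome name, length in bases)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicated chromosome name(s): {', '.join(dupes)}")
        for name, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or isinstance(length, bool):
                raise FormatError(f"chromosome {name!r}: length must be an integer, got {length!r}")
            if length < 1:
                raise FormatError(f"chromosome {name!r}: length must be >= 1, got {length}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeLayout":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @cached_property
    def _index(self) -> dict[str, int]:
        return {name: i for i, (name, _) in enumerate(self.chromosomes)}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def length_of(self, name: str) -> int:
        try:
            return self.chromosomes[self._index[name]][1]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {name!r}") from None

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chromosomes)


class BinGrid:
    """Fixed-width bin grid over a :class:`GenomeLayout`.

    Bins are 0-based half-open ``[k*bin_size, (k+1)*bin_size)`` per
    chromosome; the last bin of each chromosome is truncated at the
    chromosome end. Every genomic position maps to exactly one bin.
    """

    def __init__(self, layout: GenomeLayout, bin_size: int):
        if bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {bin_size}")
        self.layout = layout
        self.bin_size = int(bin_size)
        counts = [-(-length // self.bin_size) for _, length in layout]  # ceil div
        self._n_bins = dict(zip(layout.names, counts))
        offsets = np.concatenate([[0], np.cumsum(counts)])
        self._offsets = {name: int(offsets[i]) for i, name in enumerate(layout.names)}
        self.total_bins = int(offsets[-1])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinGrid)
            and other.layout == self.layout
            and other.bin_size == self.bin_size
        )

    def __repr__(self) -> str:
        return f"BinGrid({self.layout.n_chromosomes} chromosomes, bin_size={self.bin_size}, total_bins={self.total_bins})"

    def n_bins(self, chrom: str) -> int:
        try:
            return self._n_bins[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def chrom_offset(self, chrom: str) -> int:
        try:
            return self._offsets[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offset(chrom)
        return slice(off, off + self.n_bins(chrom))

    def bin_index(self, chrom: str, position: int) -> int:
        """Global bin index containing ``position`` on ``chrom``."""
        length = self.layout.length_of(chrom)
        if not 0 <= position < length:
            raise CoordinateError(f"position {position} outside {chrom!r} [0, {length})")
        return self.chrom_offset(chrom) + position // self.bin_size

    def bin_indices(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`bin_index` for an array of positions."""
        positions = np.asarray(positions, dtype=np.int64)
        length = self.layout.length_of(chrom)
        if positions.size and (positions.min() < 0 or positions.max() >= length):
            bad = positions[(positions < 0) | (positions >= length)][0]
            raise CoordinateError(f"position {bad} outside {chrom!r} [0, {length})")
        return self.chrom_offset(chrom) + positions // self.bin_size

    def bin_bounds(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the bin with the given global index."""
        if not 0 <= index < self.total_bins:
            raise IndexError(f"bin index {index} out of range [0, {self.total_bins})")
        for name, length in self.layout:
            off = self._offsets[name]
            if index < off + self._n_bins[name]:
                k = index - off
                start = k * self.bin_size
                return name, start, min(start + self.bin_size, length)
        raise AssertionError("unreachable")

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def bin_centers(self, chrom: str) -> np.ndarray:
        """Bin midpoints (nominal, ignoring last-bin truncation)."""
        return self.bin_starts(chrom) + self.bin_size / 2.0

    def overlapping_bins(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open global index range of bins overlapping [start, end)."""
        if not 0 <= start < end:
            raise CoordinateError(f"invalid interval [{start}, {end})")
        length = self.layout.length_of(chrom)
        if end > length:
            raise CoordinateError(f"interval [{start}, {end}) beyond {chrom!r} end ({length})")
        off = self.chrom_offset(chrom)
        lo = start // self.bin_size
        hi = (end - 1) // self.bin_size + 1
        return off + lo, off + hi

    def iter_chromosomes(self) -> Iterator[tuple[str, slice]]:
        for name, _ in self.layout:
            yield name, self.chrom_slice(name)
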