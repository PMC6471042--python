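"""Binned genome-wide tracks with validity masks.

A :class:`BinnedTrack` holds one real value per bin of a :class:`~replitime.genome.BinGrid`
plus a boolean mask; invalid bins carry no information and every downstream
statistic ignores them. :class:`RTProfile` is the same container specialised
to log2 early/late replication-timing values (conventionally on a 50 kb grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid

__all__ = ["BinnedTrack", "RTProfile"]


@dataclass
class BinnedTrack:
    grid: BinGrid
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.grid.total_bins
        if self.values.shape != (n,):
            raise ValueError(f"values shape {self.values.shape} != ({n},) for this grid")
        if self.valid.shape != (n,):
            raise ValueError(f"valid shape {self.valid.shape} != ({n},) for this grid")

    @classmethod
    def zeros(cls, grid: BinGrid, valid: bool = True):
        return cls(grid, np.zeros(grid.total_bins), np.full(grid.total_bins, valid))

    @classmethod
    def from_values(cls, grid: BinGrid, values: np.ndarray, valid: np.ndarray | None = None):
        if valid is None:
            valid = np.isfinite(np.asarray(values, dtype=float))
        return cls(grid, np.array(values, dtype=float), np.array(valid, dtype=bool))

    def copy(self):
        return type(self)(self.grid, self.values.copy(), self.valid.copy())

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.grid.chrom_slice(chrom)]

    def chrom_valid(self, chrom: str) -> np.ndarray:
        return self.valid[self.grid.chrom_slice(chrom)]


@dataclass
class RTProfile(BinnedTrack):
    """Per-bin log2 early/late replication timing with a missing-data mask."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(~np.isfinite(self.values[self.valid])):
            raise ValueError("RTProfile must be finite wherever valid")

    @property
    def rt(self) -> np.ndarray:
        return self.values

    def as_track(self) -> BinnedTrack:
        return BinnedTrack(self.grid, self.values.copy(), self.valid.copy())
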