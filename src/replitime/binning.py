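"""First pipeline stage: per-fraction read counting, spike filtering, and
aggregation from 1 kb to the 50 kb analysis resolution.

Nascent-DNA reads from each S-phase fraction are counted into 1 kb windows,
windows with signal spikes (one-sided Z score above 2.5 over currently valid
bins, genome-wide by default) are masked, and surviving windows are summed
into 50 kb bins. A 50 kb bin is kept only when at least half of its 1 kb
children survived the spike filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ReplitimeError
from .genome import BinGrid
from .tracks import BinnedTrack

__all__ = ["FractionCounts", "bin_reads", "filter_spikes", "aggregate_bins"]

DEFAULT_READ_BIN_SIZE = 1_000
DEFAULT_ANALYSIS_BIN_SIZE = 50_000
DEFAULT_SPIKE_Z = 2.5
DEFAULT_MIN_VALID_FRACTION = 0.5


@dataclass
class FractionCounts:
    """Read counts for one S-phase fraction (e.g. S1–S4, or a release
    timepoint such as "4h") on a shared bin grid."""

    label: str
    track: BinnedTrack

    def __post_init__(self) -> None:
        vals = self.track.values[self.track.valid]
        if vals.size and vals.min() < 0:
            raise ValueError(f"fraction {self.label!r}: negative counts")

    @property
    def grid(self) -> BinGrid:
        return self.track.grid

    def copy(self) -> "FractionCounts":
        return FractionCounts(self.label, self.track.copy())


def bin_reads(
    chroms: Sequence[str] | np.ndarray,
    positions: Sequence[int] | np.ndarray,
    grid: BinGrid,
    label: str = "reads",
) -> FractionCounts:
    """Count reads into grid bins by their (0-based) alignment start.

    Each bin's value is the number of reads whose position falls in it
    (half-open bin membership); all bins are valid. Positions at or beyond
    the chromosome end raise.
    """
    chroms = np.asarray(chroms, dtype=str)
    positions = np.asarray(positions, dtype=np.int64)
    if chroms.shape != positions.shape:
        raise ValueError("chroms and positions must have the same length")
    counts = np.zeros(grid.total_bins)
    for chrom in np.unique(chroms) if chroms.size else []:
        idx = grid.bin_indices(chrom, positions[chroms == chrom])
        counts += np.bincount(idx, minlength=grid.total_bins)
    track = BinnedTrack(grid, counts, np.ones(grid.total_bins, dtype=bool))
    return FractionCounts(label, track)


def filter_spikes(
    counts: FractionCounts,
    z_threshold: float = DEFAULT_SPIKE_Z,
    per_chromosome: bool = False,
    stats: tuple[float, float] | None = None,
) -> FractionCounts:
    """Mask bins with signal spikes: count Z score above ``z_threshold``.

    The test is one-sided (high outliers only — low bins are the province of
    mappability masking), with mean and sd taken over all currently valid
    bins, genome-wide by default or per chromosome. If the sd is zero no bin
    is removed. ``stats`` optionally pins (mean, sd) instead of estimating
    them, which makes the filter idempotent at fixed statistics.
    """
    out = counts.copy()
    track = out.track

    def _apply(sel: np.ndarray) -> None:
        vals = track.values[sel]
        ok = track.valid[sel]
        if stats is not None:
            mean, sd = stats
        else:
            live = vals[ok]
            if live.size == 0:
                return
            mean = float(live.mean())
            sd = float(live.std())  # population sd over valid bins
        if sd == 0:
            return
        z = (vals - mean) / sd
        new_valid = ok & ~(z > z_threshold)
        track.valid[sel] = new_valid

    if per_chromosome:
        for _, sl in track.grid.iter_chromosomes():
            idx = np.zeros(track.grid.total_bins, dtype=bool)
            idx[sl] = True
            _apply(idx)
    else:
        _apply(np.ones(track.grid.total_bins, dtype=bool))
    return out


def aggregate_bins(
    counts: FractionCounts,
    target_size: int = DEFAULT_ANALYSIS_BIN_SIZE,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> FractionCounts:
    """Sum counts from small bins into ``target_size`` bins.

    ``target_size`` must be an integer multiple of the source bin size. Each
    target bin's value is the sum over its *valid* children; the bin is
    marked invalid when fewer than ``min_valid_fraction`` of its existing
    children are valid. With no invalid children, total reads are conserved.
    """
    src = counts.grid
    if target_size % src.bin_size != 0 or target_size < src.bin_size:
        raise ReplitimeError(
            f"target size {target_size} is not a multiple of source bin size {src.bin_size}"
        )
    factor = target_size // src.bin_size
    dst = BinGrid(src.layout, target_size)
    sums = np.zeros(dst.total_bins)
    frac_valid = np.zeros(dst.total_bins)
    for chrom, sl in src.iter_chromosomes():
        vals = counts.track.values[sl]
        ok = counts.track.valid[sl].astype(float)
        parent = np.arange(vals.size) // factor
        n_parent = dst.n_bins(chrom)
        child_total = np.bincount(parent, minlength=n_parent)
        child_valid = np.bincount(parent, weights=ok, minlength=n_parent)
        off = dst.chrom_offset(chrom)
        sums[off : off + n_parent] = np.bincount(parent, weights=vals * ok, minlength=n_parent)
        frac_valid[off : off + n_parent] = child_valid / child_total
    valid = frac_valid >= min_valid_fraction
    return FractionCounts(counts.label, BinnedTrack(dst, sums, valid))
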