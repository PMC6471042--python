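"""TAD boundary extraction, cohesin-dependence classification, and RT metaplots.

Contact-domain interval lists (control and cohesin-depleted Hi-C) are turned
into boundary point sets. Each control boundary is classed, in order of
precedence: *compartment_proximal* if an A/B compartment boundary lies
within a tolerance (500 kb default) on the same chromosome — these are set
aside to control for compartment status; otherwise *invariant* if a treated
boundary lies within tolerance; otherwise *scc1_dependent*. Metaplots
average an RT profile over windows flanking each boundary of a class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import CoordinateError, ReplitimeError
from .genome import GenomeLayout
from .intervals import IntervalSet
from .tracks import RTProfile

__all__ = [
    "BoundarySet",
    "Metaplot",
    "extract_boundaries",
    "classify_boundaries",
    "boundary_metaplot",
    "COMPARTMENT_PROXIMAL",
    "INVARIANT",
    "SCC1_DEPENDENT",
    "BOUNDARY_CLASSES",
]

COMPARTMENT_PROXIMAL = "compartment_proximal"
INVARIANT = "invariant"
SCC1_DEPENDENT = "scc1_dependent"
BOUNDARY_CLASSES = (COMPARTMENT_PROXIMAL, INVARIANT, SCC1_DEPENDENT)

DEFAULT_TOLERANCE = 500_000
DEFAULT_FLANK = 5_000_000


@dataclass
class BoundarySet:
    """Per-chromosome sorted unique boundary positions with provenance.

    ``classes`` (optional) assigns each position one of the three
    cohesin-dependence classes, aligned with ``positions``.
    """

    positions: dict[str, np.ndarray]
    label: str = ""
    classes: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size != np.unique(arr).size or np.any(np.diff(arr) < 0):
                raise ReplitimeError(f"{chrom}: boundary positions must be sorted and unique")
            clean[chrom] = arr
        self.positions = clean
        if self.classes is not None:
            for chrom, cls in self.classes.items():
                if len(cls) != len(self.positions.get(chrom, ())):
                    raise ReplitimeError(f"{chrom}: classes not aligned with positions")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int]], label: str = ""
    ) -> "BoundarySet":
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in records:
            by_chrom.setdefault(str(chrom), []).append(int(pos))
        return cls(
            {c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()},
            label=label,
        )

    def check_layout(self, layout: GenomeLayout) -> None:
        for chrom, pos in self.positions.items():
            length = layout.length_of(chrom)
            if pos.size and (pos.min() < 0 or pos.max() > length):
                raise CoordinateError(f"{chrom}: boundary position outside [0, {length}]")

    @property
    def n_boundaries(self) -> int:
        return sum(p.size for p in self.positions.values())

    def class_counts(self) -> Counter:
        if self.classes is None:
            raise ReplitimeError("boundary set has no classes assigned")
        counts: Counter = Counter()
        for cls in self.classes.values():
            counts.update(cls.tolist())
        return counts

    def subset_by_class(self, wanted: str) -> "BoundarySet":
        if self.classes is None:
            raise ReplitimeError("boundary set has no classes assigned")
        positions = {}
        for chrom, pos in self.positions.items():
            keep = self.classes[chrom] == wanted
            if keep.any():
                positions[chrom] = pos[keep]
        return BoundarySet(positions, label=f"{self.label}:{wanted}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, pos in self.positions.items():
            cls = self.classes[chrom] if self.classes is not None else [None] * pos.size
            for p, c in zip(pos, cls):
                rows.append((chrom, int(p), c))
        return pd.DataFrame(rows, columns=["chrom", "position", "class"])

    def to_bed_records(self) -> list[tuple]:
        """One 1-bp BED record per boundary, class in the name column."""
        return [
            (row.chrom, row.position, row.position + 1, row[2])
            for row in self.to_frame().itertuples(index=False)
        ]


def extract_boundaries(domains: IntervalSet, label: str = "") -> BoundarySet:
    """Boundary positions = deduplicated starts and ends of domain intervals."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, start, end, _ in domains:
        by_chrom.setdefault(chrom, []).extend((start, end))
    return BoundarySet(
        {c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()},
        label=label,
    )


def _min_distance(pos: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Distance from each of ``pos`` to the nearest of ``others`` (inf if none)."""
    if others.size == 0:
        return np.full(pos.shape, np.inf)
    j = np.searchsorted(others, pos)
    left = np.where(j > 0, np.abs(pos - others[np.maximum(j - 1, 0)]), np.inf)
    right = np.where(j < others.size, np.abs(others[np.minimum(j, others.size - 1)] - pos), np.inf)
    return np.minimum(left, right)


def classify_boundaries(
    control: BoundarySet,
    treated: BoundarySet,
    compartments: BoundarySet,
    tolerance: int = DEFAULT_TOLERANCE,
) -> tuple[BoundarySet, Counter]:
    """Assign each control boundary exactly one cohesin-dependence class.

    Precedence: compartment_proximal (a compartment boundary within
    ``tolerance``, inclusive, same chromosome), else invariant (a treated
    boundary within tolerance), else scc1_dependent. The class counts
    partition the control set. Distances are absolute point-to-point.
    """
    classes: dict[str, np.ndarray] = {}
    counts: Counter = Counter()
    for chrom, pos in control.positions.items():
        comp = compartments.positions.get(chrom, np.array([], dtype=np.int64))
        trt = treated.positions.get(chrom, np.array([], dtype=np.int64))
        cls = np.full(pos.size, SCC1_DEPENDENT, dtype=object)
        near_comp = _min_distance(pos, comp) <= tolerance
        near_trt = _min_distance(pos, trt) <= tolerance
        cls[near_trt] = INVARIANT
        cls[near_comp] = COMPARTMENT_PROXIMAL  # compartment takes precedence
        classes[chrom] = cls
        counts.update(cls.tolist())
    out = BoundarySet(dict(control.positions), label=control.label, classes=classes)
    return out, counts


@dataclass
class Metaplot:
    """Per-offset mean RT around a set of aligned boundaries.

    Offsets run from -flank to +flank in profile-resolution steps, symmetric
    about 0 (offset 0 is the bin containing the boundary); ``count`` is the
    number of boundaries contributing a value at each offset.
    """

    offsets: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    n_boundaries: int

    def mean_step(self, max_offset: int | None = None) -> float:
        """|mean over negative offsets - mean over positive offsets| of the
        averaged profile; a sharp RT transition at the boundary gives a large
        step. ``max_offset`` restricts the comparison to offsets within that
        distance of the boundary — the step is a local feature, and flanks
        far from the boundary average over unrelated domains.
        """
        sel = np.ones(self.offsets.size, dtype=bool)
        if max_offset is not None:
            sel = np.abs(self.offsets) <= max_offset
        left = self.mean[sel & (self.offsets < 0) & ~np.isnan(self.mean)]
        right = self.mean[sel & (self.offsets > 0) & ~np.isnan(self.mean)]
        if left.size == 0 or right.size == 0:
            return float("nan")
        return float(abs(left.mean() - right.mean()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_rt": self.mean, "n": self.count})


def boundary_metaplot(
    profile: RTProfile,
    boundaries: BoundarySet,
    flank: int = DEFAULT_FLANK,
    orient: str = "rt-slope",
) -> Metaplot:
    """Average an RT profile over ±``flank`` windows around each boundary.

    Missing bins are skipped; windows extending past chromosome ends are
    truncated, not dropped. With ``orient='rt-slope'`` each window is flipped
    so its higher-mean-RT side lies at negative offsets before averaging (so
    opposing domain transitions do not cancel); ``orient='none'`` keeps the
    genomic orientation.
    """
    if orient not in ("rt-slope", "none"):
        raise ReplitimeError(f"unknown orientation policy {orient!r}")
    grid = profile.grid
    n_off = flank // grid.bin_size
    offsets = np.arange(-n_off, n_off + 1, dtype=np.int64) * grid.bin_size
    width = offsets.size
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    n_b = 0
    for chrom, pos_list in boundaries.positions.items():
        if chrom not in grid.layout:
            continue
        sl = grid.chrom_slice(chrom)
        vals = np.where(profile.valid[sl], profile.values[sl], np.nan)
        n_bins = sl.stop - sl.start
        for pos in pos_list:
            center = int(pos) // grid.bin_size
            if center >= n_bins:  # boundary at the chromosome end coordinate
                center = n_bins - 1
            window = np.full(width, np.nan)
            lo = max(center - n_off, 0)
            hi = min(center + n_off + 1, n_bins)
            window[lo - (center - n_off) : hi - (center - n_off)] = vals[lo:hi]
            if orient == "rt-slope":
                left = window[:n_off][~np.isnan(window[:n_off])]
                right = window[n_off + 1 :][~np.isnan(window[n_off + 1 :])]
                if left.size and right.size and left.mean() < right.mean():
                    window = window[::-1]
            got = ~np.isnan(window)
            total[got] += window[got]
            count += got
            n_b += 1
    mean = np.full(width, np.nan)
    mean[count > 0] = total[count > 0] / count[count > 0]
    return Metaplot(offsets=offsets, mean=mean, count=count, n_boundaries=n_b)
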