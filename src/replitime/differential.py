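"""Differential replication timing between a control and a treated profile.

Per mappable bin valid in both profiles, the difference
``d = rt_control - rt_treated`` is standardised into a Z score, converted to
a two-sided normal p-value, and Benjamini–Hochberg adjusted; bins with
adjusted p below alpha are called significantly changed. Helpers summarise
the dispersion of significant bins (median inter-bin distance), intersect
significant sets between experiments with direction concordance, and
stratify Z scores by TAD-boundary overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .boundaries import BoundarySet
from .errors import ReplitimeError
from .genome import BinGrid
from .tracks import BinnedTrack, RTProfile

__all__ = [
    "MappabilityMask",
    "DifferentialResult",
    "rt_difference_zscores",
    "call_significant_bins",
    "median_inter_bin_distance",
    "compare_significant_sets",
    "zscore_by_boundary_overlap",
    "IntersectionReport",
    "BoundaryZScoreReport",
]

DEFAULT_MAPPABILITY_THRESHOLD = 0.5
DEFAULT_ALPHA = 0.05


@dataclass
class MappabilityMask:
    """Per-bin mappability scores in [0, 1]; bins with score strictly above
    ``threshold`` are included in differential testing."""

    track: BinnedTrack
    threshold: float = DEFAULT_MAPPABILITY_THRESHOLD

    @property
    def included(self) -> np.ndarray:
        return self.track.valid & (self.track.values > self.threshold)


@dataclass
class DifferentialResult:
    """Per-bin timing difference, Z score, p, BH-adjusted p, and call flag.

    Arrays span the whole grid; excluded bins carry NaN (False for
    ``significant``). ``included`` records which bins entered the statistics.
    """

    grid: BinGrid
    d: np.ndarray
    z: np.ndarray
    p: np.ndarray
    padj: np.ndarray
    significant: np.ndarray
    included: np.ndarray
    alpha: Optional[float] = None
    mask_provenance: str = ""

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def significant_indices(self) -> np.ndarray:
        return np.flatnonzero(self.significant)

    def to_frame(self, included_only: bool = True) -> pd.DataFrame:
        """Tabulate as chrom/start/end/d/Z/p/padj/significant rows."""
        idx = np.flatnonzero(self.included) if included_only else np.arange(self.grid.total_bins)
        rows = [self.grid.bin_bounds(int(i)) for i in idx]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["d"] = self.d[idx]
        df["Z"] = self.z[idx]
        df["p"] = self.p[idx]
        df["padj"] = self.padj[idx]
        df["significant"] = self.significant[idx]
        return df


def rt_difference_zscores(
    control: RTProfile,
    treated: RTProfile,
    mask: MappabilityMask | None = None,
) -> DifferentialResult:
    """Standardise per-bin RT differences over included bins.

    Included bins are those valid in both profiles and (when a mask is
    given) mappable. ``d = control - treated``; ``Z = (d - mean(d)) / sd(d)``
    with the sample (ddof=1) standard deviation over included bins, so Z has
    zero mean and unit variance there. If sd is zero, all Z are zero.
    """
    if control.grid != treated.grid:
        raise ReplitimeError("profiles must share a grid")
    included = control.valid & treated.valid
    provenance = "valid-in-both"
    if mask is not None:
        if mask.track.grid != control.grid:
            raise ReplitimeError("mappability mask must share the profiles' grid")
        included &= mask.included
        provenance += f"; mappability > {mask.threshold}"
    if not included.any():
        raise ReplitimeError("no bins are valid in both profiles and mappable")
    n = control.grid.total_bins
    d = np.full(n, np.nan)
    d[included] = control.values[included] - treated.values[included]
    dv = d[included]
    sd = float(dv.std(ddof=1)) if dv.size > 1 else 0.0
    z = np.full(n, np.nan)
    z[included] = (dv - dv.mean()) / sd if sd > 0 else 0.0
    return DifferentialResult(
        grid=control.grid,
        d=d,
        z=z,
        p=np.full(n, np.nan),
        padj=np.full(n, np.nan),
        significant=np.zeros(n, dtype=bool),
        included=included,
        mask_provenance=provenance,
    )


def call_significant_bins(result: DifferentialResult, alpha: float = DEFAULT_ALPHA) -> DifferentialResult:
    """Two-sided normal p-values with Benjamini–Hochberg adjustment.

    Adjustment runs over included bins only; a bin is significant iff its
    adjusted p is below ``alpha``.
    """
    idx = np.flatnonzero(result.included)
    if idx.size == 0:
        raise ReplitimeError("no included bins")
    zv = result.z[idx]
    pv = 2.0 * _stats.norm.sf(np.abs(zv))
    _, padj_v, _, _ = multipletests(pv, method="fdr_bh")
    n = result.grid.total_bins
    p = np.full(n, np.nan)
    padj = np.full(n, np.nan)
    significant = np.zeros(n, dtype=bool)
    p[idx] = pv
    padj[idx] = padj_v
    significant[idx] = padj_v < alpha
    return replace(result, p=p, padj=padj, significant=significant, alpha=alpha)


def median_inter_bin_distance(result: DifferentialResult) -> float:
    """Median start-to-start distance between consecutive significant bins.

    Distances are taken between consecutive significant bins on the same
    chromosome; chromosomes with fewer than two significant bins contribute
    nothing. Raises if no chromosome has two or more.
    """
    sig = result.significant_indices()
    if sig.size < 2:
        raise ReplitimeError("need at least 2 significant bins")
    distances: list[np.ndarray] = []
    for chrom, sl in result.grid.iter_chromosomes():
        on_chrom = sig[(sig >= sl.start) & (sig < sl.stop)]
        if on_chrom.size >= 2:
            starts = (on_chrom - sl.start) * result.grid.bin_size
            distances.append(np.diff(starts))
    if not distances:
        raise ReplitimeError("no chromosome holds 2 or more significant bins")
    return float(np.median(np.concatenate(distances)))


@dataclass
class IntersectionReport:
    """Bins significant in two experiments, with direction concordance."""

    shared: pd.DataFrame  # chrom, start, end, d_a, d_b
    n_shared: int
    n_same_sign: int
    n_opposite_sign: int


def compare_significant_sets(a: DifferentialResult, b: DifferentialResult) -> IntersectionReport:
    """Intersect two experiments' significant bins by bin identity.

    Emits one row per shared bin with both experiments' d values, plus counts
    of shared, same-sign, and opposite-sign bins (sign of d in each).
    """
    if a.grid != b.grid:
        raise ReplitimeError("results must share a grid")
    shared_idx = np.intersect1d(a.significant_indices(), b.significant_indices())
    rows = [a.grid.bin_bounds(int(i)) for i in shared_idx]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["d_a"] = a.d[shared_idx] if shared_idx.size else np.array([], dtype=float)
    df["d_b"] = b.d[shared_idx] if shared_idx.size else np.array([], dtype=float)
    same = int(((df["d_a"] * df["d_b"]) > 0).sum())
    opposite = int(((df["d_a"] * df["d_b"]) < 0).sum())
    return IntersectionReport(df, len(df), same, opposite)


@dataclass
class BoundaryZScoreReport:
    """Z scores split by whether the bin covers a TAD boundary position."""

    boundary_z: np.ndarray
    other_z: np.ndarray
    n_boundary: int
    n_other: int
    median_boundary: float
    median_other: float
    statistic: float  # Mann-Whitney U
    pvalue: float


def zscore_by_boundary_overlap(
    result: DifferentialResult, boundaries: BoundarySet
) -> BoundaryZScoreReport:
    """Label each included bin as boundary-covering or not and compare groups.

    A bin covers a boundary when some boundary position lies in its
    half-open interval. Returns both Z-score groups with sizes, medians, and
    a two-sample Mann-Whitney location test (NaN when a group is empty).
    """
    grid = result.grid
    covers = np.zeros(grid.total_bins, dtype=bool)
    for chrom, positions in boundaries.positions.items():
        if chrom not in grid.layout:
            continue
        if positions.size:
            covers[grid.bin_indices(chrom, positions)] = True
    inc = result.included
    bz = result.z[inc & covers]
    oz = result.z[inc & ~covers]
    if bz.size and oz.size:
        stat, p = _stats.mannwhitneyu(bz, oz, alternative="two-sided")
    else:
        stat, p = float("nan"), float("nan")
    return BoundaryZScoreReport(
        boundary_z=bz,
        other_z=oz,
        n_boundary=int(bz.size),
        n_other=int(oz.size),
        median_boundary=float(np.median(bz)) if bz.size else float("nan"),
        median_other=float(np.median(oz)) if oz.size else float("nan"),
        statistic=float(stat),
        pvalue=float(p),
    )
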