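"""Replication-timing profiles from S-phase fraction counts.

The E/L RT statistic is the per-bin log2 ratio of early- over late-fraction
reads (S1/S3 for a four-fraction asynchronous experiment, 4h/10h for a
three-timepoint synchronized one), after scaling each fraction to reads per
million over its valid bins. Profiles from the conditions being compared are
quantile-normalized jointly and then loess-smoothed with a fixed 300 kb
genomic span. Weighted RT summarises all fractions into a single per-bin
timing value: the S-phase-weight average of the fraction read shares, with
earlier-replicating bins scoring higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .binning import FractionCounts
from .errors import ReplitimeError
from .genome import BinGrid
from .tracks import BinnedTrack, RTProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SampleFractions",
    "compute_el_rt",
    "quantile_normalize",
    "loess_smooth",
    "weighted_rt",
    "profile_correlation",
]

DEFAULT_LOESS_SPAN = 300_000

#: default S-phase weights (earliest fraction first): equally spaced, early-high
DEFAULT_WEIGHTS_4 = (1.0, 2.0 / 3.0, 1.0 / 3.0, 0.0)
DEFAULT_WEIGHTS_3 = (1.0, 0.5, 0.0)


@dataclass
class SampleFractions:
    """All S-phase fraction count tracks of one sample, with role tags.

    ``early``/``late`` name the fractions entering the E/L ratio; ``weights``
    are the per-fraction S-phase weights used by :func:`weighted_rt`, ordered
    earliest to latest and strictly decreasing.
    """

    fractions: list[FractionCounts]
    early: str
    late: str
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise ReplitimeError("a sample needs at least two fractions")
        labels = [f.label for f in self.fractions]
        if len(set(labels)) != len(labels):
            raise ReplitimeError(f"duplicate fraction labels: {labels}")
        for tag, name in (("early", self.early), ("late", self.late)):
            if name not in labels:
                raise ReplitimeError(f"{tag} fraction {name!r} not among {labels}")
        grid = self.fractions[0].grid
        for f in self.fractions[1:]:
            if f.grid != grid:
                raise ReplitimeError("all fractions of one sample must share one grid")
        if self.weights is None:
            self.weights = DEFAULT_WEIGHTS_4 if len(labels) == 4 else (
                DEFAULT_WEIGHTS_3 if len(labels) == 3 else None
            )
        if self.weights is not None:
            if len(self.weights) != len(self.fractions):
                raise ReplitimeError(
                    f"{len(self.weights)} weights for {len(self.fractions)} fractions"
                )
            if np.any(np.diff(self.weights) >= 0):
                raise ReplitimeError("weights must be strictly decreasing, earliest first")

    @property
    def grid(self) -> BinGrid:
        return self.fractions[0].grid

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.fractions]

    def fraction(self, label: str) -> FractionCounts:
        for f in self.fractions:
            if f.label == label:
                return f
        raise KeyError(label)


def _rpm(track: BinnedTrack) -> np.ndarray:
    """Scale counts to reads per million over valid bins."""
    total = track.values[track.valid].sum()
    if total <= 0:
        return np.zeros_like(track.values)
    return track.values * (1e6 / total)


DEFAULT_EL_MIN_COUNT = 10.0


def compute_el_rt(
    sample: SampleFractions,
    rpm_normalize: bool = True,
    min_count: float = DEFAULT_EL_MIN_COUNT,
    pseudocount: float = 0.0,
) -> RTProfile:
    """Per-bin log2(early/late) replication timing.

    Each fraction is first scaled to reads per million over its valid bins
    (``rpm_normalize=False`` uses raw counts); bins invalid in either
    fraction, or with raw count below ``min_count`` in either, are invalid.
    The default floor of 10 reads caps the log-ratio noise a bin can carry
    (sd(log2) <~ 0.65 at the floor) so that downstream bin statistics see
    near-homogeneous variance; ``min_count=0`` keeps every nonzero-count bin
    instead. ``pseudocount`` (e.g. 0.5) is added to both raw counts before
    the ratio when nonzero.
    """
    early = sample.fraction(sample.early).track
    late = sample.fraction(sample.late).track
    if early.grid != late.grid:
        raise ReplitimeError("early and late fractions must share a grid")
    if pseudocount > 0:
        early = BinnedTrack(early.grid, early.values + pseudocount, early.valid)
        late = BinnedTrack(late.grid, late.values + pseudocount, late.valid)
        floor = float(min_count)
    else:
        floor = max(float(min_count), np.nextafter(0.0, 1.0))
    e = _rpm(early) if rpm_normalize else early.values
    l = _rpm(late) if rpm_normalize else late.values
    valid = early.valid & late.valid & (early.values >= floor) & (late.values >= floor)
    rt = np.full(early.grid.total_bins, np.nan)
    rt[valid] = np.log2(e[valid] / l[valid])
    return RTProfile(early.grid, rt, valid)


def quantile_normalize(profiles: Sequence[RTProfile]) -> list[RTProfile]:
    """Jointly quantile-normalize two or more profiles on one grid.

    Restricted to bins valid in all profiles: each profile's rank-k value is
    replaced by the mean of all profiles' rank-k values, so the sorted value
    vectors of the outputs are identical. Ties within a profile receive the
    mean of their tied target values. Output validity is the shared mask.
    """
    if len(profiles) < 2:
        raise ReplitimeError("quantile normalization needs at least two profiles")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid != grid:
            raise ReplitimeError("profiles must share a grid")
    shared = np.logical_and.reduce([p.valid for p in profiles])
    n = int(shared.sum())
    if n == 0:
        raise ReplitimeError("no bins valid in all profiles")
    mat = np.stack([p.values[shared] for p in profiles], axis=1)  # (n, k)
    target = np.sort(mat, axis=0).mean(axis=1)
    out_profiles = []
    for j, prof in enumerate(profiles):
        col = mat[:, j]
        order = np.argsort(col, kind="stable")
        normalized = np.empty(n)
        normalized[order] = target
        # ties: average the target values assigned within each tied group
        uniq, inverse = np.unique(col, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inverse, weights=normalized)
            cnts = np.bincount(inverse)
            normalized = (sums / cnts)[inverse]
        rt = np.full(grid.total_bins, np.nan)
        rt[shared] = normalized
        out_profiles.append(RTProfile(grid, rt, shared.copy()))
    return out_profiles


def loess_smooth(
    profile: RTProfile, span: int = DEFAULT_LOESS_SPAN, min_support: int = 2
) -> RTProfile:
    """Loess-smooth a profile with a fixed genomic span.

    Per chromosome, each valid bin's smoothed value is a locally weighted
    linear regression over the valid bins whose centers lie within
    ±``span``/2, with tricube weights on genomic distance. Invalid bins stay
    invalid. Local linear fits are exact on constant and linear profiles.

    ``min_support`` is the minimum number of in-window valid bins (self
    included) a smoothed estimate must rest on. A bin supported by fewer
    than two usable neighbours is passed through unchanged (with a warning
    per chromosome); with ``min_support`` above 2, under-supported bins are
    instead marked invalid — estimates averaging too few points carry
    variance the rest of the profile does not, which matters when a
    downstream statistic assumes comparable noise per bin.
    """
    grid = profile.grid
    if span < 3 * grid.bin_size:
        raise ReplitimeError(f"span {span} must be at least 3 bin widths ({3 * grid.bin_size})")
    half = span / 2.0
    out = np.full(grid.total_bins, np.nan)
    out_valid = profile.valid.copy()
    for chrom, sl in grid.iter_chromosomes():
        vals = profile.values[sl]
        ok = profile.valid[sl]
        vidx = np.flatnonzero(ok)
        if vidx.size == 0:
            continue
        x = grid.bin_centers(chrom)[vidx]
        y = vals[vidx]
        if vidx.size < 2:
            if min_support > 2:
                out_valid[sl.start + vidx] = False
            else:
                out[sl.start + vidx] = y
                logger.warning("loess: %s has < 2 valid bins; values passed through", chrom)
            continue
        smoothed = np.full(vidx.size, np.nan)
        dropped = np.zeros(vidx.size, dtype=bool)
        passed_through = 0
        # valid bin centers are sorted; locate each window by search
        lo_all = np.searchsorted(x, x - half, side="left")
        hi_all = np.searchsorted(x, x + half, side="right")
        for i in range(vidx.size):
            lo, hi = lo_all[i], hi_all[i]
            xs = x[lo:hi]
            ys = y[lo:hi]
            d = np.abs(xs - x[i]) / half
            w = (1.0 - d**3) ** 3
            use = w > 0
            n_use = int(use.sum())
            if n_use < max(min_support, 2):
                if min_support > 2:
                    dropped[i] = True
                else:
                    smoothed[i] = y[i]
                    passed_through += 1
                continue
            xs, ys, w = xs[use], ys[use], w[use]
            sw = w.sum()
            xm = (w * xs).sum() / sw
            ym = (w * ys).sum() / sw
            dx = xs - xm
            sxx = (w * dx * dx).sum()
            if sxx <= 0:
                smoothed[i] = ym
                continue
            b = (w * dx * (ys - ym)).sum() / sxx
            smoothed[i] = ym + b * (x[i] - xm)
        if passed_through:
            logger.warning(
                "loess: %s: %d bin(s) had < 2 in-window neighbours; passed through", chrom, passed_through
            )
        out[sl.start + vidx] = smoothed
        out_valid[sl.start + vidx[dropped]] = False
    out[~out_valid] = np.nan
    return RTProfile(grid, out, out_valid)


def weighted_rt(sample: SampleFractions) -> BinnedTrack:
    """Weighted-average replication timing over all fractions.

    Per bin, ``wrt = sum_i w_i * f_i / sum_i f_i`` where ``f_i`` is fraction
    i's reads-per-million at the bin; bins with zero total signal (or invalid
    in any fraction) are invalid. Higher values mean earlier replication.
    The statistic is invariant to each fraction's library size by
    construction of the RPM scaling.
    """
    if sample.weights is None:
        raise ReplitimeError(
            f"no weights configured for {len(sample.fractions)} fractions; set SampleFractions.weights"
        )
    grid = sample.grid
    F = np.stack([_rpm(f.track) for f in sample.fractions], axis=0)
    valid_all = np.logical_and.reduce([f.track.valid for f in sample.fractions])
    denom = F.sum(axis=0)
    valid = valid_all & (denom > 0)
    w = np.asarray(sample.weights)
    wrt = np.full(grid.total_bins, np.nan)
    wrt[valid] = (w @ F[:, valid]) / denom[valid]
    return BinnedTrack(grid, wrt, valid)


def profile_correlation(a: RTProfile, b: RTProfile) -> float:
    """Pearson correlation between two profiles over their shared valid bins."""
    if a.grid != b.grid:
        raise ReplitimeError("profiles must share a grid")
    shared = a.valid & b.valid
    if int(shared.sum()) < 3:
        raise ReplitimeError("fewer than 3 shared valid bins")
    r, _ = _stats.pearsonr(a.values[shared], b.values[shared])
    return float(r)
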