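"""Synthetic Repli-seq data with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a piecewise-domain RT landscape (gamma-distributed domain lengths, normal
  domain RT values, linear 100 kb transition ramps between domains);
* per-fraction sequencing counts: locus RT maps through a logistic curve to
  an S-phase time in (0, 1); each fraction captures a locus with a Gaussian
  kernel around its S-phase center (overlapping FACS gates); counts are
  Poisson around depth x share (negative-binomial optionally);
* signal-spike artifacts in 1 kb bins, and unmappable regions shared
  between conditions and recorded in a mappability track;
* a treated condition sharing the control landscape except for a configured
  number of shifted domains (early<->late switches of a given log2 size);
* TAD/compartment boundary files with known cohesin-dependence classes, and
  a differential-expression gene table with known pass/fail labels.

Identical spec and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .binning import FractionCounts
from .boundaries import BoundarySet, COMPARTMENT_PROXIMAL, INVARIANT, SCC1_DEPENDENT
from .errors import ReplitimeError
from .genome import BinGrid, GenomeLayout
from .intervals import IntervalSet
from .rt import DEFAULT_WEIGHTS_3, DEFAULT_WEIGHTS_4, SampleFractions
from .tracks import BinnedTrack

__all__ = [
    "SimulationSpec",
    "RTLandscape",
    "SyntheticTruth",
    "SimulatedExperiment",
    "SimulatedBoundaries",
    "simulate_rt_landscape",
    "simulate_fraction_counts",
    "simulate_condition_pair",
    "simulate_boundaries",
    "simulate_gene_table",
    "write_simulation",
]

DEFAULT_LAYOUT = GenomeLayout.from_pairs([("chr1", 50_000_000), ("chr2", 50_000_000)])


@dataclass(frozen=True)
class SimulationSpec:
    """All generator parameters (defaults are the study conditions emulated).

    ``depth`` is the mean read count per 50 kb bin per fraction. Fraction
    capture centers default to an even grid on [0.3, 0.7] of S-phase time:
    with kernel width ``sigma`` = 0.15 this keeps every fraction's expected
    count nonzero genome-wide, as overlapping FACS gates do in the real
    assay. ``rt_to_time_scale`` sets how many log2 RT units span the
    logistic S-phase-time transition.
    """

    layout: GenomeLayout = DEFAULT_LAYOUT
    bin_size: int = 1_000
    analysis_bin_size: int = 50_000
    # RT landscape
    domain_length_mean: float = 1_000_000.0
    domain_length_shape: float = 4.0
    min_domain_length: int = 200_000
    domain_rt_sd: float = 1.5
    ramp_length: int = 100_000
    # fraction count model
    n_fractions: int = 4
    fraction_centers: Optional[tuple[float, ...]] = None
    sigma: float = 0.15
    gate_contamination: float = 0.05
    rt_to_time_scale: float = 2.0
    depth: float = 100.0
    dispersion: Optional[float] = None  # negative-binomial overdispersion; None = Poisson
    # artifacts
    spike_rate: float = 5e-4
    spike_factor: float = 50.0
    unmappable_rate: float = 0.05
    unmappable_mean_length: float = 100_000.0
    # differential design
    n_shifted_domains: int = 0
    shift_size: float = 2.0
    shift_band: tuple[float, float] = (0.75, 1.25)
    # boundary design
    tad_spacing_mean: float = 1_000_000.0
    fraction_invariant: float = 0.5
    boundary_jitter: int = 100_000
    compartment_fraction: float = 0.3
    boundary_tolerance: int = 500_000

    def __post_init__(self) -> None:
        for name in (
            "spike_rate",
            "unmappable_rate",
            "fraction_invariant",
            "compartment_fraction",
            "gate_contamination",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ReplitimeError(f"{name} must be in [0, 1], got {v}")
        if self.sigma <= 0:
            raise ReplitimeError("sigma must be > 0")
        if self.depth <= 0:
            raise ReplitimeError("depth must be > 0")
        if self.analysis_bin_size % self.bin_size != 0:
            raise ReplitimeError("analysis_bin_size must be a multiple of bin_size")

    @property
    def centers(self) -> np.ndarray:
        if self.fraction_centers is not None:
            return np.asarray(self.fraction_centers, dtype=float)
        return np.linspace(0.3, 0.7, self.n_fractions)

    @property
    def fraction_labels(self) -> list[str]:
        if self.n_fractions == 4:
            return ["S1", "S2", "S3", "S4"]
        if self.n_fractions == 3:
            return ["4h", "7h", "10h"]
        return [f"F{i + 1}" for i in range(self.n_fractions)]

    @property
    def fraction_weights(self) -> tuple[float, ...]:
        if self.n_fractions == 4:
            return DEFAULT_WEIGHTS_4
        if self.n_fractions == 3:
            return DEFAULT_WEIGHTS_3
        return tuple(np.linspace(1.0, 0.0, self.n_fractions))

    @property
    def grid(self) -> BinGrid:
        return BinGrid(self.layout, self.bin_size)

    @property
    def analysis_grid(self) -> BinGrid:
        return BinGrid(self.layout, self.analysis_bin_size)


@dataclass
class RTLandscape:
    """True RT per 1 kb bin, with its generating domain segmentation."""

    track: BinnedTrack  # 1 kb true RT, all bins valid
    domains: pd.DataFrame  # chrom, start, end, rt
    switches: dict[str, np.ndarray]  # internal domain-switch positions


def _draw_domains(length: int, spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Domain end positions tiling [0, length), rounded to the bin size."""
    scale = spec.domain_length_mean / spec.domain_length_shape
    ends: list[int] = []
    pos = 0
    while pos < length:
        l = rng.gamma(spec.domain_length_shape, scale)
        l = max(int(round(l / spec.bin_size)) * spec.bin_size, spec.min_domain_length)
        pos = min(pos + l, length)
        ends.append(pos)
    if len(ends) > 1 and ends[-1] - ends[-2] < spec.min_domain_length:
        del ends[-2]  # merge a short terminal remainder into the previous domain
    return np.asarray(ends, dtype=np.int64)


def _render_chromosome(
    centers: np.ndarray, ends: np.ndarray, values: np.ndarray, ramp: float
) -> np.ndarray:
    """Piecewise-constant domain RT with linear ramps across switches."""
    starts = np.concatenate([[0], ends[:-1]])
    xs: list[float] = []
    ys: list[float] = []
    for i, (s, e, v) in enumerate(zip(starts, ends, values)):
        left = s if i == 0 else s + ramp / 2.0
        right = e if i == len(ends) - 1 else e - ramp / 2.0
        xs.extend((left, right))
        ys.extend((v, v))
    return np.interp(centers, xs, ys)


def simulate_rt_landscape(spec: SimulationSpec, rng: np.random.Generator) -> RTLandscape:
    """Draw a domain segmentation and render the true RT track at 1 kb."""
    grid = spec.grid
    rt = np.empty(grid.total_bins)
    rows = []
    switches: dict[str, np.ndarray] = {}
    for chrom, length in spec.layout:
        ends = _draw_domains(length, spec, rng)
        values = rng.normal(0.0, spec.domain_rt_sd, ends.size)
        starts = np.concatenate([[0], ends[:-1]])
        sl = grid.chrom_slice(chrom)
        rt[sl] = _render_chromosome(grid.bin_centers(chrom), ends, values, spec.ramp_length)
        switches[chrom] = ends[:-1].copy()
        rows.extend((chrom, int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values))
    domains = pd.DataFrame(rows, columns=["chrom", "start", "end", "rt"])
    track = BinnedTrack(grid, rt, np.ones(grid.total_bins, dtype=bool))
    return RTLandscape(track=track, domains=domains, switches=switches)


def _fraction_shares(rt: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """(n_fractions, n_bins) capture shares; early RT -> small S-phase time.

    Shares mix the Gaussian gate kernel with a uniform cross-contamination
    floor (``gate_contamination``): FACS sort gates are only 80-90% pure, so
    every fraction receives a nonzero share of reads from every locus.
    """
    t = 1.0 / (1.0 + np.exp(rt / spec.rt_to_time_scale))
    k = np.exp(-((t[None, :] - spec.centers[:, None]) ** 2) / (2.0 * spec.sigma**2))
    shares = k / k.sum(axis=0, keepdims=True)
    eps = spec.gate_contamination
    return (1.0 - eps) * shares + eps / spec.n_fractions


def simulate_fraction_counts(
    true_rt: BinnedTrack,
    spec: SimulationSpec,
    rng: np.random.Generator,
    unmappable: Optional[np.ndarray] = None,
) -> SampleFractions:
    """Draw per-fraction count tracks for one sample from a true RT track.

    Counts are Poisson around ``depth * n_fractions * (bin/analysis-bin) *
    share`` (so the mean per 50 kb bin per fraction is ``depth``), with
    optional negative-binomial overdispersion. Spiked 1 kb bins have their
    rate multiplied by ``spike_factor``; unmappable bins are zeroed.
    """
    shares = _fraction_shares(true_rt.values, spec)
    per_bin_total = spec.depth * spec.n_fractions * spec.bin_size / spec.analysis_bin_size
    labels = spec.fraction_labels
    fractions = []
    n = true_rt.grid.total_bins
    for i, label in enumerate(labels):
        lam = per_bin_total * shares[i]
        spikes = rng.random(n) < spec.spike_rate
        lam = np.where(spikes, lam * spec.spike_factor, lam)
        if spec.dispersion is not None and spec.dispersion > 0:
            shape = 1.0 / spec.dispersion
            lam = rng.gamma(shape, lam * spec.dispersion)
        counts = rng.poisson(lam).astype(float)
        if unmappable is not None:
            counts[unmappable] = 0.0
        fractions.append(
            FractionCounts(label, BinnedTrack(true_rt.grid, counts, np.ones(n, dtype=bool)))
        )
    early = labels[0]
    late = labels[2] if len(labels) >= 3 else labels[-1]
    return SampleFractions(fractions, early=early, late=late, weights=spec.fraction_weights)


def _draw_unmappable(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean 1 kb mask of unmappable bins (genome property, shared between
    conditions)."""
    grid = spec.grid
    mask = np.zeros(grid.total_bins, dtype=bool)
    total = spec.layout.total_length
    n_regions = int(round(spec.unmappable_rate * total / spec.unmappable_mean_length))
    lengths = np.array([l for _, l in spec.layout], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(n_regions):
        ci = rng.choice(len(lengths), p=probs)
        chrom, clen = spec.layout.chromosomes[ci]
        span = max(int(round(rng.exponential(spec.unmappable_mean_length))), spec.bin_size)
        start = int(rng.integers(0, max(clen - span, 1)))
        lo, hi = grid.overlapping_bins(chrom, start, min(start + span, clen))
        mask[lo:hi] = True
    return mask


def _mappability_track(spec: SimulationSpec, unmappable: np.ndarray) -> BinnedTrack:
    """Fraction of mappable 1 kb children per analysis bin."""
    src, dst = spec.grid, spec.analysis_grid
    factor = spec.analysis_bin_size // spec.bin_size
    score = np.zeros(dst.total_bins)
    for chrom, sl in src.iter_chromosomes():
        ok = (~unmappable[sl]).astype(float)
        parent = np.arange(ok.size) // factor
        n_parent = dst.n_bins(chrom)
        off = dst.chrom_offset(chrom)
        score[off : off + n_parent] = np.bincount(parent, weights=ok, minlength=n_parent) / np.bincount(
            parent, minlength=n_parent
        )
    return BinnedTrack(dst, score, np.ones(dst.total_bins, dtype=bool))


def _aggregate_mean(track: BinnedTrack, spec: SimulationSpec) -> BinnedTrack:
    """Mean of 1 kb children per analysis bin (for true-RT bookkeeping)."""
    src, dst = spec.grid, spec.analysis_grid
    factor = spec.analysis_bin_size // spec.bin_size
    out = np.zeros(dst.total_bins)
    for chrom, sl in src.iter_chromosomes():
        vals = track.values[sl]
        parent = np.arange(vals.size) // factor
        n_parent = dst.n_bins(chrom)
        off = dst.chrom_offset(chrom)
        out[off : off + n_parent] = np.bincount(parent, weights=vals, minlength=n_parent) / np.bincount(
            parent, minlength=n_parent
        )
    return BinnedTrack(dst, out, np.ones(dst.total_bins, dtype=bool))


@dataclass
class SyntheticTruth:
    """Ground truth aligned bin-for-bin with the emitted data."""

    grid: BinGrid  # analysis (50 kb) grid
    true_rt_control: BinnedTrack
    true_rt_treated: BinnedTrack
    shifted_bins: np.ndarray  # fully shifted analysis bins
    partial_bins: np.ndarray  # ramp bins carrying part of a shift
    mappability: BinnedTrack
    unmappable_1kb: np.ndarray
    domains: pd.DataFrame
    shifted_domains: pd.DataFrame


@dataclass
class SimulatedExperiment:
    control: SampleFractions
    treated: SampleFractions
    truth: SyntheticTruth
    landscape: RTLandscape


def simulate_condition_pair(spec: SimulationSpec, seed: int) -> SimulatedExperiment:
    """Control + treated samples sharing one landscape, with ground truth.

    The treated condition differs only in ``n_shifted_domains`` domains whose
    RT is flipped toward the opposite timing half by ``shift_size`` log2
    units. Shifted domains are drawn from the mid-timing band ``shift_band``
    so both endpoints stay inside the informative S-phase window (an
    early<->late switch, the kind of change the assay can measure). With
    ``n_shifted_domains=0`` both conditions are draws from one landscape
    (the global null).
    """
    rng = np.random.default_rng(seed)
    landscape = simulate_rt_landscape(spec, rng)
    domains = landscape.domains
    treated_values = domains["rt"].to_numpy().copy()
    shifted_rows = np.array([], dtype=np.int64)
    if spec.n_shifted_domains > 0:
        lo, hi = spec.shift_band
        candidates = np.flatnonzero((np.abs(treated_values) >= lo) & (np.abs(treated_values) <= hi))
        n_take = min(spec.n_shifted_domains, candidates.size)
        # dose control: among random candidate subsets, keep the one whose
        # total length is closest to n * mean domain length, so the injected
        # perturbation mass is comparable across seeds
        lengths = (domains["end"] - domains["start"]).to_numpy()
        target = n_take * spec.domain_length_mean
        best: np.ndarray | None = None
        best_err = np.inf
        for _ in range(200):
            pick = rng.choice(candidates, size=n_take, replace=False)
            err = abs(float(lengths[pick].sum()) - target)
            if err < best_err:
                best, best_err = pick, err
        shifted_rows = np.sort(best)
        signs = np.where(treated_values[shifted_rows] >= 0, 1.0, -1.0)
        treated_values[shifted_rows] -= signs * spec.shift_size
    # render the treated landscape on the same segmentation
    grid = spec.grid
    treated_rt = np.empty(grid.total_bins)
    for chrom, _ in spec.layout:
        sub = domains["chrom"] == chrom
        ends = domains.loc[sub, "end"].to_numpy()
        vals = treated_values[sub.to_numpy()]
        treated_rt[grid.chrom_slice(chrom)] = _render_chromosome(
            grid.bin_centers(chrom), ends, vals, spec.ramp_length
        )
    treated_track = BinnedTrack(grid, treated_rt, np.ones(grid.total_bins, dtype=bool))

    unmappable = _draw_unmappable(spec, rng)
    control = simulate_fraction_counts(landscape.track, spec, rng, unmappable)
    treated = simulate_fraction_counts(treated_track, spec, rng, unmappable)

    true_c = _aggregate_mean(landscape.track, spec)
    true_t = _aggregate_mean(treated_track, spec)
    diff = np.abs(true_c.values - true_t.values)
    shifted = diff >= 0.9 * spec.shift_size
    partial = (diff > 1e-9) & ~shifted
    truth = SyntheticTruth(
        grid=spec.analysis_grid,
        true_rt_control=true_c,
        true_rt_treated=true_t,
        shifted_bins=shifted,
        partial_bins=partial,
        mappability=_mappability_track(spec, unmappable),
        unmappable_1kb=unmappable,
        domains=domains,
        shifted_domains=domains.iloc[shifted_rows].assign(rt_treated=treated_values[shifted_rows]),
    )
    return SimulatedExperiment(control=control, treated=treated, truth=truth, landscape=landscape)


@dataclass
class SimulatedBoundaries:
    """Boundary files plus the true class of every control boundary.

    ``control_boundaries.classes`` holds the ground-truth classes, computed
    from the emitted positions by an exhaustive all-pairs distance scan (a
    deliberately independent route from the package classifier).
    """

    control_domains: IntervalSet
    treated_domains: IntervalSet
    compartments: BoundarySet
    control_boundaries: BoundarySet  # with true classes
    treated_boundaries: BoundarySet


def _truth_classes(
    positions: np.ndarray, comp: np.ndarray, trt: np.ndarray, tol: int
) -> np.ndarray:
    cls = np.empty(positions.size, dtype=object)
    for i, p in enumerate(positions):
        if any(abs(int(p) - int(c)) <= tol for c in comp):
            cls[i] = COMPARTMENT_PROXIMAL
        elif any(abs(int(p) - int(t)) <= tol for t in trt):
            cls[i] = INVARIANT
        else:
            cls[i] = SCC1_DEPENDENT
    return cls


def _domains_between(positions: np.ndarray, chrom: str) -> list[tuple]:
    return [
        (chrom, int(a), int(b))
        for a, b in zip(positions[:-1], positions[1:])
        if b > a
    ]


def simulate_boundaries(
    landscape: RTLandscape, spec: SimulationSpec, rng: np.random.Generator
) -> SimulatedBoundaries:
    """TAD and compartment boundary files with known classes.

    Compartment boundaries sit at a random subset of RT-domain switches.
    Control TAD boundaries are a mix of invariant boundaries (placed at RT
    switches, where boundaries in the real genome track timing structure)
    and cohesin-dependent ones (placed uniformly); treated boundaries are
    the invariant subset jittered by at most ``boundary_jitter``.
    """
    comp_pos: dict[str, np.ndarray] = {}
    ctrl_pos: dict[str, np.ndarray] = {}
    trt_pos: dict[str, np.ndarray] = {}
    for chrom, length in spec.layout:
        switches = landscape.switches.get(chrom, np.array([], dtype=np.int64))
        take_comp = rng.random(switches.size) < spec.compartment_fraction
        comp = switches[take_comp]
        free_switches = switches[~take_comp]
        n_tads = max(int(round(length / spec.tad_spacing_mean)), 2)
        n_inv = int(round(spec.fraction_invariant * n_tads))
        n_dep = n_tads - n_inv
        inv_from_switch = min(n_inv, free_switches.size)
        inv = rng.choice(free_switches, size=inv_from_switch, replace=False) if inv_from_switch else np.array([], dtype=np.int64)
        extra = n_inv - inv_from_switch
        if extra > 0:
            inv = np.concatenate([inv, rng.integers(0, length, size=extra)])
        dep = rng.integers(0, length, size=n_dep) if n_dep > 0 else np.array([], dtype=np.int64)
        ctrl = np.unique(np.concatenate([inv, dep]).astype(np.int64))
        jit = rng.integers(-spec.boundary_jitter, spec.boundary_jitter + 1, size=inv.size) if inv.size else np.array([], dtype=np.int64)
        trt = np.unique(np.clip(inv.astype(np.int64) + jit, 0, length))
        comp_pos[chrom] = np.sort(comp.astype(np.int64))
        ctrl_pos[chrom] = ctrl
        trt_pos[chrom] = trt
    compartments = BoundarySet(comp_pos, label="compartments")
    treated = BoundarySet(trt_pos, label="treated TADs")
    classes = {
        chrom: _truth_classes(pos, comp_pos.get(chrom, np.array([])), trt_pos.get(chrom, np.array([])), spec.boundary_tolerance)
        for chrom, pos in ctrl_pos.items()
    }
    control = BoundarySet(ctrl_pos, label="control TADs", classes=classes)
    control_domains = IntervalSet.from_records(
        [rec for chrom, pos in ctrl_pos.items() for rec in _domains_between(pos, chrom)]
    )
    treated_domains = IntervalSet.from_records(
        [rec for chrom, pos in trt_pos.items() for rec in _domains_between(pos, chrom)]
    )
    return SimulatedBoundaries(
        control_domains=control_domains,
        treated_domains=treated_domains,
        compartments=compartments,
        control_boundaries=control,
        treated_boundaries=treated,
    )


def simulate_gene_table(
    spec: SimulationSpec,
    rng: np.random.Generator,
    n_genes: int = 200,
    n_induced: int = 25,
    n_repressed: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A gene expression table with known induced/repressed/neither labels.

    Induced genes get linear fold change > 2, adjusted p < 0.05 and
    RPKM >= 0.5 by construction; repressed genes mirror them below 1/2;
    the remainder violate at least one cutoff. Returns (table, truth) where
    truth carries a ``true_class`` column aligned by gene_id.
    """
    if n_induced + n_repressed > n_genes:
        raise ReplitimeError("n_induced + n_repressed exceeds n_genes")
    lengths = np.array([l for _, l in spec.layout], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    labels = []
    for i in range(n_genes):
        ci = rng.choice(len(lengths), p=probs)
        chrom, clen = spec.layout.chromosomes[ci]
        span = int(rng.integers(5_000, 100_000))
        start = int(rng.integers(0, clen - span))
        if i < n_induced:
            fc = float(2.0 ** rng.uniform(1.2, 3.0))
            padj = float(rng.uniform(1e-6, 0.04))
            rpkm = float(rng.uniform(0.5, 50.0))
            label = "induced"
        elif i < n_induced + n_repressed:
            fc = float(2.0 ** -rng.uniform(1.2, 3.0))
            padj = float(rng.uniform(1e-6, 0.04))
            rpkm = float(rng.uniform(0.5, 50.0))
            label = "repressed"
        else:
            # break one cutoff at random
            broken = rng.integers(0, 3)
            fc = float(2.0 ** rng.uniform(-3.0, 3.0))
            padj = float(rng.uniform(1e-6, 0.04))
            rpkm = float(rng.uniform(0.5, 50.0))
            if broken == 0:
                fc = float(2.0 ** rng.uniform(-0.9, 0.9))
            elif broken == 1:
                padj = float(rng.uniform(0.05, 1.0))
            else:
                rpkm = float(rng.uniform(0.0, 0.49))
            label = "neither"
        rows.append((f"gene{i:04d}", chrom, start, start + span, fc, padj, rpkm))
        labels.append(label)
    table = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "fold_change", "padj", "rpkm"]
    )
    truth = pd.DataFrame({"gene_id": table["gene_id"], "true_class": labels})
    return table, truth


def write_simulation(
    outdir: str | Path,
    experiment: SimulatedExperiment,
    boundaries: Optional[SimulatedBoundaries] = None,
    genes: Optional[tuple[pd.DataFrame, pd.DataFrame]] = None,
) -> dict[str, Path]:
    """Emit every simulated input as text files; returns name -> path."""
    from .io import write_bed, write_bedgraph, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _save_bedgraph(name: str, track: BinnedTrack) -> None:
        p = outdir / f"{name}.bedgraph"
        write_bedgraph(track, p)
        paths[name] = p

    layout_path = outdir / "genome.chrom.sizes"
    with open(layout_path, "w") as fh:
        for chrom, length in experiment.control.grid.layout:
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_sizes"] = layout_path

    for cond, sample in (("control", experiment.control), ("treated", experiment.treated)):
        for frac in sample.fractions:
            _save_bedgraph(f"{cond}_{frac.label}", frac.track)
    truth = experiment.truth
    _save_bedgraph("mappability", truth.mappability)
    _save_bedgraph("true_rt_control", truth.true_rt_control)
    _save_bedgraph("true_rt_treated", truth.true_rt_treated)

    shifted_path = outdir / "true_shifted_bins.tsv"
    rows = [truth.grid.bin_bounds(int(i)) for i in np.flatnonzero(truth.shifted_bins)]
    write_table(pd.DataFrame(rows, columns=["chrom", "start", "end"]), shifted_path)
    paths["true_shifted_bins"] = shifted_path
    domains_path = outdir / "true_domains.tsv"
    write_table(truth.domains, domains_path)
    paths["true_domains"] = domains_path

    if boundaries is not None:
        for name, ivals in (
            ("tads_control", boundaries.control_domains),
            ("tads_treated", boundaries.treated_domains),
        ):
            p = outdir / f"{name}.bed"
            write_bed(list(ivals), p)
            paths[name] = p
        p = outdir / "compartment_boundaries.bed"
        write_bed(
            [(c, int(x), int(x) + 1) for c, arr in boundaries.compartments.positions.items() for x in arr],
            p,
        )
        paths["compartments"] = p
        p = outdir / "true_boundary_classes.bed"
        write_bed(boundaries.control_boundaries.to_bed_records(), p)
        paths["true_boundary_classes"] = p

    if genes is not None:
        table, truth_genes = genes
        p = outdir / "genes.tsv"
        write_table(table, p)
        paths["genes"] = p
        p = outdir / "true_gene_classes.tsv"
        write_table(truth_genes, p)
        paths["true_gene_classes"] = p
    return paths
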