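"""End-to-end orchestration: binning -> RT profiles -> differential ->
boundaries -> features, with a serialized run manifest.

`analyze_condition_pair` is the in-memory composition used by the library,
tests, and simulations; `run_pipeline` is the file-based entry point behind
the CLI, consuming the standard text formats and writing every stage's
outputs plus a manifest (package version, config, input hashes). Reruns on
identical inputs and config are bit-identical: no stage uses randomness or
mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .binning import aggregate_bins, filter_spikes
from .boundaries import (
    BOUNDARY_CLASSES,
    BoundarySet,
    boundary_metaplot,
    classify_boundaries,
    extract_boundaries,
)
from .differential import (
    DifferentialResult,
    MappabilityMask,
    call_significant_bins,
    compare_significant_sets,
    median_inter_bin_distance,
    rt_difference_zscores,
)
from .errors import ReplitimeError
from .features import paired_feature_rt, select_de_genes
from .genome import BinGrid
from .intervals import IntervalSet
from .io import (
    read_bed,
    read_bedgraph_track,
    read_chrom_sizes,
    read_gene_table,
    write_bed,
    write_bedgraph,
    write_table,
)
from .rt import (
    SampleFractions,
    compute_el_rt,
    loess_smooth,
    quantile_normalize,
    weighted_rt,
)
from .tracks import BinnedTrack, RTProfile
from .binning import FractionCounts

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineInputs", "PipelineResult", "analyze_condition_pair", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with the analysis defaults.

    read_bin_size 1 kb -> analysis_bin_size 50 kb; spike Z 2.5; loess span
    300 kb; mappability threshold 0.5; alpha 0.05; boundary tolerance 500 kb;
    metaplot flank 5 Mb. Every parameter is overridable and the config is
    serialized alongside outputs.
    """

    read_bin_size: int = 1_000
    analysis_bin_size: int = 50_000
    spike_z: float = 2.5
    min_valid_fraction: float = 0.5
    loess_span: int = 300_000
    loess_min_support: int = 5
    quantile_normalization: bool = True
    rpm_normalize: bool = True
    el_min_count: float = 10.0
    el_pseudocount: float = 0.0
    mappability_threshold: float = 0.5
    alpha: float = 0.05
    boundary_tolerance: int = 500_000
    metaplot_flank: int = 5_000_000
    metaplot_orient: str = "rt-slope"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineInputs:
    """Resolvable paths to every input the pipeline consumes.

    Fraction tracks are 1 kb-binned count bedGraphs (or whatever
    ``read_bin_size`` says), one per S-phase fraction, keyed by label.
    Boundary/feature/gene inputs are optional; their stages are skipped when
    absent.
    """

    chrom_sizes: Path
    control_fractions: dict[str, Path]
    treated_fractions: dict[str, Path]
    early: str
    late: str
    weights: Optional[tuple[float, ...]] = None
    mappability: Optional[Path] = None
    control_tads: Optional[Path] = None
    treated_tads: Optional[Path] = None
    compartments: Optional[Path] = None
    feature_beds: dict[str, Path] = field(default_factory=dict)
    gene_table: Optional[Path] = None


@dataclass
class ProcessedSample:
    """One condition after binning and profile computation."""

    fractions_50kb: SampleFractions
    el_raw: RTProfile
    el_smoothed: RTProfile
    weighted: Optional[BinnedTrack]


@dataclass
class PairAnalysis:
    control: ProcessedSample
    treated: ProcessedSample
    differential: DifferentialResult
    median_distance: Optional[float]


@dataclass
class PipelineResult:
    analysis: PairAnalysis
    boundary_classes: Optional[BoundarySet]
    class_counts: Optional[dict]
    metaplots: dict
    feature_tables: Optional[tuple[pd.DataFrame, pd.DataFrame]]
    manifest: dict
    outdir: Optional[Path]


def _process_counts(sample: SampleFractions, config: PipelineConfig) -> SampleFractions:
    """Spike-filter each fraction independently, then aggregate to the
    analysis resolution."""
    processed = []
    for frac in sample.fractions:
        filtered = filter_spikes(frac, z_threshold=config.spike_z)
        if frac.grid.bin_size != config.analysis_bin_size:
            filtered = aggregate_bins(
                filtered,
                target_size=config.analysis_bin_size,
                min_valid_fraction=config.min_valid_fraction,
            )
        processed.append(filtered)
    return SampleFractions(processed, early=sample.early, late=sample.late, weights=sample.weights)


def analyze_condition_pair(
    control: SampleFractions,
    treated: SampleFractions,
    mappability: Optional[BinnedTrack] = None,
    config: PipelineConfig = PipelineConfig(),
) -> PairAnalysis:
    """Run binning, E/L RT, joint normalization, smoothing, and differential
    calling for one control/treated pair of samples."""
    ctrl_50 = _process_counts(control, config)
    trt_50 = _process_counts(treated, config)

    def _profile_stages(sample: SampleFractions) -> tuple[RTProfile, Optional[BinnedTrack]]:
        raw = compute_el_rt(
            sample,
            rpm_normalize=config.rpm_normalize,
            min_count=config.el_min_count,
            pseudocount=config.el_pseudocount,
        )
        w = weighted_rt(sample) if sample.weights is not None else None
        return raw, w

    raw_c, w_c = _profile_stages(ctrl_50)
    raw_t, w_t = _profile_stages(trt_50)
    if config.quantile_normalization:
        norm_c, norm_t = quantile_normalize([raw_c, raw_t])
    else:
        norm_c, norm_t = raw_c, raw_t
    smooth_c = loess_smooth(norm_c, span=config.loess_span, min_support=config.loess_min_support)
    smooth_t = loess_smooth(norm_t, span=config.loess_span, min_support=config.loess_min_support)

    mask = None
    if mappability is not None:
        mask = MappabilityMask(mappability, threshold=config.mappability_threshold)
    result = rt_difference_zscores(smooth_c, smooth_t, mask)
    result = call_significant_bins(result, alpha=config.alpha)
    try:
        med = median_inter_bin_distance(result)
    except ReplitimeError:
        med = None
    return PairAnalysis(
        control=ProcessedSample(ctrl_50, raw_c, smooth_c, w_c),
        treated=ProcessedSample(trt_50, raw_t, smooth_t, w_t),
        differential=result,
        median_distance=med,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: Path | str,
) -> PipelineResult:
    """Execute every stage on file inputs and write all outputs + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        layout = read_chrom_sizes(inputs.chrom_sizes)
        read_grid = BinGrid(layout, config.read_bin_size)
        analysis_grid = BinGrid(layout, config.analysis_bin_size)

        stage = "binning"

        def _load_sample(paths: dict[str, Path]) -> SampleFractions:
            fracs = []
            for label, p in paths.items():
                track = read_bedgraph_track(p, read_grid)
                # bins absent from a count bedGraph are zero-count, not missing
                track.values[~track.valid] = 0.0
                track.valid[:] = True
                fracs.append(FractionCounts(label, track))
            return SampleFractions(fracs, early=inputs.early, late=inputs.late, weights=inputs.weights)

        control = _load_sample(inputs.control_fractions)
        treated = _load_sample(inputs.treated_fractions)

        mappability = None
        if inputs.mappability is not None:
            stage = "mappability"
            mappability = read_bedgraph_track(inputs.mappability, analysis_grid)

        stage = "rt_profile/differential"
        analysis = analyze_condition_pair(control, treated, mappability, config)

        write_bedgraph(analysis.control.el_smoothed, outdir / "rt_control.bedgraph")
        write_bedgraph(analysis.treated.el_smoothed, outdir / "rt_treated.bedgraph")
        if analysis.control.weighted is not None:
            write_bedgraph(analysis.control.weighted, outdir / "weighted_rt_control.bedgraph")
            write_bedgraph(analysis.treated.weighted, outdir / "weighted_rt_treated.bedgraph")
        diff_df = analysis.differential.to_frame()
        write_table(diff_df, outdir / "differential.tsv")
        sig = diff_df[diff_df["significant"]]
        write_bed(
            [(r.chrom, r.start, r.end) for r in sig.itertuples(index=False)],
            outdir / "significant_bins.bed",
        )

        boundary_classes = None
        class_counts = None
        metaplots: dict = {}
        if inputs.control_tads and inputs.treated_tads and inputs.compartments:
            stage = "boundaries"
            ctrl_b = extract_boundaries(read_bed(inputs.control_tads, layout), "control TADs")
            trt_b = extract_boundaries(read_bed(inputs.treated_tads, layout), "treated TADs")
            comp_b = extract_boundaries(read_bed(inputs.compartments, layout), "compartments")
            boundary_classes, counts = classify_boundaries(
                ctrl_b, trt_b, comp_b, tolerance=config.boundary_tolerance
            )
            class_counts = dict(counts)
            write_bed(boundary_classes.to_bed_records(), outdir / "boundary_classes.bed")
            for cls in BOUNDARY_CLASSES:
                subset = boundary_classes.subset_by_class(cls)
                if subset.n_boundaries == 0:
                    continue
                mp = boundary_metaplot(
                    analysis.control.el_smoothed,
                    subset,
                    flank=config.metaplot_flank,
                    orient=config.metaplot_orient,
                )
                metaplots[cls] = mp
                write_table(mp.to_frame(), outdir / f"metaplot_{cls}.tsv")

        feature_tables = None
        feature_sets: dict[str, IntervalSet] = {}
        if inputs.feature_beds:
            stage = "features"
            for name, p in inputs.feature_beds.items():
                feature_sets[name] = read_bed(p, layout)
        if inputs.gene_table is not None:
            stage = "features"
            genes = read_gene_table(inputs.gene_table)
            induced, repressed = select_de_genes(genes)
            feature_sets["induced_genes"] = induced.restrict_to(layout)
            feature_sets["repressed_genes"] = repressed.restrict_to(layout)
        if feature_sets:
            wc, wt = analysis.control.weighted, analysis.treated.weighted
            if wc is None or wt is None:
                wc, wt = analysis.control.el_smoothed, analysis.treated.el_smoothed
            long_df, summary_df = paired_feature_rt(wc, wt, feature_sets)
            write_table(long_df, outdir / "feature_rt.tsv")
            write_table(summary_df, outdir / "feature_rt_summary.tsv")
            feature_tables = (long_df, summary_df)
    except Exception as exc:
        raise ReplitimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    input_paths = {
        "chrom_sizes": inputs.chrom_sizes,
        **{f"control_{k}": v for k, v in inputs.control_fractions.items()},
        **{f"treated_{k}": v for k, v in inputs.treated_fractions.items()},
    }
    for name in ("mappability", "control_tads", "treated_tads", "compartments", "gene_table"):
        p = getattr(inputs, name)
        if p is not None:
            input_paths[name] = p
    input_paths.update({f"feature_{k}": v for k, v in inputs.feature_beds.items()})

    manifest = {
        "replitime_version": __version__,
        "config": config.to_dict(),
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in input_paths.items()},
        "n_included_bins": analysis.differential.n_included,
        "n_significant_bins": analysis.differential.n_significant,
        "median_significant_distance": analysis.median_distance,
        "boundary_class_counts": class_counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        analysis=analysis,
        boundary_classes=boundary_classes,
        class_counts=class_counts,
        metaplots=metaplots,
        feature_tables=feature_tables,
        manifest=manifest,
        outdir=outdir,
    )
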