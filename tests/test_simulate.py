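"""Synthetic-data generator: determinism, calibration of its own knobs,
and agreement between emitted files and recorded truth."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from replitime.boundaries import (
    COMPARTMENT_PROXIMAL,
    INVARIANT,
    SCC1_DEPENDENT,
    classify_boundaries,
)
from replitime.features import select_de_genes
from replitime.genome import GenomeLayout
from replitime.simulate import (
    SimulationSpec,
    _fraction_shares,
    simulate_boundaries,
    simulate_condition_pair,
    simulate_fraction_counts,
    simulate_gene_table,
    simulate_rt_landscape,
    write_simulation,
)
from replitime.tracks import BinnedTrack

SMALL = SimulationSpec(layout=GenomeLayout.from_pairs([("chr1", 5_000_000), ("chr2", 5_000_000)]))


def _hash_dir(paths):
    h = hashlib.sha256()
    for name in sorted(paths):
        h.update(Path(paths[name]).read_bytes())
    return h.hexdigest()


class TestLandscape:
    def test_single_domain_is_constant(self):
        spec = SimulationSpec(
            layout=GenomeLayout.from_pairs([("chr1", 2_000_000)]),
            domain_length_mean=1e9,
        )
        rng = np.random.default_rng(0)
        ls = simulate_rt_landscape(spec, rng)
        assert np.unique(ls.track.values).size == 1
        assert len(ls.domains) == 1

    def test_deterministic_per_seed(self):
        a = simulate_condition_pair(SMALL, seed=5)
        b = simulate_condition_pair(SMALL, seed=5)
        np.testing.assert_array_equal(
            a.control.fractions[0].track.values, b.control.fractions[0].track.values
        )
        np.testing.assert_array_equal(a.truth.shifted_bins, b.truth.shifted_bins)

    def test_domain_rt_sd_matches_spec(self):
        """Empirical sd over ~500 domains is within 10% of the configured sd."""
        spec = SimulationSpec(layout=GenomeLayout.from_pairs([("chr1", 500_000_000)]))
        rng = np.random.default_rng(1)
        ls = simulate_rt_landscape(spec, rng)
        assert len(ls.domains) >= 400
        assert abs(ls.domains["rt"].std() - spec.domain_rt_sd) < 0.1 * spec.domain_rt_sd

    def test_domains_tile_chromosomes(self):
        rng = np.random.default_rng(2)
        ls = simulate_rt_landscape(SMALL, rng)
        for chrom, length in SMALL.layout:
            sub = ls.domains[ls.domains["chrom"] == chrom]
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == length
            assert (sub["start"].iloc[1:].to_numpy() == sub["end"].iloc[:-1].to_numpy()).all()


class TestFractionCounts:
    def test_flat_kernel_limit_gives_zero_el(self):
        """With a very wide capture kernel all fractions share reads equally,
        so the expected E/L log-ratio is ~0 regardless of true RT."""
        spec = SimulationSpec(
            layout=GenomeLayout.from_pairs([("chr1", 5_000_000)]),
            sigma=50.0,
            depth=400.0,
            spike_rate=0.0,
            unmappable_rate=0.0,
        )
        rng = np.random.default_rng(0)
        ls = simulate_rt_landscape(spec, rng)
        sample = simulate_fraction_counts(ls.track, spec, rng)
        from replitime.binning import aggregate_bins
        from replitime.rt import SampleFractions, compute_el_rt

        agg = SampleFractions(
            [aggregate_bins(f) for f in sample.fractions],
            early=sample.early, late=sample.late, weights=sample.weights,
        )
        profile = compute_el_rt(agg)
        assert abs(np.nanmean(profile.values[profile.valid])) < 0.05

    def test_share_monotone_in_true_rt(self):
        """An early locus (+2) claims a larger earliest-fraction share than a
        late one (-2)."""
        spec = SimulationSpec()
        shares = _fraction_shares(np.array([2.0, -2.0]), spec)
        assert shares[0, 0] > shares[0, 1]
        np.testing.assert_allclose(shares.sum(axis=0), 1.0)

    def test_mean_depth_matches_spec(self):
        spec = SimulationSpec(
            layout=GenomeLayout.from_pairs([("chr1", 20_000_000)]),
            spike_rate=0.0,
            unmappable_rate=0.0,
        )
        rng = np.random.default_rng(3)
        ls = simulate_rt_landscape(spec, rng)
        sample = simulate_fraction_counts(ls.track, spec, rng)
        total = sum(f.track.values.sum() for f in sample.fractions)
        n_50kb = spec.analysis_grid.total_bins
        mean_depth = total / (n_50kb * spec.n_fractions)
        se = np.sqrt(spec.depth / (n_50kb * spec.n_fractions))
        assert abs(mean_depth - spec.depth) < 2 * se + 0.5

    def test_synchronized_mode_has_three_fractions(self):
        spec = SimulationSpec(layout=SMALL.layout, n_fractions=3)
        rng = np.random.default_rng(0)
        ls = simulate_rt_landscape(spec, rng)
        sample = simulate_fraction_counts(ls.track, spec, rng)
        assert sample.labels == ["4h", "7h", "10h"]
        assert sample.early == "4h" and sample.late == "10h"
        assert sample.weights == (1.0, 0.5, 0.0)

    def test_spikes_and_unmappable_recorded(self):
        spec = SimulationSpec(layout=SMALL.layout, spike_rate=0.01, unmappable_rate=0.1)
        exp = simulate_condition_pair(spec, seed=7)
        assert exp.truth.unmappable_1kb.any()
        assert (exp.truth.mappability.values < 1.0).any()
        # unmappable 1 kb bins carry no reads
        for frac in exp.control.fractions:
            assert frac.track.values[exp.truth.unmappable_1kb].sum() == 0


class TestConditionPair:
    def test_global_null_has_no_shifted_bins(self):
        exp = simulate_condition_pair(SMALL, seed=1)
        assert not exp.truth.shifted_bins.any()
        np.testing.assert_array_equal(
            exp.truth.true_rt_control.values, exp.truth.true_rt_treated.values
        )

    def test_shift_bookkeeping(self):
        spec = SimulationSpec(n_shifted_domains=2, shift_size=2.0)
        exp = simulate_condition_pair(spec, seed=2)
        assert len(exp.truth.shifted_domains) == 2
        diff = np.abs(
            exp.truth.true_rt_control.values - exp.truth.true_rt_treated.values
        )
        assert diff[exp.truth.shifted_bins].min() >= 0.9 * spec.shift_size
        untouched = ~exp.truth.shifted_bins & ~exp.truth.partial_bins
        np.testing.assert_allclose(diff[untouched], 0.0, atol=1e-12)

    def test_shifted_domains_flip_timing_half(self):
        spec = SimulationSpec(n_shifted_domains=2, shift_size=2.0)
        exp = simulate_condition_pair(spec, seed=2)
        for row in exp.truth.shifted_domains.itertuples(index=False):
            assert row.rt * row.rt_treated < 0  # early<->late switch
            assert abs(row.rt - row.rt_treated) == pytest.approx(spec.shift_size)


class TestBoundaryFiles:
    def test_all_invariant_when_fraction_one(self):
        spec = SimulationSpec(layout=SMALL.layout, fraction_invariant=1.0, boundary_jitter=0)
        rng = np.random.default_rng(0)
        ls = simulate_rt_landscape(spec, rng)
        bounds = simulate_boundaries(ls, spec, rng)
        for cls in bounds.control_boundaries.classes.values():
            assert set(cls) <= {COMPARTMENT_PROXIMAL, INVARIANT}

    def test_all_dependent_when_fraction_zero(self):
        spec = SimulationSpec(layout=SMALL.layout, fraction_invariant=0.0)
        rng = np.random.default_rng(0)
        ls = simulate_rt_landscape(spec, rng)
        bounds = simulate_boundaries(ls, spec, rng)
        for cls in bounds.control_boundaries.classes.values():
            assert set(cls) <= {COMPARTMENT_PROXIMAL, SCC1_DEPENDENT}

    @pytest.mark.parametrize("seed", [3, 11, 27])
    def test_classifier_reproduces_generator_truth(self, seed):
        spec = SimulationSpec()
        rng = np.random.default_rng(seed)
        ls = simulate_rt_landscape(spec, rng)
        bounds = simulate_boundaries(ls, spec, rng)
        classified, counts = classify_boundaries(
            bounds.control_boundaries,
            bounds.treated_boundaries,
            bounds.compartments,
            tolerance=spec.boundary_tolerance,
        )
        for chrom, truth_cls in bounds.control_boundaries.classes.items():
            assert (classified.classes[chrom] == truth_cls).all()
        assert sum(counts.values()) == bounds.control_boundaries.n_boundaries

    def test_extracted_domain_boundaries_match_positions(self):
        spec = SimulationSpec()
        rng = np.random.default_rng(5)
        ls = simulate_rt_landscape(spec, rng)
        bounds = simulate_boundaries(ls, spec, rng)
        from replitime.boundaries import extract_boundaries

        extracted = extract_boundaries(bounds.control_domains)
        for chrom, pos in bounds.control_boundaries.positions.items():
            np.testing.assert_array_equal(extracted.positions[chrom], pos)


class TestGeneTable:
    def test_truth_labels_match_selection_rule(self):
        spec = SimulationSpec()
        table, truth = simulate_gene_table(spec, np.random.default_rng(0))
        induced, repressed = select_de_genes(table)
        assert set(induced.frame["name"]) == set(truth.loc[truth["true_class"] == "induced", "gene_id"])
        assert set(repressed.frame["name"]) == set(truth.loc[truth["true_class"] == "repressed", "gene_id"])


class TestEmittedFiles:
    def test_write_simulation_deterministic(self, tmp_path):
        spec = SimulationSpec(layout=SMALL.layout, n_shifted_domains=1)
        hashes = []
        for sub in ("a", "b"):
            exp = simulate_condition_pair(spec, seed=9)
            rng = np.random.default_rng(9)
            bounds = simulate_boundaries(exp.landscape, spec, rng)
            genes = simulate_gene_table(spec, rng)
            paths = write_simulation(tmp_path / sub, exp, bounds, genes)
            hashes.append(_hash_dir(paths))
        assert hashes[0] == hashes[1]

    def test_truth_aligns_with_emitted_tracks(self, tmp_path):
        from replitime.io import read_bedgraph_track

        spec = SimulationSpec(layout=SMALL.layout)
        exp = simulate_condition_pair(spec, seed=4)
        paths = write_simulation(tmp_path, exp)
        back = read_bedgraph_track(paths["true_rt_control"], spec.analysis_grid)
        np.testing.assert_allclose(
            back.values, exp.truth.true_rt_control.values, rtol=1e-11
        )
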