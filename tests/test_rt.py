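"""E/L RT computation, quantile normalization, loess smoothing, weighted RT."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from replitime.binning import FractionCounts
from replitime.errors import ReplitimeError
from replitime.genome import BinGrid, GenomeLayout
from replitime.rt import (
    SampleFractions,
    compute_el_rt,
    loess_smooth,
    profile_correlation,
    quantile_normalize,
    weighted_rt,
)

from .conftest import make_profile, make_track


def sample_from_counts(grid, early, late, labels=("S1", "S3"), weights=None):
    fracs = [
        FractionCounts(labels[0], make_track(grid, early)),
        FractionCounts(labels[1], make_track(grid, late)),
    ]
    return SampleFractions(fracs, early=labels[0], late=labels[1], weights=weights)


class TestSampleFractions:
    def test_requires_two_fractions(self, grid_50kb):
        with pytest.raises(ReplitimeError):
            SampleFractions(
                [FractionCounts("S1", make_track(grid_50kb, np.zeros(20)))],
                early="S1",
                late="S1",
            )

    def test_unknown_role_label_rejected(self, grid_50kb):
        fr = [
            FractionCounts("S1", make_track(grid_50kb, np.zeros(20))),
            FractionCounts("S2", make_track(grid_50kb, np.zeros(20))),
        ]
        with pytest.raises(ReplitimeError, match="late"):
            SampleFractions(fr, early="S1", late="S9")

    def test_weights_must_decrease(self, grid_50kb):
        fr = [
            FractionCounts("S1", make_track(grid_50kb, np.zeros(20))),
            FractionCounts("S2", make_track(grid_50kb, np.zeros(20))),
        ]
        with pytest.raises(ReplitimeError, match="decreasing"):
            SampleFractions(fr, early="S1", late="S2", weights=(0.5, 1.0))


class TestComputeElRt:
    def test_equal_counts_give_zero(self, grid_50kb):
        sample = sample_from_counts(grid_50kb, np.full(20, 200.0), np.full(20, 200.0))
        profile = compute_el_rt(sample)
        assert profile.valid.all()
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-12)

    def test_twofold_ratio_is_one(self, grid_50kb):
        """Early 200, late 100 at equal library sizes -> rt = log2(2) = 1."""
        sample = sample_from_counts(grid_50kb, np.full(20, 200.0), np.full(20, 100.0))
        profile = compute_el_rt(sample, rpm_normalize=False)
        np.testing.assert_allclose(profile.values, 1.0)

    def test_rpm_normalization_removes_library_size(self, grid_50kb):
        """A 10x deeper late library does not bias the ratio under RPM scaling."""
        sample = sample_from_counts(grid_50kb, np.full(20, 200.0), np.full(20, 2000.0))
        profile = compute_el_rt(sample)
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-12)

    def test_zero_count_bins_invalid(self, grid_50kb):
        early = np.full(20, 100.0)
        late = np.full(20, 100.0)
        early[3] = 0.0
        late[7] = 0.0
        profile = compute_el_rt(sample_from_counts(grid_50kb, early, late), min_count=0)
        assert not profile.valid[3] and not profile.valid[7]
        assert profile.valid.sum() == 18

    def test_min_count_floor(self, grid_50kb):
        early = np.full(20, 100.0)
        early[4] = 9.0
        profile = compute_el_rt(sample_from_counts(grid_50kb, early, np.full(20, 100.0)))
        assert not profile.valid[4]

    def test_pseudocount_mode_keeps_zero_bins(self, grid_50kb):
        early = np.full(20, 100.0)
        early[3] = 0.0
        profile = compute_el_rt(
            sample_from_counts(grid_50kb, early, np.full(20, 100.0)),
            min_count=0,
            pseudocount=0.5,
            rpm_normalize=False,
        )
        assert profile.valid[3]
        assert profile.values[3] == pytest.approx(np.log2(0.5 / 100.5))

    def test_mismatched_grids_rejected(self, grid_50kb):
        other = BinGrid(grid_50kb.layout, 25_000)
        fracs = [
            FractionCounts("S1", make_track(grid_50kb, np.full(20, 100.0))),
            FractionCounts("S3", make_track(other, np.full(40, 100.0))),
        ]
        with pytest.raises(ReplitimeError):
            SampleFractions(fracs, early="S1", late="S3")


class TestQuantileNormalize:
    def test_identical_profiles_unchanged(self, grid_50kb):
        values = np.linspace(-1, 1, 20)
        a = make_profile(grid_50kb, values)
        b = make_profile(grid_50kb, values.copy())
        na, nb = quantile_normalize([a, b])
        np.testing.assert_allclose(na.values, values)
        np.testing.assert_allclose(nb.values, values)

    def test_rank_mean_example(self):
        """(1,2,3) and (4,6,8) both become (2.5, 4, 5.5)."""
        grid = BinGrid(GenomeLayout.from_pairs([("chr1", 150_000)]), 50_000)
        a = make_profile(grid, [1.0, 2.0, 3.0])
        b = make_profile(grid, [4.0, 6.0, 8.0])
        na, nb = quantile_normalize([a, b])
        np.testing.assert_allclose(na.values, [2.5, 4.0, 5.5])
        np.testing.assert_allclose(nb.values, [2.5, 4.0, 5.5])

    def test_ties_get_mean_of_targets(self):
        grid = BinGrid(GenomeLayout.from_pairs([("chr1", 150_000)]), 50_000)
        a = make_profile(grid, [1.0, 1.0, 2.0])
        b = make_profile(grid, [3.0, 4.0, 5.0])
        na, _ = quantile_normalize([a, b])
        # targets are (2, 2.5, 3.5); the tied pair shares (2 + 2.5)/2
        np.testing.assert_allclose(na.values, [2.25, 2.25, 3.5])

    def test_fewer_than_two_profiles_rejected(self, grid_50kb):
        with pytest.raises(ReplitimeError):
            quantile_normalize([make_profile(grid_50kb, np.zeros(20))])

    @given(st.integers(0, 2**31 - 1))
    def test_sorted_vectors_equalized(self, seed):
        """After normalization all profiles share one sorted value vector."""
        rng = np.random.default_rng(seed)
        grid = BinGrid(GenomeLayout.from_pairs([("chr1", 2_000_000)]), 50_000)
        profiles = [
            make_profile(grid, rng.normal(loc=rng.normal(), size=40)) for _ in range(3)
        ]
        normed = quantile_normalize(profiles)
        ref = np.sort(normed[0].values[normed[0].valid])
        for p in normed[1:]:
            np.testing.assert_allclose(np.sort(p.values[p.valid]), ref, rtol=1e-10)

    def test_restricted_to_shared_bins(self, grid_50kb):
        a = make_profile(grid_50kb, np.arange(20.0))
        b = make_profile(grid_50kb, np.arange(20.0)[::-1].copy())
        b.valid[5] = False
        na, nb = quantile_normalize([a, b])
        assert not na.valid[5] and not nb.valid[5]


class TestLoessSmooth:
    def test_constant_profile_reproduced(self, grid_50kb):
        profile = make_profile(grid_50kb, np.full(20, 1.25))
        out = loess_smooth(profile)
        np.testing.assert_allclose(out.values, 1.25, atol=1e-12)

    def test_linear_profile_reproduced(self):
        """Local linear fits are exact on linear data (within 1e-9)."""
        grid = BinGrid(GenomeLayout.from_pairs([("chr1", 5_000_000)]), 50_000)
        x = grid.bin_centers("chr1")
        profile = make_profile(grid, 0.3 + 4e-7 * x)
        out = loess_smooth(profile, span=300_000)
        np.testing.assert_allclose(out.values, profile.values, atol=1e-9)

    def test_invalid_bins_stay_invalid(self, grid_50kb):
        values = np.random.default_rng(0).normal(size=20)
        valid = np.ones(20, dtype=bool)
        valid[8] = False
        out = loess_smooth(make_profile(grid_50kb, values, valid))
        assert not out.valid[8]

    def test_span_below_three_bins_rejected(self, grid_50kb):
        with pytest.raises(ReplitimeError):
            loess_smooth(make_profile(grid_50kb, np.zeros(20)), span=100_000)

    def test_total_variation_reduced(self):
        """Smoothing does not increase sum |delta rt| on noisy profiles."""
        grid = BinGrid(GenomeLayout.from_pairs([("chr1", 10_000_000)]), 50_000)
        rng = np.random.default_rng(11)
        profile = make_profile(grid, rng.normal(size=grid.total_bins))
        out = loess_smooth(profile)
        tv = lambda v: np.abs(np.diff(v)).sum()
        assert tv(out.values) <= tv(profile.values)

    def test_min_support_invalidates_sparse_windows(self, grid_50kb):
        values = np.zeros(20)
        valid = np.zeros(20, dtype=bool)
        valid[[0, 10]] = True  # two isolated bins, no in-window neighbours
        out = loess_smooth(make_profile(grid_50kb, values, valid), min_support=5)
        assert not out.valid[[0, 10]].any()
        # default keeps them via pass-through
        out2 = loess_smooth(make_profile(grid_50kb, values, valid))
        assert out2.valid[[0, 10]].all()


class TestWeightedRt:
    def make_sample(self, grid, count_rows, weights=(1.0, 2 / 3, 1 / 3, 0.0)):
        fracs = [
            FractionCounts(f"S{i+1}", make_track(grid, row))
            for i, row in enumerate(count_rows)
        ]
        return SampleFractions(fracs, early="S1", late="S3", weights=weights)

    def test_all_reads_in_earliest_fraction(self, grid_50kb):
        rows = [np.full(20, 50.0)] + [np.zeros(20)] * 3
        wrt = weighted_rt(self.make_sample(grid_50kb, rows))
        np.testing.assert_allclose(wrt.values[wrt.valid], 1.0)

    def test_equal_fractions_give_mean_weight(self, grid_50kb):
        rows = [np.full(20, 40.0)] * 4
        wrt = weighted_rt(self.make_sample(grid_50kb, rows))
        np.testing.assert_allclose(wrt.values, 0.5)  # mean of (1, 2/3, 1/3, 0)

    def test_library_size_invariance(self, grid_50kb):
        rng = np.random.default_rng(5)
        rows = [rng.poisson(30, 20).astype(float) + 1 for _ in range(4)]
        base = weighted_rt(self.make_sample(grid_50kb, rows))
        scaled_rows = [r * s for r, s in zip(rows, (3.0, 0.5, 7.0, 1.1))]
        scaled = weighted_rt(self.make_sample(grid_50kb, scaled_rows))
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-12)

    def test_weight_count_mismatch_rejected(self, grid_50kb):
        rows = [np.full(20, 1.0)] * 3
        with pytest.raises(ReplitimeError):
            self.make_sample(grid_50kb, rows, weights=(1.0, 2 / 3, 1 / 3, 0.0))


class TestProfileCorrelation:
    def test_self_correlation_is_one(self, grid_50kb):
        p = make_profile(grid_50kb, np.random.default_rng(1).normal(size=20))
        assert profile_correlation(p, p) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, grid_50kb):
        v = np.random.default_rng(2).normal(size=20)
        a = make_profile(grid_50kb, v)
        b = make_profile(grid_50kb, -v)
        assert profile_correlation(a, b) == pytest.approx(-1.0)

    def test_perfect_linear_relation(self):
        grid = BinGrid(GenomeLayout.from_pairs([("chr1", 200_000)]), 50_000)
        a = make_profile(grid, [1.0, 2.0, 3.0, 4.0])
        b = make_profile(grid, [2.0, 4.0, 6.0, 8.0])
        assert profile_correlation(a, b) == pytest.approx(1.0)

    def test_too_few_shared_bins_rejected(self, grid_50kb):
        a = make_profile(grid_50kb, np.zeros(20))
        b = make_profile(grid_50kb, np.zeros(20))
        a.valid[:] = False
        a.valid[:2] = True
        with pytest.raises(ReplitimeError):
            profile_correlation(a, b)


class TestSignConvention:
    def test_early_bins_have_positive_rt(self):
        """On synthetic data with known timing, early loci get rt > 0."""
        from replitime.simulate import SimulationSpec, simulate_fraction_counts
        from replitime.tracks import BinnedTrack

        spec = SimulationSpec(depth=200.0)
        grid = spec.grid
        rng = np.random.default_rng(0)
        true_rt = np.where(np.arange(grid.total_bins) < grid.total_bins // 2, 1.5, -1.5)
        sample = simulate_fraction_counts(
            BinnedTrack(grid, true_rt, np.ones(grid.total_bins, bool)), spec, rng
        )
        from replitime.binning import aggregate_bins

        agg = SampleFractions(
            [aggregate_bins(f) for f in sample.fractions],
            early=sample.early,
            late=sample.late,
            weights=sample.weights,
        )
        profile = compute_el_rt(agg)
        half = profile.grid.total_bins // 2
        assert np.nanmean(profile.values[:half][profile.valid[:half]]) > 0
        assert np.nanmean(profile.values[half:][profile.valid[half:]]) < 0
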