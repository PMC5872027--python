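"""Gaussian-copula joint-rank sampling and Monte-Carlo power estimation."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from neuronspan import (
    PowerTargetError,
    correlation_grid,
    detection_threshold,
    multi_neuron_power_at,
    power_at,
    power_curve,
    sample_joint_ranks,
    spearman_to_pearson,
    synthesize_survival_groups,
)
from neuronspan.power import PowerCurve, PowerPoint, GroupBand

try:
    from hypothesis import given, settings, strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


class TestSpearmanToPearson:
    @pytest.mark.parametrize("rho,r", [(0.0, 0.0), (1.0, 1.0), (-1.0, -1.0),
                                       (0.5, 2 * math.sin(math.pi / 12))])
    def test_closed_form_points(self, rho, r):
        assert spearman_to_pearson(rho) == pytest.approx(r)

    def test_odd_and_increasing(self):
        xs = np.linspace(-1, 1, 41)
        ys = [spearman_to_pearson(x) for x in xs]
        assert np.all(np.diff(ys) > 0)
        for x in xs:
            assert spearman_to_pearson(-x) == pytest.approx(-spearman_to_pearson(x))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            spearman_to_pearson(1.2)


class TestSampleJointRanks:
    def test_lowest_neuronspan_ranks_labeled_absent(self):
        s = sample_joint_ranks(5, 0.3, 2, seed=0)
        assert sorted(s.neuronspan_rank[s.absent]) == [1, 2]
        assert s.absent.sum() == 2

    def test_ranks_are_permutations(self):
        s = sample_joint_ranks(100, -0.4, 30, seed=1)
        assert sorted(s.lifespan_rank) == list(range(1, 101))
        assert sorted(s.neuronspan_rank) == list(range(1, 101))

    def test_independence_at_zero(self):
        s = sample_joint_ranks(10_000, 0.0, 1000, seed=2)
        r, _ = sps.spearmanr(s.lifespan_rank, s.neuronspan_rank)
        assert abs(r) < 0.03

    def test_target_spearman_recovered(self):
        s = sample_joint_ranks(100_000, 0.5, 1000, seed=3)
        r, _ = sps.spearmanr(s.lifespan_rank, s.neuronspan_rank)
        assert r == pytest.approx(0.5, abs=0.01)

    def test_positive_coupling_orders_group_means(self):
        """Strong positive dependence: animals losing the neuron early (absent)
        have stochastically lower lifespan ranks."""
        s = sample_joint_ranks(10_000, 0.9, 2000, seed=4)
        assert s.lifespan_rank[s.absent].mean() < s.lifespan_rank[~s.absent].mean()

    @pytest.mark.parametrize("k", [0, 10])
    def test_k_absent_bounds(self, k):
        with pytest.raises(ValueError):
            sample_joint_ranks(10, 0.0, k, seed=0)


class TestSynthesizeGroups:
    def test_rank_lookup_example(self):
        s = sample_joint_ranks(4, 0.0, 2, seed=7)
        absent, present = synthesize_survival_groups(s, [8, 6, 5, 7])
        expected_absent = np.sort(np.array([5, 6, 7, 8]))[s.lifespan_rank[s.absent] - 1]
        np.testing.assert_array_equal(np.sort(absent), np.sort(expected_absent))

    def test_multiset_conservation(self, day_lifespans):
        s = sample_joint_ranks(day_lifespans.size, 0.4, 150, seed=8)
        absent, present = synthesize_survival_groups(s, day_lifespans)
        union = np.sort(np.concatenate([absent, present]))
        np.testing.assert_array_equal(union, np.sort(day_lifespans))

    def test_tied_degenerate_marginal(self):
        s = sample_joint_ranks(4, 0.9, 2, seed=9)
        absent, present = synthesize_survival_groups(s, [3, 3, 3, 3])
        assert set(absent) == set(present) == {3.0}

    def test_size_mismatch(self):
        s = sample_joint_ranks(5, 0.0, 2, seed=0)
        with pytest.raises(ValueError):
            synthesize_survival_groups(s, [1, 2, 3])

    if HAVE_HYPOTHESIS:

        @given(st.lists(st.integers(1, 30), min_size=5, max_size=40),
               st.integers(0, 10_000))
        @settings(max_examples=40, deadline=None, derandomize=True)
        def test_conservation_property(self, lifespans, seed):
            n = len(lifespans)
            s = sample_joint_ranks(n, 0.2, max(1, n // 3), seed=seed)
            absent, present = synthesize_survival_groups(s, lifespans)
            assert sorted(np.concatenate([absent, present])) == sorted(
                float(x) for x in lifespans
            )


class TestCorrelationGrid:
    def test_three_point_grid(self):
        np.testing.assert_allclose(correlation_grid(3, 0.5), [-0.5, 0.0, 0.5])

    def test_densification_near_zero(self):
        g = correlation_grid(21, 0.5)
        gaps = np.diff(g)
        assert gaps[len(gaps) // 2] < gaps[-1]
        assert np.all(gaps > 0)

    @pytest.mark.parametrize("n,contains_zero", [(5, True), (6, False), (75, True)])
    def test_zero_membership(self, n, contains_zero):
        assert (0.0 in correlation_grid(n, 0.5)) == contains_zero

    def test_default_size(self):
        assert correlation_grid().size == 75


class TestPowerAt:
    def test_type_one_error_at_zero_coupling(self, day_lifespans):
        """At rho=0 the 'power' is the type-I error rate, ~ alpha."""
        pt = power_at(day_lifespans[:500], 100, 0.0, replicates=1000, seed=10)
        assert 0.035 <= pt.power <= 0.07

    def test_perfect_coupling_full_power(self, day_lifespans):
        """|rho|=1 separates the rank space completely: every replicate
        detects the group difference."""
        pt = power_at(day_lifespans[:500], 100, 1.0, replicates=100, seed=11)
        assert pt.power == 1.0

    def test_bands_overlap_marginal_mean_at_zero(self, day_lifespans):
        pool = day_lifespans[:500].astype(float)
        pt = power_at(pool, 100, 0.0, replicates=400, seed=12)
        for band in pt.group_means.values():
            assert band.lower <= pool.mean() <= band.upper

    def test_deterministic_given_seed(self, day_lifespans):
        a = power_at(day_lifespans, 150, 0.2, replicates=50, seed=13)
        b = power_at(day_lifespans, 150, 0.2, replicates=50, seed=13)
        assert a == b


class TestPowerCurve:
    def test_sign_symmetry(self, day_lifespans):
        curve = power_curve(day_lifespans, 200, [-0.3, 0.0, 0.3],
                            replicates=300, seed=14)
        p = curve.powers()
        assert p[0] == pytest.approx(p[2], abs=0.08)

    def test_monotone_in_magnitude(self, day_lifespans):
        """Power is nondecreasing in |rho| up to Monte-Carlo error: the
        isotonic-regression residual stays below 0.05."""
        from sklearn.isotonic import IsotonicRegression

        grid = np.linspace(0.0, 0.25, 6)
        curve = power_curve(day_lifespans, 200, grid, replicates=300, seed=15)
        iso = IsotonicRegression(increasing=True).fit(grid, curve.powers())
        assert np.max(np.abs(iso.predict(grid) - curve.powers())) < 0.05

    def test_single_replicate_powers_are_binary(self, day_lifespans):
        curve = power_curve(day_lifespans, 200, [0.0, 0.2], replicates=1, seed=16)
        assert set(curve.powers()) <= {0.0, 1.0}

    def test_rank_invariance_under_monotone_marginal_transform(self, day_lifespans):
        """The whole engine is rank-based: strictly increasing transforms of
        the empirical lifespans (fixed ties) leave the powers unchanged."""
        grid = [0.0, 0.15]
        a = power_curve(day_lifespans, 150, grid, replicates=200, seed=17)
        transformed = day_lifespans.astype(float) ** 2 + 3.0
        b = power_curve(transformed, 150, grid, replicates=200, seed=17)
        np.testing.assert_array_equal(a.powers(), b.powers())

    def test_power_nondecreasing_in_n(self, wt_gompertz):
        """Paired-seed comparison: a larger cohort at the same k/n ratio has
        at least as much power."""
        from neuronspan import discretize_to_days, sample_lifespans

        small = discretize_to_days(sample_lifespans(wt_gompertz, 400, seed=18))
        large = discretize_to_days(sample_lifespans(wt_gompertz, 1600, seed=18))
        p_small = power_at(small, 80, 0.15, replicates=400, seed=19).power
        p_large = power_at(large, 320, 0.15, replicates=400, seed=19).power
        assert p_large >= p_small

    def test_bad_grid_rejected(self, day_lifespans):
        with pytest.raises(ValueError):
            power_curve(day_lifespans, 100, [0.3, 0.1], replicates=10, seed=0)


class TestMultiNeuron:
    def test_single_neuron_reduces_to_power_at(self, day_lifespans):
        a = power_at(day_lifespans, 150, 0.2, replicates=100, seed=20)
        b = multi_neuron_power_at(day_lifespans, [150], 0.2, replicates=100, seed=20)
        assert a.power == b.power

    def test_union_rate_bounds_at_zero(self, day_lifespans):
        """Four tests at alpha=0.05 each: union rejection rate must lie in
        [alpha, 4 alpha] (inclusion and Bonferroni bounds) up to MC error."""
        pt = multi_neuron_power_at(day_lifespans[:500], [35, 35, 150, 150], 0.0,
                                   replicates=1000, seed=21)
        assert 0.05 - 0.02 <= pt.power <= 0.20 + 0.035

    def test_union_power_dominates_single(self, day_lifespans):
        ks = [35, 35, 150, 150]
        union = multi_neuron_power_at(day_lifespans[:500], ks, 0.12,
                                      replicates=600, seed=22).power
        singles = [power_at(day_lifespans[:500], k, 0.12, replicates=600,
                            seed=22).power for k in ks]
        assert union >= max(singles) - 0.04

    def test_too_many_neurons(self, day_lifespans):
        with pytest.raises(ValueError):
            multi_neuron_power_at(day_lifespans, [10] * 5, 0.1, replicates=5, seed=0)


class TestDetectionThreshold:
    def _curve(self, grid, powers, n=100):
        points = [
            PowerPoint(rho_s=r, power=p, replicates=1000, alpha=0.05, n=n,
                       group_means={"absent": GroupBand(5.0, 4.0, 6.0)})
            for r, p in zip(grid, powers)
        ]
        return PowerCurve(points=points, grid=np.asarray(grid, float),
                          replicates=1000, alpha=0.05, n=n, k_absent=(10,), seed=0)

    def test_linear_interpolation_arithmetic(self):
        curve = self._curve([0.1, 0.2], [0.50, 0.96])
        expected = 0.1 + (0.95 - 0.50) / (0.96 - 0.50) * 0.1
        assert detection_threshold(curve, 0.95) == pytest.approx(expected)

    def test_target_reached_everywhere_returns_smallest_magnitude(self):
        curve = self._curve([0.05, 0.1, 0.2], [0.97, 0.98, 1.0])
        assert detection_threshold(curve, 0.95) == pytest.approx(0.05)

    def test_target_never_reached_raises(self):
        curve = self._curve([0.1, 0.2], [0.2, 0.6])
        with pytest.raises(PowerTargetError, match="0.6"):
            detection_threshold(curve, 0.95)

    def test_symmetric_grid_collapses_to_magnitude(self):
        curve = self._curve([-0.2, -0.1, 0.0, 0.1, 0.2],
                            [0.98, 0.5, 0.05, 0.6, 0.96])
        thr = detection_threshold(curve, 0.95)
        assert 0.1 < thr <= 0.2

    def test_isotonic_smoothing_tames_noise(self):
        """A small non-monotone dip does not derail the crossing estimate."""
        curve = self._curve([0.05, 0.1, 0.15, 0.2], [0.3, 0.92, 0.90, 0.99])
        thr = detection_threshold(curve, 0.95)
        assert 0.15 < thr <= 0.2
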