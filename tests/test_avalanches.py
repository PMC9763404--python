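import numpy as np
import pytest

from wc2d.avalanches import (AvalancheSet, extract_avalanches, fit_gamma,
                             fit_powerlaw_tail, mean_size_vs_duration, pool,
                             sample_truncated_powerlaw, scaling_relation_check,
                             shape_collapse, size_duration_distributions,
                             sliding_window_gamma, synthetic_crackling)


def rle_oracle(row):
    """Brute-force run-length extraction with boundary censoring."""
    out = []
    cur = None
    for i, c in enumerate(row):
        if c > 0:
            if cur is None:
                cur = [i, 0, 0]
            cur[1] += c
            cur[2] += 1
        else:
            if cur is not None:
                if cur[0] > 0:
                    out.append((cur[1], cur[2]))
                cur = None
    # a trailing run touches the boundary: censored, dropped
    return out


class TestExtraction:
    def test_forced_example(self):
        av = extract_avalanches(np.array([[0, 2, 1, 0, 0, 3, 0]]), delta=1.0)
        assert sorted(zip(av.sizes, av.durations)) == [(3, 1), (3, 2)]

    def test_all_zero_trace_is_empty(self):
        av = extract_avalanches(np.zeros((3, 50), dtype=int))
        assert len(av) == 0

    def test_boundary_runs_discarded(self):
        av = extract_avalanches(np.array([[1, 1, 0, 2, 0, 0, 3]]))
        assert list(av.sizes) == [2]
        assert list(av.durations) == [1]

    def test_matches_rle_oracle_on_random_trace(self, rng):
        row = rng.binomial(1, 0.5, size=10_000)
        av = extract_avalanches(row[None, :])
        expected = rle_oracle(row)
        got = list(zip(av.sizes, av.durations))
        assert got == expected

    def test_profiles_consistent_with_sizes(self, rng):
        counts = rng.poisson(0.7, size=(4, 500))
        av = extract_avalanches(counts)
        for i in range(len(av)):
            prof = av.profile(i)
            assert prof.sum() == av.sizes[i]
            assert prof.size == av.durations[i]
            assert prof.min() >= 1

    def test_total_spikes_conserved_up_to_boundary_runs(self, rng):
        counts = rng.poisson(0.5, size=(6, 2000))
        av = extract_avalanches(counts)
        boundary = 0
        for row in counts:
            starts, ends = [], []
            active = np.concatenate(([0], (row > 0).astype(int), [0]))
            d = np.diff(active)
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for s, e in zip(starts, ends):
                if s == 0 or e == row.size:
                    boundary += row[s:e].sum()
        assert av.sizes.sum() == counts.sum() - boundary

    def test_site_permutation_invariance(self, rng):
        counts = rng.poisson(0.6, size=(5, 300))
        a = extract_avalanches(counts)
        b = extract_avalanches(counts[::-1])
        assert sorted(a.sizes) == sorted(b.sizes)
        assert sorted(a.durations) == sorted(b.durations)

    def test_pooling_is_order_independent(self, rng):
        sets = [extract_avalanches(rng.poisson(0.5, size=(2, 200)))
                for _ in range(3)]
        ab = pool(sets)
        ba = pool(sets[::-1])
        assert sorted(ab.sizes) == sorted(ba.sizes)
        assert ab.n_sites == ba.n_sites


class TestDistributions:
    def test_single_avalanche_point_mass(self):
        av = AvalancheSet(sizes=np.array([7]), durations=np.array([3]),
                          delta=1.0)
        ps, pt = size_duration_distributions(av)
        assert (ps.density * ps.widths).sum() == pytest.approx(1.0)
        assert (pt.density * pt.widths).sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("bins_per_decade", [5, 10, 20])
    def test_normalization_invariant_under_binning(self, rng, bins_per_decade):
        sizes = sample_truncated_powerlaw(rng, 1.5, 1, 1e4, 20_000)
        av = AvalancheSet(sizes=sizes, durations=np.ones(sizes.size, int),
                          delta=1.0)
        ps, _ = size_duration_distributions(av, bins_per_decade=bins_per_decade)
        assert (ps.density * ps.widths).sum() == pytest.approx(1.0, abs=1e-10)

    def test_empty_set_rejected(self):
        av = AvalancheSet(sizes=np.zeros(0, int), durations=np.zeros(0, int),
                          delta=1.0)
        with pytest.raises(ValueError):
            size_duration_distributions(av)


class TestPowerlawMLE:
    @pytest.mark.parametrize("exponent", [1.3, 1.5, 2.0])
    def test_round_trip_recovers_planted_exponent(self, exponent):
        rng = np.random.default_rng(int(exponent * 100))
        x = sample_truncated_powerlaw(rng, exponent, 1.0, 1e5, 100_000)
        fit = fit_powerlaw_tail(x, (1.0, 1e5))
        assert fit.exponent == pytest.approx(exponent, abs=0.02)
        assert fit.stderr < 0.02

    def test_scale_invariance(self, rng):
        x = sample_truncated_powerlaw(rng, 1.7, 1.0, 1e3, 5000)
        f1 = fit_powerlaw_tail(x, (1.0, 1e3))
        f2 = fit_powerlaw_tail(1000.0 * x, (1e3, 1e6))
        assert f2.exponent == pytest.approx(f1.exponent, rel=1e-6)

    def test_agrees_with_grid_likelihood_oracle(self, rng):
        """MLE within 2 SE of a brute-force grid maximization."""
        x = sample_truncated_powerlaw(rng, 1.8, 2.0, 500.0, 1000)
        fit = fit_powerlaw_tail(x, (2.0, 500.0))
        grid = np.linspace(1.0, 3.0, 4001)
        lo, hi = 2.0, 500.0

        def loglik(a):
            if abs(a - 1.0) < 1e-12:
                z = np.log(hi / lo)
            else:
                z = (lo ** (1 - a) - hi ** (1 - a)) / (a - 1)
            return -a * np.log(x).sum() - x.size * np.log(z)

        best = grid[np.argmax([loglik(a) for a in grid])]
        assert abs(fit.exponent - best) < max(2 * fit.stderr, 1e-3)

    def test_too_few_samples_error_carries_count(self):
        with pytest.raises(ValueError, match="37"):
            fit_powerlaw_tail(np.linspace(1, 10, 37), (0.5, 20))


class TestMeanSizeVsDuration:
    def test_identical_avalanches_flat_curve(self):
        av = AvalancheSet(sizes=np.full(50, 40), durations=np.full(50, 4),
                          delta=1.0)
        T, S, n = mean_size_vs_duration(av)
        assert list(T) == [4.0]
        assert list(S) == [40.0]

    def test_exact_quadratic_scaling(self):
        d = np.arange(1, 80)
        av = AvalancheSet(sizes=d ** 2, durations=d, delta=1.0)
        curve = mean_size_vs_duration(av)
        fit = fit_gamma(curve, (1.0, 79.0))
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)

    def test_synthetic_crackling_round_trip(self):
        """Generator with planted tau/gamma: all three exponents recovered."""
        rng = np.random.default_rng(99)
        tau, gamma = 1.8, 1.5
        av = synthetic_crackling(rng, 200_000, tau=tau, gamma=gamma,
                                 t_range=(2, 3000), amplitude=30.0)
        tfit = fit_powerlaw_tail(av.durations_ms, (5, 1000))
        assert tfit.exponent == pytest.approx(tau, abs=0.05)
        curve = mean_size_vs_duration(av)
        gfit = fit_gamma(curve, (5, 1000))
        assert gfit.exponent == pytest.approx(gamma, abs=0.05)
        alpha_planted = 1 + (tau - 1) / gamma
        afit = fit_powerlaw_tail(av.sizes,
                                 (np.interp(5, curve[0], curve[1]),
                                  np.interp(1000, curve[0], curve[1])))
        assert afit.exponent == pytest.approx(alpha_planted, abs=0.05)


class TestSlidingWindowGamma:
    def test_pure_power_law_constant(self):
        T = np.geomspace(1, 1e4, 200)
        S = 3.0 * T ** 1.4
        anchors, g = sliding_window_gamma((T, S))
        assert np.allclose(g, 1.4, atol=1e-10)

    def test_piecewise_power_law_plateaus(self):
        T = np.geomspace(1, 1e6, 400)
        S = np.where(T < 1e3, T ** 2.0, 1e3 ** 0.7 * T ** 1.3)
        anchors, g = sliding_window_gamma((T, S))
        small = g[anchors < 1e2]
        large = g[(anchors > 1e3) & (anchors < 1e5)]
        assert np.allclose(small, 2.0, atol=0.01)
        assert np.allclose(large, 1.3, atol=0.01)

    def test_unit_invariance_of_window(self):
        T = np.geomspace(1, 1e4, 100)
        S = T ** 1.7
        a1, g1 = sliding_window_gamma((T, S))
        a2, g2 = sliding_window_gamma((T * 0.5, S))   # T in different units
        assert np.allclose(g1, g2)


class TestScalingRelation:
    def test_branching_class_exact(self):
        from wc2d.avalanches import ExponentFit
        mk = lambda e, s: ExponentFit(e, s, 1, 10, "MLE", 1000)
        rep = scaling_relation_check(mk(1.5, 0.01), mk(2.0, 0.01),
                                     mk(2.0, 0.01))
        assert rep.gamma_predicted == pytest.approx(2.0)
        assert rep.deviation_se_units == pytest.approx(0.0, abs=1e-9)

    def test_reference_arithmetic(self):
        from wc2d.avalanches import ExponentFit
        mk = lambda e, s: ExponentFit(e, s, 1, 10, "MLE", 1000)
        rep = scaling_relation_check(mk(1.48, 0.01), mk(2.05, 0.01),
                                     mk(2.04, 0.01))
        assert rep.gamma_predicted == pytest.approx((2.05 - 1) / (1.48 - 1),
                                                    rel=1e-12)

    def test_alpha_at_most_one_flagged(self):
        from wc2d.avalanches import ExponentFit
        mk = lambda e, s: ExponentFit(e, s, 1, 10, "MLE", 1000)
        with pytest.raises(ArithmeticError):
            scaling_relation_check(mk(1.0, 0.01), mk(2.0, 0.01), mk(2.0, 0.01))


class TestShapeCollapse:
    def test_single_band_zero_error(self):
        rng = np.random.default_rng(1)
        av = synthetic_crackling(rng, 3000, tau=1.5, gamma=2.0,
                                 t_range=(50, 70))
        grid, curves, err, bands = shape_collapse(av, 2.0, [60.0])
        assert err == 0.0
        assert curves.shape[0] == 1

    def test_exact_scaling_family_minimized_at_planted_gamma(self):
        """Deterministic V(t)=T^{gamma-1} g(t/T): error ~0 at gamma, larger off."""
        rng = np.random.default_rng(2)
        av = synthetic_crackling(rng, 40_000, tau=1.3, gamma=2.0,
                                 t_range=(20, 2000), amplitude=200.0,
                                 poisson_noise=False)
        bands = [30.0, 100.0, 300.0, 1000.0]
        _, _, err_true, _ = shape_collapse(av, 2.0, bands)
        assert err_true < 1e-3
        for off in (1.7, 2.3):
            _, _, err_off, _ = shape_collapse(av, off, bands)
            assert err_off > 10 * err_true

    def test_undersampled_band_skipped(self):
        rng = np.random.default_rng(3)
        av = synthetic_crackling(rng, 500, tau=1.5, gamma=2.0,
                                 t_range=(10, 100))
        grid, curves, err, bands = shape_collapse(av, 2.0, [50.0, 1e6])
        assert bands == [50.0]
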