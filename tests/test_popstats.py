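import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cryptlineage import lineage, models, popstats
from cryptlineage.popstats import (
    BootstrapNullResult,
    CountSeries,
    FitError,
    bootstrap_symmetry_null,
    clone_bootstrap_errors,
    clone_size_distribution,
    clone_sizes_at,
    fit_growth_rate,
    fluctuation_stats,
    growth_curves,
    positional_division_histogram,
)


class TestGrowthFit:
    def make_series(self, alpha, T=16.2, N0=30.0, M0=10.0, t_max=60.0, rng=None):
        t = np.arange(0.0, t_max + 1e-9, 1.0)
        n, u = growth_curves(t, alpha, T, N0, M0)
        if rng is not None:
            # proliferating counts jitter around the mean; births arrive as
            # Poisson increments so the cumulative total stays monotone
            n = rng.poisson(n).astype(float)
            n[0] = N0
            incr = rng.poisson(np.diff(u))
            u = (M0 + N0) + np.concatenate([[0.0], np.cumsum(incr)])
        return CountSeries(times=t, n_proliferating=n, n_total_born=u)

    @pytest.mark.parametrize("alpha", [-0.5, -0.2, 0.0, 0.1, 0.3, 0.5])
    def test_exact_recovery_on_noiseless_input(self, alpha):
        fit = fit_growth_rate(self.make_series(alpha))
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)

    def test_constant_proliferating_linear_total_is_alpha_zero(self):
        t = np.arange(0.0, 61.0, 1.0)
        series = CountSeries(t, np.full_like(t, 30.0), 40.0 + 30.0 * t / 16.2)
        assert fit_growth_rate(series).alpha == pytest.approx(0.0, abs=1e-6)

    def test_noisy_alpha_zero_matches_reported_spread_in_scale(self):
        # crypt-sized counts over 60 hr: the fitted growth rate is unbiased
        # and scatters around zero with a spread on the order of 0.07
        fits = np.array([
            fit_growth_rate(self.make_series(0.0, rng=np.random.default_rng(s))).alpha
            for s in range(20)
        ])
        assert abs(fits.mean()) < 0.04
        assert 0.02 < fits.std() < 0.1

    def test_degenerate_series_raises(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(FitError):
            fit_growth_rate(CountSeries(t, np.zeros_like(t), np.zeros_like(t)))


class TestFluctuationStats:
    def test_constant_count_is_sub_poissonian(self):
        t = np.arange(0.0, 10.0)
        mean, sd, cv, sub = fluctuation_stats(CountSeries(t, np.full_like(t, 30.0), np.full_like(t, 30.0)))
        assert (mean, sd) == (30.0, 0.0)
        assert sub

    def test_two_point_alternation(self):
        t = np.arange(0.0, 21.0)
        n = np.tile([0.0, 10.0], 11)[:21]
        u = np.full_like(t, 50.0)
        mean, sd, cv, sub = fluctuation_stats(CountSeries(t, n, u))
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(5.0)
        assert not sub  # sd = 5 > sqrt(5)

    def test_poisson_birth_death_ratio_near_one(self):
        # M/M/inf oracle: births at rate lam, deaths at rate mu per cell;
        # stationary occupancy is Poisson(lam/mu), so sd ~ sqrt(mean)
        rng = np.random.default_rng(8)
        lam, mu, n = 30.0 / 16.2, 1.0 / 16.2, 30
        times, counts = [0.0], [n]
        t = 0.0
        while t < 6000.0:
            rate = lam + mu * n
            t += rng.exponential(1.0 / rate)
            n += 1 if rng.random() < lam / rate else -1
            times.append(t)
            counts.append(n)
        series = CountSeries(np.array(times), np.array(counts, float), np.full(len(times), 1e9))
        mean, sd, cv, sub = fluctuation_stats(series)
        assert sd / math.sqrt(mean) == pytest.approx(1.0, abs=0.12)


class TestBootstrapNull:
    def test_all_proliferative_is_always_symmetric(self):
        res = bootstrap_symmetry_null(100, 1.0, 200, observed_phi=0.99, seed=0)
        assert res.mean_phi == 1.0 and res.sd_phi == 0.0

    def test_half_probability_converges_to_half(self):
        res = bootstrap_symmetry_null(2000, 0.5, 2000, observed_phi=0.9, seed=1)
        se = res.sd_phi / math.sqrt(res.n_iterations)
        assert abs(res.mean_phi - 0.5) < 4 * se + 1e-4

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.79])
    def test_mean_matches_analytic_concordance(self, p):
        # two independent Bernoulli(p) agree with probability p^2 + (1-p)^2
        q = p * p + (1 - p) * (1 - p)
        res = bootstrap_symmetry_null(499, p, 5000, observed_phi=1.01, seed=2)
        mc_se = res.sd_phi / math.sqrt(res.n_iterations)
        assert abs(res.mean_phi - q) <= 3 * mc_se + 1e-5
        assert res.p_is_upper_bound  # nothing can reach phi > 1

    def test_p_value_reported_as_bound_never_zero(self):
        res = bootstrap_symmetry_null(499, 0.79, 1000, observed_phi=0.97, seed=3)
        assert res.n_exceeding == 0
        assert res.p_is_upper_bound and res.p_value_bound == pytest.approx(1e-3)
        assert res.p_label().startswith("p <")

    def test_seed_reproducibility(self):
        a = bootstrap_symmetry_null(200, 0.7, 500, seed=7)
        b = bootstrap_symmetry_null(200, 0.7, 500, seed=7)
        assert a == b


class TestPositionalHistogram:
    def test_empty_events(self):
        counts, pe, te, profile = positional_division_histogram(pd.DataFrame(columns=["t_hr", "p_um"]))
        assert counts.sum() == 0 and profile.sum() == 0

    def test_profile_normalized(self, analyzed_crypt):
        from cryptlineage.analysis import division_events

        ev = division_events(analyzed_crypt["forest"], analyzed_crypt["tracks"], analyzed_crypt["axis"])
        counts, pe, te, profile = positional_division_histogram(ev)
        assert counts.sum() == len(ev)
        assert profile.sum() == pytest.approx(1.0)

    def test_divisions_confined_to_proliferative_region(self, analyzed_crypt):
        from cryptlineage.analysis import division_events

        ev = division_events(analyzed_crypt["forest"], analyzed_crypt["tracks"], analyzed_crypt["axis"])
        counts, pe, te, profile = positional_division_histogram(ev)
        below_60 = profile[: np.searchsorted(pe, 60.0)].sum()
        assert below_60 >= 0.97


def _forest_from_rows(rows):
    df = pd.DataFrame(rows, columns=["cell_id", "parent_id", "frame", "t_hr", "x_um", "y_um", "z_um", "is_paneth", "died"])
    return lineage.build_lineage_forest(df)


def _rows(cid, parent, f0, f1, dt=0.2, died_last=False):
    return [
        (cid, parent, f, round(f * dt, 6), 0.0, 0.0, 0.0, 0, int(died_last and f == f1))
        for f in range(f0, f1 + 1)
    ]


class TestCloneSizes:
    def test_never_dividing_cell_is_clone_of_one(self):
        forest = _forest_from_rows(_rows("x", "", 0, 250))  # 50 hr
        assert clone_sizes_at(forest, 0.0, 40.0) == [1]

    def test_one_division_gives_clone_of_two(self):
        rows = _rows("m", "", 0, 50) + _rows("a", "m", 51, 250) + _rows("b", "m", 51, 250)
        forest = _forest_from_rows(rows)
        sizes = clone_sizes_at(forest, 0.0, 40.0)
        assert sorted(sizes) == [2]  # only the mother is alive at t=0

    def test_death_removes_progeny(self):
        rows = _rows("m", "", 0, 50) + _rows("a", "m", 51, 100, died_last=True) + _rows("b", "m", 51, 250)
        forest = _forest_from_rows(rows)
        assert clone_sizes_at(forest, 0.0, 40.0) == [1]

    def test_lost_cell_censors_the_clone(self):
        rows = _rows("m", "", 0, 50) + _rows("a", "m", 51, 100) + _rows("b", "m", 51, 250)
        # cell a ends at 20 hr without death in a 50-hr recording -> lost
        forest = _forest_from_rows(rows)
        assert clone_sizes_at(forest, 0.0, 40.0) == []

    def test_synchronous_symmetric_divisions_give_powers_of_two(self):
        # every cell divides exactly every 10 hr; window = 2 cycles
        dt = 0.2
        rows = list(_rows("r", "", 0, 50))
        gen1 = ["a", "b"]
        for c in gen1:
            rows += _rows(c, "r", 51, 100)
        for i, parent in enumerate(gen1):
            for suffix in ("0", "1"):
                rows += _rows(parent + suffix, parent, 101, 150)
        forest = _forest_from_rows(rows)
        sizes = clone_sizes_at(forest, 0.0, 20.0)
        assert sizes == [4]
        assert clone_sizes_at(forest, 0.0, 10.0) == [2]

    def test_forest_shorter_than_window_raises(self):
        forest = _forest_from_rows(_rows("x", "", 0, 100))
        with pytest.raises(ValueError):
            clone_size_distribution(forest, window=40.0)

    def test_distribution_fractions_sum_to_one(self, analyzed_crypt):
        dist = clone_size_distribution(analyzed_crypt["forest"], window=40.0, stride=2.0, seed=0)
        assert dist.fractions.sum() == pytest.approx(1.0)
        assert (dist.sizes >= 1).all()


class TestCloneBootstrap:
    def test_single_clone_has_zero_sd(self):
        sds = clone_bootstrap_errors([3], n_runs=50, seed=0)
        assert sds[3] == 0.0

    def test_two_clone_enumeration_oracle(self):
        # clones {2, 3}: the 4 equally likely resamples give fraction(2) in
        # {1, 1/2, 1/2, 0}; exact sd = sqrt(1/8)
        fracs = [np.mean([a == 2, b == 2]) for a, b in itertools.product([2, 3], repeat=2)]
        exact_sd = float(np.std(fracs))
        assert exact_sd == pytest.approx(math.sqrt(0.125))
        est = clone_bootstrap_errors([2, 3], n_runs=20000, seed=1)
        assert est[2] == pytest.approx(exact_sd, abs=0.01)
        assert est[3] == pytest.approx(exact_sd, abs=0.01)

    def test_sd_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(5)
        base = rng.integers(1, 6, size=100).tolist()
        sd_small = clone_bootstrap_errors(base, n_runs=800, seed=2)
        sd_large = clone_bootstrap_errors(base * 4, n_runs=800, seed=3)
        for s in sd_small:
            if sd_small[s] > 0.01:
                assert sd_large[s] == pytest.approx(sd_small[s] / 2, rel=0.35)

    def test_reproducible_under_seed(self):
        a = clone_bootstrap_errors([1, 2, 2, 3, 5], n_runs=100, seed=9)
        b = clone_bootstrap_errors([1, 2, 2, 3, 5], n_runs=100, seed=9)
        assert a == b
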