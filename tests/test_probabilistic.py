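import numpy as np
import pytest
from scipy.stats import norm

from atckit.changes import ChangeSeries
from atckit.probabilistic import (
    InvalidCDFError,
    ProbabilisticSeries,
    QuantileSet,
    brier_score,
    increase_indicators,
    prob_increase_from_cdf,
    prob_increase_from_quantiles,
    prob_positive_change_two_dists,
    quantile_sampler,
    reliability_table,
    zero_change_count,
)


class TestProbFromCDF:
    def test_standard_normal_median(self):
        assert prob_increase_from_cdf(norm.cdf, 0.0) == pytest.approx(0.5)

    def test_below_support_gives_one(self):
        F = lambda v: 0.0 if v < 0 else 1.0
        assert prob_increase_from_cdf(F, -5.0) == 1.0

    def test_shifted_normal_median(self):
        F = norm(loc=3, scale=1).cdf
        assert prob_increase_from_cdf(F, 3.0) == pytest.approx(0.5)

    def test_invalid_cdf_rejected(self):
        with pytest.raises(InvalidCDFError):
            prob_increase_from_cdf(lambda v: 1.3, 0.0)


class TestProbFromQuantiles:
    @pytest.fixture
    def qs(self):
        return QuantileSet([0.25, 0.5, 0.75], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "y_prev, expected",
        [
            (2.0, 0.5),  # at the median
            (2.5, 0.375),  # interior interpolation: p_c = 0.625
            (0.5, 0.875),  # lower tail: p_c = 0.125
            (3.5, 0.125),  # upper tail, symmetric rule
            (-5.0, 1.0),  # far below: negative change impossible
            (9.0, 0.0),  # far above
        ],
    )
    def test_worked_examples(self, qs, y_prev, expected):
        assert prob_increase_from_quantiles(qs, y_prev) == pytest.approx(expected)

    def test_monotone_and_continuous(self, qs):
        grid = np.linspace(-2, 6, 801)
        p = np.array([prob_increase_from_quantiles(qs, v) for v in grid])
        assert (np.diff(p) <= 1e-12).all()
        assert np.abs(np.diff(p)).max() < 0.01  # no jumps at the knots
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_dense_grid_recovers_known_distribution(self):
        levels = np.linspace(0.01, 0.99, 99)
        qs = QuantileSet(levels, norm.ppf(levels))
        for y in (-1.3, -0.2, 0.0, 0.4, 1.7):
            got = prob_increase_from_quantiles(qs, y)
            assert got == pytest.approx(1 - norm.cdf(y), abs=0.01)

    def test_uneven_levels_reduce_to_piecewise_linear(self):
        qs = QuantileSet([0.1, 0.5, 0.9], [0.0, 1.0, 2.0])
        # halfway between q_0.5 and q_0.9: p_c = 0.5 + 0.4/2
        assert prob_increase_from_quantiles(qs, 1.5) == pytest.approx(1 - 0.7)

    def test_mass_point_uses_upper_level_with_warning(self):
        qs = QuantileSet([0.25, 0.5, 0.75], [1.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="mass point"):
            p = prob_increase_from_quantiles(qs, 2.0)
        assert p == pytest.approx(0.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            QuantileSet([0.5], [1.0])
        with pytest.raises(ValueError):
            QuantileSet([0.2, 0.2], [1.0, 2.0])
        with pytest.raises(ValueError):
            QuantileSet([0.2, 0.8], [2.0, 1.0])

    def test_sampler_draws_from_interpolated_cdf(self, qs, rng):
        draws = quantile_sampler(qs)(50_000, rng)
        # median and quartiles of the draws match the quantile set
        assert np.quantile(draws, 0.5) == pytest.approx(2.0, abs=0.05)
        assert np.quantile(draws, 0.25) == pytest.approx(1.0, abs=0.05)


class TestTwoDistributions:
    def test_identical_point_masses_give_zero(self):
        point = lambda n, rng: np.full(n, 3.0)
        assert prob_positive_change_two_dists(point, point, 200, seed=0) == 0.0

    def test_normal_difference_closed_form(self):
        p = prob_positive_change_two_dists(
            lambda n, rng: rng.normal(1, 1, n),
            lambda n, rng: rng.normal(0, 1, n),
            n_samples=10**6,
            seed=1,
        )
        assert p == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.005)

    def test_swap_complements_probability(self):
        a = lambda n, rng: rng.normal(0.4, 1, n)
        b = lambda n, rng: rng.normal(0.0, 1, n)
        p = prob_positive_change_two_dists(a, b, 10**6, seed=2)
        q = prob_positive_change_two_dists(b, a, 10**6, seed=3)
        assert p == pytest.approx(1 - q, abs=0.005)

    def test_too_few_samples_rejected(self):
        point = lambda n, rng: np.zeros(n)
        with pytest.raises(ValueError):
            prob_positive_change_two_dists(point, point, 50)


class TestIndicatorsAndBrier:
    def test_indicators(self):
        yd = ChangeSeries(1, [1, 2, 3], [2.0, -1.0, 0.0])
        z = increase_indicators(yd)
        assert z.tolist() == [1, 0, 0]
        assert zero_change_count(yd) == 1

    def test_indicators_empty(self):
        yd = ChangeSeries(1, [], [])
        assert len(increase_indicators(yd)) == 0

    def test_random_guessing_scores_quarter(self, rng):
        z = rng.integers(0, 2, 200)
        series = ProbabilisticSeries(np.arange(200), np.full(200, 0.5), z)
        assert brier_score(series) == 0.25

    def test_perfect_certainty_scores_zero(self):
        z = np.array([1, 0, 1, 1])
        series = ProbabilisticSeries(np.arange(4), z.astype(float), z)
        assert brier_score(series) == 0.0

    def test_hand_computed_example(self):
        series = ProbabilisticSeries([1, 2], [0.8, 0.2], [1, 1])
        assert brier_score(series) == pytest.approx(0.34)

    def test_alignment_excludes_missing(self):
        import pandas as pd

        p = pd.Series({1: 0.2, 2: 0.9, 3: np.nan, 4: 0.5})
        z = pd.Series({2: 1, 3: 0, 4: 1, 5: 0})
        series = ProbabilisticSeries.from_series(p, z)
        assert series.times.tolist() == [2, 4]

    def test_true_probability_beats_constant_forecasts(self, rng):
        p_true = rng.random(20_000)
        z = (rng.random(20_000) < p_true).astype(int)
        t = np.arange(z.size)
        bs_true = brier_score(ProbabilisticSeries(t, p_true, z))
        for const in (0.1, 0.3, 0.5, 0.7, 0.9):
            bs_const = brier_score(
                ProbabilisticSeries(t, np.full(z.size, const), z)
            )
            assert bs_true < bs_const


class TestReliability:
    def test_calibrated_data_sits_on_diagonal(self, rng):
        n = 10**5
        p = rng.random(n)
        z = (rng.random(n) < p).astype(int)
        table = reliability_table(ProbabilisticSeries(np.arange(n), p, z), 10)
        assert len(table) == 10
        assert (table["mean_p"] - table["obs_freq"]).abs().max() <= 0.02

    def test_counts_partition_the_series(self, rng):
        n = 1234
        p = rng.random(n)
        z = rng.integers(0, 2, n)
        table = reliability_table(ProbabilisticSeries(np.arange(n), p, z), 7)
        assert table["count"].sum() == n

    def test_constant_probabilities_collapse_to_one_bin(self):
        series = ProbabilisticSeries([1, 2, 3], [0.4] * 3, [0, 1, 0])
        with pytest.warns(UserWarning, match="merged"):
            table = reliability_table(series, 5)
        filled = table[table["count"] > 0]
        assert len(filled) == 1
        assert filled["count"].iloc[0] == 3

    def test_equal_width_emits_empty_bins(self, rng):
        p = np.concatenate([rng.uniform(0, 0.2, 50), rng.uniform(0.8, 1.0, 50)])
        z = rng.integers(0, 2, 100)
        table = reliability_table(
            ProbabilisticSeries(np.arange(100), p, z), 5, binning="equal_width"
        )
        assert len(table) == 5
        empty = table[table["count"] == 0]
        assert len(empty) >= 1
        assert empty["obs_freq"].isna().all()
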