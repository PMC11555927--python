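import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atckit.changes import PairedChangeSeries
from atckit.measures import (
    NO_EXCLUSION,
    ExclusionArea,
    UndefinedEstimateError,
    atc_over_exclusion_sizes,
    atc_ratio,
    atc_ratio_signed,
    exclusion_from_quantile,
    in_exclusion,
    rolling_atc,
)
from atckit.synthetic_data import GeneratorSpec, gen_bivariate_normal, gen_scheme1

from conftest import random_pairs


def brute_force_ratio(x, y, area, direction=None):
    """Independent double-loop recount of the ratio estimators."""
    num = den = 0
    for xi, yi in zip(x, y):
        if area.contains(yi, xi):
            continue
        if direction == "positive" and not xi > 0:
            continue
        if direction == "negative" and not xi < 0:
            continue
        den += 1
        if xi * yi > 0:
            num += 1
    if den == 0:
        return None
    return num / den


class TestExclusionArea:
    @pytest.mark.parametrize(
        "shape, point, expected",
        [
            ("rectangle", (0.5, 0.5), True),
            ("rectangle", (2.0, 0.5), False),  # large in the true component
            ("rectangle", (0.5, 2.0), False),  # large in the predicted component
            ("cross", (2.0, 0.5), True),
            ("cross", (0.5, 2.0), True),
            ("x_band", (5.0, 0.5), True),
            ("x_band", (0.5, 2.0), False),
            ("y_band", (0.5, 5.0), True),
            ("none", (0.0, 0.0), False),
        ],
    )
    def test_membership(self, shape, point, expected):
        area = ExclusionArea(shape=shape, eps_x=1.0, eps_y=1.0)
        assert in_exclusion(area, *point) is expected

    def test_boundary_is_inclusive(self):
        area = ExclusionArea(shape="rectangle", eps_x=1.0, eps_y=1.0)
        assert in_exclusion(area, 1.0, -1.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ExclusionArea(shape="rectangle", eps_x=-0.1)


class TestATCRatio:
    def test_quadrant_count(self):
        pairs = PairedChangeSeries.from_arrays([1, -1, 2], [2, -3, -1])
        est = atc_ratio(pairs)
        assert est.value == pytest.approx(2 / 3)
        assert est.n_used == est.n_total == 3

    def test_all_concordant(self):
        pairs = PairedChangeSeries.from_arrays([1, 2, 3], [0.5, 1, 9])
        assert atc_ratio(pairs).value == 1.0

    def test_zero_product_counts_denominator_only(self):
        pairs = PairedChangeSeries.from_arrays([0.0, 1.0], [1.0, 1.0])
        assert atc_ratio(pairs).value == 0.5

    def test_empty_denominator_errors(self):
        pairs = PairedChangeSeries.from_arrays([0.1], [0.1])
        area = ExclusionArea(shape="rectangle", eps_x=1, eps_y=1)
        with pytest.raises(UndefinedEstimateError):
            atc_ratio(pairs, area)

    def test_signed_examples(self):
        pairs = PairedChangeSeries.from_arrays([1, 2, -1], [1, -1, -1])
        assert atc_ratio_signed(pairs, "positive").value == pytest.approx(0.5)
        assert atc_ratio_signed(pairs, "negative").value == 1.0

    @pytest.mark.parametrize("direction", [None, "positive", "negative"])
    @pytest.mark.parametrize(
        "area",
        [
            NO_EXCLUSION,
            ExclusionArea("rectangle", 0.5, 0.8),
            ExclusionArea("x_band", 0.7),
            ExclusionArea("cross", 0.4, 0.4),
        ],
    )
    def test_brute_force_oracle(self, rng, direction, area):
        for n in (5, 37, 200, 500):
            pairs = random_pairs(rng, n, zeros=True)
            expected = brute_force_ratio(pairs.x_delta, pairs.y_delta, area, direction)
            if expected is None:
                continue
            if direction is None:
                got = atc_ratio(pairs, area).value
            else:
                got = atc_ratio_signed(pairs, direction, area).value
            assert got == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_sign_flip_symmetry(self, points):
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        pairs = PairedChangeSeries.from_arrays(x, y)
        flipped = PairedChangeSeries.from_arrays(-x, -y)
        assert atc_ratio(pairs).value == atc_ratio(flipped).value
        for d_orig, d_flip in (("positive", "negative"), ("negative", "positive")):
            try:
                a = atc_ratio_signed(pairs, d_orig).value
            except UndefinedEstimateError:
                with pytest.raises(UndefinedEstimateError):
                    atc_ratio_signed(flipped, d_flip)
                continue
            assert a == atc_ratio_signed(flipped, d_flip).value

    def test_signed_decomposition_identity(self, rng):
        # n+·mu+ + n-·mu- == n·mu when no predicted change is exactly 0
        pairs = random_pairs(rng, 300)
        n = len(pairs)
        mu = atc_ratio(pairs)
        pos = atc_ratio_signed(pairs, "positive")
        neg = atc_ratio_signed(pairs, "negative")
        assert pos.n_used + neg.n_used == n
        assert pos.n_used * pos.value + neg.n_used * neg.value == pytest.approx(
            n * mu.value
        )

    def test_consistency_on_constant_k(self):
        T = 10**5
        pairs = gen_scheme1(GeneratorSpec("scheme1_constant", T, k=0.75, seed=99))
        se = np.sqrt(0.75 * 0.25 / T)
        assert abs(atc_ratio(pairs).value - 0.75) < 3 * se


class TestRolling:
    def test_full_window_equals_overall(self, rng):
        pairs = random_pairs(rng, 40)
        out = rolling_atc(pairs, len(pairs))
        assert len(out) == 1
        assert out.iloc[0] == pytest.approx(atc_ratio(pairs).value)

    def test_all_concordant_window(self):
        pairs = PairedChangeSeries.from_arrays([1, 1, 1, 1], [2, 2, 2, 2])
        assert (rolling_atc(pairs, 2) == 1.0).all()

    def test_window_too_large(self, rng):
        with pytest.raises(ValueError):
            rolling_atc(random_pairs(rng, 10), 11)

    def test_rolling_lags_seasonal_truth(self):
        # Backward-looking windows shift the estimated seasonal cycle to
        # the right of the true concordance probability k_t.
        pairs = gen_scheme1(GeneratorSpec("scheme1_timevarying", 1461, seed=21))
        w = 90
        rolled = rolling_atc(pairs, w)
        k_t = pairs.meta["true_k"][w - 1 :]
        est = rolled.to_numpy() - rolled.mean()
        kc = k_t - k_t.mean()
        lags = np.arange(0, 130)
        xcorr = [np.dot(est[lag:], kc[: kc.size - lag]) for lag in lags]
        best = lags[int(np.argmax(xcorr))]
        assert 0 < best < 120


class TestExclusionSizing:
    def test_quantile_definition(self):
        x = np.arange(1.0, 11.0)
        pairs = PairedChangeSeries.from_arrays(x, x[::-1].copy())
        area = exclusion_from_quantile(pairs, 0.1)
        assert area.eps_x == pytest.approx(np.quantile(np.abs(x), 0.1))

    def test_small_q_excludes_almost_nothing(self, rng):
        pairs = random_pairs(rng, 200)
        area = exclusion_from_quantile(pairs, 1e-6)
        est = atc_ratio(pairs, area)
        assert est.n_used >= len(pairs) - 2

    def test_rectangle_requires_both_small(self, rng):
        pairs = random_pairs(rng, 500)
        area = exclusion_from_quantile(pairs, 0.1, shape="rectangle")
        inside = area.contains(pairs.y_delta, pairs.x_delta)
        both_small = (np.abs(pairs.x_delta) <= area.eps_x) & (
            np.abs(pairs.y_delta) <= area.eps_y
        )
        assert (inside == both_small).all()

    @pytest.mark.parametrize("q", [0.0, 1.0, -1, 2])
    def test_invalid_quantile(self, rng, q):
        with pytest.raises(ValueError):
            exclusion_from_quantile(random_pairs(rng, 10), q)

    def test_sweep_size_zero_matches_plain_ratio(self, rng):
        pairs = random_pairs(rng, 100)
        table = atc_over_exclusion_sizes(pairs, [0.0, 0.5, 1.0, 2.0])
        assert table["value"].iloc[0] == pytest.approx(atc_ratio(pairs).value)
        assert (np.diff(table["n_used"]) <= 0).all()

    def test_sweep_nondecreasing_on_bivariate_normal(self):
        pairs = gen_bivariate_normal(GeneratorSpec("bivariate_normal", 10**5, seed=3))
        table = atc_over_exclusion_sizes(pairs, [0.0, 0.5, 1.0, 1.5, 2.0])
        # larger changes are more reliably concordant; allow tiny MC slack
        assert (np.diff(table["value"]) > -0.01).all()
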