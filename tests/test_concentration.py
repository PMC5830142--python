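"""Concentration index, generalized index, curve, and standard errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hhrineq.concentration import (
    ConcentrationModel,
    concentration_curve,
    concentration_index,
    concentration_index_se,
    curve_position,
    generalized_concentration_index,
)
from hhrineq.exceptions import DomainError, ValidationError
from hhrineq.ranks import fractional_rank

from conftest import brute_force_ci


class TestConcentrationIndex:
    def test_constant_variable_has_zero_index(self, toy_ranked):
        res = concentration_index([7.0, 7.0, 7.0, 7.0], toy_ranked)
        assert res.c == 0.0
        assert res.mu == 7.0

    def test_ascending_toy_example(self, toy_ranked):
        # brute force: 2/2.5 * cov([1..4], [.125,.375,.625,.875]) = 0.25
        res = concentration_index([1.0, 2.0, 3.0, 4.0], toy_ranked)
        assert res.c == pytest.approx(0.25, abs=1e-15)

    def test_reversal_flips_sign(self, toy_ranked):
        res = concentration_index([4.0, 3.0, 2.0, 1.0], toy_ranked)
        assert res.c == pytest.approx(-0.25, abs=1e-15)

    def test_matches_longhand_oracle_on_random_data(self):
        rng = np.random.default_rng(42)
        x = rng.lognormal(10, 0.3, size=57)
        h = rng.gamma(2.0, 3.0, size=57)
        ranked = fractional_rank(x)
        res = concentration_index(h, ranked)
        assert res.c == pytest.approx(brute_force_ci(h, ranked.ranks), abs=1e-12)

    def test_nonpositive_mean_rejected(self, toy_ranked):
        with pytest.raises(DomainError):
            concentration_index([0.0, 0.0, 0.0, 0.0], toy_ranked)

    def test_length_mismatch_rejected(self, toy_ranked):
        with pytest.raises(ValidationError):
            concentration_index([1.0, 2.0], toy_ranked)

    def test_reversal_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=101)
        h = rng.gamma(2.0, size=101)
        c_fwd = concentration_index(h, fractional_rank(x)).c
        c_rev = concentration_index(h, fractional_rank(-x)).c
        assert c_fwd == pytest.approx(-c_rev, abs=1e-14)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(size=80)
        h = rng.gamma(2.0, size=80)
        perm = rng.permutation(80)
        c1 = concentration_index(h, fractional_rank(x)).c
        c2 = concentration_index(h[perm], fractional_rank(x[perm])).c
        assert c1 == pytest.approx(c2, abs=1e-13)


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
        min_size=3,
        max_size=50,
    ).filter(lambda h: sum(h) > 0),
    st.floats(min_value=1e-6, max_value=1e6),
)
def test_bounds_and_scale_invariance(h, c_scale):
    """For nonnegative h: C in [-1, 1]; C(c*h) = C(h) for c > 0."""
    rng = np.random.default_rng(len(h))
    ranked = fractional_rank(rng.normal(size=len(h)))
    res = concentration_index(h, ranked)
    assert -1.0 - 1e-12 <= res.c <= 1.0 + 1e-12
    scaled = concentration_index(c_scale * np.asarray(h), ranked)
    assert scaled.c == pytest.approx(res.c, abs=1e-12)


class TestGeneralizedIndex:
    def test_zero_input(self, toy_ranked):
        assert generalized_concentration_index(np.zeros(4), toy_ranked) == 0.0

    def test_toy_value(self, toy_ranked):
        # 2 * cov([1..4], [.125,.375,.625,.875]) = 2 * 0.3125 = 0.625
        gc = generalized_concentration_index([1.0, 2.0, 3.0, 4.0], toy_ranked)
        assert gc == pytest.approx(0.625, abs=1e-15)

    def test_zero_mean_input_is_fine(self, toy_ranked):
        u = np.array([1.0, -1.0, 2.0, -2.0])  # mean zero, like OLS residuals
        gc = generalized_concentration_index(u, toy_ranked)
        assert np.isfinite(gc)
        assert gc == pytest.approx(2 * np.cov(u, toy_ranked.ranks, ddof=0)[0, 1])


class TestStandardErrors:
    def test_constant_variable(self, toy_ranked):
        res = concentration_index_se([3.0] * 4, toy_ranked)
        assert (res.c, res.se) == (0.0, 0.0)
        assert (res.ci95_low, res.ci95_high) == (0.0, 0.0)

    def test_convenient_regression_slope_equals_index(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.lognormal(size=60)
            h = rng.gamma(2.0, 4.0, size=60)
            ranked = fractional_rank(x)
            base = concentration_index(h, ranked)
            res = concentration_index_se(h, ranked, method="convenient_regression")
            assert res.c == pytest.approx(base.c, abs=1e-10)
            assert res.se is not None and res.se > 0
            assert res.ci95_low <= res.c <= res.ci95_high

    def test_bootstrap_is_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(size=40)
        h = rng.gamma(2.0, size=40)
        ranked = fractional_rank(x)
        a = concentration_index_se(h, ranked, method="bootstrap", n_boot=200, seed=5)
        b = concentration_index_se(h, ranked, method="bootstrap", n_boot=200, seed=5)
        assert (a.ci95_low, a.ci95_high) == (b.ci95_low, b.ci95_high)

    def test_bootstrap_and_analytic_se_agree_in_order_of_magnitude(self):
        rng = np.random.default_rng(21)
        x = rng.lognormal(size=150)
        h = rng.gamma(3.0, 2.0, size=150)
        ranked = fractional_rank(x)
        a = concentration_index_se(h, ranked, method="convenient_regression")
        b = concentration_index_se(h, ranked, method="bootstrap", n_boot=400, seed=1)
        assert b.se == pytest.approx(a.se, rel=0.5)

    def test_small_bootstrap_rejected(self, toy_ranked):
        with pytest.raises(ValidationError):
            concentration_index_se(
                [1.0, 2.0, 3.0, 4.0], toy_ranked, method="bootstrap", n_boot=10
            )


class TestCurve:
    def test_cumulative_share_knots(self, toy_ranked):
        curve = concentration_curve([1.0, 2.0, 3.0, 4.0], toy_ranked)
        np.testing.assert_allclose(curve.cum_pop_share, [0, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(curve.cum_health_share, [0, 0.1, 0.3, 0.6, 1.0])

    def test_constant_variable_gives_diagonal(self, toy_ranked):
        curve = concentration_curve([5.0] * 4, toy_ranked)
        np.testing.assert_allclose(curve.cum_health_share, curve.cum_pop_share)
        assert curve_position(curve) == "coincident"

    def test_endpoints(self):
        rng = np.random.default_rng(17)
        ranked = fractional_rank(rng.normal(size=33))
        curve = concentration_curve(rng.gamma(1.0, size=33), ranked)
        assert curve.cum_pop_share[0] == 0.0 and curve.cum_health_share[0] == 0.0
        assert curve.cum_pop_share[-1] == pytest.approx(1.0, abs=1e-12)
        assert curve.cum_health_share[-1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self, toy_ranked):
        with pytest.raises(DomainError):
            concentration_curve([0.0] * 4, toy_ranked)

    @pytest.mark.parametrize(
        "h,expected",
        [
            ([1.0, 2.0, 3.0, 4.0], "below"),  # pro-rich
            ([4.0, 3.0, 2.0, 1.0], "above"),  # pro-poor
            ([3.0, 1.0, 1.0, 3.0], "crossing"),
        ],
    )
    def test_position_classification(self, toy_ranked, h, expected):
        assert curve_position(concentration_curve(h, toy_ranked)) == expected

    def test_area_under_curve_matches_covariance_formula(self):
        """Independent geometric oracle: C equals twice the signed area
        between the diagonal and the curve, to O(1/N)."""
        rng = np.random.default_rng(2024)
        n = 2000
        x = rng.lognormal(10.0, 0.4, size=n)
        h = np.exp(0.8 * np.log(x) + rng.normal(0, 0.5, size=n))
        ranked = fractional_rank(x)
        c_cov = concentration_index(h, ranked).c
        c_area = concentration_curve(h, ranked).area_index()
        assert c_area == pytest.approx(c_cov, abs=1e-3)


def test_model_wrapper_round_trip(small_table):
    model = ConcentrationModel.from_dataframe(small_table, "doctors_per_10k")
    res = model.fit()
    direct = concentration_index(
        small_table["doctors_per_10k"].to_numpy(),
        fractional_rank(small_table["pergdp"].to_numpy()),
    )
    assert res.c == pytest.approx(direct.c, abs=1e-14)
    assert "Concentration index" in res.summary()
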