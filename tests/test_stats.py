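import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippot2.stats import (
    GroupStats,
    classify,
    fit_logistic,
    paired_comparison,
    pooled_bilateral_stats,
    reference_range,
    training_accuracy,
    two_sample_t,
)

from _oracles import maximize_logistic_likelihood


def _exact_moment_sample(rng, mean, sd, n):
    """A sample whose sample mean and SD (n-1) are exactly as requested."""
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestPooledBilateralStats:
    def test_matches_concatenation_oracle(self, rng):
        left = _exact_moment_sample(rng, 115.5, 4.11, 50)
        right = _exact_moment_sample(rng, 116.8, 3.60, 50)
        pooled = pooled_bilateral_stats(
            GroupStats.from_samples(left), GroupStats.from_samples(right)
        )
        concat = np.concatenate([left, right])
        assert pooled.mean == pytest.approx(np.mean(concat), rel=1e-12)
        assert pooled.sd == pytest.approx(np.std(concat, ddof=1), rel=1e-12)
        assert pooled.mean == pytest.approx(116.15)
        assert pooled.sd == pytest.approx(3.899, abs=5e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        m1=st.floats(-50, 150), m2=st.floats(-50, 150),
        s1=st.floats(0.1, 30), s2=st.floats(0.1, 30),
        n=st.integers(3, 40),
    )
    def test_concatenation_identity_holds_generally(self, m1, m2, s1, s2, n):
        rng = np.random.default_rng(7)
        a = _exact_moment_sample(rng, m1, s1, n)
        b = _exact_moment_sample(rng, m2, s2, n)
        pooled = pooled_bilateral_stats(
            GroupStats.from_samples(a), GroupStats.from_samples(b)
        )
        concat = np.concatenate([a, b])
        assert pooled.sd == pytest.approx(np.std(concat, ddof=1), rel=1e-9, abs=1e-9)

    def test_identical_sides_unchanged(self):
        g = GroupStats(mean=115.0, sd=4.0, n=50)
        pooled = pooled_bilateral_stats(g, g)
        assert pooled.mean == 115.0
        assert pooled.sd == pytest.approx(4.0 * np.sqrt(49 * 2 / 99))

    def test_degenerate_zero_spread(self):
        g = GroupStats(mean=100.0, sd=0.0, n=10)
        pooled = pooled_bilateral_stats(g, g)
        assert pooled.sd == 0.0

    def test_unequal_n_rejected(self):
        with pytest.raises(ValueError):
            pooled_bilateral_stats(
                GroupStats(1.0, 1.0, 10), GroupStats(1.0, 1.0, 11)
            )


class TestReferenceRange:
    def test_control_t2_upper_bounds(self):
        left = reference_range(GroupStats(115.5, 4.11, 50))
        right = reference_range(GroupStats(116.8, 3.60, 50))
        assert round(left.upper, 1) == 123.6
        assert round(right.upper, 1) == 123.9

    def test_zero_sd_collapses_to_mean(self):
        rr = reference_range(GroupStats(100.0, 0.0, 10))
        assert rr.lower == rr.upper == 100.0

    def test_flagging(self):
        rr = reference_range(GroupStats(100.0, 5.0, 10))
        assert rr.flag(100.0) == "within"
        assert rr.flag(111.0) == "above"
        assert rr.flag(89.0) == "below"


class TestLogisticRegression:
    def _fixture(self, rng, n=20):
        X = np.vstack([
            rng.normal([3.0, 115.0], [0.4, 5.0], size=(n // 2, 2)),
            rng.normal([2.4, 124.0], [0.4, 6.0], size=(n // 2, 2)),
        ])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_separable_clusters_classified_perfectly(self, rng):
        X = np.vstack([
            rng.normal([0.0, 0.0], 0.2, size=(10, 2)),
            rng.normal([5.0, 5.0], 0.2, size=(10, 2)),
        ])
        y = np.repeat([0, 1], 10)
        model = fit_logistic(X, y)
        assert training_accuracy(model, X, y) == 1.0
        assert not model.converged  # perfect separation is flagged

    def test_matches_independent_likelihood_maximizer(self, rng):
        """IRLS coefficients agree with a generic BFGS maximiser of the
        logistic log-likelihood on an overlapping 20-point fixture."""
        X, y = self._fixture(rng)
        model = fit_logistic(X, y)
        assert model.converged
        oracle = maximize_logistic_likelihood(X, y.astype(float))
        fitted = np.concatenate([[model.intercept], model.coefficients])
        np.testing.assert_allclose(fitted, oracle, atol=1e-6)

    def test_matches_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        X, y = self._fixture(rng)
        model = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        fitted = np.concatenate([[model.intercept], model.coefficients])
        np.testing.assert_allclose(fitted, ref.params, atol=1e-6)

    def test_log_likelihood_non_decreasing_over_iterations(self, rng):
        X, y = self._fixture(rng, n=40)
        lls = [
            fit_logistic(X, y, max_iter=k).log_likelihood for k in range(1, 8)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_logistic(X, np.zeros(10))

    def test_named_coefficients(self, rng):
        X, y = self._fixture(rng)
        model = fit_logistic(X, y, feature_names=("volume", "t2"))
        assert model.coef_volume == model.coefficients[0]
        assert model.coef_t2 == model.coefficients[1]


class TestClassify:
    def test_boundary_probability_is_half(self, rng):
        X, y = np.array([[0.0], [1.0], [2.0], [3.0]]), np.array([0, 0, 1, 1])
        model = fit_logistic(X, y, feature_names=("t2",))
        boundary = -model.intercept / model.coefficients[0]
        prob, _ = classify(model, np.array([[boundary]]))
        assert prob[0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_coefficients_give_half_everywhere(self):
        from hippot2.stats import ClassifierModel

        model = ClassifierModel(
            intercept=0.0, coefficients=np.zeros(2),
            feature_names=("volume", "t2"), converged=True, n_iter=0,
        )
        prob, flags = classify(model, np.array([[1.0, 2.0], [5.0, -3.0]]))
        np.testing.assert_allclose(prob, 0.5)

    def test_probability_monotone_in_t2(self, rng):
        X = np.vstack([
            rng.normal(115, 4, size=(20, 1)), rng.normal(128, 6, size=(20, 1))
        ])
        y = np.repeat([0, 1], 20)
        model = fit_logistic(X, y, feature_names=("t2",))
        assert model.coefficients[0] > 0
        grid = np.linspace(100, 140, 30).reshape(-1, 1)
        prob, _ = classify(model, grid)
        assert np.all(np.diff(prob) > 0)


class TestTwoSampleT:
    def test_identical_samples_null(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_pooled_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p = two_sample_t(a, b)
        # pooled variance 1, se = sqrt(1 * (1/3 + 1/3))
        expected = (2.0 - 5.0) / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_joint_location_scale(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(3.0 * a + 7.0, 3.0 * b + 7.0)
        assert t1 == pytest.approx(t2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0])


class TestPairedComparison:
    def test_identical_repeats(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_comparison(x, x)
        assert res.mean_diff == 0.0
        assert res.sd_diff == 0.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_comparison(x + 5.0, x)
        assert res.mean_diff == pytest.approx(5.0)
        assert res.sd_diff == 0.0

    def test_limits_of_agreement_identity(self, rng):
        x = rng.normal(115, 4, 40)
        y = x + rng.normal(0, 3.59, 40)
        res = paired_comparison(x, y)
        assert res.loa_upper - res.loa_lower == pytest.approx(
            2 * 1.96 * res.sd_diff, rel=1e-12
        )

    def test_recovers_difference_sd(self, rng):
        """With a true difference SD of 3.59 msec and 40 hippocampi the
        estimated SD of differences lands within 30% of truth."""
        x = rng.normal(116, 4.0, 40)
        y = x + rng.normal(0.0, 3.59, 40)
        res = paired_comparison(x, y)
        assert abs(res.sd_diff - 3.59) / 3.59 < 0.30

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0])
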