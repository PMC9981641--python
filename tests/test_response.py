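import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import logistic

from emabayes.response import (
    attribute_log_likelihood,
    ordinal_loglik_grad,
    ordinal_logpmf,
    raw_to_interior,
    raw_to_interior_vjp,
    response_prob,
    shift_identifiability,
    thresholds_from_raw,
)


def oracle_probs(theta, interior):
    """Direct logistic-CDF differences."""
    cdf = np.r_[0.0, logistic.cdf(np.asarray(interior) - theta), 1.0]
    return np.diff(cdf)


class TestResponseProb:
    def test_five_category_example(self):
        # location 1.8 against thresholds (-3.2, -1.2, 0.6, 2.7)
        tau = np.array([-3.2, -1.2, 0.6, 2.7])
        p = response_prob(1.8, tau)
        assert np.allclose(p, oracle_probs(1.8, tau), atol=1e-12)
        assert p[4] == pytest.approx(1.0 - logistic.cdf(2.7 - 1.8), abs=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_binary_scale_at_threshold_is_half_half(self):
        p = response_prob(-0.3, np.array([-0.3]))
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_mass_moves_to_top_category_for_large_location(self):
        tau = np.array([-1.0, 0.0, 1.0])
        p = response_prob(40.0, tau)
        assert p[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(p[:-1] < 1e-12)

    def test_nonfinite_location_rejected(self):
        with pytest.raises(ValueError):
            response_prob(np.nan, np.array([0.0]))

    @given(
        theta=st.floats(-30, 30),
        widths=st.lists(st.floats(0.05, 3.0), min_size=1, max_size=8),
        start=st.floats(-8, 8),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_and_oracle_agreement_fuzz(self, theta, widths, start):
        interior = start + np.cumsum(widths)
        p = response_prob(theta, interior)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p, oracle_probs(theta, interior), atol=1e-12)

    def test_log_probabilities_finite_for_extreme_locations(self):
        interior = np.array([-2.0, 0.0, 2.0])
        for theta in (-30.0, 30.0):
            lp = ordinal_logpmf(theta, interior)
            assert np.all(np.isfinite(lp))

    @given(theta_lo=st.floats(-5, 5), delta=st.floats(0.01, 5))
    @settings(max_examples=100, deadline=None)
    def test_stochastic_ordering_in_location(self, theta_lo, delta):
        # larger location never decreases any upper-tail probability
        interior = np.array([-2.1, -0.3, 0.4, 1.9])
        p_lo = response_prob(theta_lo, interior)
        p_hi = response_prob(theta_lo + delta, interior)
        tail_lo = np.cumsum(p_lo[::-1])[::-1]
        tail_hi = np.cumsum(p_hi[::-1])[::-1]
        assert np.all(tail_hi >= tail_lo - 1e-12)


class TestThresholdMap:
    def test_equal_raw_gives_equally_spaced_median_zero(self):
        tau = thresholds_from_raw(np.zeros(6))
        gaps = np.diff(tau.interior)
        assert np.allclose(gaps, gaps[0])
        assert np.median(tau.interior) == pytest.approx(0.0, abs=1e-12)

    @given(raw=st.lists(st.floats(-4, 4), min_size=2, max_size=9))
    @settings(max_examples=150, deadline=None)
    def test_interior_strictly_increasing_for_any_raw(self, raw):
        tau = thresholds_from_raw(np.array(raw))
        assert len(tau.interior) == len(raw) - 1
        assert np.all(np.diff(tau.interior) > 0)
        assert np.median(tau.interior) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_each_raw_coordinate(self, rng):
        raw = rng.normal(size=7)
        base = raw_to_interior(raw, mode="free")
        for j in range(1, 7):
            bumped = raw.copy()
            bumped[j] += 0.1
            upper = raw_to_interior(bumped, mode="free")
            # raising one width never lowers any threshold at or above it
            assert np.all(upper[j - 1 :] >= base[j - 1 :])
            assert np.allclose(upper[: j - 1], base[: j - 1])

    def test_vjp_matches_finite_differences(self, rng):
        raw = rng.normal(size=6)
        dtau = rng.normal(size=5)
        for mode in ("median-zero", "free"):
            got = raw_to_interior_vjp(raw, dtau, mode)
            eps = 1e-6
            fd = np.array(
                [
                    (
                        dtau @ raw_to_interior(raw + eps * e, mode)
                        - dtau @ raw_to_interior(raw - eps * e, mode)
                    )
                    / (2 * eps)
                    for e in np.eye(6)
                ]
            )
            assert np.allclose(got, fd, atol=1e-6)


class TestShiftInvariance:
    def test_common_shift_leaves_probabilities_unchanged(self):
        tau = thresholds_from_raw(np.array([0.1, 0.5, -0.2, 1.0, 0.3]), mode="free")
        theta = np.array([1.8, -0.4, 0.0])
        c = 3.7
        p0 = response_prob(theta, tau.interior)
        p1 = response_prob(theta + c, tau.interior + c)
        assert np.allclose(p0, p1, atol=1e-12)

    def test_median_zero_restriction(self):
        tau = thresholds_from_raw(np.array([2.0, 1.0, 0.3, -0.5, 0.7]), mode="free")
        theta = np.array([0.5, 1.5])
        th2, tau2 = shift_identifiability(theta, tau, "median-zero")
        assert np.median(tau2.interior) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(
            response_prob(theta, tau.interior), response_prob(th2, tau2.interior)
        )

    def test_zero_mean_attribute_restriction(self):
        tau = thresholds_from_raw(np.array([2.0, 1.0, 0.3]), mode="free")
        theta = np.array([0.5, 1.5, -3.0])
        th2, tau2 = shift_identifiability(theta, tau, "zero-mean-attribute")
        assert th2.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(
            response_prob(theta, tau.interior), response_prob(th2, tau2.interior)
        )


class TestCumulativeLogitCrossCheck:
    def test_likelihood_matches_statsmodels_ordered_model(self, rng):
        # independent route: statsmodels' ordinal regression evaluates the
        # same cumulative-logit likelihood under its own parameterization
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        n, L = 120, 4
        X = rng.integers(0, 2, size=(n, 2)).astype(float)
        beta = np.array([0.8, -0.5])
        cuts = np.array([-1.0, 0.2, 1.1])
        theta = X @ beta
        y = np.array(
            [rng.choice(L, p=response_prob(t, cuts)) for t in theta]
        )
        if len(np.unique(y)) < L:  # all categories must occur for statsmodels
            y[:L] = np.arange(L)
        sm_model = OrderedModel(y, X, distr="logit")
        sm_params = np.r_[beta, cuts[0], np.log(np.diff(cuts))]
        want = sm_model.loglike(sm_params)
        counts = np.zeros((n, L))
        counts[np.arange(n), y] = 1
        got = attribute_log_likelihood(counts, theta, cuts)
        assert got == pytest.approx(want, rel=1e-10)


class TestAttributeLogLikelihood:
    def test_zero_records_gives_zero(self):
        tau = thresholds_from_raw(np.zeros(5))
        assert attribute_log_likelihood(np.zeros((3, 5)), np.zeros(3), tau) == 0.0

    def test_single_record_is_log_of_its_probability(self):
        tau = thresholds_from_raw(np.array([0.0, 0.5, 1.0, 0.2, 0.9]))
        counts = np.zeros((2, 5))
        counts[1, 3] = 1
        theta = np.array([0.0, 0.7])
        p = response_prob(0.7, tau.interior)[3]
        assert attribute_log_likelihood(counts, theta, tau) == pytest.approx(np.log(p))

    def test_matches_per_record_brute_force(self, rng):
        tau = thresholds_from_raw(rng.normal(size=6))
        theta = rng.normal(size=4)
        records = [(rng.integers(4), rng.integers(5)) for _ in range(10)]
        counts = np.zeros((4, 6))
        brute = 0.0
        for cell, level in records:
            counts[cell, level] += 1
            brute += np.log(response_prob(theta[cell], tau.interior)[level])
        assert attribute_log_likelihood(counts, theta, tau) == pytest.approx(brute)

    def test_gradient_matches_finite_differences(self, rng):
        counts = rng.integers(0, 5, size=(3, 5)).astype(float)
        theta = rng.normal(size=3)
        interior = np.sort(rng.normal(size=4))
        ll, dth, dta = ordinal_loglik_grad(counts, theta, interior)
        eps = 1e-6
        for c in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[c] += eps
            tm[c] -= eps
            fd = (
                ordinal_loglik_grad(counts, tp, interior)[0]
                - ordinal_loglik_grad(counts, tm, interior)[0]
            ) / (2 * eps)
            assert dth[c] == pytest.approx(fd, rel=1e-5, abs=1e-7)
        for m in range(4):
            ip, im = interior.copy(), interior.copy()
            ip[m] += eps
            im[m] -= eps
            fd = (
                ordinal_loglik_grad(counts, theta, ip)[0]
                - ordinal_loglik_grad(counts, theta, im)[0]
            ) / (2 * eps)
            assert dta[m] == pytest.approx(fd, rel=1e-5, abs=1e-7)
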