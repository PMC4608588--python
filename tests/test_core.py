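"""Unit and property tests of the DLR probability layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import dlogit as dl
from dlogit.core import DLRParams


def params(beta0=0.0, beta=(0.0,), lam=0.0):
    return DLRParams.from_lam(beta0, np.asarray(beta), lam)


class TestParams:
    def test_mu_lam_consistency(self):
        p = DLRParams.from_mu(0.0, [1.0], mu=0.25)
        assert p.lam == pytest.approx(0.2)
        q = DLRParams.from_lam(0.0, [1.0], lam=0.2)
        assert q.mu == pytest.approx(0.25)

    @pytest.mark.parametrize("lam", [-0.1, 1.0, 1.5])
    def test_lam_domain(self, lam):
        with pytest.raises(ValueError):
            DLRParams.from_lam(0.0, [1.0], lam)

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            DLRParams.from_mu(0.0, [1.0], mu=-0.01)


class TestLinearPredictor:
    def test_null_model_is_zero(self):
        eta = dl.linear_predictor(params(0.0, (0.0, 0.0)), np.ones((5, 2)))
        assert np.all(eta == 0.0)

    def test_affine_arithmetic(self):
        eta = dl.linear_predictor(params(1.0, (2.0,)), [[3.0]])
        assert eta == pytest.approx([7.0])

    def test_matches_dot_product_oracle(self, rng):
        b0, b = -2.953, rng.normal(size=4)
        X = rng.normal(size=(10, 4))
        eta = dl.linear_predictor(params(b0, b), X)
        oracle = [b0 + sum(bj * xj for bj, xj in zip(b, row)) for row in X]
        assert eta == pytest.approx(oracle)

    def test_shape_error(self):
        with pytest.raises(ValueError, match="shape"):
            dl.linear_predictor(params(0.0, (1.0, 2.0)), np.ones((4, 3)))


class TestProbabilities:
    def test_logistic_symmetry_and_value(self):
        assert dl.prob_case(params(), [[0.0]]) == pytest.approx([0.5])
        p2 = dl.prob_case(params(2.0, (0.0,)), [[1.0]])
        assert p2 == pytest.approx([np.exp(2) / (1 + np.exp(2))])
        assert p2 == pytest.approx([0.8807971], abs=1e-7)

    def test_extreme_eta_stable(self):
        p = dl.prob_case(params(-700.0, (0.0,)), [[0.0]])
        assert np.isfinite(p).all() and p[0] == pytest.approx(0.0, abs=1e-300)
        hi = dl.prob_case(params(700.0, (0.0,)), [[0.0]])
        assert hi[0] == pytest.approx(1.0)

    def test_observed_case_scales_by_one_minus_lam(self):
        # P(y=1|x) = 0.5 at eta = 0; with lam = 0.2, P(z=1|x) = 0.4
        assert dl.prob_observed_case(params(lam=0.2), [[0.0]]) == pytest.approx([0.4])
        assert dl.prob_control(params(lam=0.2), [[0.0]]) == pytest.approx([0.6])

    def test_no_contamination_reduces_to_logistic(self, rng):
        X = rng.normal(size=(20, 1))
        p = params(0.3, (1.1,), lam=0.0)
        np.testing.assert_allclose(dl.prob_observed_case(p, X), dl.prob_case(p, X))

    def test_full_contamination_limit(self):
        p = DLRParams.from_lam(5.0, [0.0], lam=1 - 1e-12)
        assert dl.prob_observed_case(p, [[0.0]]) == pytest.approx([0.0], abs=1e-11)

    @given(lam=st.floats(0.0, 0.999), eta=st.floats(-700, 700))
    @settings(deadline=None, derandomize=True)
    def test_normalization_property(self, lam, eta):
        p = DLRParams.from_lam(eta, [0.0], lam)
        X = [[0.0]]
        total = dl.prob_observed_case(p, X) + dl.prob_control(p, X)
        assert total == pytest.approx([1.0], abs=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.1, 0.5, 0.9])
    def test_defectiveness_bound(self, lam):
        eta = np.linspace(-40, 40, 401).reshape(-1, 1)
        p = DLRParams.from_lam(0.0, [1.0], lam)
        assert dl.prob_observed_case(p, eta).max() <= 1 - lam + 1e-15
        assert dl.prob_control(p, eta).min() >= lam - 1e-15


class TestPosterior:
    def test_zero_when_no_contamination(self, rng):
        p = params(0.5, (1.0,), lam=0.0)
        assert np.all(dl.prob_case_given_control(p, rng.normal(size=(9, 1))) == 0.0)

    def test_bayes_hand_value(self):
        # lam=0.2, P(y=1|x)=0.5: posterior = 0.2*0.5 / 0.6
        post = dl.prob_case_given_control(params(lam=0.2), [[0.0]])
        assert post == pytest.approx([0.1 / 0.6])

    def test_certain_case_must_be_mislabeled(self):
        post = dl.prob_case_given_control(params(40.0, (0.0,), lam=0.05), [[0.0]])
        assert post == pytest.approx([1.0], abs=1e-12)

    @given(lam=st.floats(0.01, 0.95), eta=st.floats(-30, 30))
    @settings(deadline=None, derandomize=True)
    def test_matches_two_cell_bayes_table(self, lam, eta):
        """Brute-force joint table: P(y=1,z=0) = lam*p, P(y=0,z=0) = 1-p."""
        p = expit(eta)
        table_posterior = lam * p / (lam * p + (1 - p))
        got = dl.prob_case_given_control(params(eta, (0.0,), lam), [[0.0]])
        assert got == pytest.approx([table_posterior], rel=1e-9, abs=1e-12)
        assert 0.0 <= got[0] <= 1.0


class TestLogLikelihood:
    def test_four_row_hand_summation(self):
        lam, b0, b1 = 0.3, -0.2, 0.8
        X = np.array([[0.5], [-1.0], [2.0], [0.0]])
        z = np.array([1, 0, 1, 0])
        p = expit(b0 + b1 * X[:, 0])
        hand = sum(
            np.log((1 - lam) * pi) if zi else np.log(1 - (1 - lam) * pi)
            for zi, pi in zip(z, p)
        )
        got = dl.log_likelihood(params(b0, (b1,), lam), X, z)
        assert got == pytest.approx(hand, rel=1e-12)

    def test_reduces_to_bernoulli_loglik_at_lam_zero(self, random_dataset, rng):
        b0, b = 0.2, rng.normal(size=random_dataset.p)
        p = expit(b0 + random_dataset.X @ b)
        z = random_dataset.z
        plain = np.sum(z * np.log(p) + (1 - z) * np.log1p(-p))
        got = dl.log_likelihood(params(b0, b, 0.0), random_dataset.X, z)
        assert got == pytest.approx(plain, abs=1e-10)

    def test_marginal_identity(self, rng):
        # mean P(y=1|x) = mean P(z=1|x) / (1 - lam), an algebraic identity
        p = params(0.1, (0.7,), lam=0.35)
        X = rng.normal(size=(500, 1))
        lhs = dl.prob_case(p, X).mean()
        rhs = dl.prob_observed_case(p, X).mean() / (1 - 0.35)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_no_log_zero_at_extreme_eta(self):
        X = np.array([[-800.0], [800.0]])
        z = np.array([0, 1])
        ll = dl.log_likelihood(params(0.0, (1.0,), 0.1), X, z)
        assert np.isfinite(ll)


class TestExpectedMislabeled:
    @pytest.mark.parametrize(
        "mu, n1, value, reported",
        [(0.180, 49, 8.82, 9), (0.869, 133, 115.577, 116), (0.0, 10, 0.0, 0)],
    )
    def test_count_and_rounding(self, mu, n1, value, reported):
        got = dl.expected_mislabeled(mu, n1)
        assert got == pytest.approx(value, abs=5e-3)
        assert dl.round_count(got) == reported

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            dl.expected_mislabeled(-0.1, 10)

    def test_round_half_away_from_zero(self):
        assert dl.round_count(8.5) == 9
        assert dl.round_count(-8.5) == -9
        assert dl.round_count(8.49) == 8
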