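"""Tests of maximum-likelihood fitting: plain logistic, DLR, profiles."""

import warnings

import numpy as np
import pytest

import dlogit as dl
from dlogit.model import ConvergenceError, DefectiveLogit

from conftest import make_random_dataset


def _fit_quiet(model, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(**kw)


class TestLogistic:
    def test_binary_covariate_equals_log_odds_ratio(self):
        # 2x2 table with counts (z, x): closed-form cross-product ratio
        n = {(0, 0): 40, (0, 1): 20, (1, 0): 15, (1, 1): 30}
        z = np.repeat([0, 0, 1, 1], [n[0, 0] + n[0, 1], 0, n[1, 0] + n[1, 1], 0])
        x = np.concatenate(
            [np.repeat([0.0, 1.0], [n[0, 0], n[0, 1]]),
             np.repeat([0.0, 1.0], [n[1, 0], n[1, 1]])]
        )
        data = dl.ContaminatedDataset(X=x.reshape(-1, 1), z=z)
        res = dl.fit_logistic(data)
        log_or = np.log(n[1, 1] * n[0, 0] / (n[1, 0] * n[0, 1]))
        assert res.beta[0] == pytest.approx(log_or, abs=1e-6)
        assert res.beta0 == pytest.approx(np.log(n[1, 0] / n[0, 0]), abs=1e-6)

    def test_intercept_only_balanced(self):
        data = dl.ContaminatedDataset(X=np.empty((40, 0)), z=np.tile([0, 1], 20))
        res = dl.fit_logistic(data)
        assert res.beta0 == pytest.approx(0.0, abs=1e-8)

    def test_rank_deficiency_names_columns(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        X = np.column_stack([X[:, 0], X[:, 0] * 2.0, X[:, 1]])
        z = np.tile([0, 1], 25)
        with pytest.raises(np.linalg.LinAlgError, match="x"):
            DefectiveLogit(dl.ContaminatedDataset(X=X, z=z, names=("a", "a_x2", "b")))

    def test_separation_raises(self):
        x = np.concatenate([-1 - np.arange(10.0), 1 + np.arange(10.0)])
        z = np.repeat([0, 1], 10)
        with pytest.raises(ConvergenceError):
            dl.fit_logistic(dl.ContaminatedDataset(X=x.reshape(-1, 1), z=z))


class TestDLRFit:
    def test_loglik_at_least_logistic(self, study_fits):
        lr, dlr = study_fits
        assert dlr.llf >= lr.llf - 1e-9
        assert dlr.neg2loglik == pytest.approx(-2 * dlr.llf)

    @pytest.mark.parametrize("seed", range(10))
    def test_nesting_on_random_datasets(self, seed):
        data = make_random_dataset(seed)
        model = DefectiveLogit(data)
        lr = model.fit_logistic()
        dlr = _fit_quiet(model)
        assert dlr.neg2loglik <= lr.neg2loglik + 1e-7

    def test_recovers_contamination_scale(self, study_fits, study_contaminated):
        """67 of 200 cases relabeled: mu-hat should estimate a count near 67
        and its 95% interval is expected to cover the injected truth."""
        _, dlr = study_fits
        assert dlr.mu > 0
        ci = dlr.confint_mislabeled()
        assert ci.lower <= 67 <= ci.upper
        # point estimate on the right scale (not 0, not the whole stratum)
        assert 10 < dlr.expected_mislabeled() < study_contaminated.n0

    def test_scale_invariance(self, study_contaminated):
        model = DefectiveLogit(study_contaminated)
        base = _fit_quiet(model)
        c = 10.0
        X2 = study_contaminated.X.copy()
        X2[:, 0] *= c
        scaled = _fit_quiet(
            DefectiveLogit(dl.ContaminatedDataset(X=X2, z=study_contaminated.z,
                                                  y_true=study_contaminated.y_true))
        )
        assert scaled.llf == pytest.approx(base.llf, abs=1e-6)
        assert scaled.lam == pytest.approx(base.lam, abs=1e-6)
        assert scaled.beta[0] == pytest.approx(base.beta[0] / c, abs=1e-6)
        assert scaled.beta[1] == pytest.approx(base.beta[1], abs=1e-5)

    def test_boundary_flagged_and_lam_exact_zero(self):
        """On data simulated without contamination the MLE often sits at
        mu = 0; the fit must flag it, zero lambda exactly, and suppress
        the mu standard error."""
        for seed in range(30):
            data = dl.generate_dataset(
                dl.example_study_config(seed=seed, contamination=None))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = DefectiveLogit(data).fit()
            if res.boundary:
                break
        else:
            pytest.fail("no boundary fit found in 30 clean replicates")
        assert res.lam == 0.0 and res.mu == 0.0
        assert np.isnan(res.bse_mu)
        assert np.isfinite(res.bse.iloc[1:]).all()  # regression SEs still there
        with pytest.raises(ValueError, match="boundary"):
            res.wald_test_mu()

    def test_lam_upper_bound_respected(self, study_contaminated):
        model = DefectiveLogit(study_contaminated)
        res = _fit_quiet(model, bound_lambda=True)
        assert res.lam <= model.lam_upper + 1e-9

    def test_bad_start_length(self, study_contaminated):
        with pytest.raises(ValueError, match="start"):
            DefectiveLogit(study_contaminated).fit(start=np.zeros(2))

    def test_predict_kinds(self, study_fits, study_contaminated):
        _, dlr = study_fits
        p = dlr.predict(which="case")
        pz = dlr.predict(which="observed")
        post = dlr.predict(which="case_given_control")
        np.testing.assert_allclose(pz, (1 - dlr.lam) * p)
        assert np.all((post >= 0) & (post <= 1))
        with pytest.raises(ValueError):
            dlr.predict(which="nope")

    def test_summary_mentions_key_quantities(self, study_fits):
        lr, dlr = study_fits
        s = dlr.summary()
        assert "mu" in s and "-2*log(L)" in s and "lambda" in s
        assert f"{dlr.neg2loglik:.2f}" in s
        assert f"{lr.neg2loglik:.2f}" in lr.summary()


class TestProfile:
    def test_profile_properties(self, study_contaminated, study_fits):
        lr, dlr = study_fits
        model = DefectiveLogit(study_contaminated)
        # grid includes lambda-hat so profiling there must recover the joint max
        grid = np.unique(np.concatenate([np.linspace(0.0, 0.8, 25), [dlr.lam]]))
        curve = model.profile_lambda(lam_grid=grid)
        # at lam = 0 the profile is the plain logistic fit
        assert curve.profile_loglik[0] == pytest.approx(lr.llf, abs=1e-6)
        # the curve max matches the joint MLE within optimizer tolerance
        assert curve.profile_loglik.max() == pytest.approx(dlr.llf, abs=1e-4)
        # argmax within one grid step of lambda-hat
        step = 0.8 / 24
        assert abs(curve.argmax_lam - dlr.lam) <= step + 1e-12
        # unimodal synthetic instance: decreasing beyond the maximum
        imax = int(np.argmax(curve.profile_loglik))
        assert np.all(np.diff(curve.profile_loglik[imax:]) <= 1e-8)
        assert curve.converged.all()

    def test_bad_grid(self, study_contaminated):
        model = DefectiveLogit(study_contaminated)
        with pytest.raises(ValueError):
            model.profile_lambda(lam_grid=np.array([0.3, 0.2]))
        with pytest.raises(ValueError):
            model.profile_lambda(lam_grid=np.array([0.0, 1.0]))
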