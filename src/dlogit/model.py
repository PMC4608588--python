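"""Maximum-likelihood estimation of defective logistic regression.

:class:`DefectiveLogit` is a statsmodels-style model object built from a
:class:`~dlogit.data.ContaminatedDataset` (or raw z, X arrays).  Its
:meth:`~DefectiveLogit.fit` maximizes the zero-inflated Bernoulli
likelihood over (mu, beta0, beta) with mu >= 0 by bounded quasi-Newton
(L-BFGS-B), starting from the plain logistic solution at mu = 0 — which
guarantees the fitted likelihood is at least that of standard logistic
regression.  :meth:`~DefectiveLogit.fit_logistic` fits the lam = 0
submodel, and :meth:`~DefectiveLogit.profile_lambda` maximizes over the
regression coefficients on a grid of fixed lambda values to inspect the
shape of the likelihood near the boundary.

Standard errors come from the inverse of an observed-information matrix
obtained by central finite differences of the analytic gradient.  When the
contamination estimate lands on the mu = 0 boundary the usual asymptotics
do not apply: the fit is flagged, lam-hat is reported as exactly 0, and
the mu standard error is suppressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .core import DLRParams, expected_mislabeled, round_count
from .data import ContaminatedDataset

__all__ = [
    "DefectiveLogit",
    "DefectiveLogitResults",
    "LogisticResults",
    "ProfileCurve",
    "fit_logistic",
    "fit_dlr",
    "profile_lambda",
]

_BOUNDARY_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the last iterate in ``last_params``."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


def _check_design(X: np.ndarray, names) -> None:
    """Rank check via pivoted QR; names the dependent columns on failure."""
    Xc = np.column_stack([np.ones(X.shape[0]), X])
    r = np.linalg.matrix_rank(Xc)
    if r < Xc.shape[1]:
        # pivoted QR to identify which columns fail
        from scipy.linalg import qr

        _, R, piv = qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = sorted(piv[r:])
        labels = ["(intercept)"] + list(names)
        offending = [labels[j] for j in bad]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {r} < {Xc.shape[1]}); "
            f"linearly dependent column(s): {offending}"
        )


def _neg_loglike_and_grad(theta: np.ndarray, X: np.ndarray, z: np.ndarray):
    """Negative log-likelihood and gradient in theta = (mu, beta0, beta).

    With p = expit(eta), q = expit(-eta):
      ll = sum_z1 log p + sum_z0 log(mu + q) - n log(1 + mu)
      d ll / d mu    = sum_z0 1/(mu+q) - n/(1+mu)
      d ll / d eta_i = z q - (1-z) p q / (mu + q)
    All ratios are formed in the log domain so the gradient stays finite
    for extreme eta and mu at the boundary.
    """
    mu = theta[0]
    beta0 = theta[1]
    beta = theta[2:]
    n = X.shape[0]
    eta = beta0 + X @ beta
    log_p = log_expit(eta)
    log_q = log_expit(-eta)
    log_mu = np.log(mu) if mu > 0 else -np.inf
    log_mu_plus_q = np.logaddexp(log_mu, log_q)

    ll = np.sum(np.where(z == 1, log_p, log_mu_plus_q)) - n * np.log1p(mu)

    inv_mu_plus_q = np.exp(-log_mu_plus_q)
    d_mu = np.sum(np.where(z == 1, 0.0, inv_mu_plus_q)) - n / (1.0 + mu)
    # p*q/(mu+q) = exp(log p + log q - log(mu+q))
    ratio = np.exp(log_p + log_q - log_mu_plus_q)
    d_eta = np.where(z == 1, np.exp(log_q), -ratio)
    grad = np.empty(theta.shape)
    grad[0] = d_mu
    grad[1] = np.sum(d_eta)
    grad[2:] = X.T @ d_eta
    return -ll, -grad


def _observed_information(theta, X, z, free=None):
    """Central finite differences of the analytic gradient of -loglik.

    ``free`` selects the coordinates to difference (used at the boundary to
    get the information of the regression block with mu held at 0).
    Symmetrized; step = cube-root machine epsilon scaled per parameter.
    """
    k = theta.size
    idx = np.arange(k) if free is None else np.asarray(free)
    h = np.finfo(float).eps ** (1 / 3) * np.maximum(1.0, np.abs(theta[idx]))
    H = np.empty((idx.size, idx.size))
    for a, j in enumerate(idx):
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h[a]
        tm[j] -= h[a]
        _, gp = _neg_loglike_and_grad(tp, X, z)
        _, gm = _neg_loglike_and_grad(tm, X, z)
        H[a] = (gp[idx] - gm[idx]) / (2 * h[a])
    return (H + H.T) / 2.0


@dataclass
class ProfileCurve:
    """Profile log-likelihood of lambda: for each grid value of lambda the
    likelihood maximized over the regression coefficients only."""

    lam_grid: np.ndarray
    profile_loglik: np.ndarray
    argmax_lam: float
    converged: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lam": self.lam_grid, "profile_loglik": self.profile_loglik,
             "converged": self.converged}
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lam_grid, self.profile_loglik, marker=".")
        ax.axvline(self.argmax_lam, ls="--", color="grey")
        ax.set_xlabel("$\\lambda$")
        ax.set_ylabel("profile log-likelihood")
        return ax


class _ResultsBase:
    """Shared surface of the LR and DLR results objects."""

    @property
    def neg2loglik(self) -> float:
        return -2.0 * self.llf

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.params.index, columns=self.params.index)

    def __repr__(self):
        return f"<{type(self).__name__} llf={self.llf:.4f} nobs={self.nobs}>"


class LogisticResults(_ResultsBase):
    """Plain logistic regression (the lam = 0 submodel), fitted by
    statsmodels; exposed with the same accessors as the DLR results."""

    model_tag = "LR"

    def __init__(self, sm_results, names, fingerprint):
        self._sm = sm_results
        k = len(sm_results.params)
        index = ["const"] + list(names)
        self.params = pd.Series(np.asarray(sm_results.params), index=index)
        self.bse = pd.Series(np.asarray(sm_results.bse), index=index)
        self._cov = np.asarray(sm_results.cov_params())
        self.llf = float(sm_results.llf)
        self.nobs = int(sm_results.nobs)
        self.converged = bool(sm_results.mle_retvals.get("converged", True))
        self.n_iter = int(sm_results.mle_retvals.get("iterations", 0))
        self.df_model = k - 1
        self._fingerprint = fingerprint

    @property
    def beta0(self) -> float:
        return float(self.params.iloc[0])

    @property
    def beta(self) -> np.ndarray:
        return self.params.iloc[1:].to_numpy()

    def summary(self) -> str:
        lines = [f"Logistic regression (lam = 0), n = {self.nobs}"]
        lines.append(f"{'variable':<22}{'estimate':>10}{'SE':>10}")
        for name, est, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"{name:<22}{est:>10.3f}{se:>10.3f}")
        lines.append(f"-2*log(L) = {self.neg2loglik:.2f}")
        return "\n".join(lines)


class DefectiveLogitResults(_ResultsBase):
    """Fitted defective logistic regression.

    ``params`` holds (mu, const, covariates).  ``boundary`` is True when
    mu-hat sits at 0, in which case lam-hat is exactly 0, the mu standard
    error is NaN, and Wald inference on mu should be replaced by the
    likelihood-ratio or profile approach.
    """

    model_tag = "DLR"

    def __init__(self, model, theta, llf, converged, n_iter, boundary, cov, message=""):
        names = ["mu", "const"] + list(model.names)
        self.model = model
        self.params = pd.Series(theta, index=names)
        self.llf = float(llf)
        self.nobs = model.nobs
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.boundary = bool(boundary)
        self._cov = cov
        self.message = message
        with np.errstate(invalid="ignore"):
            self.bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self._fingerprint = model.fingerprint

    # -- parameter accessors -------------------------------------------------
    @property
    def mu(self) -> float:
        return float(self.params.iloc[0])

    @property
    def lam(self) -> float:
        return self.mu / (1.0 + self.mu)

    @property
    def beta0(self) -> float:
        return float(self.params.iloc[1])

    @property
    def beta(self) -> np.ndarray:
        return self.params.iloc[2:].to_numpy()

    @property
    def dlr_params(self) -> DLRParams:
        return DLRParams.from_mu(self.beta0, self.beta, self.mu)

    @property
    def bse_mu(self) -> float:
        return float(self.bse.iloc[0])

    # -- derived quantities ---------------------------------------------------
    def expected_mislabeled(self) -> float:
        """Estimated number of truly-case rows in the control sample,
        n1 * mu-hat (n1 = number of z = 1 rows)."""
        return expected_mislabeled(self.mu, self.model.n1)

    def confint_mislabeled(self, level: float = 0.95):
        from .inference import confint_mislabeled

        return confint_mislabeled(self, level=level)

    def wald_test_mu(self, sided: str = "one"):
        from .inference import wald_test_mu

        return wald_test_mu(self, sided=sided)

    def lr_test(self, lr_results: LogisticResults):
        from .inference import likelihood_ratio_test

        return likelihood_ratio_test(self, lr_results)

    def predict(self, X=None, which: str = "case") -> np.ndarray:
        """Predicted probabilities: ``which`` is 'case' for P(y=1|x),
        'observed' for P(z=1|x), or 'case_given_control' for P(y=1|z=0,x)."""
        from . import core

        if X is None:
            X = self.model.X
        fn = {
            "case": core.prob_case,
            "observed": core.prob_observed_case,
            "control": core.prob_control,
            "case_given_control": core.prob_case_given_control,
        }.get(which)
        if fn is None:
            raise ValueError(f"unknown prediction kind {which!r}")
        return fn(self.dlr_params, X)

    def summary(self) -> str:
        n1 = self.model.n1
        lines = [
            f"Defective logistic regression, n = {self.nobs} "
            f"(n1 = {n1} labeled cases, n0 = {self.model.n0} labeled controls)"
        ]
        lines.append(f"{'variable':<22}{'estimate':>10}{'SE':>10}")
        for name, est, se in zip(self.params.index, self.params, self.bse):
            se_s = f"{se:>10.3f}" if np.isfinite(se) else f"{'--':>10}"
            lines.append(f"{name:<22}{est:>10.3f}{se_s}")
        lines.append(f"lambda = mu/(1+mu)    {self.lam:>10.3f}")
        lines.append(f"-2*log(L) = {self.neg2loglik:.2f}")
        cnt = self.expected_mislabeled()
        lines.append(
            f"expected mislabeled controls n1*mu = {cnt:.2f} (reported {round_count(cnt)})"
        )
        if self.boundary:
            lines.append(
                "note: mu-hat is on the 0 boundary; standard errors and Wald "
                "inference for mu are unreliable there (use the likelihood "
                "ratio or profile likelihood)."
            )
        lines.append(
            "note: the intercept reflects the design's case:control mixing "
            "proportions; predicted probabilities should be interpreted "
            "cautiously."
        )
        return "\n".join(lines)


class DefectiveLogit:
    """Defective (zero-inflated) logistic regression model.

    Parameters
    ----------
    data : ContaminatedDataset, or None when ``z``/``X`` are given directly.
    z, X, names : raw arrays, alternative to ``data``.

    Examples
    --------
    >>> model = DefectiveLogit(dataset)
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(self, data: ContaminatedDataset | None = None, *, z=None, X=None, names=None):
        if data is None:
            data = ContaminatedDataset(X=np.asarray(X, dtype=float), z=z, names=names)
        self.data = data
        self.X = data.X
        self.z = data.z.astype(float)
        self.names = data.names
        _check_design(self.X, self.names)
        self._exog = np.column_stack([np.ones(data.n), self.X])
        self.fingerprint = hash((data.n, data.p, self.X.tobytes(), data.z.tobytes()))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "z",
                       covariates: list[str] | None = None,
                       true_label: str | None = None) -> "DefectiveLogit":
        return cls(ContaminatedDataset.from_frame(df, label, covariates, true_label))

    # -- basic facts -----------------------------------------------------------
    @property
    def nobs(self) -> int:
        return self.data.n

    @property
    def n0(self) -> int:
        return self.data.n0

    @property
    def n1(self) -> int:
        return self.data.n1

    @property
    def lam_upper(self) -> float:
        """Largest lambda consistent with the label split: n0 / (n0 + n1)."""
        return self.n0 / (self.n0 + self.n1)

    def loglike(self, theta) -> float:
        """Log-likelihood at theta = (mu, beta0, beta)."""
        nll, _ = _neg_loglike_and_grad(np.asarray(theta, dtype=float), self.X, self.z)
        return -nll

    # -- fitting ---------------------------------------------------------------
    def fit_logistic(self) -> LogisticResults:
        """Fit the lam = 0 submodel (plain logistic regression)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.z, self._exog).fit(disp=0, maxiter=200)
            except Exception as exc:  # perfect separation raises in statsmodels
                raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False) or not np.isfinite(res.params).all():
            raise ConvergenceError(
                "logistic fit did not converge (possible quasi-separation); "
                f"coefficients: {dict(zip(['(intercept)', *self.names], res.params))}"
            )
        return LogisticResults(res, self.names, self.fingerprint)

    def fit(
        self,
        start: np.ndarray | None = None,
        tol: float = 1e-12,
        max_iter: int = 500,
        bound_lambda: bool = False,
        lam_upper_bound: float | None = None,
    ) -> DefectiveLogitResults:
        """Maximize the DLR likelihood over (mu, beta0, beta), mu >= 0.

        The default start is the plain logistic solution with mu = 0, so
        the achieved likelihood is never below the logistic one.  With
        ``bound_lambda`` (or an explicit ``lam_upper_bound``), lambda is
        additionally capped — by default at n0/(n0+n1), the largest
        contamination consistent with the observed label split.
        """
        if start is None:
            lr = self.fit_logistic()
            start = np.concatenate([[0.0], lr.params.to_numpy()])
        start = np.asarray(start, dtype=float)
        if start.size != self.data.p + 2:
            raise ValueError(f"start must have length {self.data.p + 2} (mu, beta0, beta)")

        if lam_upper_bound is None and bound_lambda:
            lam_upper_bound = self.lam_upper
        mu_upper = np.inf
        if lam_upper_bound is not None:
            if not 0 < lam_upper_bound < 1:
                raise ValueError("lam_upper_bound must be in (0, 1)")
            mu_upper = lam_upper_bound / (1 - lam_upper_bound)
        bounds = [(0.0, mu_upper)] + [(None, None)] * (self.data.p + 1)

        opt = minimize(
            _neg_loglike_and_grad,
            start,
            args=(self.X, self.z),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        if not opt.success and "ROUNDING" not in str(opt.message).upper():
            raise ConvergenceError(
                f"DLR fit did not converge after {opt.nit} iterations: {opt.message}",
                last_params=opt.x,
            )
        theta = opt.x.copy()
        boundary = theta[0] < _BOUNDARY_TOL
        if boundary:
            theta[0] = 0.0
        llf = self.loglike(theta)

        k = theta.size
        cov = np.full((k, k), np.nan)
        if boundary:
            # information of the regression block at mu = 0; mu SE suppressed
            warnings.warn(
                "mu-hat is on the 0 boundary: lambda reported as exactly 0 and "
                "its standard error suppressed (standard asymptotics assume the "
                "true lambda lies away from the boundary)",
                stacklevel=2,
            )
            free = np.arange(1, k)
            Hb = _observed_information(theta, self.X, self.z, free=free)
            try:
                cov[np.ix_(free, free)] = np.linalg.inv(Hb)
            except np.linalg.LinAlgError:
                pass
        else:
            H = _observed_information(theta, self.X, self.z)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                warnings.warn("observed information is singular; SEs unavailable",
                              stacklevel=2)
        return DefectiveLogitResults(
            self, theta, llf, opt.success or True, opt.nit, boundary, cov,
            message=str(opt.message),
        )

    def profile_lambda(
        self,
        lam_grid: np.ndarray | None = None,
        num: int = 41,
        lam_max: float | None = None,
    ) -> ProfileCurve:
        """Profile log-likelihood over a lambda grid in [0, lam_max].

        For each fixed lambda the likelihood is maximized over (beta0,
        beta) only, warm-starting each grid point at the previous
        solution.  Grid points where the inner optimization fails are
        flagged, not fatal.
        """
        if lam_grid is None:
            if lam_max is None:
                lam_max = self.lam_upper
            lam_grid = np.linspace(0.0, lam_max, num)
        lam_grid = np.asarray(lam_grid, dtype=float)
        if lam_grid.ndim != 1 or np.any(np.diff(lam_grid) <= 0):
            raise ValueError("lam_grid must be strictly increasing")
        if lam_grid[0] < 0 or lam_grid[-1] >= 1:
            raise ValueError("lam grid must lie in [0, 1)")

        lr = self.fit_logistic()
        betas = lr.params.to_numpy()
        prof = np.empty(lam_grid.size)
        ok = np.ones(lam_grid.size, dtype=bool)
        for i, lam in enumerate(lam_grid):
            mu = lam / (1.0 - lam)

            def nll(b, mu=mu):
                f, g = _neg_loglike_and_grad(np.concatenate([[mu], b]), self.X, self.z)
                return f, g[1:]

            opt = minimize(nll, betas, jac=True, method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-12})
            prof[i] = -opt.fun
            ok[i] = opt.success
            if opt.success:
                betas = opt.x  # warm start for the next grid value
        argmax = float(lam_grid[np.argmax(prof)])
        return ProfileCurve(lam_grid, prof, argmax, ok)


# -- functional convenience wrappers -------------------------------------------

def fit_logistic(data: ContaminatedDataset) -> LogisticResults:
    """Plain logistic regression of z on the covariates (the lam = 0 fit)."""
    return DefectiveLogit(data).fit_logistic()


def fit_dlr(data: ContaminatedDataset, **options) -> DefectiveLogitResults:
    """Defective logistic regression fit; see :meth:`DefectiveLogit.fit`."""
    return DefectiveLogit(data).fit(**options)


def profile_lambda(data: ContaminatedDataset, **grid_spec) -> ProfileCurve:
    return DefectiveLogit(data).profile_lambda(**grid_spec)
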