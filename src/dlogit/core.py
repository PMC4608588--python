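"""Probability model for defective logistic regression (DLR).

A binary classifier is trained on case-control data in which the control
sample is contaminated: a fraction of the rows labeled ``z = 0`` are in
truth cases (``y = 1``), while every row labeled ``z = 1`` really is a
case.  Let

    P(y = 1 | x) = expit(beta0 + beta' x)

be the true logistic discrimination function and let
``lam = P(z = 0 | y = 1)`` be the mislabeling probability, assumed
constant across covariates.  Then the observed label follows

    P(z = 1 | x) = (1 - lam) * expit(beta0 + beta' x),

a *defective* logistic curve that saturates at ``1 - lam`` instead of 1 —
formally a zero-inflated Bernoulli regression.  Maximizing the Bernoulli
likelihood of z under this curve recovers (beta0, beta, lam) jointly, and
``n1 * lam / (1 - lam)`` estimates how many labeled controls are actually
cases, where ``n1`` is the number of z = 1 rows.

This module holds the parameter container and the pure, vectorized
probability/likelihood functions; fitting lives in :mod:`dlogit.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "DLRParams",
    "linear_predictor",
    "prob_case",
    "prob_observed_case",
    "prob_control",
    "prob_case_given_control",
    "log_likelihood",
    "expected_mislabeled",
    "round_count",
]


def _mu_from_lam(lam: float) -> float:
    return lam / (1.0 - lam)


def _lam_from_mu(mu: float) -> float:
    return mu / (1.0 + mu)


@dataclass(frozen=True)
class DLRParams:
    """Parameters of the defective logistic model.

    The contamination probability ``lam`` (lambda) and its odds
    reparameterization ``mu = lam / (1 - lam)`` are kept consistent; build
    instances with :meth:`from_lam` or :meth:`from_mu`.  ``mu`` is the
    internal canonical scale: it is unbounded above and puts the
    no-contamination boundary at a plain 0, and its profile likelihood is
    more symmetric than lambda's.
    """

    beta0: float
    beta: np.ndarray
    lam: float
    mu: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if not 0.0 <= self.lam < 1.0:
            raise ValueError(f"lam must lie in [0, 1), got {self.lam}")
        mu = _mu_from_lam(self.lam) if self.mu is None else self.mu
        if mu < 0:
            raise ValueError(f"mu must be nonnegative, got {mu}")
        if abs(_lam_from_mu(mu) - self.lam) > 1e-12:
            raise ValueError("lam and mu are inconsistent")
        object.__setattr__(self, "mu", mu)

    @classmethod
    def from_lam(cls, beta0: float, beta, lam: float) -> "DLRParams":
        return cls(beta0=float(beta0), beta=beta, lam=float(lam))

    @classmethod
    def from_mu(cls, beta0: float, beta, mu: float) -> "DLRParams":
        if mu < 0:
            raise ValueError(f"mu must be nonnegative, got {mu}")
        return cls(beta0=float(beta0), beta=beta, lam=_lam_from_mu(float(mu)), mu=float(mu))

    @property
    def p(self) -> int:
        return self.beta.shape[0]


def _as_matrix(X, p: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1) if p > 1 else X.reshape(-1, 1)
    if X.ndim != 2 or X.shape[1] != p:
        raise ValueError(
            f"covariate matrix has shape {X.shape}, expected (n, {p}) to match beta"
        )
    return X


def linear_predictor(params: DLRParams, X) -> np.ndarray:
    """eta_i = beta0 + beta' x_i for each row of X."""
    X = _as_matrix(X, params.p)
    return params.beta0 + X @ params.beta


def prob_case(params: DLRParams, X) -> np.ndarray:
    """P(y = 1 | x): the underlying (uncontaminated) logistic curve."""
    return expit(linear_predictor(params, X))


def prob_observed_case(params: DLRParams, X) -> np.ndarray:
    """P(z = 1 | x) = (1 - lam) * P(y = 1 | x), bounded by 1 - lam."""
    return (1.0 - params.lam) * prob_case(params, X)


def prob_control(params: DLRParams, X) -> np.ndarray:
    """P(z = 0 | x) = 1 - (1 - lam) * P(y = 1 | x), bounded below by lam."""
    return 1.0 - prob_observed_case(params, X)


def prob_case_given_control(params: DLRParams, X) -> np.ndarray:
    """Posterior P(y = 1 | z = 0, x): probability that a labeled control
    is in truth a case.

    By Bayes' rule on the joint model,
    ``lam * P(y=1|x) / P(z=0|x)``; identically 0 when lam = 0, and 1 for
    any lam > 0 when P(y=1|x) = 1 (a certain case seen with a control
    label must be mislabeled).
    """
    if params.lam == 0.0:
        return np.zeros(_as_matrix(X, params.p).shape[0])
    p = prob_case(params, X)
    return params.lam * p / (1.0 - (1.0 - params.lam) * p)


def _log_prob_terms(mu: float, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable (log P(z=1|x), log P(z=0|x)) on the mu scale.

    With q = expit(-eta):  P(z=1) = expit(eta)/(1+mu)  and
    P(z=0) = (mu + q)/(1 + mu).  Both logs are formed in the log domain so
    neither large |eta| nor mu at the boundary produces log(0) spuriously.
    """
    log_p = log_expit(eta)
    log_q = log_expit(-eta)
    log1pmu = np.log1p(mu)
    if mu > 0:
        log_mu_plus_q = np.logaddexp(np.log(mu), log_q)
    else:
        log_mu_plus_q = log_q
    return log_p - log1pmu, log_mu_plus_q - log1pmu


def log_likelihood(params: DLRParams, X, z) -> float:
    """Bernoulli log-likelihood of observed labels z under the DLR model.

    sum_i [ z_i log P(z=1|x_i) + (1 - z_i) log P(z=0|x_i) ].
    At lam = 0 this is exactly the standard logistic log-likelihood.
    """
    z = np.asarray(z)
    eta = linear_predictor(params, X)
    if eta.shape != z.shape:
        raise ValueError("z length does not match number of rows in X")
    log_p1, log_p0 = _log_prob_terms(params.mu, eta)
    return float(np.sum(np.where(z == 1, log_p1, log_p0)))


def expected_mislabeled(mu: float, n1: int) -> float:
    """Expected number of labeled controls that are truly cases: n1 * mu.

    ``mu = lam / (1 - lam)``, so this is the n1 * lam / (1 - lam) count of
    mislabeled cases hiding in the control sample.  Returned unrounded;
    reporting layers use :func:`round_count`.
    """
    if mu < 0:
        raise ValueError(f"mu must be nonnegative, got {mu}")
    if n1 < 0:
        raise ValueError(f"n1 must be nonnegative, got {n1}")
    return float(n1) * float(mu)


def round_count(x: float) -> int:
    """Round half away from zero (8.82 -> 9, 115.6 -> 116, -0.5 -> -1)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))
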