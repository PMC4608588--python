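"""Tests of lambda = 0 and intervals for the mislabeled count.

The no-contamination hypothesis puts lambda (equivalently mu) on the
boundary of its parameter space, so the usual asymptotics are only a
guide.  Two tests are provided:

* a Wald test on the mu scale, one-sided by default (mu >= 0 by
  construction, so the alternative is mu > 0);
* a likelihood-ratio test of the defective model against plain logistic
  regression, referred to chi-square with 1 df.  At the boundary the
  standard chi2(1) reference is conservative; the 50:50 mixture of
  chi2(0) and chi2(1) is available via ``boundary_mixture=True`` and
  halves the p-value.

The mislabeled-count interval is a Wald interval for mu scaled by n1 and
truncated at zero: point n1*mu-hat, limits n1*(mu-hat +/- z*SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import round_count

__all__ = [
    "TestResult",
    "CountInterval",
    "wald_test_mu",
    "wald_test_from_estimate",
    "likelihood_ratio_test",
    "lrt_from_deviances",
    "confint_mislabeled",
    "mislabeled_count_interval",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_tag: str
    sided: str
    df: int | None = None
    note: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def __str__(self):
        s = f"{self.test_tag}: statistic = {self.statistic:.3f}"
        if self.df is not None:
            s += f", df = {self.df}"
        s += f", {self.sided}-sided P = {self.p_value:.4g}"
        if self.note:
            s += f"  [{self.note}]"
        return s


@dataclass(frozen=True)
class CountInterval:
    """Point estimate and confidence limits for the expected number of
    mislabeled controls, on the count scale (lower truncated at 0)."""

    point: float
    lower: float
    upper: float
    level: float

    def __post_init__(self):
        if not (0 <= self.lower <= self.point <= self.upper):
            raise ValueError("interval must satisfy 0 <= lower <= point <= upper")

    def rounded(self) -> tuple[int, int, int]:
        return round_count(self.point), round_count(self.lower), round_count(self.upper)

    def __str__(self):
        pt, lo, hi = self.rounded()
        return f"{pt} ({self.level:.0%} CI: {lo} to {hi})"


def wald_test_from_estimate(mu_hat: float, se_mu: float, sided: str = "one") -> TestResult:
    """Wald test of mu = 0 from an estimate and its standard error."""
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if not np.isfinite(se_mu) or se_mu <= 0:
        raise ValueError(
            "no usable standard error for mu (boundary fit?); use the "
            "likelihood-ratio test or the profile likelihood instead"
        )
    z = mu_hat / se_mu
    p = stats.norm.sf(z) if sided == "one" else 2 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(p), test_tag="wald_mu", sided=sided)


def wald_test_mu(fit, sided: str = "one") -> TestResult:
    """Wald test of lambda = 0 from a fitted DLR model (on the mu scale)."""
    if getattr(fit, "boundary", False):
        raise ValueError(
            "mu-hat is on the 0 boundary and its Wald SE is suppressed; "
            "use the likelihood-ratio test or the profile likelihood"
        )
    return wald_test_from_estimate(fit.mu, fit.bse_mu, sided=sided)


def lrt_from_deviances(neg2loglik_lr: float, neg2loglik_dlr: float) -> TestResult:
    """Likelihood-ratio test of DLR vs plain logistic from the two
    deviances (-2 log L); statistic clamped at 0, chi2(1) upper tail."""
    stat = max(0.0, float(neg2loglik_lr) - float(neg2loglik_dlr))
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(
        statistic=stat,
        p_value=p,
        test_tag="lrt",
        sided="one",
        df=1,
        note="lambda = 0 lies on the boundary of the parameter space; "
        "treat this chi-square p-value with caution",
    )


def likelihood_ratio_test(fit_dlr, fit_lr, boundary_mixture: bool = False) -> TestResult:
    """Likelihood-ratio test of the defective model against plain logistic.

    Both fits must come from the same dataset and covariates.  With
    ``boundary_mixture`` the p-value uses the 0.5*chi2(0) + 0.5*chi2(1)
    reference appropriate for a one-sided boundary test (half the plain
    chi2(1) tail when the statistic is positive).
    """
    if getattr(fit_dlr, "_fingerprint", None) != getattr(fit_lr, "_fingerprint", object()):
        raise ValueError("LR and DLR fits come from different datasets")
    res = lrt_from_deviances(fit_lr.neg2loglik, fit_dlr.neg2loglik)
    if boundary_mixture:
        p = 0.5 * res.p_value if res.statistic > 0 else 1.0
        res = TestResult(res.statistic, p, "lrt", "one", 1,
                         note="0.5*chi2(0) + 0.5*chi2(1) boundary reference")
    return res


def mislabeled_count_interval(
    mu_hat: float, se_mu: float, n1: int, level: float = 0.95
) -> CountInterval:
    """Wald interval for the expected mislabeled count n1*mu.

    The interval is built on the mu scale and multiplied by n1; truncation
    of the lower limit at 0 commutes with that scaling.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if not np.isfinite(se_mu) or se_mu < 0:
        raise ValueError("missing or invalid standard error for mu")
    zq = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, n1 * (mu_hat - zq * se_mu))
    hi = n1 * (mu_hat + zq * se_mu)
    return CountInterval(point=n1 * mu_hat, lower=lo, upper=hi, level=level)


def confint_mislabeled(fit, n1: int | None = None, level: float = 0.95) -> CountInterval:
    """Mislabeled-count interval from a fitted DLR model."""
    if n1 is None:
        n1 = fit.model.n1
    return mislabeled_count_interval(fit.mu, fit.bse_mu, n1, level=level)
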