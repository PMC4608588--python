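"""Synthetic case-control data with one-sided label noise.

The generator emulates the sampling scheme the model assumes: covariates
are drawn from user-specified distributions, true case status follows the
logistic P(y = 1 | x) = expit(beta0 + beta'x), the sample is stratified to
exactly n1 true cases and n0 true controls (rejection sampling per
stratum), and contamination relabels cases as controls — either an exact
count k (the artificial-mislabeling experiment) or independently with
probability lam per case.

Reproducibility contract: a single integer seed governs everything, and
per-replicate randomness is derived by ``numpy.random.SeedSequence``
spawning, so replicate r does not depend on how many replicates are run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .data import ContaminatedDataset
from .model import DefectiveLogit

__all__ = [
    "Covariate",
    "SimulationConfig",
    "generate_dataset",
    "contaminate",
    "ContaminationStudyResult",
    "repeated_contamination_study",
    "RecoveryResult",
    "recovery_experiment",
    "example_study_config",
]

_OVERSAMPLE_CAP = 1000  # refuse after drawing 1000x the stratum target


@dataclass(frozen=True)
class Covariate:
    """A covariate distribution: normal(mean, sd), bernoulli(p), or
    categorical(p0, p1, ...) taking integer levels 0..L-1."""

    kind: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.kind == "normal":
            if len(self.params) != 2 or self.params[1] <= 0:
                raise ValueError("normal needs (mean, sd > 0)")
        elif self.kind == "bernoulli":
            if len(self.params) != 1 or not 0 <= self.params[0] <= 1:
                raise ValueError("bernoulli needs one probability in [0, 1]")
        elif self.kind == "categorical":
            pr = np.asarray(self.params)
            if pr.size < 2 or (pr < 0).any() or abs(pr.sum() - 1) > 1e-9:
                raise ValueError("categorical needs >= 2 probabilities summing to 1")
        else:
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.params[0], self.params[1], size)
        if self.kind == "bernoulli":
            return rng.binomial(1, self.params[0], size).astype(float)
        return rng.choice(len(self.params), size=size, p=self.params).astype(float)

    @classmethod
    def parse(cls, text: str) -> "Covariate":
        m = re.fullmatch(r"\s*(\w+)\s*\(([^)]*)\)\s*", text)
        if not m:
            raise ValueError(f"cannot parse covariate spec {text!r}")
        params = tuple(float(v) for v in m.group(2).split(",") if v.strip())
        return cls(m.group(1).lower(), params)

    def __str__(self):
        return f"{self.kind}({', '.join(f'{v:g}' for v in self.params)})"


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one synthetic study.

    ``contamination`` is either a float lambda in [0, 1) — each true case
    is relabeled independently with that probability — or an int k giving
    the exact number of cases to relabel; None means clean labels.
    """

    n0: int
    n1: int
    beta0: float
    beta: tuple[float, ...]
    covariates: tuple[Covariate, ...]
    contamination: float | int | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("need at least one observation per stratum")
        if len(self.beta) != len(self.covariates):
            raise ValueError("beta length must match number of covariates")
        c = self.contamination
        if c is not None:
            if isinstance(c, (int, np.integer)) and not isinstance(c, bool):
                if not 0 <= c <= self.n1:
                    raise ValueError("k must satisfy 0 <= k <= n1")
            elif not 0 <= float(c) < 1:
                raise ValueError("lambda must lie in [0, 1)")

    # -- flat key=value (de)serialization for the CLI --------------------------
    def to_text(self) -> str:
        lines = [
            f"n0 = {self.n0}",
            f"n1 = {self.n1}",
            f"beta0 = {self.beta0:g}",
            f"beta = {','.join(f'{b:g}' for b in self.beta)}",
        ]
        for i, cov in enumerate(self.covariates, 1):
            lines.append(f"covariate{i} = {cov}")
        if self.contamination is not None:
            key = "contamination_k" if isinstance(self.contamination, (int, np.integer)) \
                else "contamination_lam"
            lines.append(f"{key} = {self.contamination:g}")
        lines.append(f"seed = {self.seed}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SimulationConfig":
        kv = {}
        for ln in text.splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise ValueError(f"config line without '=': {ln!r}")
            k, v = ln.split("=", 1)
            kv[k.strip().lower()] = v.strip()
        covs = [Covariate.parse(kv[k]) for k in sorted(kv) if k.startswith("covariate")]
        contamination = None
        if "contamination_k" in kv:
            contamination = int(kv["contamination_k"])
        elif "contamination_lam" in kv:
            contamination = float(kv["contamination_lam"])
        return cls(
            n0=int(kv["n0"]),
            n1=int(kv["n1"]),
            beta0=float(kv["beta0"]),
            beta=tuple(float(b) for b in kv["beta"].split(",")),
            covariates=tuple(covs),
            contamination=contamination,
            seed=int(kv.get("seed", 0)),
        )


def _draw_stratified(config: SimulationConfig, rng: np.random.Generator):
    """Rejection-sample covariate/label pairs until each stratum is full."""
    p_cov = len(config.covariates)
    beta = np.asarray(config.beta)
    need = {0: config.n0, 1: config.n1}
    got = {0: [], 1: []}
    drawn = 0
    cap = _OVERSAMPLE_CAP * (config.n0 + config.n1)
    batch = max(1024, config.n0 + config.n1)
    while (len(got[0]) < need[0] or len(got[1]) < need[1]) and drawn < cap:
        X = np.column_stack([c.sample(rng, batch) for c in config.covariates]) \
            if p_cov else np.empty((batch, 0))
        y = rng.random(batch) < expit(config.beta0 + X @ beta)
        drawn += batch
        for lab in (0, 1):
            short = need[lab] - len(got[lab])
            if short > 0:
                rows = X[y == bool(lab)][:short]
                got[lab].extend(rows)
    if len(got[0]) < need[0] or len(got[1]) < need[1]:
        raise RuntimeError(
            "stratum target unreachable: drew "
            f"{drawn} candidates but found only {len(got[0])} controls / "
            f"{len(got[1])} cases (is P(y=1|x) degenerate?)"
        )
    X = np.vstack([np.asarray(got[0]), np.asarray(got[1])])
    y = np.concatenate([np.zeros(need[0], dtype=np.int8), np.ones(need[1], dtype=np.int8)])
    perm = rng.permutation(y.size)
    return X[perm], y[perm]


def generate_dataset(config: SimulationConfig, rng: np.random.Generator | None = None
                     ) -> ContaminatedDataset:
    """Generate a clean stratified sample (z = y) and apply the configured
    contamination, if any.  Deterministic given the config seed."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    X, y = _draw_stratified(config, rng)
    data = ContaminatedDataset(X=X, z=y.copy(), y_true=y)
    c = config.contamination
    if c is None:
        return data
    if isinstance(c, (int, np.integer)) and not isinstance(c, bool):
        k = int(c)
    else:
        k = int(rng.binomial(int(np.sum(y == 1)), float(c)))
    return contaminate(data, k, rng=rng)


def contaminate(data: ContaminatedDataset, k: int,
                seed: int | None = None,
                rng: np.random.Generator | None = None) -> ContaminatedDataset:
    """Relabel exactly k uniformly chosen z = 1 rows as z = 0.

    True labels are preserved (set to the pre-contamination z when absent),
    so the one-sided-noise invariant remains checkable afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cases = np.flatnonzero(data.z == 1)
    if k < 0 or k > cases.size:
        raise ValueError(f"k = {k} exceeds the {cases.size} available z = 1 rows")
    z = data.z.copy()
    if k:
        z[rng.choice(cases, size=k, replace=False)] = 0
    y_true = data.y_true if data.y_true is not None else data.z.copy()
    return ContaminatedDataset(X=data.X, z=z, y_true=y_true, names=data.names)


@dataclass(frozen=True)
class ContaminationStudyResult:
    """Sampling distribution of the estimated mislabeled count n1*mu-hat
    over repeated random relabelings of the same base data."""

    estimates: np.ndarray
    n_reps: int
    n_failed: int
    seed: int

    @property
    def median(self) -> float:
        return float(np.median(self.estimates))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.estimates, [25, 75])
        return float(lo), float(hi)

    def __str__(self):
        lo, hi = self.iqr
        s = (f"median estimated mislabeled count {self.median:.1f} "
             f"(IQR: {lo:.1f} to {hi:.1f}) over {self.estimates.size} replicates")
        if self.n_failed:
            s += f"; {self.n_failed} replicate fit(s) failed and were excluded"
        return s


def repeated_contamination_study(
    data: ContaminatedDataset, k: int, n_reps: int = 100, seed: int = 0
) -> ContaminationStudyResult:
    """Repeatedly relabel k random cases of ``data`` (taken with its clean
    labels), refit the defective model, and record n1*mu-hat each time."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    estimates, n_failed = [], 0
    for child in children:
        rep = contaminate(data, k, rng=np.random.default_rng(child))
        try:
            fit = DefectiveLogit(rep).fit()
            estimates.append(fit.expected_mislabeled())
        except Exception:
            n_failed += 1
    return ContaminationStudyResult(
        estimates=np.asarray(estimates), n_reps=n_reps, n_failed=n_failed, seed=seed
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Bias / spread / coverage summary of a parameter-recovery experiment."""

    param_names: tuple[str, ...]
    true_values: np.ndarray
    mean_bias: np.ndarray
    empirical_sd: np.ndarray
    mean_se: np.ndarray
    coverage: np.ndarray  # Wald CI coverage per regression parameter (NaN for lam)
    lam_true: float
    lam_estimates: np.ndarray
    boundary_fraction: float
    n_reps: int
    n_failed: int
    level: float

    @property
    def lam_mean(self) -> float:
        return float(np.mean(self.lam_estimates))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "truth": self.true_values,
                "mean_bias": self.mean_bias,
                "empirical_sd": self.empirical_sd,
                "mean_se": self.mean_se,
                "coverage": self.coverage,
            },
            index=list(self.param_names),
        )

    def __str__(self):
        out = [
            f"recovery over {self.n_reps - self.n_failed} replicates "
            f"(lam_true = {self.lam_true:g}):",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
            f"mean lambda-hat = {self.lam_mean:.4f}; "
            f"fraction of fits at the lambda = 0 boundary: {self.boundary_fraction:.2f}",
        ]
        return "\n".join(out)


def design_intercept(config: SimulationConfig, n_draws: int = 200_000) -> float:
    """The intercept identified under stratified case-control sampling.

    Sampling n1 cases and n0 controls leaves the slopes of the logistic
    model untouched but shifts the intercept to
    beta0 + log(n1/n0) - logit(pi1), where pi1 = E_x[expit(beta0 + beta'x)]
    is the marginal case probability under the covariate distribution.
    pi1 is computed by Monte Carlo on a fixed substream (exact when there
    are no covariates).
    """
    beta = np.asarray(config.beta)
    if beta.size == 0:
        pi1 = float(expit(config.beta0))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(987654321))
        X = np.column_stack([c.sample(rng, n_draws) for c in config.covariates])
        pi1 = float(np.mean(expit(config.beta0 + X @ beta)))
    return config.beta0 + np.log(config.n1 / config.n0) - np.log(pi1 / (1.0 - pi1))


def recovery_experiment(config: SimulationConfig, n_reps: int = 200,
                        level: float = 0.95) -> RecoveryResult:
    """Generate + contaminate + fit ``n_reps`` independent replicates of
    ``config`` and summarize estimator behavior.

    Reports, per parameter of (mu, beta0, beta): mean bias, empirical SD,
    mean model SE, and Wald CI coverage at ``level`` (coverage for mu is
    reported only over non-boundary fits, where a Wald SE exists).  The
    intercept is judged against its design-adjusted value (see
    :func:`design_intercept`), not the population beta0, since stratified
    sampling shifts it.
    """
    from scipy import stats as _st

    c = config.contamination
    if c is None:
        lam_true = 0.0
    elif isinstance(c, (int, np.integer)) and not isinstance(c, bool):
        lam_true = c / config.n1
    else:
        lam_true = float(c)
    mu_true = lam_true / (1.0 - lam_true)
    truth = np.concatenate([[mu_true, design_intercept(config)], config.beta])
    names = ("mu", "const") + tuple(f"x{j+1}" for j in range(len(config.beta)))

    children = np.random.SeedSequence(config.seed).spawn(n_reps)
    zq = _st.norm.ppf(0.5 + level / 2)
    est, ses, cover, lams, bnd = [], [], [], [], []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        try:
            data = generate_dataset(replace(config, seed=0), rng=rng)
            fit = DefectiveLogit(data).fit()
        except Exception:
            n_failed += 1
            continue
        theta = fit.params.to_numpy()
        se = fit.bse.to_numpy()
        est.append(theta)
        ses.append(se)
        with np.errstate(invalid="ignore"):
            cover.append(np.abs(theta - truth) <= zq * se)
        lams.append(fit.lam)
        bnd.append(fit.boundary)
    if not est:
        raise RuntimeError("every replicate failed to fit")
    est = np.asarray(est)
    ses = np.asarray(ses)
    cover = np.asarray(cover, dtype=float)
    # boundary fits have no mu SE; coverage for mu averages over the rest
    cover[np.isnan(ses)] = np.nan
    return RecoveryResult(
        param_names=names,
        true_values=truth,
        mean_bias=est.mean(axis=0) - truth,
        empirical_sd=est.std(axis=0, ddof=1),
        mean_se=np.nanmean(ses, axis=0),
        coverage=np.nanmean(cover, axis=0),
        lam_true=lam_true,
        lam_estimates=np.asarray(lams),
        boundary_fraction=float(np.mean(bnd)),
        n_reps=n_reps,
        n_failed=n_failed,
        level=level,
    )


def example_study_config(seed: int = 0,
                         contamination: float | int | None = 67) -> SimulationConfig:
    """A synthetic stand-in for a strongly discriminating case-control
    study: 200 true cases and 776 true controls, a standardized continuous
    risk score and a binary exposure, with 67 cases relabeled as controls
    by default.  Entirely simulated; the covariates are generic, not real
    risk factors."""
    return SimulationConfig(
        n0=776,
        n1=200,
        beta0=-2.0,
        beta=(1.5, 1.0),
        covariates=(Covariate("normal", (0.0, 1.0)), Covariate("bernoulli", (0.35,))),
        contamination=contamination,
        seed=seed,
    )
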