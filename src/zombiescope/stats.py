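"""Statistical procedures of the zombie-cell study.

* Welch's two-sample t-test from group summaries or raw samples
  (Welch–Satterthwaite degrees of freedom).
* One-within-factor repeated-measures ANOVA by sum-of-squares
  decomposition with subject blocking.
* The +0.001 zero transform that moves proportions into the open support
  of the beta distribution.
* Logit-link, mean-precision Bayesian beta regression with flat priors on
  the coefficients, sampled by adaptive random-walk Metropolis on the
  study's schedule (4 chains, 2000 retained draws each after 2000 warmup),
  with equal-tailed credible intervals, posterior tail fractions and a
  split-Rhat convergence check.
* A matching beta-data simulator for recovery experiments.

The beta density is mean-parameterized: y ~ Beta(mu*phi, (1-mu)*phi) with
mu = logistic(b0 + b1*x); phi is the precision (Var y = mu(1-mu)/(1+phi)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

__all__ = [
    "GroupSummary", "WelchResult", "welch_t", "RmAnovaResult", "rm_anova",
    "transform_zero", "McmcConfig", "BetaRegressionFit",
    "fit_beta_regression", "posterior_tail_fraction", "simulate_beta_data",
    "beta_loglik", "ml_beta_regression",
]


# ---------------------------------------------------------------------------
# Welch's t-test

@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def _as_summary(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        x.validate()
        return x
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("raw sample must be 1-D with n >= 2")
    return GroupSummary(n=arr.size, mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)))


def welch_t(a, b) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided p.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b); df by
    Welch–Satterthwaite.  Accepts GroupSummary or raw 1-D samples.
    """
    a, b = _as_summary(a), _as_summary(b)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        raise ValueError("both group variances are zero (degenerate)")
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def rm_anova(data: pd.DataFrame, subject: str = "subject",
             condition: str = "condition", value: str = "value"
             ) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with subject blocking.

    ``data`` is long-format (subject, condition, value) or a wide
    subject x condition table.  F = MS_condition / MS_(condition x subject),
    df = (k-1, (k-1)(n-1)).  Missing cells are an error (no imputation).
    """
    if {subject, condition, value}.issubset(data.columns):
        wide = data.pivot(index=subject, columns=condition, values=value)
    else:
        wide = data
    if wide.isna().any().any():
        raise ValueError("incomplete table: every subject needs every condition")
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    gm = y.mean()
    ss_cond = n * float(((y.mean(axis=0) - gm) ** 2).sum())
    ss_subj = k * float(((y.mean(axis=1) - gm) ** 2).sum())
    ss_total = float(((y - gm) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        F = 0.0 if ss_cond == 0 else float("inf")
    else:
        F = ms_cond / ms_err
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return RmAnovaResult(F=float(F), df1=df1, df2=df2, p=p)


# ---------------------------------------------------------------------------
# zero transform

def transform_zero(x, eps: float = 0.001):
    """Shift proportions by ``eps`` so zeros enter the beta support (0,1).

    Applied uniformly to the response.  Values with x + eps >= 1 (or x < 0)
    are outside the transform's domain and raise.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("proportions must be non-negative")
    if np.any(arr + eps >= 1):
        raise ValueError("x + eps must stay below 1 (beta support)")
    out = arr + eps
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# Bayesian beta regression

@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    iterations: int = 2000   # retained draws per chain
    warmup: int = 2000
    seed: int = 0
    target_accept: tuple[float, float] = (0.3, 0.45)
    phi_prior_scale: float = 50.0   # half-normal scale on precision


@dataclass
class BetaRegressionFit:
    """Posterior summaries of a logit-link mean-precision beta regression."""

    formula: str
    params: tuple[str, ...]                 # ("intercept", "slope", "phi")
    draws: dict[str, np.ndarray]            # param -> (chains, iterations)
    mean: dict[str, float]
    sd: dict[str, float]
    ci95: dict[str, tuple[float, float]]    # equal-tailed
    rhat: dict[str, float]
    accept_rate: float
    converged: bool
    mcmc: McmcConfig
    n_obs: int

    @property
    def n_draws(self) -> int:
        return self.draws["slope"].size

    def flat(self, param: str) -> np.ndarray:
        return self.draws[param].reshape(-1)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.params:
            lo, hi = self.ci95[p]
            rows.append({"param": p, "mean": self.mean[p], "sd": self.sd[p],
                         "ci2.5": lo, "ci97.5": hi, "rhat": self.rhat[p]})
        return pd.DataFrame(rows)


def _parse_formula(formula: str) -> tuple[str, str]:
    parts = [s.strip() for s in formula.split("~")]
    if len(parts) != 2 or not all(parts):
        raise ValueError("formula must look like 'response ~ covariate'")
    return parts[0], parts[1]


def beta_loglik(y: np.ndarray, x: np.ndarray, b0, b1, phi):
    """Log likelihood of the mean-precision beta regression.

    Broadcasts over leading axes of (b0, b1, phi); y, x are 1-D length n.
    """
    eta = b0[..., None] + b1[..., None] * x
    mu = special.expit(eta)
    a = mu * phi[..., None]
    b = (1.0 - mu) * phi[..., None]
    return np.sum(
        special.gammaln(phi[..., None]) - special.gammaln(a)
        - special.gammaln(b) + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y),
        axis=-1,
    )


def ml_beta_regression(y: np.ndarray, x: np.ndarray):
    """Maximum-likelihood point estimate (independent of the sampler path).

    Returns (intercept, slope, phi).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)

    def nll(theta):
        b0, b1, lphi = theta
        return -beta_loglik(y, x, np.array(b0), np.array(b1),
                            np.array(np.exp(lphi)))

    mu0 = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    start = np.array([special.logit(mu0), 0.0, np.log(10.0)])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-8,
                                     "fatol": 1e-10})
    b0, b1, lphi = res.x
    return float(b0), float(b1), float(np.exp(lphi))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat (Gelman et al.) over a (chains, draws) array."""
    m, n = chains.shape
    half = n // 2
    seq = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m2, n2 = seq.shape
    means = seq.mean(axis=1)
    B = n2 * means.var(ddof=1)
    W = seq.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_plus / W))


def fit_beta_regression(
    data: pd.DataFrame,
    formula: str,
    mcmc: McmcConfig | None = None,
    min_rows: int = 10,
) -> BetaRegressionFit:
    """Fit mu_i = logistic(b0 + b1 x_i), y_i ~ Beta(mu_i phi, (1-mu_i) phi).

    Priors: improper flat on intercept and slope; half-normal(0, scale) on
    the precision phi.  Sampling: adaptive random-walk Metropolis, all
    chains advanced in lockstep; warmup adapts per-chain step scales toward
    the target acceptance window, then a pooled-covariance proposal is
    frozen for the retained draws.  Non-convergence (split-Rhat >= 1.05) is
    flagged on the returned fit, never silent.
    """
    mcmc = mcmc or McmcConfig()
    resp, cov = _parse_formula(formula)
    for col in (resp, cov):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    y = data[resp].to_numpy(dtype=float)
    x = data[cov].to_numpy(dtype=float)
    if len(y) < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {len(y)}")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("response must lie strictly in (0, 1); "
                         "apply transform_zero first")

    rng = np.random.default_rng(mcmc.seed)
    C = mcmc.chains
    scale2 = mcmc.phi_prior_scale ** 2

    def logpost(theta):
        b0, b1, lphi = theta[:, 0], theta[:, 1], theta[:, 2]
        phi = np.exp(lphi)
        # half-normal prior on phi plus log-Jacobian of the log transform
        lp = -phi**2 / (2 * scale2) + lphi
        return beta_loglik(y, x, b0, b1, phi) + lp

    mu0 = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    theta = np.tile([special.logit(mu0), 0.0, np.log(10.0)], (C, 1))
    theta = theta + rng.normal(0, 0.1, size=theta.shape)
    lp = logpost(theta)

    step = np.full((C, 3), 0.1)
    lo_acc, hi_acc = mcmc.target_accept
    target = 0.5 * (lo_acc + hi_acc)

    half = mcmc.warmup // 2
    hist = np.empty((C, half, 3))
    acc_win = np.zeros(C)
    n_win = 0
    chol = None
    global_scale = np.full(C, 1.0)

    def propose(theta):
        if chol is None:
            return theta + rng.normal(size=theta.shape) * step
        z = rng.normal(size=theta.shape)
        return theta + global_scale[:, None] * (z @ chol.T)

    for it in range(mcmc.warmup):
        prop = propose(theta)
        lp_prop = logpost(prop)
        accept = np.log(rng.random(C)) < lp_prop - lp
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        acc_win += accept
        n_win += 1
        if it >= half:
            hist[:, it - half] = theta
        if (it + 1) % 50 == 0:
            rate = acc_win / n_win
            if chol is None:
                step *= np.exp((rate - target))[:, None]
            else:
                global_scale *= np.exp(rate - target)
            acc_win[:] = 0
            n_win = 0
        if it + 1 == mcmc.warmup - half // 2:
            # pooled covariance proposal for the tail of warmup + sampling
            pooled = hist[:, : it - half + 1].reshape(-1, 3)
            cov_mat = np.cov(pooled.T) + 1e-8 * np.eye(3)
            chol = np.linalg.cholesky((2.38**2 / 3) * cov_mat)
            global_scale = np.full(C, 1.0)

    draws = np.empty((C, mcmc.iterations, 3))
    n_acc = 0
    for it in range(mcmc.iterations):
        prop = propose(theta)
        lp_prop = logpost(prop)
        accept = np.log(rng.random(C)) < lp_prop - lp
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        n_acc += int(accept.sum())
        draws[:, it] = theta

    draws[:, :, 2] = np.exp(draws[:, :, 2])  # back to phi scale
    params = ("intercept", "slope", "phi")
    by_param = {p: draws[:, :, i] for i, p in enumerate(params)}
    mean = {p: float(v.mean()) for p, v in by_param.items()}
    sd = {p: float(v.std(ddof=1)) for p, v in by_param.items()}
    ci = {p: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for p, v in by_param.items()}
    rhat = {p: _split_rhat(v) for p, v in by_param.items()}
    converged = all(r < 1.05 for r in rhat.values())
    return BetaRegressionFit(
        formula=formula, params=params, draws=by_param, mean=mean, sd=sd,
        ci95=ci, rhat=rhat,
        accept_rate=n_acc / (C * mcmc.iterations),
        converged=converged, mcmc=mcmc, n_obs=len(y),
    )


def posterior_tail_fraction(fit: BetaRegressionFit, direction: str,
                            param: str = "slope", threshold: float = 0.0
                            ) -> tuple[float, int]:
    """Fraction of retained draws with param <= threshold ("le") or >=
    threshold ("ge"); returns (fraction, draw count)."""
    draws = fit.flat(param)
    if draws.size == 0:
        raise ValueError("fit contains no draws")
    if direction == "le":
        frac = float(np.mean(draws <= threshold))
    elif direction == "ge":
        frac = float(np.mean(draws >= threshold))
    else:
        raise ValueError("direction must be 'le' or 'ge'")
    return frac, int(draws.size)


# ---------------------------------------------------------------------------
# simulator

def simulate_beta_data(
    intercept: float,
    slope: float,
    phi: float,
    n: int,
    covariate_law: tuple[str, float, float] | Callable = ("uniform", 0.0, 0.15),
    seed: int = 0,
    response_name: str = "rel_infT",
    covariate_name: str = "Zombie_cells",
) -> pd.DataFrame:
    """Draw (x, y) from the logit-linear beta model for recovery studies.

    Covariates default to uniform over the observed zombie-fraction range
    [0, 0.15]; responses are Beta(mu*phi, (1-mu)*phi) with
    mu = logistic(intercept + slope * x).
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if callable(covariate_law):
        x = np.asarray(covariate_law(rng, n), dtype=float)
    else:
        kind, lo, hi = covariate_law
        if kind != "uniform":
            raise ValueError("only 'uniform' covariate law is built in")
        x = rng.uniform(lo, hi, size=n)
    mu = special.expit(intercept + slope * x)
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    # guard against floating-point 0/1 draws at extreme mu
    y = np.clip(y, 1e-12, 1 - 1e-12)
    return pd.DataFrame({covariate_name: x, response_name: y})
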