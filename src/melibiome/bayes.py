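"""Bayesian model engines: Gibbs and Metropolis samplers, summaries, diagnostics.

Three model classes are implemented directly from their full conditionals
rather than through a probabilistic-programming engine, so the repository
embodies the models it fits:

* an unequal-variance group model (a Bayesian analog of one-way ANOVA in
  which each group has its own Normal mean and precision),
* a Normal linear regression with conjugate Gibbs updates, and
* a Bernoulli-logit regression sampled by adaptive random-walk Metropolis
  (adaptation during burn-in only, frozen afterward to preserve detailed
  balance).

Priors follow the study convention: Normal(0, tau0 = 1e-6) on means and
coefficients and Gamma(shape = 0.01, rate = 0.01) on precisions.  Point
estimates are posterior medians ("pm"), uncertainty is the 95% equal-tail
probability interval (ETPI), and tail posterior probabilities ("pp") are
fractions of pooled draws.  The default MCMC schedule is 3 chains, each a
1000-iteration burn-in followed by 10,000 iterations thinned to every third
draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "McmcSettings",
    "PriorSpec",
    "ChainSet",
    "PosteriorSummary",
    "GroupModelFit",
    "RegressionFit",
    "fit_group_model",
    "fit_linear_model",
    "fit_logistic_model",
    "summarize",
    "gelman_rubin",
    "effective_sample_size",
    "dic",
]


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 3
    burn_in: int = 1000
    n_iter: int = 10_000
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chains", "burn_in", "n_iter", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def n_kept(self) -> int:
        return self.n_iter // self.thin


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse priors: Normal(coef_mean, 1/coef_precision) on location
    parameters, Gamma(precision_shape, precision_rate) on precisions."""

    coef_mean: float = 0.0
    coef_precision: float = 1e-6
    precision_shape: float = 0.01
    precision_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.coef_precision <= 0 or self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("precisions and gamma parameters must be > 0")


@dataclass
class ChainSet:
    """Raw retained MCMC draws plus per-draw log-likelihood.

    ``draws`` has shape (chains, retained iterations, parameters);
    ``loglik_at`` maps a parameter vector to the data log-likelihood and is
    needed for the deviance-at-posterior-mean term of DIC.
    """

    draws: np.ndarray
    param_names: list[str]
    log_likelihood: np.ndarray | None = None  # (chains, retained)
    loglik_at: Callable[[np.ndarray], float] | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws")
        if self.draws.shape[2] != len(self.param_names):
            raise ValueError("param_names length mismatch")

    def pooled(self) -> np.ndarray:
        """Draws pooled across chains, shape (chains*iterations, parameters)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        c, t, p = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), t * p),
                "iteration": np.tile(np.repeat(np.arange(t), p), c),
                "parameter": np.tile(self.param_names, c * t),
                "value": self.draws.reshape(-1),
            }
        )


@dataclass(frozen=True)
class PosteriorSummary:
    pm: float
    etpi_95: tuple[float, float]
    pp_gt0: float
    pp_lt0: float


@dataclass
class GroupModelFit:
    groups: list[str]
    mu: dict[str, PosteriorSummary]
    sigma: dict[str, PosteriorSummary]
    chains: ChainSet

    def contrast_pp(self, group_a: str, group_b: str) -> float:
        """Pr(mu_a > mu_b) from paired pooled draws of the joint fit."""
        pooled = self.chains.pooled()
        ia = self.chains.param_names.index(f"mu_{group_a}")
        ib = self.chains.param_names.index(f"mu_{group_b}")
        return float(np.mean(pooled[:, ia] > pooled[:, ib]))


@dataclass
class RegressionFit:
    coefficients: dict[str, PosteriorSummary]
    sigma: PosteriorSummary | None
    dic: float
    pd_eff: float
    dbar: float
    chains: ChainSet
    fitted_probabilities: dict[str, PosteriorSummary] | None = None


def _seeds(settings: McmcSettings) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(settings.seed)
    return [np.random.default_rng(s) for s in ss.spawn(settings.n_chains)]


def summarize(chains: ChainSet) -> dict[str, PosteriorSummary]:
    """pm (median), 95% ETPI, and tail probabilities over pooled draws."""
    pooled = chains.pooled()
    out = {}
    for j, name in enumerate(chains.param_names):
        x = pooled[:, j]
        lo, hi = np.percentile(x, [2.5, 97.5])
        out[name] = PosteriorSummary(
            pm=float(np.median(x)),
            etpi_95=(float(lo), float(hi)),
            pp_gt0=float(np.mean(x > 0)),
            pp_lt0=float(np.mean(x < 0)),
        )
    return out


# ---------------------------------------------------------------------------
# Group model (unequal-variance one-way layout)

def fit_group_model(
    values: np.ndarray,
    groups: Sequence[str],
    prior: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
    fixed_tau: float | None = None,
) -> GroupModelFit:
    """Per-group Normal(mu_g, 1/tau_g) model with conjugate Gibbs updates.

    mu_g | tau_g ~ Normal((tau_g n ybar)/(tau_g n + tau0), 1/(tau_g n + tau0))
    tau_g | mu_g ~ Gamma(shape + n/2, rate + sum((y - mu_g)^2)/2)

    ``fixed_tau`` pins every group precision (degenerate prior), used for
    closed-form validation.  Groups may have n = 1; empty groups are errors.
    """
    y = np.asarray(values, dtype=float)
    labels = list(groups)
    if len(y) != len(labels):
        raise ValueError("values and groups length mismatch")
    names = sorted(set(labels))
    ys = {g: y[np.array(labels) == g] for g in names}
    for g, yg in ys.items():
        if len(yg) == 0:
            raise ValueError(f"empty group {g!r}")
    tau0, m0 = prior.coef_precision, prior.coef_mean
    a0, b0 = prior.precision_shape, prior.precision_rate
    param_names = [f"mu_{g}" for g in names] + [f"sigma_{g}" for g in names]
    n_kept = settings.n_kept
    all_draws = np.empty((settings.n_chains, n_kept, 2 * len(names)))
    all_ll = np.empty((settings.n_chains, n_kept))
    for c, rng in enumerate(_seeds(settings)):
        mu = {g: float(np.mean(ys[g])) for g in names}
        tau = {g: (fixed_tau if fixed_tau is not None else 1.0) for g in names}
        kept = 0
        for it in range(settings.burn_in + settings.n_iter):
            for g in names:
                yg = ys[g]
                n = len(yg)
                prec = tau[g] * n + tau0
                mean = (tau[g] * n * yg.mean() + tau0 * m0) / prec
                mu[g] = rng.normal(mean, 1.0 / np.sqrt(prec))
                if fixed_tau is None:
                    ssr = float(np.sum((yg - mu[g]) ** 2))
                    tau[g] = rng.gamma(a0 + n / 2.0, 1.0 / (b0 + ssr / 2.0))
            post = it - settings.burn_in
            if post >= 0 and (post + 1) % settings.thin == 0 and kept < n_kept:
                row = [mu[g] for g in names] + [1.0 / np.sqrt(tau[g]) for g in names]
                all_draws[c, kept] = row
                all_ll[c, kept] = sum(
                    np.sum(stats.norm.logpdf(ys[g], mu[g], 1.0 / np.sqrt(tau[g])))
                    for g in names
                )
                kept += 1

    def loglik_at(theta: np.ndarray) -> float:
        k = len(names)
        return float(
            sum(
                np.sum(stats.norm.logpdf(ys[g], theta[i], theta[k + i]))
                for i, g in enumerate(names)
            )
        )

    chains = ChainSet(all_draws, param_names, all_ll, loglik_at)
    summ = summarize(chains)
    return GroupModelFit(
        groups=names,
        mu={g: summ[f"mu_{g}"] for g in names},
        sigma={g: summ[f"sigma_{g}"] for g in names},
        chains=chains,
    )


# ---------------------------------------------------------------------------
# Linear regression

def _check_design(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a minimal set of columns past which rank stops growing
        bad = []
        running: list[int] = []
        for j in range(x.shape[1]):
            if np.linalg.matrix_rank(x[:, running + [j]]) == len(running):
                bad.append(names[j])
            else:
                running.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return x, names


def fit_linear_model(
    y: np.ndarray,
    design: pd.DataFrame,
    prior: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
    fixed_tau: float | None = None,
) -> RegressionFit:
    """Normal linear model y ~ N(X beta, 1/tau) via conjugate Gibbs.

    beta | tau ~ N(V (tau X'y + tau0 m0), V), V = (tau X'X + tau0 I)^-1;
    tau | beta ~ Gamma(a0 + n/2, b0 + SSR/2).  The design must be full
    rank and include the intercept column explicitly; binary covariates
    are coded 0/1 by the caller and age stays in raw days.
    """
    y = np.asarray(y, dtype=float)
    x, names = _check_design(design)
    n, p = x.shape
    if len(y) != n:
        raise ValueError("y length does not match design rows")
    tau0, m0 = prior.coef_precision, prior.coef_mean
    a0, b0 = prior.precision_shape, prior.precision_rate
    xtx = x.T @ x
    xty = x.T @ y
    param_names = names + ["sigma"]
    n_kept = settings.n_kept
    all_draws = np.empty((settings.n_chains, n_kept, p + 1))
    all_ll = np.empty((settings.n_chains, n_kept))
    for c, rng in enumerate(_seeds(settings)):
        tau = fixed_tau if fixed_tau is not None else 1.0
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        kept = 0
        for it in range(settings.burn_in + settings.n_iter):
            prec = tau * xtx + tau0 * np.eye(p)
            cov = np.linalg.inv(prec)
            mean = cov @ (tau * xty + tau0 * m0)
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            resid = y - x @ beta
            ssr = float(resid @ resid)
            if fixed_tau is None:
                tau = rng.gamma(a0 + n / 2.0, 1.0 / (b0 + ssr / 2.0))
            post = it - settings.burn_in
            if post >= 0 and (post + 1) % settings.thin == 0 and kept < n_kept:
                sigma = 1.0 / np.sqrt(tau)
                all_draws[c, kept] = np.append(beta, sigma)
                all_ll[c, kept] = float(np.sum(stats.norm.logpdf(resid, 0.0, sigma)))
                kept += 1

    def loglik_at(theta: np.ndarray) -> float:
        beta, sigma = theta[:-1], theta[-1]
        return float(np.sum(stats.norm.logpdf(y - x @ beta, 0.0, sigma)))

    chains = ChainSet(all_draws, param_names, all_ll, loglik_at)
    summ = summarize(chains)
    dic_val, pd_eff, dbar = dic(chains)
    return RegressionFit(
        coefficients={nm: summ[nm] for nm in names},
        sigma=summ["sigma"],
        dic=dic_val,
        pd_eff=pd_eff,
        dbar=dbar,
        chains=chains,
    )


# ---------------------------------------------------------------------------
# Logistic regression

def _logit_loglik(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    eta = x @ beta
    # stable log Bernoulli-logit likelihood: y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_model(
    y: np.ndarray,
    design: pd.DataFrame,
    prior: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
    cells: dict[str, np.ndarray] | None = None,
) -> RegressionFit:
    """Bernoulli-logit regression by adaptive random-walk Metropolis.

    A joint Normal proposal on beta is scaled during burn-in toward a
    0.2-0.4 acceptance rate (Robbins-Monro on the log step size); the
    adaptation is frozen after burn-in.  ``cells`` optionally maps a label
    to a covariate vector for which fitted survival probabilities (with
    ETPIs) are reported.  Complete separation does not abort the fit (the
    prior is proper) but emits a diagnostic warning.
    """
    y = np.asarray(y, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    x, names = _check_design(design)
    n, p = x.shape
    if len(y) != n:
        raise ValueError("y length does not match design rows")
    if np.all(y == 1) or np.all(y == 0):
        warnings.warn("degenerate response (all 0 or all 1); posterior driven far from 0",
                      stacklevel=2)
    tau0, m0 = prior.coef_precision, prior.coef_mean
    n_kept = settings.n_kept
    all_draws = np.empty((settings.n_chains, n_kept, p))
    all_ll = np.empty((settings.n_chains, n_kept))
    for c, rng in enumerate(_seeds(settings)):
        beta = np.zeros(p)
        ll = _logit_loglik(beta, x, y)
        lp = ll - 0.5 * tau0 * np.sum((beta - m0) ** 2)
        log_step = np.log(2.38 / np.sqrt(p) * 0.5)
        kept = 0
        n_acc = 0
        for it in range(settings.burn_in + settings.n_iter):
            prop = beta + np.exp(log_step) * rng.standard_normal(p)
            ll_prop = _logit_loglik(prop, x, y)
            lp_prop = ll_prop - 0.5 * tau0 * np.sum((prop - m0) ** 2)
            if np.log(rng.random()) < lp_prop - lp:
                beta, ll, lp = prop, ll_prop, lp_prop
                n_acc += 1
            if it < settings.burn_in and (it + 1) % 50 == 0:
                rate = n_acc / 50.0
                n_acc = 0
                if rate < 0.2:
                    log_step -= 0.2
                elif rate > 0.4:
                    log_step += 0.2
            post = it - settings.burn_in
            if post >= 0 and (post + 1) % settings.thin == 0 and kept < n_kept:
                all_draws[c, kept] = beta
                all_ll[c, kept] = ll
                kept += 1

    def loglik_at(theta: np.ndarray) -> float:
        return _logit_loglik(theta, x, y)

    chains = ChainSet(all_draws, names, all_ll, loglik_at)
    summ = summarize(chains)
    dic_val, pd_eff, dbar = dic(chains)
    fitted = None
    if cells:
        pooled = chains.pooled()
        fitted = {}
        for label, xvec in cells.items():
            probs = 1.0 / (1.0 + np.exp(-(pooled @ np.asarray(xvec, dtype=float))))
            lo, hi = np.percentile(probs, [2.5, 97.5])
            fitted[label] = PosteriorSummary(
                pm=float(np.median(probs)),
                etpi_95=(float(lo), float(hi)),
                pp_gt0=float(np.mean(probs > 0)),
                pp_lt0=float(np.mean(probs < 0)),
            )
    return RegressionFit(
        coefficients={nm: summ[nm] for nm in names},
        sigma=None,
        dic=dic_val,
        pd_eff=pd_eff,
        dbar=dbar,
        chains=chains,
        fitted_probabilities=fitted,
    )


# ---------------------------------------------------------------------------
# Diagnostics

def gelman_rubin(chains: ChainSet) -> dict[str, float]:
    """Classic potential scale reduction factor per parameter.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance; reported as max(1, value).
    """
    m, n, _ = chains.draws.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires >= 2 chains")
    out = {}
    for j, name in enumerate(chains.param_names):
        x = chains.draws[:, :, j]
        chain_means = x.mean(axis=1)
        w = float(np.mean(x.var(axis=1, ddof=1)))
        b = float(n * chain_means.var(ddof=1))
        if w == 0:
            out[name] = 1.0
            continue
        var_plus = (n - 1) / n * w + b / n
        out[name] = max(1.0, float(np.sqrt(var_plus / w)))
    return out


def effective_sample_size(chains: ChainSet) -> dict[str, float]:
    """ESS per parameter: N / (1 + 2 sum rho_k), autocorrelations summed by
    Geyer's initial-positive rule (stop at the first negative even/odd pair),
    computed per chain and summed over chains."""
    m, n, _ = chains.draws.shape
    out = {}
    for j, name in enumerate(chains.param_names):
        total = 0.0
        degenerate = False
        for c in range(m):
            x = chains.draws[c, :, j]
            v = x.var()
            if v == 0:
                degenerate = True
                continue
            xc = x - x.mean()
            acf = np.correlate(xc, xc, mode="full")[n - 1:] / (n * v)
            s = 0.0
            k = 1
            while k + 1 < n:
                pair = acf[k] + acf[k + 1]
                if pair < 0:
                    break
                s += pair
                k += 2
            total += n / (1.0 + 2.0 * s)
        if degenerate and total == 0.0:
            warnings.warn(f"constant chain for {name!r}; ESS reported as 0", stacklevel=2)
        out[name] = float(total)
    return out


def dic(chains: ChainSet) -> tuple[float, float, float]:
    """Deviance information criterion (Spiegelhalter variant).

    Dbar = mean(-2 loglik); pD = Dbar - D(theta_bar) with the deviance
    evaluated at the posterior means of the parameters; DIC = Dbar + pD.
    """
    if chains.log_likelihood is None or chains.loglik_at is None:
        raise ValueError("ChainSet lacks per-draw log-likelihood")
    dbar = float(np.mean(-2.0 * chains.log_likelihood))
    theta_bar = chains.pooled().mean(axis=0)
    d_at_mean = -2.0 * chains.loglik_at(theta_bar)
    pd_eff = dbar - d_at_mean
    return dbar + pd_eff, pd_eff, dbar
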