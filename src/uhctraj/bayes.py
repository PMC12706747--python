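"""Bayesian logit-linear trend model fitted by Gibbs sampling.

The observed coverage proportions are logit-transformed and modelled as

    logit(p_t) = a + b * (t - t_center) + eps_t,    eps_t ~ N(0, sigma2)

with diffuse priors a, b ~ N(0, 1e6) independently and
sigma2 ~ InverseGamma(1e-3, 1e-3).  Conjugacy gives closed-form full
conditionals — Gaussian for (a, b) given sigma2 and inverse-gamma for
sigma2 given (a, b) — which the Gibbs sampler alternates.  Centering the
year covariate at the series mean makes the (a, b) conditional diagonal,
so each sweep is a handful of scalar updates.

Posterior predictive draws map back through the inverse logit, so every
projection lies strictly inside (0, 1); the fraction of horizon-year
draws at or above a coverage target is the target-attainment
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .data import (
    CoverageSeries,
    CoverageValidationError,
    inverse_logit,
    logit,
)
from .trend import cagr_pct

# Diffuse-prior hyperparameters (explicit so they can be logged).
PRIOR_COEF_VARIANCE = 1e6
PRIOR_SIGMA2_SHAPE = 1e-3
PRIOR_SIGMA2_RATE = 1e-3


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings: chains, burn-in, retained draws, seed, diagnostics."""

    n_chains: int = 2
    n_burn: int = 5000
    n_keep: int = 10000
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if self.n_chains < 2:
            raise CoverageValidationError("at least 2 chains required for R-hat diagnostics")
        if self.n_burn <= 0 or self.n_keep <= 0:
            raise CoverageValidationError("n_burn and n_keep must be positive")


@dataclass(frozen=True)
class LogitLinearPosterior:
    """Retained MCMC draws of the logit-scale linear model.

    Draw arrays have shape (n_chains, n_keep); ``year_center`` is the
    reference year subtracted from t before fitting.
    """

    a: np.ndarray
    b: np.ndarray
    sigma2: np.ndarray
    year_center: float
    settings: MCMCSettings
    rhat: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.a.shape != (self.settings.n_chains, self.settings.n_keep):
            raise CoverageValidationError(
                f"draw arrays must have shape (n_chains, n_keep); got {self.a.shape}"
            )
        if np.any(self.sigma2 <= 0):
            raise CoverageValidationError("sigma2 draws must be positive")

    @property
    def n_draws(self) -> int:
        return int(self.a.size)

    @property
    def converged(self) -> bool:
        return all(v <= self.settings.rhat_threshold for v in self.rhat.values())

    def flat(self, name: str) -> np.ndarray:
        return getattr(self, name).reshape(-1)


@dataclass(frozen=True)
class ProjectionResult:
    """Per-horizon-year posterior predictive summaries and target probability."""

    years: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    prob_target: np.ndarray
    target: float
    include_noise: bool

    def __post_init__(self):
        if not (
            np.all(self.lower <= self.median + 1e-15)
            and np.all(self.median <= self.upper + 1e-15)
        ):
            raise CoverageValidationError("credible interval must bracket the median")


def _gibbs_chain(
    y: np.ndarray, x: np.ndarray, n_burn: int, n_keep: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One chain of the conjugate Gibbs sampler.

    x must already be centered (sum x == 0), which decouples the
    intercept and slope conditionals.
    """
    n = y.size
    sy = float(np.sum(y))
    sty = float(np.sum(x * y))
    stt = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    v0inv = 1.0 / PRIOR_COEF_VARIANCE
    a_shape = PRIOR_SIGMA2_SHAPE + 0.5 * n

    total = n_burn + n_keep
    # Pre-draw the fixed-shape randomness; the loop is scalar arithmetic.
    z = rng.standard_normal((total, 2))
    g = rng.gamma(a_shape, 1.0, size=total)

    a_draws = np.empty(n_keep)
    b_draws = np.empty(n_keep)
    s2_draws = np.empty(n_keep)

    # Start sigma2 at the method-of-moments residual variance.
    ybar = sy / n
    bhat = sty / stt if stt > 0 else 0.0
    sigma2 = max((syy - n * ybar * ybar - bhat * bhat * stt) / max(n - 2, 1), 1e-8)

    for i in range(total):
        prec_a = n / sigma2 + v0inv
        prec_b = stt / sigma2 + v0inv
        a = (sy / sigma2) / prec_a + z[i, 0] / np.sqrt(prec_a)
        b = (sty / sigma2) / prec_b + z[i, 1] / np.sqrt(prec_b)
        rss = syy - 2.0 * a * sy - 2.0 * b * sty + a * a * n + b * b * stt
        sigma2 = (PRIOR_SIGMA2_RATE + 0.5 * max(rss, 0.0)) / g[i]
        if i >= n_burn:
            j = i - n_burn
            a_draws[j] = a
            b_draws[j] = b
            s2_draws[j] = sigma2
    return a_draws, b_draws, s2_draws


def _compute_rhat(draws: dict[str, np.ndarray]) -> dict[str, float]:
    ds = az.from_dict(posterior=draws)
    r = az.rhat(ds)
    return {k: float(r[k].values) for k in draws}


def fit_logit_linear(
    series: CoverageSeries, settings: MCMCSettings = MCMCSettings()
) -> LogitLinearPosterior:
    """Fit the logit-linear trend model to a coverage series by Gibbs sampling.

    Requires at least 3 observations.  Reproducible: identical settings
    and data give bit-identical draw streams.  Non-convergence (any
    R-hat above the threshold) is flagged on the result, never silent.
    """
    series.require_min_observations(3)
    y = logit(series.values)
    year_center = float(np.mean(series.years))
    x = series.years.astype(float) - year_center

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains_a, chains_b, chains_s2 = [], [], []
    for ss in seeds:
        a, b, s2 = _gibbs_chain(
            y, x, settings.n_burn, settings.n_keep, np.random.default_rng(ss)
        )
        chains_a.append(a)
        chains_b.append(b)
        chains_s2.append(s2)
    a = np.vstack(chains_a)
    b = np.vstack(chains_b)
    s2 = np.vstack(chains_s2)
    rhat = _compute_rhat({"a": a, "b": b, "sigma2": s2})
    post = LogitLinearPosterior(
        a=a, b=b, sigma2=s2, year_center=year_center, settings=settings, rhat=rhat
    )
    if not post.converged:
        import warnings

        warnings.warn(
            f"chains not converged: R-hat {rhat} exceeds "
            f"{settings.rhat_threshold}",
            stacklevel=2,
        )
    return post


def posterior_predictive_draws(
    posterior: LogitLinearPosterior, years, include_noise: bool = True
) -> np.ndarray:
    """Coverage draws at the given years, shape (n_draws, n_years).

    With ``include_noise`` the draws integrate residual noise (a future
    observation); without it they describe the mean trend curve only.
    The noise stream is derived deterministically from the sampler seed,
    so repeated calls agree bit-for-bit.
    """
    years = np.atleast_1d(np.asarray(years, dtype=float))
    if years.size == 0:
        raise CoverageValidationError("at least one projection year required")
    a = posterior.flat("a")[:, None]
    b = posterior.flat("b")[:, None]
    t = years[None, :] - posterior.year_center
    z = a + b * t
    if include_noise:
        rng = np.random.default_rng(
            np.random.SeedSequence([posterior.settings.seed, 0x5EED])
        )
        eps = rng.standard_normal((posterior.n_draws, years.size))
        z = z + eps * np.sqrt(posterior.flat("sigma2"))[:, None]
    return inverse_logit(z)


def project(
    posterior: LogitLinearPosterior,
    years,
    target: float = 0.8,
    include_noise: bool = True,
) -> ProjectionResult:
    """Posterior predictive projection with 95% CrIs and target probabilities.

    For each horizon year, reports the median and central 2.5-97.5
    percentile interval of the back-transformed draws, and the fraction
    of draws at or above ``target``.
    """
    if not (0.0 < target < 1.0):
        raise CoverageValidationError(f"target must lie in (0, 1); got {target}")
    p = posterior_predictive_draws(posterior, years, include_noise=include_noise)
    years = np.atleast_1d(np.asarray(years, dtype=int))
    return ProjectionResult(
        years=years,
        median=np.median(p, axis=0),
        lower=np.percentile(p, 2.5, axis=0),
        upper=np.percentile(p, 97.5, axis=0),
        prob_target=np.mean(p >= target, axis=0),
        target=target,
        include_noise=include_noise,
    )


def growth_rate_interval(
    posterior: LogitLinearPosterior,
    year_start: int,
    year_end: int,
    include_noise: bool = True,
) -> tuple[float, float]:
    """95% credible interval of the average annual growth rate, in percent.

    The endpoint CAGR is evaluated on each posterior-predictive draw
    pair (value at year_start, value at year_end); the 2.5 and 97.5
    percentiles are returned.
    """
    if year_start == year_end:
        raise CoverageValidationError("growth interval needs two distinct years")
    p = posterior_predictive_draws(
        posterior, [year_start, year_end], include_noise=include_noise
    )
    rates = 100.0 * ((p[:, 1] / p[:, 0]) ** (1.0 / (year_end - year_start)) - 1.0)
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return float(lo), float(hi)


class BayesianLogitTrend(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for the Gibbs-sampled logit-linear trend.

    Parameters
    ----------
    n_chains, n_burn, n_keep, seed, rhat_threshold
        Sampler settings (see :class:`MCMCSettings`).
    include_noise : bool
        Whether predictions integrate residual noise (posterior
        predictive) or describe the mean trend curve only.

    Attributes
    ----------
    posterior_ : LogitLinearPosterior
        Retained draws with chain metadata and R-hat diagnostics.
    converged_ : bool
        All R-hat values at or below the threshold.

    Examples
    --------
    >>> from uhctraj.synthetic import generate_study_like
    >>> s = generate_study_like(seed=1)
    >>> m = BayesianLogitTrend(n_burn=500, n_keep=1000, seed=1)
    >>> m.fit(s.years.reshape(-1, 1), s.values)  # doctest: +ELLIPSIS
    BayesianLogitTrend(...)
    """

    def __init__(
        self,
        n_chains: int = 2,
        n_burn: int = 5000,
        n_keep: int = 10000,
        seed: int = 0,
        rhat_threshold: float = 1.1,
        include_noise: bool = True,
    ):
        self.n_chains = n_chains
        self.n_burn = n_burn
        self.n_keep = n_keep
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.include_noise = include_noise

    def _settings(self) -> MCMCSettings:
        return MCMCSettings(
            n_chains=self.n_chains,
            n_burn=self.n_burn,
            n_keep=self.n_keep,
            seed=self.seed,
            rhat_threshold=self.rhat_threshold,
        )

    @staticmethod
    def _years(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise CoverageValidationError("X must be a single column of years")
            X = X[:, 0]
        return X

    def fit(self, X, y, series_id: str = "series"):
        """Fit to years ``X`` (n or n x 1) and coverage proportions ``y``."""
        years = self._years(X)
        series = CoverageSeries(series_id, years.astype(int), np.asarray(y, dtype=float))
        self.posterior_ = fit_logit_linear(series, self._settings())
        self.converged_ = self.posterior_.converged
        self.rhat_ = dict(self.posterior_.rhat)
        return self

    def fit_series(self, series: CoverageSeries):
        self.posterior_ = fit_logit_linear(series, self._settings())
        self.converged_ = self.posterior_.converged
        self.rhat_ = dict(self.posterior_.rhat)
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior predictive median coverage at the given years."""
        years = self._years(X)
        p = posterior_predictive_draws(
            self.posterior_, years, include_noise=self.include_noise
        )
        return np.median(p, axis=0)

    def project(self, years, target: float = 0.8) -> ProjectionResult:
        return project(
            self.posterior_, years, target=target, include_noise=self.include_noise
        )

    def growth_rate_interval(self, year_start: int, year_end: int) -> tuple[float, float]:
        return growth_rate_interval(
            self.posterior_, year_start, year_end, include_noise=self.include_noise
        )
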