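"""Logistic scenario model of coverage vs health-system inputs.

The structural form links the coverage index p to calendar year y and
three system inputs — the service capacity and access subindex (c),
health expenditure per capita (e), and health centres per 100 000
population (h):

    logit(p_est) = alpha0 + beta0 * y + beta1 * c + beta2 * e + beta3 * h

Coefficients are estimated by ordinary least squares on the
logit-transformed index with covariates standardized (the outcome is an
index, not Bernoulli trials, so least squares on the logit is the
deterministic, testable choice; a fractional-logit quasi-likelihood fit
is available behind a flag).  Fitted models answer two questions:

* what happens to projected coverage at a horizon year when an input is
  scaled up (e.g. doubled), alone or in combination; and
* what bounded percentage increase of the inputs would be needed to hit
  a coverage target, found by L-BFGS-B minimization of the squared gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .data import (
    CoverageValidationError,
    IndicatorPanel,
    inverse_logit,
    logit,
)

FACTORS = ("c", "e", "h")


class DegenerateDesignError(CoverageValidationError):
    """The regression design is rank deficient (constant/collinear columns)."""


@dataclass(frozen=True)
class ScenarioModelFit:
    """Fitted structural coefficients with standardization constants.

    Coefficients are on the logit scale per standardized covariate unit;
    ``standardization`` maps each factor to its (center, scale) so raw
    paths can be projected reproducibly.  ``raw_coefficients`` converts
    back to per-raw-unit coefficients for comparison with generating
    values.
    """

    alpha0: float
    beta_year: float
    beta_c: float
    beta_e: float
    beta_h: float
    reference_year: int
    standardization: dict = field(default_factory=dict)
    rss: float = float("nan")

    def __post_init__(self):
        coefs = [self.alpha0, self.beta_year, self.beta_c, self.beta_e, self.beta_h]
        if not np.all(np.isfinite(coefs)):
            raise CoverageValidationError(f"non-finite fitted coefficients: {coefs}")
        missing = [f for f in FACTORS if f not in self.standardization]
        if missing:
            raise CoverageValidationError(
                f"standardization constants missing for {missing}"
            )

    def standardized(self, factor: str, values) -> np.ndarray:
        center, scale = self.standardization[factor]
        return (np.asarray(values, dtype=float) - center) / scale

    @property
    def raw_coefficients(self) -> dict[str, float]:
        """Coefficients per raw covariate unit (intercept at reference year)."""
        out = {"beta_year": self.beta_year}
        alpha = self.alpha0
        for factor, beta in zip(FACTORS, (self.beta_c, self.beta_e, self.beta_h)):
            center, scale = self.standardization[factor]
            out[f"beta_{factor}"] = beta / scale
            alpha -= beta * center / scale
        out["alpha0"] = alpha
        return out

    def predict_logit(self, years, c, e, h) -> np.ndarray:
        t = np.asarray(years, dtype=float) - self.reference_year
        return (
            self.alpha0
            + self.beta_year * t
            + self.beta_c * self.standardized("c", c)
            + self.beta_e * self.standardized("e", e)
            + self.beta_h * self.standardized("h", h)
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """Multiplicative what-if on the factor paths from a reference year on."""

    multipliers: dict
    horizon_year: int
    reference_year: int

    def __post_init__(self):
        unknown = set(self.multipliers) - set(FACTORS)
        if unknown:
            raise CoverageValidationError(f"unknown factor(s) {sorted(unknown)}")
        if any(m <= 0 for m in self.multipliers.values()):
            raise CoverageValidationError("multipliers must be positive")
        if self.horizon_year < self.reference_year:
            raise CoverageValidationError("horizon_year must not precede reference_year")

    def multiplier(self, factor: str) -> float:
        return float(self.multipliers.get(factor, 1.0))


@dataclass(frozen=True)
class RequiredIncreaseResult:
    """Bounded-optimization answer: percent increases needed per factor."""

    increase_pct: dict
    objective_value: float
    converged: bool
    at_bound: dict
    projected_coverage: float

    def __post_init__(self):
        if self.objective_value < 0:
            raise CoverageValidationError("squared objective cannot be negative")


def _design(panel: IndicatorPanel, reference_year: int):
    std = {}
    cols = []
    for factor in FACTORS:
        raw = getattr(panel, factor)
        center = float(np.mean(raw))
        scale = float(np.std(raw, ddof=0))
        if scale < 1e-12:
            raise DegenerateDesignError(
                f"covariate {factor!r} is constant over the fitting years"
            )
        std[factor] = (center, scale)
        cols.append((raw - center) / scale)
    t = panel.years.astype(float) - reference_year
    X = np.column_stack([t] + cols)
    return X, std


def fit_scenario_model(
    panel: IndicatorPanel,
    reference_year: int | None = None,
    method: str = "ols",
) -> ScenarioModelFit:
    """Estimate the structural coefficients from a historical panel.

    Least squares of logit(coverage) on (year - reference_year) and the
    standardized factors; ``method="fractional"`` fits the same linear
    predictor by fractional-logit quasi-likelihood instead.  Needs at
    least 6 years and non-constant, non-collinear covariates.
    """
    if len(panel) < 6:
        raise CoverageValidationError(
            f"scenario model needs at least 6 years; got {len(panel)}"
        )
    if reference_year is None:
        reference_year = int(panel.years[0])
    X, std = _design(panel, reference_year)
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # Name the columns involved in the collinearity for the error.
        names = ["year"] + list(FACTORS)
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise DegenerateDesignError(
            f"design is rank deficient (rank {rank} < {Xc.shape[1]}); "
            f"collinear column pair(s): {pairs or 'unidentified'}"
        )
    if method == "ols":
        res = sm.OLS(logit(panel.coverage), Xc).fit()
        params = res.params
        rss = float(np.sum(res.resid**2))
    elif method == "fractional":
        res = sm.GLM(
            panel.coverage, Xc, family=sm.families.Binomial()
        ).fit(scale="X2")
        params = res.params
        mu = res.predict(Xc)
        rss = float(np.sum((logit(panel.coverage) - logit(mu)) ** 2))
    else:
        raise CoverageValidationError(f"unknown fit method {method!r}")
    return ScenarioModelFit(
        alpha0=float(params[0]),
        beta_year=float(params[1]),
        beta_c=float(params[2]),
        beta_e=float(params[3]),
        beta_h=float(params[4]),
        reference_year=reference_year,
        standardization=std,
        rss=rss,
    )


def extrapolate_covariate(
    years: np.ndarray, values: np.ndarray, horizon_year: int, window: int = 5
) -> float:
    """Baseline covariate value at the horizon, log-linearly extrapolated.

    A log-linear trend is fitted to the last ``window`` observed years and
    evaluated at the horizon; if any windowed value is non-positive the
    trend falls back to linear.  A horizon inside the observed range
    returns the observed value.
    """
    if horizon_year <= years[-1]:
        idx = np.nonzero(years == horizon_year)[0]
        if idx.size:
            return float(values[idx[0]])
        raise CoverageValidationError(
            f"horizon year {horizon_year} inside observed range but not observed"
        )
    yw = years[-window:].astype(float)
    vw = values[-window:]
    if np.all(vw > 0):
        slope, intercept = np.polyfit(yw, np.log(vw), 1)
        return float(np.exp(intercept + slope * horizon_year))
    slope, intercept = np.polyfit(yw, vw, 1)
    return float(max(intercept + slope * horizon_year, 0.0))


def project_scenario(
    fit: ScenarioModelFit, panel: IndicatorPanel, spec: ScenarioSpec
) -> float:
    """Projected coverage proportion at the horizon under a scenario.

    Factor baselines are extended to the horizon (log-linear from the
    last five observed years) and scaled by the scenario multipliers;
    all-ones multipliers reproduce the baseline projection exactly.
    """
    if spec.horizon_year < panel.years[-1]:
        raise CoverageValidationError(
            f"horizon {spec.horizon_year} precedes last observed year {panel.years[-1]}"
        )
    vals = {}
    for factor in FACTORS:
        base = extrapolate_covariate(
            panel.years, getattr(panel, factor), spec.horizon_year
        )
        vals[factor] = base * spec.multiplier(factor)
    z = fit.predict_logit(
        [spec.horizon_year], [vals["c"]], [vals["e"]], [vals["h"]]
    )
    return float(inverse_logit(z[0]))


def scenario_deltas(
    fit: ScenarioModelFit,
    panel: IndicatorPanel,
    horizon_year: int,
    multiplier: float = 2.0,
) -> pd.DataFrame:
    """Doubling table: each factor scaled alone, then all in combination.

    Returns one row per scenario with projected horizon coverage and the
    delta versus baseline in percentage points.  The combined delta is
    generally not the sum of individual deltas (logistic nonlinearity).
    """
    ref = int(panel.years[-1])
    baseline = project_scenario(
        fit, panel, ScenarioSpec({}, horizon_year, ref)
    )
    rows = [("baseline", {}, baseline)]
    for factor in FACTORS:
        p = project_scenario(
            fit, panel, ScenarioSpec({factor: multiplier}, horizon_year, ref)
        )
        rows.append((factor, {factor: multiplier}, p))
    combined = {f: multiplier for f in FACTORS}
    rows.append(
        ("combined", combined, project_scenario(fit, panel, ScenarioSpec(combined, horizon_year, ref)))
    )
    return pd.DataFrame(
        {
            "scenario": [r[0] for r in rows],
            "multiplier": [multiplier if r[1] else 1.0 for r in rows],
            "coverage_pct": [100 * r[2] for r in rows],
            "delta_pp": [100 * (r[2] - baseline) for r in rows],
        }
    )


def required_increase(
    fit: ScenarioModelFit,
    panel: IndicatorPanel,
    target: float = 0.8,
    horizon_year: int = 2030,
    bounds: tuple[float, float] = (0.0, 100.0),
    init: float = 50.0,
) -> RequiredIncreaseResult:
    """Percent increases of (c, e, h) needed to reach the target by the horizon.

    Minimizes the squared difference between the projected horizon
    coverage and the target over the box ``bounds`` (percent increases)
    with the L-BFGS-B algorithm, starting from ``init`` percent for every
    factor.  If the baseline already meets the target the answer is zero
    increases with zero objective.
    """
    if not (0.0 < target < 1.0):
        raise CoverageValidationError(f"target must lie in (0, 1); got {target}")
    ref = int(panel.years[-1])

    def objective(x: np.ndarray) -> float:
        spec = ScenarioSpec(
            {f: 1.0 + pct / 100.0 for f, pct in zip(FACTORS, x)}, horizon_year, ref
        )
        return (project_scenario(fit, panel, spec) - target) ** 2

    baseline = project_scenario(fit, panel, ScenarioSpec({}, horizon_year, ref))
    if baseline >= target:
        # Target attained with no scale-up: the attainment shortfall is zero.
        return RequiredIncreaseResult(
            increase_pct={f: 0.0 for f in FACTORS},
            objective_value=0.0,
            converged=True,
            at_bound={f: False for f in FACTORS},
            projected_coverage=baseline,
        )

    # The squared-gap surface is shallow near the solution manifold; the
    # default stopping tolerances would stall at the initial guess.
    res = minimize(
        objective,
        x0=np.full(3, float(init)),
        method="L-BFGS-B",
        bounds=[bounds] * 3,
        options={"ftol": 1e-15, "gtol": 1e-12, "eps": 1e-6, "maxiter": 500},
    )
    if not res.success and res.fun > 1e-8:
        # Carry the last iterate in the error so callers can inspect it.
        raise RuntimeError(
            f"L-BFGS-B failed: {res.message}; last iterate {res.x}, objective {res.fun}"
        )
    x = np.clip(res.x, bounds[0], bounds[1])
    tol = 1e-6 * max(1.0, bounds[1] - bounds[0])
    at_bound = {
        f: bool(abs(v - bounds[0]) < tol or abs(v - bounds[1]) < tol)
        for f, v in zip(FACTORS, x)
    }
    spec = ScenarioSpec(
        {f: 1.0 + v / 100.0 for f, v in zip(FACTORS, x)}, horizon_year, ref
    )
    return RequiredIncreaseResult(
        increase_pct={f: float(v) for f, v in zip(FACTORS, x)},
        objective_value=float(res.fun),
        converged=bool(res.success),
        at_bound=at_bound,
        projected_coverage=project_scenario(fit, panel, spec),
    )


class ScenarioLogisticModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for the logistic scenario model.

    ``fit(X, y)`` takes ``X`` with columns (year, c, e, h) and coverage
    proportions ``y``.  Fitted attributes expose the structural
    coefficients; scenario operations take an :class:`IndicatorPanel`
    for the covariate baselines.

    Attributes
    ----------
    fit_ : ScenarioModelFit
        Coefficients with standardization constants.
    coef_ : ndarray of shape (4,)
        (beta_year, beta_c, beta_e, beta_h) per standardized unit.
    intercept_ : float
    """

    def __init__(self, reference_year: int | None = None, method: str = "ols"):
        self.reference_year = reference_year
        self.method = method

    @staticmethod
    def _panel(X, y) -> IndicatorPanel:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise CoverageValidationError("X must have columns (year, c, e, h)")
        return IndicatorPanel(
            years=X[:, 0].astype(int),
            coverage=np.asarray(y, dtype=float),
            c=X[:, 1],
            e=X[:, 2],
            h=X[:, 3],
        )

    def fit(self, X, y):
        panel = self._panel(X, y)
        self.fit_ = fit_scenario_model(
            panel, reference_year=self.reference_year, method=self.method
        )
        self.panel_ = panel
        self.coef_ = np.array(
            [self.fit_.beta_year, self.fit_.beta_c, self.fit_.beta_e, self.fit_.beta_h]
        )
        self.intercept_ = self.fit_.alpha0
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted coverage proportions for rows of (year, c, e, h)."""
        X = np.asarray(X, dtype=float)
        z = self.fit_.predict_logit(X[:, 0], X[:, 1], X[:, 2], X[:, 3])
        return inverse_logit(z)

    def project_scenario(self, spec: ScenarioSpec, panel: IndicatorPanel | None = None) -> float:
        return project_scenario(self.fit_, panel or self.panel_, spec)

    def scenario_deltas(self, horizon_year: int, multiplier: float = 2.0,
                        panel: IndicatorPanel | None = None) -> pd.DataFrame:
        return scenario_deltas(self.fit_, panel or self.panel_, horizon_year, multiplier)

    def required_increase(self, target: float = 0.8, horizon_year: int = 2030,
                          bounds: tuple[float, float] = (0.0, 100.0), init: float = 50.0,
                          panel: IndicatorPanel | None = None) -> RequiredIncreaseResult:
        return required_increase(
            self.fit_, panel or self.panel_, target, horizon_year, bounds, init
        )
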