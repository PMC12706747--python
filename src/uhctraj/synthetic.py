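"""Synthetic coverage trajectories and covariate panels.

The generators produce data with the statistical structure the analysis
assumes — a linear trend on the logit scale with Gaussian observation
noise, an optional growth shock (e.g. a stall), and smoothly growing
health-system covariates — so every downstream stage can be tested
end-to-end without any external download.

`generate_study_like` emulates the published Ethiopia composite-index
trajectory: ~15.3% in 2000, ~28.0% in 2010, ~45.9% in 2020, with growth
stalling entirely over 2019-2021.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import (
    CoverageSeries,
    CoverageValidationError,
    EPS,
    IndicatorPanel,
    inverse_logit,
    logit,
)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Parameters of a logit-linear trajectory with an optional growth shock.

    ``z0`` is the logit-scale level at ``start_year``; ``slope`` the annual
    logit increment; over the optional ``[shock_start, shock_end]`` window
    the increment is multiplied by ``shock_multiplier`` (0 = stall).
    ``noise_sd`` is the SD of i.i.d. Gaussian observation noise on the
    logit scale.
    """

    start_year: int = 2000
    end_year: int = 2021
    z0: float = -1.71
    slope: float = 0.08
    shock_start: int | None = None
    shock_end: int | None = None
    shock_multiplier: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.end_year <= self.start_year:
            raise CoverageValidationError(
                f"end_year ({self.end_year}) must be after start_year ({self.start_year})"
            )
        if self.noise_sd < 0:
            raise CoverageValidationError("noise_sd must be non-negative")
        if (self.shock_start is None) != (self.shock_end is None):
            raise CoverageValidationError("shock window needs both start and end")
        if self.shock_start is not None:
            if not (self.start_year <= self.shock_start < self.shock_end <= self.end_year):
                raise CoverageValidationError(
                    "shock window must lie inside [start_year, end_year]"
                )


def _trajectory_logits(config: TrajectoryConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless logit path: slope accumulates year-by-year, shock-scaled."""
    years = np.arange(config.start_year, config.end_year + 1)
    increments = np.full(years.size - 1, config.slope)
    if config.shock_start is not None:
        # An increment belongs to the shock window if the year it starts
        # from lies in [shock_start, shock_end).
        left = years[:-1]
        in_shock = (left >= config.shock_start) & (left < config.shock_end)
        increments[in_shock] *= config.shock_multiplier
    z = config.z0 + np.concatenate([[0.0], np.cumsum(increments)])
    return years, z


def generate_series(config: TrajectoryConfig, series_id: str = "synthetic") -> CoverageSeries:
    """Draw one coverage series from the trajectory model.

    Deterministic given ``config.seed``: the same config always yields an
    identical series.
    """
    years, z = _trajectory_logits(config)
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=years.size) if config.noise_sd > 0 else 0.0
    return CoverageSeries(series_id, years, inverse_logit(z + noise))


# Printed composite-index anchors the study-like generator reproduces in
# expectation: 15.3% (2000), 28.0% (2010), 45.9% (2020), with the 2019-2021
# stall meaning the 2019 level already equals the 2020 one.
STUDY_ANCHORS = {2000: 0.153, 2010: 0.280, 2020: 0.459}
STUDY_STALL = (2019, 2021)

#: Published 2000/2010/2020 anchor values for the four subindices, used to
#: generate study-like companions to the composite series.
SUBINDEX_ANCHORS = {
    "rmnch": {2000: 0.187, 2010: 0.326, 2020: 0.526},
    "infectious": {2000: 0.048, 2010: 0.145, 2020: 0.368},
    "ncd": {2000: 0.400, 2010: 0.462, 2020: 0.524},
    "capacity": {2000: 0.120, 2010: 0.135, 2020: 0.210},
}
#: Observation noise of the study-like series, logit units.  WHO index
#: series are smoothed model estimates, so their year-to-year scatter is
#: small relative to raw survey indicators.
STUDY_NOISE_SD = 0.02


def anchored_logits(
    anchors: dict[int, float],
    start_year: int = 2000,
    end_year: int = 2021,
    stall_start: int | None = STUDY_STALL[0],
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless logit path through printed anchor values with a stall.

    Piecewise linear on the logit scale between consecutive anchors; the
    last anchor level is reached already at ``stall_start`` and held flat
    through ``end_year`` (the stall).
    """
    years = np.arange(start_year, end_year + 1)
    anchor_years = sorted(anchors)
    knot_years = list(anchor_years)
    knot_z = [logit(anchors[y]) for y in anchor_years]
    if stall_start is not None and stall_start < knot_years[-1]:
        # The final anchor is attained at the stall onset, then held.
        knot_years[-1] = stall_start
    z = np.interp(years, knot_years, knot_z)
    return years, z


def study_like_logits() -> tuple[np.ndarray, np.ndarray]:
    """Noiseless composite-index logit path (anchors + 2019-2021 stall)."""
    return anchored_logits(STUDY_ANCHORS)


def generate_anchored(
    anchors: dict[int, float],
    seed: int = 0,
    series_id: str = "series",
    noise_sd: float = STUDY_NOISE_SD,
    start_year: int = 2000,
    end_year: int = 2021,
    stall_start: int | None = STUDY_STALL[0],
) -> CoverageSeries:
    """Draw a series around an anchored noiseless path."""
    years, z = anchored_logits(anchors, start_year, end_year, stall_start)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=years.size) if noise_sd > 0 else 0.0
    return CoverageSeries(series_id, years, inverse_logit(z + noise))


def generate_study_like(seed: int = 0, series_id: str = "composite") -> CoverageSeries:
    """A 2000-2021 composite-index series emulating the published trajectory."""
    return generate_anchored(STUDY_ANCHORS, seed=seed, series_id=series_id)


def generate_study_bundle(seed: int = 0) -> list[CoverageSeries]:
    """Composite plus the four subindex series, each with its own noise stream."""
    out = [generate_study_like(seed=seed)]
    for i, (name, anchors) in enumerate(SUBINDEX_ANCHORS.items(), start=1):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        out.append(generate_anchored(anchors, seed=child, series_id=name))
    return out


@dataclass(frozen=True)
class PanelConfig:
    """Generating model for a coverage + covariate panel.

    Coverage follows the logistic structural form
    ``logit(p_t) = alpha0 + beta_year (t - start) + beta_c c_t + beta_e e_t
    + beta_h h_t + noise`` with the covariates on their raw scales, so
    parameter-recovery tests compare against these raw-scale coefficients.

    Covariates grow exponentially at the given per-year rates with
    seeded log-scale idiosyncratic variation (``*_noise``).  That
    variation is what identifies the structural coefficients: perfectly
    smooth exponentials plus a linear year term are near-collinear, and
    no fit could separate the factors.  The defaults give each factor an
    orthogonal logit-scale contribution of ~0.03 SD, comfortably above
    the outcome noise floor at 22 annual observations.
    """

    trajectory: TrajectoryConfig = TrajectoryConfig()
    true_alpha0: float = -2.4
    true_beta_year: float = 0.04
    true_beta_c: float = 2.2
    true_beta_e: float = 0.006
    true_beta_h: float = 0.22
    c0: float = 0.10
    e0: float = 20.0
    h0: float = 1.0
    c_growth: float = 0.025
    e_growth: float = 0.08
    h_growth: float = 0.05
    c_noise: float = 0.15
    e_noise: float = 0.10
    h_noise: float = 0.12
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise CoverageValidationError("noise_sd must be non-negative")
        if min(self.c_noise, self.e_noise, self.h_noise) < 0:
            raise CoverageValidationError("covariate noise SDs must be non-negative")
        if self.c0 <= 0 or self.e0 <= 0 or self.h0 < 0:
            raise CoverageValidationError("covariate baselines must be positive (h0 >= 0)")


def panel_covariates(
    config: PanelConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Covariate paths: exponential growth with seeded log-scale variation.

    The covariate noise stream is a fixed substream of the config seed,
    so outcome noise and covariate paths are independently reproducible.
    """
    traj = config.trajectory
    years = np.arange(traj.start_year, traj.end_year + 1)
    t = years - traj.start_year
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    c = config.c0 * np.exp(config.c_growth * t + rng.normal(0, config.c_noise, t.size))
    e = config.e0 * np.exp(config.e_growth * t + rng.normal(0, config.e_noise, t.size))
    h = config.h0 * np.exp(config.h_growth * t + rng.normal(0, config.h_noise, t.size))
    return years, c, e, h


def panel_logits(config: PanelConfig, c, e, h) -> np.ndarray:
    """Structural (noise-free) logits for realized covariate paths."""
    traj = config.trajectory
    t = np.arange(traj.start_year, traj.end_year + 1) - traj.start_year
    return (
        config.true_alpha0
        + config.true_beta_year * t
        + config.true_beta_c * c
        + config.true_beta_e * e
        + config.true_beta_h * h
    )


def generate_panel(config: PanelConfig) -> IndicatorPanel:
    """Draw a panel whose coverage follows the logistic structural form.

    Raises a validation error naming the first offending year if the
    generating curve leaves the representable open interval, or if the
    capacity covariate c escapes (0, 1).
    """
    years, c, e, h = panel_covariates(config)
    if np.any(c >= 1.0):
        bad = int(years[np.argmax(c >= 1.0)])
        raise CoverageValidationError(
            f"capacity covariate c reaches 1 at year {bad}; lower c0 or c_growth"
        )
    z = panel_logits(config, c, e, h)
    bound = logit(1.0 - EPS)
    if np.any(np.abs(z) > bound):
        bad = int(years[np.argmax(np.abs(z) > bound)])
        raise CoverageValidationError(
            f"generating coefficients drive coverage outside (0, 1) at year {bad}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    noise = rng.normal(0.0, config.noise_sd, size=years.size) if config.noise_sd > 0 else 0.0
    return IndicatorPanel(
        years=years, coverage=inverse_logit(z + noise), c=c, e=e, h=h
    )


def study_like_panel(seed: int = 0) -> IndicatorPanel:
    """A 2000-2021 panel pairing Eq.-form coverage with its covariates.

    Alias for :func:`generate_panel` at the default study conditions;
    the resulting coverage path rises from ~14% to ~50% over 2000-2021.
    """
    return generate_panel(replace(PanelConfig(), seed=seed))
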