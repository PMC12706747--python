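"""Shared fixtures: small fixtures are generated in memory, never stored."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from uhctraj.bayes import MCMCSettings
from uhctraj.data import CoverageSeries, IndicatorPanel
from uhctraj.scenario import ScenarioModelFit
from uhctraj.synthetic import PanelConfig, generate_panel, generate_study_like


@pytest.fixture(scope="session")
def fast_mcmc() -> MCMCSettings:
    """Reduced sampler settings for unit tests; defaults stay 5000/10000."""
    return MCMCSettings(n_chains=2, n_burn=500, n_keep=1500, seed=42)


@pytest.fixture(scope="session")
def study_series() -> CoverageSeries:
    return generate_study_like(seed=7)


@pytest.fixture(scope="session")
def five_point_series() -> CoverageSeries:
    """Tiny fixed fixture for conjugate-oracle comparisons."""
    return CoverageSeries(
        "fixture5",
        np.arange(2000, 2005),
        np.array([0.20, 0.235, 0.26, 0.31, 0.33]),
    )


@pytest.fixture(scope="session")
def noiseless_panel() -> IndicatorPanel:
    return generate_panel(replace(PanelConfig(), noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def noisy_panel() -> IndicatorPanel:
    return generate_panel(PanelConfig(seed=5))


def make_known_fit(
    beta_c: float = 0.8,
    beta_e: float = 0.5,
    beta_h: float = 0.6,
    alpha0: float = 0.0,
    beta_year: float = 0.02,
    reference_year: int = 2021,
) -> ScenarioModelFit:
    """A hand-built scenario fit with unit standardization for oracle tests."""
    return ScenarioModelFit(
        alpha0=alpha0,
        beta_year=beta_year,
        beta_c=beta_c,
        beta_e=beta_e,
        beta_h=beta_h,
        reference_year=reference_year,
        standardization={"c": (0.0, 1.0), "e": (0.0, 1.0), "h": (0.0, 1.0)},
        rss=0.0,
    )


@pytest.fixture(scope="session")
def flat_covariate_panel() -> IndicatorPanel:
    """Panel whose covariates are constant-ish paths ending at known values.

    With constant paths the log-linear extrapolation reproduces the last
    value at any horizon, so hand computations on known-coefficient fits
    are exact.
    """
    years = np.arange(2010, 2022)
    n = years.size
    return IndicatorPanel(
        years=years,
        coverage=np.linspace(0.3, 0.45, n),
        c=np.full(n, 0.2),
        e=np.full(n, 1.0),
        h=np.full(n, 0.5),
    )
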