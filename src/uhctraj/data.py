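"""Core domain types and transforms for coverage-index analysis.

A *coverage index* is a bounded proportion (service coverage on a 0-1
scale, conventionally printed as 0-100%).  Everything downstream models
its logit, so this module owns the logit/inverse-logit pair, the
boundary-clamping rule that keeps the transform defined, the composite
(geometric-mean) aggregation of subindices, and CSV input/output for
annual series and covariate panels.

Internal storage is always the proportion scale; the percent scale
exists only at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import gmean

#: Half-width of the open interval used when clamping boundary proportions.
#: Values of exactly 0 or 1 (ART coverage approaches 1) have no logit; they
#: are pulled to EPS / 1 - EPS with a warning.
EPS = 1e-6

PERCENT = "percent"
PROPORTION = "proportion"


class CoverageDomainError(ValueError):
    """A value lies outside the domain an operation is defined on."""


class CoverageValidationError(ValueError):
    """A series or panel violates a structural invariant."""


def logit(p):
    """Log-odds transform ln(p / (1 - p)), defined on the open unit interval.

    Parameters
    ----------
    p : float or array-like
        Proportion(s) strictly inside (0, 1).

    Returns
    -------
    float or ndarray
        Logit value(s); ``inverse_logit(logit(p)) == p`` to machine tolerance.
    """
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise CoverageDomainError(f"logit requires values strictly in (0, 1); got {p!r}")
    out = special.logit(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_logit(z):
    """Logistic function 1 / (1 + exp(-z)); maps the real line into (0, 1)."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CoverageDomainError(f"inverse_logit requires finite input; got {z!r}")
    out = special.expit(arr)
    # expit underflows to exactly 0/1 for |z| > ~745; keep the interval open.
    out = np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


def clamp_proportion(values, eps: float = EPS, warn: bool = True):
    """Pull values equal to 0 or 1 just inside the open interval.

    Returns the clamped array; emits a single warning if anything moved.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise CoverageDomainError(
            f"proportions must lie in [0, 1] before clamping; got {arr!r}"
        )
    clamped = np.clip(arr, eps, 1.0 - eps)
    if warn and np.any(clamped != arr):
        warnings.warn(
            f"boundary proportion(s) clamped to the open interval (eps={eps})",
            stacklevel=2,
        )
    return clamped


def normalize_scale(values, scale_hint: str | None = None):
    """Normalize raw inputs in [0, 100] or [0, 1] to the proportion scale.

    With no hint, any value above 1 marks the whole column as percent.
    Returns ``(proportions, scale_used)``.
    """
    arr = np.asarray(values, dtype=float)
    if scale_hint is None:
        scale_hint = PERCENT if np.any(arr > 1.0) else PROPORTION
    if scale_hint not in (PERCENT, PROPORTION):
        raise CoverageValidationError(f"unknown scale hint {scale_hint!r}")
    if scale_hint == PERCENT:
        if np.any(arr < 0.0) or np.any(arr > 100.0):
            raise CoverageDomainError(f"percent values must lie in [0, 100]; got {arr!r}")
        arr = arr / 100.0
    return arr, scale_hint


@dataclass(frozen=True)
class CoverageSeries:
    """One annual time series of a coverage proportion.

    ``values`` are stored as proportions strictly inside (0, 1);
    ``display_scale`` records how external I/O renders them.
    """

    series_id: str
    years: np.ndarray
    values: np.ndarray
    display_scale: str = PERCENT

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.size != values.size:
            raise CoverageValidationError("years and values must have equal length")
        if years.size == 0:
            raise CoverageValidationError("a series needs at least one observation")
        if np.any(np.diff(years) <= 0):
            raise CoverageValidationError(
                f"years must be strictly increasing; got {years.tolist()}"
            )
        if np.any(values <= 0.0) or np.any(values >= 1.0):
            raise CoverageValidationError(
                "stored values must be strictly inside (0, 1); "
                "normalize and clamp raw inputs with CoverageSeries.from_raw"
            )
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_raw(
        cls,
        series_id: str,
        years,
        values,
        scale_hint: str | None = None,
        eps: float = EPS,
    ) -> "CoverageSeries":
        """Build a series from raw numbers, normalizing scale and clamping bounds."""
        props, scale = normalize_scale(values, scale_hint)
        props = clamp_proportion(props, eps=eps)
        return cls(series_id, np.asarray(years, dtype=int), props, display_scale=scale)

    def __len__(self) -> int:
        return int(self.years.size)

    def value_at(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not present in series {self.series_id!r}")
        return float(self.values[idx[0]])

    def require_min_observations(self, n: int = 3) -> None:
        if len(self) < n:
            raise CoverageValidationError(
                f"series {self.series_id!r} has {len(self)} observations; "
                f"at least {n} required for model fitting"
            )

    def display_values(self) -> np.ndarray:
        """Values on the external display scale."""
        return self.values * 100.0 if self.display_scale == PERCENT else self.values.copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.display_values()})


@dataclass(frozen=True)
class IndicatorPanel:
    """Per-year coverage joined with the three health-system inputs.

    ``c`` is the service capacity and access subindex (proportion),
    ``e`` health expenditure per capita (monetary units per person per
    year), ``h`` health centres per 100 000 population.
    """

    years: np.ndarray
    coverage: np.ndarray
    c: np.ndarray
    e: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        cols = {}
        for name in ("coverage", "c", "e", "h"):
            col = np.asarray(getattr(self, name), dtype=float)
            if col.size != years.size:
                raise CoverageValidationError(
                    f"panel column {name!r} has length {col.size}, expected {years.size}"
                )
            cols[name] = col
        if np.any(np.diff(years) <= 0):
            raise CoverageValidationError("panel years must be strictly increasing")
        for name in ("coverage", "c"):
            if np.any(cols[name] <= 0.0) or np.any(cols[name] >= 1.0):
                raise CoverageValidationError(
                    f"panel column {name!r} must lie strictly inside (0, 1)"
                )
        if np.any(cols["e"] <= 0.0):
            raise CoverageValidationError("health expenditure e must be positive")
        if np.any(cols["h"] < 0.0):
            raise CoverageValidationError("health-centre density h must be non-negative")
        object.__setattr__(self, "years", years)
        for name, col in cols.items():
            object.__setattr__(self, name, col)

    def __len__(self) -> int:
        return int(self.years.size)

    def coverage_series(self, series_id: str = "composite") -> CoverageSeries:
        return CoverageSeries(series_id, self.years, self.coverage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "coverage": self.coverage * 100.0,
                "c": self.c * 100.0,
                "e": self.e,
                "h": self.h,
            }
        )


#: Canonical 4+4+3+3 grouping of the 14 tracer indicators into subindices.
DEFAULT_GROUPING: dict[str, tuple[str, ...]] = {
    "rmnch": (
        "family_planning",
        "antenatal_care_4plus",
        "dtp3_immunization",
        "care_seeking_ari",
    ),
    "infectious": (
        "tb_treatment",
        "art_coverage",
        "insecticide_treated_nets",
        "water_sanitation_hygiene",
    ),
    "ncd": (
        "hypertension_treatment",
        "diabetes_prevalence",
        "tobacco_non_use",
    ),
    "capacity": (
        "hospital_bed_density",
        "health_worker_density",
        "ihr_core_capacity",
    ),
}


@dataclass(frozen=True)
class SubindexWeights:
    """Grouping of tracer indicators into the four coverage subindices."""

    grouping: dict = field(default_factory=lambda: dict(DEFAULT_GROUPING))

    def __post_init__(self):
        if len(self.grouping) != 4:
            raise CoverageValidationError(
                f"exactly four subindices expected; got {len(self.grouping)}"
            )
        seen: dict[str, str] = {}
        for sub, members in self.grouping.items():
            if not members:
                raise CoverageValidationError(f"subindex {sub!r} has no indicators")
            for m in members:
                if m in seen:
                    raise CoverageValidationError(
                        f"indicator {m!r} assigned to both {seen[m]!r} and {sub!r}"
                    )
                seen[m] = sub

    @property
    def indicators(self) -> list[str]:
        return [m for members in self.grouping.values() for m in members]


def aggregate_geometric(values) -> float:
    """Geometric mean of subindex proportions: the composite-index aggregation.

    The composite service-coverage index is the unweighted geometric mean
    of its components, so a collapse in any one subindex drags the
    composite down more than an arithmetic mean would.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise CoverageValidationError("cannot aggregate an empty list of subindices")
    if np.any(arr <= 0.0):
        raise CoverageDomainError("geometric mean undefined for values <= 0")
    if np.any(arr > 1.0):
        raise CoverageDomainError("subindex values must be proportions in (0, 1]")
    return float(gmean(arr))


# ---------------------------------------------------------------------------
# CSV input/output


def _read_csv(path, expected_cols):
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CoverageValidationError(f"{path}: file is empty") from None
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise CoverageValidationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    for col in expected_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            # +2: header line plus 1-based indexing.
            raise CoverageValidationError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} "
                f"in column {col!r} at line {bad[0] + 2}"
            )
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise CoverageValidationError(
                f"{path}: missing value in column {col!r} at line {row + 2}"
            )
        df[col] = coerced
    if df.empty:
        raise CoverageValidationError(f"{path}: no data rows")
    return df


def read_coverage_csv(
    path, scale_hint: str | None = None, series_id: str | None = None
) -> CoverageSeries:
    """Read a two-column (year,value) CSV into a validated CoverageSeries.

    ``scale_hint`` may force ``"percent"`` or ``"proportion"``; by default
    the scale is inferred (any value above 1 implies percent).
    """
    df = _read_csv(path, ["year", "value"])
    years = df["year"].to_numpy()
    if np.any(years != np.round(years)):
        raise CoverageValidationError(f"{path}: years must be integers")
    years = years.astype(int)
    dup = pd.Series(years).duplicated()
    if dup.any():
        raise CoverageValidationError(
            f"{path}: duplicate year {years[dup.idxmax()]}"
        )
    order = np.argsort(years)
    if series_id is None:
        import os

        series_id = os.path.splitext(os.path.basename(str(path)))[0]
    return CoverageSeries.from_raw(
        series_id, years[order], df["value"].to_numpy()[order], scale_hint=scale_hint
    )


def write_coverage_csv(series: CoverageSeries, path) -> None:
    """Write a series on its display scale; read-back reproduces it bit-for-bit."""
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_panel_csv(path) -> IndicatorPanel:
    """Read a (year,coverage,c,e,h) CSV into a validated IndicatorPanel.

    Coverage and the capacity subindex c are scale-normalized like series
    values; e and h are taken as-is (their units are arbitrary — the
    scenario model standardizes them).
    """
    df = _read_csv(path, ["year", "coverage", "c", "e", "h"])
    years = df["year"].to_numpy().astype(int)
    order = np.argsort(years)
    coverage, _ = normalize_scale(df["coverage"].to_numpy()[order])
    c, _ = normalize_scale(df["c"].to_numpy()[order])
    return IndicatorPanel(
        years=years[order],
        coverage=clamp_proportion(coverage),
        c=clamp_proportion(c),
        e=df["e"].to_numpy()[order],
        h=df["h"].to_numpy()[order],
    )


def write_panel_csv(panel: IndicatorPanel, path) -> None:
    panel.to_frame().to_csv(path, index=False, float_format="%.17g")
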