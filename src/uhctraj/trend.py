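"""Descriptive trend analysis: compound annual growth rates of coverage.

"Average annual change" of a coverage series is the geometric endpoint
CAGR, 100 * ((v_end / v_start)^(1/(y_end - y_start)) - 1): the constant
yearly growth that compounds the start value into the end value exactly.
It is invariant to uniform rescaling (percent vs proportion) and reverses
through (1 + r)(1 + r') = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .data import CoverageDomainError, CoverageSeries, CoverageValidationError


@dataclass(frozen=True)
class TrendSummary:
    """Endpoint growth summary of one series over [year_start, year_end]."""

    series_id: str
    year_start: int
    year_end: int
    value_start: float
    value_end: float
    annual_growth_pct: float
    ci_lower_pct: float | None = None
    ci_upper_pct: float | None = None


def cagr_pct(value_start: float, value_end: float, n_years: int) -> float:
    """Compound annual growth rate in percent per year."""
    if n_years == 0:
        raise CoverageValidationError("growth rate undefined over a zero-year span")
    if value_start <= 0:
        raise CoverageDomainError(f"start value must be positive; got {value_start}")
    return 100.0 * ((value_end / value_start) ** (1.0 / n_years) - 1.0)


def annual_growth_rate(
    series: CoverageSeries, year_start: int, year_end: int
) -> TrendSummary:
    """Average annual growth rate of a series between two observed years.

    Both years must be present in the series; the rate is the endpoint
    CAGR in percent per year.
    """
    v0 = series.value_at(year_start)
    v1 = series.value_at(year_end)
    rate = cagr_pct(v0, v1, year_end - year_start)
    return TrendSummary(
        series_id=series.series_id,
        year_start=year_start,
        year_end=year_end,
        value_start=v0,
        value_end=v1,
        annual_growth_pct=rate,
    )


def trend_table(
    series_set: list[CoverageSeries], year_start: int, year_end: int
) -> list[TrendSummary]:
    """One TrendSummary per series, in the given order.

    Duplicate series ids are preserved (with a warning), never silently
    deduplicated.  Per-series failures are re-raised with the offending
    series id attached.
    """
    ids = [s.series_id for s in series_set]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        warnings.warn(f"duplicate series id(s) in trend table: {sorted(dupes)}", stacklevel=2)
    rows = []
    for s in series_set:
        try:
            rows.append(annual_growth_rate(s, year_start, year_end))
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"series {s.series_id!r}: {exc}") from exc
    return rows


def trend_frame(rows: list[TrendSummary]) -> pd.DataFrame:
    """Render trend summaries as a table, percent values to one decimal."""
    return pd.DataFrame(
        {
            "series": [r.series_id for r in rows],
            "year_start": [r.year_start for r in rows],
            "year_end": [r.year_end for r in rows],
            "coverage_start_pct": [round(100 * r.value_start, 1) for r in rows],
            "coverage_end_pct": [round(100 * r.value_end, 1) for r in rows],
            "annual_growth_pct": [round(r.annual_growth_pct, 1) for r in rows],
            "growth_ci_lower_pct": [
                None if r.ci_lower_pct is None else round(r.ci_lower_pct, 1) for r in rows
            ],
            "growth_ci_upper_pct": [
                None if r.ci_upper_pct is None else round(r.ci_upper_pct, 1) for r in rows
            ],
        }
    )
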