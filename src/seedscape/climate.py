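"""Windowed linear trends on annual climate series.

The study area's station records are summarized over fixed multi-decade
windows (by default 1931–1960, 1961–1990, 1991–2020 and the full
1931–2020 span).  Each window gets an ordinary least-squares line of the
annual value on the year; the reported "increase/decrease by X" is the
difference between the fitted values at the window's last and first year.
The window mean is reported alongside, since for OLS it equals the mean
of the observed in-window values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_WINDOWS",
    "TrendWindow",
    "validate_climate",
    "window_trend",
    "summarize_windows",
    "read_climate_csv",
]

DEFAULT_WINDOWS: tuple[tuple[int, int], ...] = (
    (1931, 1960),
    (1961, 1990),
    (1991, 2020),
    (1931, 2020),
)

#: Variables recognized in a climate frame, with their units.
VARIABLES = {"temp_c": "degC", "rain_mm": "mm"}


class ClimateValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TrendWindow:
    """OLS trend of one variable over one year window."""

    variable: str
    start_year: int
    end_year: int
    n_years: int
    slope: float            # units per year
    intercept: float
    fitted_start: float     # fitted value at start_year
    fitted_end: float       # fitted value at end_year
    delta: float            # fitted_end - fitted_start = slope * (end - start)
    mean: float             # arithmetic mean of in-window observations
    p_value: float
    coverage: float         # fraction of window years with data
    low_coverage: bool      # flagged when coverage < 0.8


def validate_climate(df: pd.DataFrame) -> pd.DataFrame:
    """Check the (year, temp_c, rain_mm) frame invariants; returns the frame."""
    if "year" not in df.columns:
        raise ClimateValidationError("climate frame needs a 'year' column")
    years = df["year"].to_numpy()
    if not np.all(np.diff(years) > 0):
        raise ClimateValidationError("years must be strictly increasing")
    if "temp_c" in df.columns:
        t = df["temp_c"].dropna()
        if ((t < -20) | (t > 50)).any():
            raise ClimateValidationError("temperature outside plausible range (-20..50 degC)")
    if "rain_mm" in df.columns:
        r = df["rain_mm"].dropna()
        if (r < 0).any():
            raise ClimateValidationError("rainfall must be non-negative")
    return df


def window_trend(
    series: pd.DataFrame,
    variable: str,
    start_year: int,
    end_year: int,
    min_coverage: float = 0.8,
) -> TrendWindow:
    """Fit the OLS line of ``variable`` on year over [start_year, end_year]."""
    if start_year >= end_year:
        raise ValueError(f"window start {start_year} must precede end {end_year}")
    validate_climate(series)
    if variable not in series.columns:
        raise ValueError(f"variable {variable!r} not in series")
    win = series[(series["year"] >= start_year) & (series["year"] <= end_year)]
    win = win.dropna(subset=[variable])
    if len(win) < 3:
        raise ValueError(
            f"window {start_year}-{end_year} has {len(win)} usable years; need >= 3"
        )
    x = win["year"].to_numpy(float)
    y = win[variable].to_numpy(float)
    fit = stats.linregress(x, y)
    fitted_start = fit.intercept + fit.slope * start_year
    fitted_end = fit.intercept + fit.slope * end_year
    coverage = len(win) / (end_year - start_year + 1)
    return TrendWindow(
        variable=variable,
        start_year=start_year,
        end_year=end_year,
        n_years=len(win),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fitted_start=float(fitted_start),
        fitted_end=float(fitted_end),
        delta=float(fitted_end - fitted_start),
        mean=float(y.mean()),
        p_value=float(fit.pvalue),
        coverage=float(coverage),
        low_coverage=bool(coverage < min_coverage),
    )


def summarize_windows(
    series: pd.DataFrame,
    windows: Sequence[tuple[int, int]] = DEFAULT_WINDOWS,
    variables: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """window_trend over every (window, variable) pair, as a tidy frame.

    A window failing its precondition (fewer than 3 usable years) is
    reported as a row with an ``error`` message rather than aborting the
    whole batch.
    """
    if variables is None:
        variables = [v for v in VARIABLES if v in series.columns]
    rows = []
    for variable in variables:
        for start, end in windows:
            try:
                tw = window_trend(series, variable, start, end)
            except ValueError as exc:
                rows.append(
                    {"variable": variable, "start_year": start, "end_year": end,
                     "error": str(exc)}
                )
                continue
            d = tw.__dict__.copy()
            d["error"] = ""
            rows.append(d)
    return pd.DataFrame(rows)


def read_climate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_climate(df)
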