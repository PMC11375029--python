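"""Epi-week calendar, lagged model designs and PACF lag diagnostics.

The response is a weekly admission count per diagnostic category; the
predictors are national weekly exposures.  The model design pairs week t
with the exposures and counts of weeks t-1..t-l (optionally also week t,
the "immediate" effect), plus the epi-week number and calendar year that
feed the seasonal smooths.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPOSURES = ("rain_mm", "temp_c", "wind_kmh", "pm10_ugm3", "so2_ppb", "co_ppm")


# ---------------------------------------------------------------------------
# MMWR epi-week calendar
# ---------------------------------------------------------------------------

def _epi_year_start(year: int) -> _dt.date:
    """First day (a Sunday) of MMWR week 1 of `year`.

    Week 1 is the Sunday-started week containing at least four days of the
    new calendar year.
    """
    jan1 = _dt.date(year, 1, 1)
    days_since_sunday = (jan1.weekday() + 1) % 7
    start = jan1 - _dt.timedelta(days=days_since_sunday)
    if days_since_sunday > 3:
        start += _dt.timedelta(days=7)
    return start


def epiweeks_in_year(year: int) -> int:
    """Number of MMWR epi-weeks (52 or 53) in `year`."""
    return (_epi_year_start(year + 1) - _epi_year_start(year)).days // 7


def date_to_epiweek(date: _dt.date) -> tuple[int, int]:
    """Map a calendar date to its (epi-year, epi-week)."""
    for year in (date.year + 1, date.year, date.year - 1):
        start = _epi_year_start(year)
        offset = (date - start).days
        if 0 <= offset < 7 * epiweeks_in_year(year):
            return year, offset // 7 + 1
    raise RuntimeError(f"no epi-week found for {date}")  # pragma: no cover


def epiweek_calendar(start_year: int, end_year: int) -> pd.DataFrame:
    """Enumerate MMWR epi-weeks from EW1 of start_year to the last EW of end_year.

    Returns a DataFrame with ``week_index`` (0-based, contiguous), ``year``,
    ``epiweek`` and the week's ``start_date`` (a Sunday).
    """
    if start_year > end_year:
        raise ValueError("start_year must be <= end_year")
    rows = []
    idx = 0
    for year in range(start_year, end_year + 1):
        start = _epi_year_start(year)
        for week in range(1, epiweeks_in_year(year) + 1):
            rows.append(
                {
                    "week_index": idx,
                    "year": year,
                    "epiweek": week,
                    "start_date": start + _dt.timedelta(days=7 * (week - 1)),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lagged design
# ---------------------------------------------------------------------------

@dataclass
class LagDesign:
    """Aligned lagged design for one admission category.

    ``frame`` holds only the usable rows (the first ``max_lag`` weeks are
    dropped): response ``y``, autoregressive columns ``y_lag{n}``, exposure
    columns ``{name}_lag{n}`` for n = 1..max_lag (plus n = 0 when
    ``include_immediate``), and the seasonal covariates ``week`` / ``year``.
    """

    frame: pd.DataFrame
    max_lag: int
    include_immediate: bool
    exposure_names: tuple[str, ...]
    n_total: int
    category: str | None = None
    column_roles: dict = field(default_factory=dict)

    @property
    def n_usable(self) -> int:
        return len(self.frame)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy()

    def exposure_column(self, exposure: str, lag: int) -> str:
        name = f"{exposure}_lag{lag}"
        if name not in self.frame.columns:
            raise KeyError(f"{name} not in design")
        return name

    def smooth_columns(self) -> list[str]:
        """All covariate columns that receive a smooth, in a stable order."""
        cols = [f"y_lag{n}" for n in range(1, self.max_lag + 1)]
        lags = range(0 if self.include_immediate else 1, self.max_lag + 1)
        cols += [f"{e}_lag{n}" for n in lags for e in self.exposure_names if n > 0 or self.include_immediate]
        return cols


def build_lag_design(
    admissions: pd.DataFrame,
    exposures: pd.DataFrame,
    max_lag: int = 3,
    include_immediate: bool = False,
    category: str | None = None,
) -> LagDesign:
    """Assemble the lagged design for one admission category.

    Parameters
    ----------
    admissions : DataFrame with ``week_index`` and ``count`` (optionally a
        ``category`` column already filtered to one category).
    exposures : DataFrame with ``week_index``, ``year``, ``epiweek`` and the
        six exposure columns.
    max_lag : maximum lag l in weeks (1..3 in the study protocol).
    include_immediate : also include the lag-0 exposure columns.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    adm = admissions
    if "category" in adm.columns:
        cats = adm["category"].unique()
        if len(cats) != 1:
            raise ValueError("admissions must be filtered to a single category")
        category = category or cats[0]
        adm = adm.drop(columns=["category"])
    adm = adm.set_index("week_index").sort_index()
    exp = exposures.set_index("week_index").sort_index()
    if not adm.index.equals(exp.index):
        raise ValueError("admissions and exposures week indices are misaligned")
    n = len(adm)
    if n <= max_lag:
        raise ValueError(f"horizon {n} must exceed max_lag {max_lag}")

    y = adm["count"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"y": y}
    roles: dict[str, dict] = {}
    for lag in range(1, max_lag + 1):
        cols[f"y_lag{lag}"] = np.roll(y, lag)
        roles[f"y_lag{lag}"] = {"role": "autoregressive", "lag": lag}
    lag_range = range(0 if include_immediate else 1, max_lag + 1)
    exposure_names = tuple(e for e in EXPOSURES if e in exp.columns)
    if not exposure_names:
        raise ValueError("no recognised exposure columns in exposures table")
    for name in exposure_names:
        series = exp[name].to_numpy(dtype=float)
        for lag in lag_range:
            cols[f"{name}_lag{lag}"] = np.roll(series, lag)
            roles[f"{name}_lag{lag}"] = {"role": "exposure", "exposure": name, "lag": lag}
    cols["week"] = exp["epiweek"].to_numpy(dtype=float)
    cols["year"] = exp["year"].to_numpy(dtype=float)
    roles["week"] = {"role": "season_week"}
    roles["year"] = {"role": "season_year"}

    frame = pd.DataFrame(cols, index=adm.index).iloc[max_lag:]
    if frame.isna().any().any():
        raise ValueError("missing values among usable design rows")
    return LagDesign(
        frame=frame,
        max_lag=max_lag,
        include_immediate=include_immediate,
        exposure_names=exposure_names,
        n_total=n,
        category=category,
        column_roles=roles,
    )


# ---------------------------------------------------------------------------
# PACF via Durbin–Levinson
# ---------------------------------------------------------------------------

def pacf(series, max_lag: int) -> pd.DataFrame:
    """Partial autocorrelations at lags 1..max_lag via Durbin–Levinson.

    Returns a DataFrame with columns ``lag``, ``pacf`` and ``band`` (the
    +-1.96/sqrt(n) white-noise band).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    if np.ptp(x) == 0:
        raise ValueError("PACF undefined for a constant series")
    x = x - x.mean()
    # biased sample autocovariances, the standard choice for D-L stability
    acov = np.array([x[: n - k] @ x[k:] for k in range(max_lag + 1)]) / n
    rho = acov / acov[0]

    phi_prev = np.zeros(0)
    pac = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        if k == 1:
            phi_kk = rho[1]
            phi = np.array([phi_kk])
        else:
            num = rho[k] - phi_prev @ rho[k - 1 : 0 : -1]
            den = 1.0 - phi_prev @ rho[1:k]
            phi_kk = num / den
            phi = np.append(phi_prev - phi_kk * phi_prev[::-1], phi_kk)
        pac[k - 1] = phi_kk
        phi_prev = phi
    band = 1.96 / np.sqrt(n)
    return pd.DataFrame({"lag": np.arange(1, max_lag + 1), "pacf": pac, "band": band})
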