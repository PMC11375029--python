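"""Inverse-distance-weighted interpolation of station weather records.

Daily station observations (rainfall, temperature, wind speed) are
interpolated to a complete raster with IDW, the distance power being
selected by leave-one-out cross-validation, and the daily rasters are then
aggregated to national weekly means on the epi-week calendar.

Coordinates are planar kilometres; at city-state scale (~50 km) the
geodesic correction is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .features import date_to_epiweek

#: stations closer than this (km) to a query point take over exactly
ZERO_DISTANCE_KM = 1e-9

#: default candidate IDW powers for LOO selection
DEFAULT_POWERS = tuple(np.arange(0.5, 5.0 + 1e-9, 0.25))


@dataclass
class GridSpec:
    """Regular raster: origin (x0, y0), square cells of `cell_km`, shape."""

    x0: float
    y0: float
    cell_km: float
    n_rows: int
    n_cols: int

    def cell_centers(self) -> np.ndarray:
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_km
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_km
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @classmethod
    def covering(cls, xy: np.ndarray, cell_km: float = 1.0, pad: float = 0.10) -> "GridSpec":
        """Grid over the bounding box of `xy`, padded by `pad` per side."""
        xmin, ymin = xy.min(axis=0)
        xmax, ymax = xy.max(axis=0)
        w, h = max(xmax - xmin, cell_km), max(ymax - ymin, cell_km)
        x0, y0 = xmin - pad * w, ymin - pad * h
        n_cols = int(np.ceil(w * (1 + 2 * pad) / cell_km))
        n_rows = int(np.ceil(h * (1 + 2 * pad) / cell_km))
        return cls(x0, y0, cell_km, max(n_rows, 1), max(n_cols, 1))


@dataclass
class GriddedField:
    """One interpolated daily raster."""

    grid: GridSpec
    values: np.ndarray  # (n_rows, n_cols)
    date: object
    variable: str

    def spatial_mean(self) -> float:
        return float(self.values.mean())


class IDWInterpolator(RegressorMixin, BaseEstimator):
    """Inverse-distance-weighting interpolator.

    Predictions are convex combinations of station values with weights
    d^(-power); a query within ``ZERO_DISTANCE_KM`` of a station returns
    that station's value exactly.
    """

    def __init__(self, power: float = 2.0):
        self.power = power

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.power <= 0:
            raise ValueError("power must be positive")
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_stations, 2) planar km coordinates")
        if len(X) == 0:
            raise ValueError("empty observation set")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite station coordinates or values")
        self.X_ = X
        self.y_ = y
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.sqrt(((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2))
        out = np.empty(len(X))
        exact = d < ZERO_DISTANCE_KM
        any_exact = exact.any(axis=1)
        with np.errstate(divide="ignore"):
            w = d ** (-self.power)
        w[~np.isfinite(w)] = 0.0
        denom = w.sum(axis=1)
        safe = ~any_exact
        out[safe] = (w[safe] @ self.y_) / denom[safe]
        for i in np.nonzero(any_exact)[0]:
            out[i] = self.y_[np.argmax(exact[i])]
        return out


def idw_interpolate(
    observations: pd.DataFrame,
    power: float,
    grid: GridSpec | None = None,
    cell_km: float = 1.0,
) -> GriddedField:
    """Interpolate one date/variable's station observations to a raster.

    `observations` needs columns x, y, value (one row per station) and
    single-valued date / variable columns if present.
    """
    if len(observations) == 0:
        raise ValueError("empty observation set")
    xy = observations[["x", "y"]].to_numpy(dtype=float)
    vals = observations["value"].to_numpy(dtype=float)
    date = observations["date"].iloc[0] if "date" in observations else None
    variable = observations["variable"].iloc[0] if "variable" in observations else ""
    if grid is None:
        grid = GridSpec.covering(xy, cell_km=cell_km)
    interp = IDWInterpolator(power=power).fit(xy, vals)
    z = interp.predict(grid.cell_centers()).reshape(grid.n_rows, grid.n_cols)
    return GriddedField(grid=grid, values=z, date=date, variable=variable)


def loo_rmse(xy: np.ndarray, values: np.ndarray, power: float) -> float:
    """Leave-one-out RMSE of IDW at a given power."""
    n = len(values)
    if n < 3:
        raise ValueError("need >= 3 stations for leave-one-out selection")
    errs = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        pred = IDWInterpolator(power=power).fit(xy[mask], values[mask]).predict(xy[i])
        errs[i] = pred[0] - values[i]
        mask[i] = True
    return float(np.sqrt(np.mean(errs**2)))


def fit_idw_power(
    observations: pd.DataFrame,
    candidate_powers=DEFAULT_POWERS,
) -> tuple[float, pd.DataFrame]:
    """Select the IDW power minimising leave-one-out RMSE.

    Ties (within floating-point equality) break toward the smallest power.
    Returns the winning power and the full candidate/RMSE table.
    """
    candidates = sorted(float(p) for p in candidate_powers)
    if not candidates:
        raise ValueError("need at least one candidate power")
    if any(p <= 0 for p in candidates):
        raise ValueError("candidate powers must be positive")
    xy = observations[["x", "y"]].to_numpy(dtype=float)
    vals = observations["value"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {"power": candidates, "loo_rmse": [loo_rmse(xy, vals, p) for p in candidates]}
    )
    best = table.loc[table["loo_rmse"].idxmin(), "power"]  # idxmin takes first = smallest power
    return float(best), table


def aggregate_weekly(
    daily_means: pd.DataFrame,
    calendar: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate daily national (spatial-mean) values to epi-week means.

    Parameters
    ----------
    daily_means : DataFrame with columns ``date`` (datetime.date) and one or
        more value columns (e.g. the raster spatial means per variable).
    calendar : optional epi-week calendar restricting/ordering the output;
        every day of every epi-week covered must be present.

    Raises
    ------
    ValueError naming the missing dates if an epi-week is incomplete.
    """
    df = daily_means.copy()
    ew = [date_to_epiweek(d) for d in df["date"]]
    df["year"] = [y for y, _ in ew]
    df["epiweek"] = [w for _, w in ew]
    value_cols = [c for c in df.columns if c not in ("date", "year", "epiweek")]
    groups = df.groupby(["year", "epiweek"])
    counts = groups["date"].size()
    incomplete = counts[counts != 7]
    if len(incomplete):
        missing = []
        for (y, w), _ in incomplete.items():
            have = set(df.loc[(df["year"] == y) & (df["epiweek"] == w), "date"])
            from .features import _epi_year_start
            import datetime as _dt

            start = _epi_year_start(y) + _dt.timedelta(days=7 * (w - 1))
            want = {start + _dt.timedelta(days=i) for i in range(7)}
            missing += sorted(want - have)
        raise ValueError(
            "incomplete epi-weeks; missing dates: "
            + ", ".join(d.isoformat() for d in missing)
        )
    weekly = groups[value_cols].mean().reset_index()
    if calendar is not None:
        weekly = calendar.merge(weekly, on=["year", "epiweek"], how="inner")
    return weekly
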