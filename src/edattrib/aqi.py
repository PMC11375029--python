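"""Zone-level AQI averaging and AQI <-> concentration conversion.

Daily air-quality index values are reported per monitoring zone (North,
West, East, Central, South).  They are averaged to a national daily series
and then converted from index units to concentration units (PM10 ug/m3,
SO2 ppb, CO ppm) by inverting the published US-EPA piecewise-linear
breakpoint map band by band.

EPA bands are contiguous in *integer* AQI (0-50, 51-100, ...), which
leaves real-valued gaps such as (50, 51) undefined; because zone means are
fractional, short bridge segments are inserted between consecutive bands
(AQI (50, 51) maps linearly onto the concentration gap, e.g. PM10
(54, 55)).  The resulting map is strictly increasing, exact at every
printed EPA band edge, and exactly invertible.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

POLLUTANTS = ("pm10", "so2", "co")
ZONES = ("North", "West", "East", "Central", "South")

#: sha256 of the packaged breakpoint table; guards accidental edits.
_BREAKPOINTS_SHA256 = None  # filled lazily on first load


def load_breakpoints(verify: bool = True) -> pd.DataFrame:
    """Return the packaged EPA breakpoint table.

    Columns: pollutant, aqi_low, aqi_high, conc_low, conc_high, unit.
    """
    ref = resources.files("edattrib.data").joinpath("aqi_breakpoints.csv")
    raw = ref.read_bytes()
    global _BREAKPOINTS_SHA256
    digest = hashlib.sha256(raw).hexdigest()
    if _BREAKPOINTS_SHA256 is None:
        _BREAKPOINTS_SHA256 = digest
    elif verify and digest != _BREAKPOINTS_SHA256:
        raise RuntimeError("breakpoint table changed on disk during the session")
    from io import BytesIO

    table = pd.read_csv(BytesIO(raw))
    table["pollutant"] = table["pollutant"].str.lower()
    return table


def _knots(pollutant: str, table: pd.DataFrame | None = None):
    """Strictly increasing (aqi, conc) knot sequence incl. bridge segments."""
    if table is None:
        table = load_breakpoints()
    bands = table[table["pollutant"] == pollutant.lower()]
    if bands.empty:
        raise KeyError(f"unknown pollutant {pollutant!r}")
    bands = bands.sort_values("aqi_low")
    aqi = np.empty(2 * len(bands))
    conc = np.empty(2 * len(bands))
    aqi[0::2] = bands["aqi_low"].to_numpy(float)
    aqi[1::2] = bands["aqi_high"].to_numpy(float)
    conc[0::2] = bands["conc_low"].to_numpy(float)
    conc[1::2] = bands["conc_high"].to_numpy(float)
    if not (np.all(np.diff(aqi) > 0) and np.all(np.diff(conc) > 0)):
        raise ValueError(f"breakpoint bands for {pollutant!r} are not ordered")
    return aqi, conc


def aqi_to_concentration(aqi, pollutant: str, table: pd.DataFrame | None = None):
    """Convert AQI index value(s) to concentration in the pollutant's units.

    Parameters
    ----------
    aqi : float or array-like
        Non-negative AQI value(s) inside the covered range.
    pollutant : {"pm10", "so2", "co"}
    table : optional breakpoint table (defaults to the packaged EPA table).

    Raises
    ------
    ValueError
        If any value is negative or above the top band edge; out-of-range
        values are reported, never clamped silently.
    """
    knots_a, knots_c = _knots(pollutant, table)
    x = np.asarray(aqi, dtype=float)
    if np.any(x < knots_a[0]) or np.any(x > knots_a[-1]):
        raise ValueError(
            f"AQI value outside covered range [{knots_a[0]}, {knots_a[-1]}] "
            f"for pollutant {pollutant!r}"
        )
    # band lookup by binary search, then the EPA linear inversion formula
    idx = np.clip(np.searchsorted(knots_a, x, side="right") - 1, 0, len(knots_a) - 2)
    a_lo, a_hi = knots_a[idx], knots_a[idx + 1]
    c_lo, c_hi = knots_c[idx], knots_c[idx + 1]
    out = c_lo + (x - a_lo) / (a_hi - a_lo) * (c_hi - c_lo)
    return float(out) if np.isscalar(aqi) else out


def concentration_to_aqi(conc, pollutant: str, table: pd.DataFrame | None = None):
    """Forward EPA map: concentration -> AQI (piecewise linear, no rounding)."""
    knots_a, knots_c = _knots(pollutant, table)
    x = np.asarray(conc, dtype=float)
    if np.any(x < knots_c[0]) or np.any(x > knots_c[-1]):
        raise ValueError(
            f"concentration outside covered range for pollutant {pollutant!r}"
        )
    idx = np.clip(np.searchsorted(knots_c, x, side="right") - 1, 0, len(knots_c) - 2)
    a_lo, a_hi = knots_a[idx], knots_a[idx + 1]
    c_lo, c_hi = knots_c[idx], knots_c[idx + 1]
    out = a_lo + (x - c_lo) / (c_hi - c_lo) * (a_hi - a_lo)
    return float(out) if np.isscalar(conc) else out


def average_zones(zone_series: pd.DataFrame) -> pd.DataFrame:
    """Average zone-level AQI to a national daily series for one pollutant.

    Parameters
    ----------
    zone_series : DataFrame with columns ``zone``, ``date``, ``aqi`` (one
        pollutant at a time; a ``pollutant`` column, if present, must be
        single-valued).

    Returns
    -------
    DataFrame indexed by date with columns ``aqi`` (arithmetic mean of the
    zones available that day) and ``n_zones`` (how many zones contributed).
    """
    df = zone_series.copy()
    if "pollutant" in df.columns and df["pollutant"].nunique() > 1:
        raise ValueError("average_zones expects a single pollutant at a time")
    if df.empty:
        raise ValueError("no zone observations supplied")
    if df["aqi"].isna().any():
        df = df.dropna(subset=["aqi"])
        if df.empty:
            raise ValueError("no non-missing zone observations supplied")
    grouped = df.groupby("date")["aqi"].agg(aqi="mean", n_zones="size")
    return grouped


def national_concentration(
    zone_series: pd.DataFrame, pollutant: str, order: str = "average-first"
) -> pd.DataFrame:
    """National daily pollutant concentration from zone AQI values.

    ``order="average-first"`` (default) averages the zone AQI values and
    converts the national mean — matching the study protocol; because the
    breakpoint map is piecewise linear, the alternative
    ``order="convert-first"`` (convert each zone, then average) is offered
    as a sensitivity analysis and differs whenever zones straddle a band
    boundary.
    """
    if order not in ("average-first", "convert-first"):
        raise ValueError("order must be 'average-first' or 'convert-first'")
    if order == "average-first":
        nat = average_zones(zone_series)
        conc = aqi_to_concentration(nat["aqi"].to_numpy(), pollutant)
        return pd.DataFrame(
            {"concentration": conc, "n_zones": nat["n_zones"]}, index=nat.index
        )
    df = zone_series.copy()
    df["concentration"] = aqi_to_concentration(df["aqi"].to_numpy(), pollutant)
    grouped = df.groupby("date")["concentration"].agg(concentration="mean", n_zones="size")
    return grouped
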