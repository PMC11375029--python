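"""Synthetic study data with known ground truth.

The admissions data behind the original analysis is restricted, so every
downstream stage is exercised on simulated data whose generative process
has exactly the form of the fitted model: weekly counts with a log-link
mean built from an intercept, lagged smooth exposure effects, lagged
autoregressive terms and weekly/annual seasonal terms.  The exposure
marginals (mean, sd, range, units) are calibrated to the published weekly
summary statistics of the Singapore 2014-2018 study period, and the
horizon defaults to the 261 epi-weeks of that period.

Because the truth is known, closed-form oracles for the incidence rate
ratio and the population attributable fraction are available for recovery
testing: under the log link, IRR(x) = exp(f(x) - f(x_mean)) and the
per-week PAF from removing one smooth with contribution c_t is
(1 - exp(-c_t)) * 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .features import EXPOSURES, epiweek_calendar

# ---------------------------------------------------------------------------
# exposure configuration (defaults = published weekly summary statistics)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal of one weekly exposure series."""

    mean: float
    sd: float
    min: float
    max: float
    unit: str = ""

    def __post_init__(self):
        if not self.min < self.max:
            raise ValueError("marginal requires min < max")
        if self.sd < 0:
            raise ValueError("marginal requires sd >= 0")


@dataclass(frozen=True)
class SpikeSpec:
    """Bernoulli spike process emulating transboundary-haze pollutant surges."""

    prob: float = 0.02  # per-week probability
    mult_lo: float = 2.0
    mult_hi: float = 4.0


#: weekly exposure marginals of the study period (Table-2-calibrated defaults)
DEFAULT_MARGINALS: dict[str, MarginalSpec] = {
    "rain_mm": MarginalSpec(6.04, 4.52, 0.0, 21.72, "mm"),
    "temp_c": MarginalSpec(28.01, 0.86, 25.01, 29.99, "degC"),
    "wind_kmh": MarginalSpec(8.24, 1.81, 5.43, 15.24, "km/hr"),
    "pm10_ugm3": MarginalSpec(29.06, 12.37, 16.03, 117.01, "ug/m3"),
    "so2_ppb": MarginalSpec(3.81, 1.83, 0.78, 8.57, "ppb"),
    "co_ppm": MarginalSpec(0.36, 0.11, 0.19, 1.10, "ppm"),
}


@dataclass(frozen=True)
class ExposureConfig:
    """Configuration of the weekly exposure generator.

    Each exposure is a truncated AR(1) Gaussian whose latent parameters are
    moment-matched so the *observed* (truncated, spiked) marginal hits the
    configured mean/sd; PM10 additionally carries a haze spike process.
    """

    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    autocorrelation: float = 0.5
    spikes: dict = field(default_factory=lambda: {"pm10_ugm3": SpikeSpec()})
    cross_correlation: float = 0.0  # shared-innovation mixing in [0, 1)

    def __post_init__(self):
        if not 0.0 <= self.autocorrelation < 1.0:
            raise ValueError("autocorrelation must be in [0, 1)")
        if not 0.0 <= self.cross_correlation < 1.0:
            raise ValueError("cross_correlation must be in [0, 1)")


def _match_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Latent (mu, sigma) whose [lo, hi]-truncated normal has the target moments."""

    def eqs(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(max(v, 1e-300)) - sd]

    sol = optimize.fsolve(eqs, [mean, math.log(sd)], full_output=False, xtol=1e-10)
    return float(sol[0]), float(math.exp(sol[1]))


def _spike_adjusted_target(spec: MarginalSpec, spike: SpikeSpec):
    """Base-process moments so that base + spikes reproduces the target marginal."""
    p = spike.prob
    em = (spike.mult_lo + spike.mult_hi) / 2.0
    em2 = (spike.mult_hi**3 - spike.mult_lo**3) / (3.0 * (spike.mult_hi - spike.mult_lo))
    e_m1_sq = em2 - 2.0 * em + 1.0
    mean_base = spec.mean / (1.0 + p * (em - 1.0))
    var_target = spec.sd**2
    var_base = (var_target - p * e_m1_sq * mean_base**2) / (1.0 + p * e_m1_sq)
    var_base = max(var_base, (0.2 * spec.sd) ** 2)
    return mean_base, math.sqrt(var_base)


def generate_exposures(
    config: ExposureConfig | None = None,
    n_weeks: int = 261,
    seed: int = 0,
    start_year: int = 2014,
) -> pd.DataFrame:
    """Simulate the national weekly exposure table.

    Returns a DataFrame with ``week_index``, ``year``, ``epiweek`` and the
    six exposure columns, all values inside their configured ranges.
    """
    if n_weeks < 8:
        raise ValueError("n_weeks must be >= 8 (a few rows beyond the maximum lag)")
    config = config or ExposureConfig()
    rho = config.autocorrelation
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(EXPOSURES) + 1)
    rng_common = np.random.default_rng(children[-1])
    eps_common = rng_common.standard_normal(n_weeks + 1)

    cols: dict[str, np.ndarray] = {}
    for name, child in zip(EXPOSURES, children[:-1]):
        spec = config.marginals[name]
        rng = np.random.default_rng(child)
        if spec.sd == 0.0:
            cols[name] = np.full(n_weeks, spec.mean)
            continue
        spike = config.spikes.get(name)
        if spike is not None and spike.prob > 0:
            mean_b, sd_b = _spike_adjusted_target(spec, spike)
        else:
            mean_b, sd_b = spec.mean, spec.sd
        mu, sigma = _match_truncnorm(mean_b, sd_b, spec.min, spec.max)
        c = config.cross_correlation
        innov_sd = sigma * math.sqrt(1.0 - rho**2)

        x = np.empty(n_weeks)
        # stationary start by rejection from the latent marginal
        val = mu + sigma * rng.standard_normal()
        tries = 0
        while not (spec.min <= val <= spec.max):
            val = mu + sigma * rng.standard_normal()
            tries += 1
            if tries > 10000:
                raise RuntimeError("truncation rejection failed; check marginal spec")
        for t in range(n_weeks):
            if t > 0:
                # rejection: redraw the own innovation until inside range
                for _ in range(10000):
                    eps = math.sqrt(1 - c) * rng.standard_normal() + math.sqrt(c) * eps_common[t]
                    cand = mu + rho * (val - mu) + innov_sd * eps
                    if spec.min <= cand <= spec.max:
                        val = cand
                        break
                else:
                    val = float(np.clip(mu + rho * (val - mu), spec.min, spec.max))
            x[t] = val
        if spike is not None and spike.prob > 0:
            hit = rng.random(n_weeks) < spike.prob
            mult = rng.uniform(spike.mult_lo, spike.mult_hi, size=n_weeks)
            x = np.where(hit, np.clip(x * mult, spec.min, spec.max), x)
        cols[name] = x

    need_years = int(np.ceil(n_weeks / 52.0)) + 1
    cal = epiweek_calendar(start_year, start_year + need_years)
    cal = cal.iloc[:n_weeks].reset_index(drop=True)
    out = pd.DataFrame({"week_index": np.arange(n_weeks)})
    out["year"] = cal["year"].to_numpy()
    out["epiweek"] = cal["epiweek"].to_numpy()
    for name in EXPOSURES:
        out[name] = cols[name]
    return out


# ---------------------------------------------------------------------------
# station-level daily weather with a known spatial surface
# ---------------------------------------------------------------------------


def generate_station_daily(
    config: ExposureConfig | None = None,
    n_stations: int = 21,
    n_days: int = 7,
    seed: int = 0,
    variable: str = "temp_c",
    domain_km: float = 50.0,
    noise_sd: float = 0.1,
    n_bumps: int = 4,
):
    """Simulate daily station records over a planar domain.

    The daily field is a smooth surface (base level + Gaussian bumps with
    daily-varying amplitudes); station observations add i.i.d. noise.  The
    true surface is returned as a callable ``surface(x, y, day_index)`` so
    interpolation error is measurable against ground truth.

    Returns (records DataFrame with station_id, x, y, date, variable,
    value; surface callable; stations DataFrame with station_id, x, y).
    """
    if n_stations < 2:
        raise ValueError("need at least 2 stations (leave-one-out is undefined below 3)")
    if n_days < 1:
        raise ValueError("n_days must be positive")
    config = config or ExposureConfig()
    spec = config.marginals[variable]
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, domain_km, size=(n_stations, 2))
    centers = rng.uniform(0.0, domain_km, size=(n_bumps, 2))
    widths = rng.uniform(0.2 * domain_km, 0.5 * domain_km, size=n_bumps)
    amps = rng.normal(0.0, spec.sd if spec.sd > 0 else 1.0, size=(n_days, n_bumps))

    def surface(x, y, day):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.full(np.broadcast(x, y).shape, float(spec.mean))
        for b in range(n_bumps):
            d2 = (x - centers[b, 0]) ** 2 + (y - centers[b, 1]) ** 2
            z = z + amps[day, b] * np.exp(-0.5 * d2 / widths[b] ** 2)
        return z

    import datetime as _dt

    day0 = _dt.date(2014, 1, 5)
    rows = []
    for day in range(n_days):
        truth = surface(xy[:, 0], xy[:, 1], day)
        obs = truth + noise_sd * rng.standard_normal(n_stations)
        date = day0 + _dt.timedelta(days=day)
        for s in range(n_stations):
            rows.append(
                {
                    "station_id": f"S{s:02d}",
                    "x": xy[s, 0],
                    "y": xy[s, 1],
                    "date": date,
                    "variable": variable,
                    "value": obs[s],
                }
            )
    stations = pd.DataFrame({"station_id": [f"S{s:02d}" for s in range(n_stations)],
                             "x": xy[:, 0], "y": xy[:, 1]})
    return pd.DataFrame(rows), surface, stations


# ---------------------------------------------------------------------------
# truth model for admissions
# ---------------------------------------------------------------------------

#: weekly-count baselines per admission category (published means)
CATEGORY_BASELINES: dict[str, float] = {
    "Cardiovascular disease": 873.57,
    "Chronic respiratory disease": 598.93,
    "Diabetes mellitus": 66.33,
    "Digestive disease": 1161.74,
    "Endocrine disorders": 323.30,
    "Genitourinary disorders": 695.89,
    "Infectious and parasitic disease": 1362.46,
    "Musculoskeletal disease": 1211.36,
    "Neurological and sense disorders": 800.29,
    "Oral diseases": 65.76,
    "Respiratory infection": 2276.84,
    "Skin diseases": 739.26,
}

CATEGORIES = tuple(CATEGORY_BASELINES)


def _shape_fn(shape: dict):
    kind = shape["shape"]
    if kind == "linear":
        return lambda x: shape["slope"] * np.asarray(x, dtype=float)
    if kind == "hockey":
        thr, slope = shape["threshold"], shape["slope"]
        return lambda x: slope * np.maximum(np.asarray(x, dtype=float) - thr, 0.0)
    if kind == "inverted_u":
        c, w, h = shape["center"], shape["width"], shape["height"]
        return lambda x: h * np.exp(-0.5 * ((np.asarray(x, dtype=float) - c) / w) ** 2)
    if kind == "zero":
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    raise ValueError(f"unknown smooth shape {kind!r}")


@dataclass
class TruthModel:
    """Known generative model for one admission category.

    ``smooth_shapes`` maps (exposure, lag) to a declarative shape dict
    (serializable); the callables are built on demand and centered so the
    contribution at the exposure's configured mean is exactly zero, making
    the intercept the log baseline rate and the IRR/PAF oracles closed
    form.  Autoregressive feedback enters linearly through the relative
    deviation of the lagged count from the stationary mean.
    """

    category: str
    intercept: float  # log scale
    smooth_shapes: dict = field(default_factory=dict)  # (exposure, lag) -> shape dict
    ar_coefs: tuple = (0.0, 0.0, 0.0)
    week_amplitude: float = 0.0
    year_slope: float = 0.0
    family: str = "poisson"
    theta: float = 10.0
    exposure_means: dict = field(
        default_factory=lambda: {k: v.mean for k, v in DEFAULT_MARGINALS.items()}
    )

    def __post_init__(self):
        if self.family not in ("poisson", "negbin"):
            raise ValueError("truth family must be poisson or negbin")
        if self.family == "negbin" and self.theta <= 0:
            raise ValueError("negbin dispersion theta must be positive")

    @property
    def max_lag(self) -> int:
        lags = [lag for (_, lag) in self.smooth_shapes] + [
            i + 1 for i, a in enumerate(self.ar_coefs) if a != 0.0
        ]
        return max(lags, default=1)

    def smooth(self, exposure: str, lag: int):
        """Centered truth smooth f for (exposure, lag); zero at the exposure mean."""
        shape = self.smooth_shapes.get((exposure, lag))
        if shape is None:
            return lambda x: np.zeros_like(np.asarray(x, dtype=float))
        g = _shape_fn(shape)
        center = g(self.exposure_means[exposure])
        return lambda x: g(x) - center

    def s_week(self, week):
        w = np.asarray(week, dtype=float)
        return self.week_amplitude * np.sin(2.0 * np.pi * (w - 1.0) / 52.0)

    def s_year(self, year):
        y = np.asarray(year, dtype=float)
        return self.year_slope * (y - 2016.0)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "intercept": self.intercept,
            "smooths": [
                {"exposure": e, "lag": lag, **shape}
                for (e, lag), shape in self.smooth_shapes.items()
            ],
            "ar_coefs": list(self.ar_coefs),
            "week_amplitude": self.week_amplitude,
            "year_slope": self.year_slope,
            "family": self.family,
            "theta": self.theta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthModel":
        shapes = {}
        for s in d.get("smooths", []):
            s = dict(s)
            e, lag = s.pop("exposure"), s.pop("lag")
            shapes[(e, lag)] = s
        return cls(
            category=d["category"],
            intercept=d["intercept"],
            smooth_shapes=shapes,
            ar_coefs=tuple(d.get("ar_coefs", (0.0, 0.0, 0.0))),
            week_amplitude=d.get("week_amplitude", 0.0),
            year_slope=d.get("year_slope", 0.0),
            family=d.get("family", "poisson"),
            theta=d.get("theta", 10.0),
        )


def generate_admissions(
    exposures: pd.DataFrame, truth: TruthModel, seed: int = 0
) -> pd.DataFrame:
    """Draw a weekly admission count series from a known truth model.

    The first max-lag weeks are seeded at the stationary baseline count;
    subsequent weeks draw from the configured family with the log-link
    mean assembled from the truth's intercept, lagged smooths, AR feedback
    and seasonal terms.
    """
    n = len(exposures)
    max_lag = truth.max_lag
    if n < max_lag + 1:
        raise ValueError("exposure horizon must exceed the truth's maximum lag")
    rng = np.random.default_rng(seed)
    base = math.exp(truth.intercept)
    smooths = {
        (e, lag): truth.smooth(e, lag) for (e, lag) in truth.smooth_shapes
    }
    for (e, lag), f in smooths.items():
        vals = exposures[e].to_numpy(dtype=float)
        if not np.all(np.isfinite(f(vals))):
            raise ValueError(f"truth smooth for ({e}, lag {lag}) undefined on generated values")

    weeks = exposures["epiweek"].to_numpy(dtype=float)
    years = exposures["year"].to_numpy(dtype=float)
    y = np.empty(n, dtype=int)
    y[:max_lag] = int(round(base))
    for t in range(max_lag, n):
        eta = truth.intercept
        for i, a in enumerate(truth.ar_coefs):
            lag = i + 1
            if a != 0.0 and t - lag >= 0:
                eta += a * (y[t - lag] - base) / base
        for (e, lag), f in smooths.items():
            eta += float(f(exposures[e].iloc[t - lag]))
        eta += float(truth.s_week(weeks[t])) + float(truth.s_year(years[t]))
        mu = math.exp(eta)
        if truth.family == "poisson":
            y[t] = rng.poisson(mu)
        else:
            # NB as Poisson-gamma mixture with size theta
            lam = rng.gamma(truth.theta, mu / truth.theta)
            y[t] = rng.poisson(lam)
    return pd.DataFrame(
        {
            "week_index": exposures["week_index"].to_numpy(),
            "category": truth.category,
            "count": y,
        }
    )


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------


def oracle_irr(truth: TruthModel, exposure: str, lag: int, grid) -> np.ndarray:
    """True incidence rate ratio exp(f(x) - f(x_mean)) on a value grid."""
    f = truth.smooth(exposure, lag)
    g = np.asarray(grid, dtype=float)
    return np.exp(f(g))  # f is centered: f(x_mean) = 0


def oracle_paf(
    truth: TruthModel, exposures: pd.DataFrame, exposure: str, lag: int
) -> pd.Series:
    """True per-week PAF (%) from removing one smooth's contribution.

    PAF_t = (mu_t - mu_t^(-i)) / mu_t * 100 = (1 - exp(-f(X_{t-lag}))) * 100,
    defined for weeks t >= lag.
    """
    f = truth.smooth(exposure, lag)
    x = exposures[exposure].to_numpy(dtype=float)
    idx = exposures["week_index"].to_numpy()
    contrib = f(x[:-lag] if lag > 0 else x)
    weeks = idx[lag:] if lag > 0 else idx
    return pd.Series((1.0 - np.exp(-contrib)) * 100.0, index=weeks, name="paf_pct")


# ---------------------------------------------------------------------------
# default truths and full bundles
# ---------------------------------------------------------------------------

#: qualitative lagged effects per category, echoing the study's curve types
_DEFAULT_EFFECTS: dict[str, list] = {
    "Respiratory infection": [
        ("rain_mm", 1, {"shape": "hockey", "threshold": 13.0, "slope": 0.010}),
        ("wind_kmh", 1, {"shape": "hockey", "threshold": 12.0, "slope": 0.035}),
        ("co_ppm", 1, {"shape": "hockey", "threshold": 0.6, "slope": 1.2}),
        ("pm10_ugm3", 1, {"shape": "hockey", "threshold": 60.0, "slope": 0.003}),
    ],
    "Infectious and parasitic disease": [
        ("rain_mm", 1, {"shape": "hockey", "threshold": 13.0, "slope": 0.012}),
        ("temp_c", 3, {"shape": "inverted_u", "center": 29.0, "width": 1.0, "height": 0.04}),
    ],
    "Cardiovascular disease": [
        ("pm10_ugm3", 3, {"shape": "hockey", "threshold": 43.0, "slope": 0.002}),
        ("co_ppm", 2, {"shape": "hockey", "threshold": 0.65, "slope": 0.35}),
        ("temp_c", 3, {"shape": "inverted_u", "center": 26.5, "width": 1.0, "height": 0.03}),
    ],
    "Chronic respiratory disease": [
        ("so2_ppb", 2, {"shape": "hockey", "threshold": 6.0, "slope": 0.03}),
        ("rain_mm", 1, {"shape": "linear", "slope": -0.004}),
    ],
    "Diabetes mellitus": [
        ("so2_ppb", 2, {"shape": "linear", "slope": -0.02}),
        ("co_ppm", 2, {"shape": "hockey", "threshold": 0.6, "slope": 0.5}),
    ],
    "Digestive disease": [
        ("temp_c", 1, {"shape": "hockey", "threshold": 28.0, "slope": 0.04}),
        ("pm10_ugm3", 3, {"shape": "hockey", "threshold": 60.0, "slope": 0.004}),
    ],
    "Endocrine disorders": [
        ("temp_c", 1, {"shape": "linear", "slope": -0.03}),
        ("pm10_ugm3", 3, {"shape": "hockey", "threshold": 60.0, "slope": 0.003}),
    ],
    "Genitourinary disorders": [
        ("temp_c", 1, {"shape": "hockey", "threshold": 28.0, "slope": 0.03}),
        ("wind_kmh", 1, {"shape": "linear", "slope": -0.01}),
    ],
    "Musculoskeletal disease": [
        ("rain_mm", 2, {"shape": "hockey", "threshold": 13.0, "slope": 0.008}),
        ("pm10_ugm3", 3, {"shape": "hockey", "threshold": 50.0, "slope": 0.002}),
    ],
    "Neurological and sense disorders": [
        ("temp_c", 2, {"shape": "hockey", "threshold": 27.0, "slope": -0.03}),
        ("wind_kmh", 1, {"shape": "linear", "slope": -0.008}),
    ],
    "Oral diseases": [
        ("wind_kmh", 1, {"shape": "hockey", "threshold": 12.0, "slope": 0.12}),
    ],
    "Skin diseases": [
        ("temp_c", 2, {"shape": "hockey", "threshold": 27.0, "slope": -0.04}),
        ("rain_mm", 1, {"shape": "linear", "slope": -0.005}),
    ],
}


def default_truth(category: str, family: str = "poisson") -> TruthModel:
    """Study-flavoured truth model for one admission category."""
    if category not in CATEGORY_BASELINES:
        raise KeyError(f"unknown admission category {category!r}")
    shapes = {(e, lag): dict(shape) for e, lag, shape in _DEFAULT_EFFECTS.get(category, [])}
    return TruthModel(
        category=category,
        intercept=math.log(CATEGORY_BASELINES[category]),
        smooth_shapes=shapes,
        ar_coefs=(0.3, 0.15, 0.05),
        week_amplitude=0.03,
        year_slope=0.01,
        family=family,
    )


@dataclass
class SyntheticDataset:
    """One complete synthetic study bundle."""

    exposures: pd.DataFrame
    admissions: pd.DataFrame  # long: week_index, category, count
    truths: dict  # category -> TruthModel
    seed: int

    def admissions_for(self, category: str) -> pd.DataFrame:
        out = self.admissions[self.admissions["category"] == category]
        if out.empty:
            raise KeyError(f"no admissions for category {category!r}")
        return out.reset_index(drop=True)


def generate_bundle(
    n_weeks: int = 261,
    seed: int = 0,
    categories=CATEGORIES,
    config: ExposureConfig | None = None,
    family: str = "poisson",
) -> SyntheticDataset:
    """Generate the full synthetic study: exposures + all category series."""
    ss = np.random.SeedSequence(seed)
    exp_seed, *cat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(categories) + 1)]
    exposures = generate_exposures(config, n_weeks=n_weeks, seed=exp_seed)
    truths = {}
    frames = []
    for cat, cseed in zip(categories, cat_seeds):
        truth = default_truth(cat, family=family)
        truths[cat] = truth
        frames.append(generate_admissions(exposures, truth, seed=cseed))
    admissions = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["week_index", "category", "count"])
    )
    return SyntheticDataset(exposures=exposures, admissions=admissions, truths=truths, seed=seed)


def save_bundle(dataset: SyntheticDataset, outdir) -> None:
    """Write exposures.csv, admissions.csv and truth.yaml into `outdir`."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.exposures.to_csv(out / "exposures.csv", index=False)
    dataset.admissions.to_csv(out / "admissions.csv", index=False)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {"seed": dataset.seed, "truths": [t.to_dict() for t in dataset.truths.values()]},
            fh,
            sort_keys=False,
        )


def load_bundle(indir) -> SyntheticDataset:
    import pathlib

    import yaml

    indir = pathlib.Path(indir)
    exposures = pd.read_csv(indir / "exposures.csv")
    admissions = pd.read_csv(indir / "admissions.csv")
    with open(indir / "truth.yaml") as fh:
        meta = yaml.safe_load(fh)
    truths = {d["category"]: TruthModel.from_dict(d) for d in meta["truths"]}
    return SyntheticDataset(exposures, admissions, truths, seed=meta["seed"])
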