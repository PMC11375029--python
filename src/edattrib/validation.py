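"""Simulation-based validation suites run against known ground truth.

Each function here simulates data from a truth model of the same form the
engine fits, runs the relevant part of the pipeline, and returns a
measurable recovery/calibration quantity.  They are shared by the test
suite and the reproduction script so the numbers reported are always
recomputed from scratch.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import effects
from .attribution import paf_series
from .basis import SmoothSpec
from .features import build_lag_design
from .gam import CountGAM, default_terms
from .synthetic import TruthModel, generate_admissions, generate_exposures, oracle_paf


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def single_effect_truth(
    exposure: str = "pm10_ugm3",
    lag: int = 1,
    baseline: float = 200.0,
    threshold: float = 40.0,
    slope: float = 0.005,
    family: str = "poisson",
    theta: float = 2.0,
) -> TruthModel:
    """Truth with one hockey-stick exposure effect and nothing else."""
    return TruthModel(
        category="synthetic-single-effect",
        intercept=math.log(baseline),
        smooth_shapes={(exposure, lag): {"shape": "hockey", "threshold": threshold, "slope": slope}},
        ar_coefs=(0.0, 0.0, 0.0),
        family=family,
        theta=theta,
    )


def _fit_single_effect(seed: int, truth: TruthModel, exposure: str, lag: int, n_weeks: int = 261):
    s_exp, s_adm = _child_seeds(seed, 2)
    exposures = generate_exposures(n_weeks=n_weeks, seed=s_exp)
    adm = generate_admissions(exposures, truth, seed=s_adm)
    design = build_lag_design(adm, exposures, max_lag=lag)
    col = design.exposure_column(exposure, lag)
    model = CountGAM(terms=[SmoothSpec(col, k=8)], family="poisson").fit(design)
    return exposures, design, model


def smooth_recovery_trial(
    seed: int, exposure: str = "pm10_ugm3", lag: int = 1, n_grid: int = 50
) -> float:
    """Fraction of grid points where the true IRR lies inside the fitted 95% band.

    One hockey-stick exposure effect, 261 weeks of Poisson counts; the
    model fits a single rank-8 smooth of the lagged exposure.
    """
    truth = single_effect_truth(exposure=exposure, lag=lag)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exposures, design, model = _fit_single_effect(seed, truth, exposure, lag)
        col = design.exposure_column(exposure, lag)
        x = design.frame[col].to_numpy()
        grid = np.quantile(x, np.linspace(0.0, 1.0, n_grid))
        curve = effects.irr_curve_at(model, design, exposure, lag, grid)
    # oracle reference is the training-sample mean, matching the fitted curve
    f = truth.smooth(exposure, lag)
    true_irr = np.exp(f(grid) - f(curve.reference))
    return float(np.mean((true_irr >= curve.lo) & (true_irr <= curve.hi)))


def smooth_recovery_rate(n_seeds: int = 50, seed: int = 0, min_cover: float = 0.9) -> float:
    """Share of seeds whose IRR curve covers the truth at >= `min_cover` of points."""
    hits = [smooth_recovery_trial(s) >= min_cover for s in _child_seeds(seed, n_seeds)]
    return float(np.mean(hits))


def paf_recovery_trial(seed: int, exposure: str = "pm10_ugm3", lag: int = 1) -> tuple[float, float]:
    """(fitted, oracle) mean PAF over weeks with the exposure above its 90th pctile."""
    truth = single_effect_truth(exposure=exposure, lag=lag)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exposures, design, model = _fit_single_effect(seed, truth, exposure, lag)
        ps = paf_series(model, design, exposure, lag, mode="drop-term")
    col = design.exposure_column(exposure, lag)
    x = design.frame[col]
    hi_weeks = x.index[x >= x.quantile(0.9)]
    fitted = ps.frame.set_index("week_index").loc[hi_weeks, "paf_pct"].mean()
    oracle = oracle_paf(truth, exposures, exposure, lag).loc[hi_weeks].mean()
    return float(fitted), float(oracle)


def paf_recovery_rate(n_seeds: int = 50, seed: int = 0, tol_pp: float = 5.0) -> float:
    """Share of seeds with |fitted - oracle| mean high-exposure PAF below `tol_pp`."""
    hits = []
    for s in _child_seeds(seed, n_seeds):
        fitted, oracle = paf_recovery_trial(s)
        hits.append(abs(fitted - oracle) <= tol_pp)
    return float(np.mean(hits))


def dispersion_trial(seed: int, family: str = "poisson", theta: float = 2.0) -> float:
    """Pearson dispersion of a Poisson fit on Poisson or NB(theta) data."""
    truth = single_effect_truth(family=family, theta=theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, model = _fit_single_effect(seed, truth, "pm10_ugm3", 1)
    return model.dispersion_


def dispersion_rates(n_seeds: int = 100, seed: int = 0) -> dict:
    """Calibration of the overdispersion diagnostic under both truths."""
    seeds = _child_seeds(seed, 2 * n_seeds)
    pois = [dispersion_trial(s, "poisson") for s in seeds[:n_seeds]]
    nb = [dispersion_trial(s, "negbin", theta=2.0) for s in seeds[n_seeds:]]
    return {
        "poisson_in_band": float(np.mean([(0.7 <= d <= 1.3) for d in pois])),
        "negbin_flagged": float(np.mean([d > 1.5 for d in nb])),
    }


def selection_trial(seed: int, n_weeks: int = 261) -> int:
    """Winning max-lag (by AIC over Poisson lag-1/2/3 candidates) on 3-lag truth."""
    truth = TruthModel(
        category="synthetic-3lag",
        intercept=math.log(400.0),
        smooth_shapes={
            ("pm10_ugm3", 3): {"shape": "hockey", "threshold": 40.0, "slope": 0.006},
            ("temp_c", 3): {"shape": "linear", "slope": 0.08},
            ("rain_mm", 1): {"shape": "linear", "slope": -0.01},
        },
        ar_coefs=(0.2, 0.0, 0.0),
        week_amplitude=0.03,
    )
    s_exp, s_adm = _child_seeds(seed, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exposures = generate_exposures(n_weeks=n_weeks, seed=s_exp)
        adm = generate_admissions(exposures, truth, seed=s_adm)
        best_aic, best_lag = np.inf, None
        for max_lag in (1, 2, 3):
            design = build_lag_design(adm, exposures, max_lag=max_lag)
            model = CountGAM(terms=default_terms(design), family="poisson").fit(design)
            if model.aic_ < best_aic:
                best_aic, best_lag = model.aic_, max_lag
    return best_lag


def selection_rate(n_seeds: int = 50, seed: int = 0) -> float:
    """Share of seeds where the true 3-lag Poisson candidate wins by AIC."""
    wins = [selection_trial(s) == 3 for s in _child_seeds(seed, n_seeds)]
    return float(np.mean(wins))


def random_fitted_model(seed: int, n_weeks: int = 80):
    """A small fitted model on randomized single-effect data (for identities)."""
    rng = np.random.default_rng(seed)
    exposure = str(rng.choice(["rain_mm", "temp_c", "wind_kmh", "pm10_ugm3", "so2_ppb", "co_ppm"]))
    lag = int(rng.integers(1, 4))
    shapes = ["linear", "hockey", "inverted_u", "zero"]
    kind = str(rng.choice(shapes))
    from .synthetic import DEFAULT_MARGINALS

    ms = DEFAULT_MARGINALS[exposure]
    if kind == "linear":
        shape = {"shape": "linear", "slope": float(rng.normal(0, 0.5)) / ms.sd / 4}
    elif kind == "hockey":
        shape = {
            "shape": "hockey",
            "threshold": float(rng.uniform(ms.mean, ms.mean + ms.sd)),
            "slope": float(rng.uniform(0, 0.5)) / ms.sd,
        }
    elif kind == "inverted_u":
        shape = {
            "shape": "inverted_u",
            "center": float(rng.uniform(ms.mean - ms.sd, ms.mean + ms.sd)),
            "width": float(ms.sd),
            "height": float(rng.uniform(-0.3, 0.3)),
        }
    else:
        shape = {"shape": "zero"}
    truth = TruthModel(
        category="synthetic-random",
        intercept=float(rng.uniform(np.log(50), np.log(1000))),
        smooth_shapes={(exposure, lag): shape},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exposures, design, model = _fit_single_effect(seed, truth, exposure, lag, n_weeks=n_weeks)
    return model, design, exposure, lag


def irr_identity_check(seed: int) -> dict:
    """Reference identity + dual-route agreement on one randomized model."""
    model, design, exposure, lag = random_fitted_model(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = effects.irr_curve(model, design, exposure, lag, n_grid=25)
        alt = effects.irr_from_smooth(model, design, exposure, lag, curve.grid)
        # third, fully independent route: explicit ratio of predictions
        col = design.exposure_column(exposure, lag)
        rows, ref = effects._reference_rows(model, design, col, curve.grid)
        pred_ratio = model.predict(rows) / model.predict(ref)[0]
    at_ref = curve.grid == curve.reference
    return {
        "irr_at_ref": float(curve.irr[at_ref][0]),
        "lo_at_ref": float(curve.lo[at_ref][0]),
        "hi_at_ref": float(curve.hi[at_ref][0]),
        "dual_route_max_diff": float(
            max(np.max(np.abs(curve.irr - alt)), np.max(np.abs(curve.irr - pred_ratio)))
        ),
    }
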