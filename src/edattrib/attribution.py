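"""Population attributable fractions by counterfactual exposure removal.

For one exposure-lag term the procedure is: (1) remove the exposure from
the population, (2) predict the expected admissions under that removal
with the already-fitted model, (3) per week,

    PAF_t = (observed_t - expected_t) / observed_t * 100.

Removal has two modes.  ``drop-term`` (default) subtracts the fitted
smooth's contribution from the linear predictor — the removal of the
smooth function that setting the exposure to zero is intended to achieve.
``set-zero`` literally zeroes the exposure column, which for every
exposure here (e.g. temperature, minimum 25 degC) forces the spline far
outside its training range and is retained only as the literal
sensitivity mode, with extrapolation warnings.

A negative PAF means the exposure was protective that week; PAF is always
< 100% because expected counts are strictly positive under the log link.

The weekly PAF points are summarised as a smoothed trend against the
lagged exposure value: local-linear regression with tricube weights
(default span 0.75) and a pointwise variance band from the equivalent
kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .features import LagDesign
from .gam import CountGAM

#: grouping of admission categories by physiological system
CATEGORY_GROUPS: dict[str, str] = {
    "Cardiovascular disease": "Cardiorespiratory system disorders",
    "Chronic respiratory disease": "Cardiorespiratory system disorders",
    "Respiratory infection": "Cardiorespiratory system disorders",
    "Infectious and parasitic disease": "Cardiorespiratory system disorders",
    "Diabetes mellitus": "Metabolic and digestive system disorders",
    "Digestive disease": "Metabolic and digestive system disorders",
    "Endocrine disorders": "Metabolic and digestive system disorders",
    "Genitourinary disorders": "Metabolic and digestive system disorders",
    "Musculoskeletal disease": "Others",
    "Neurological and sense disorders": "Others",
    "Oral diseases": "Others",
    "Skin diseases": "Others",
}

REMOVAL_MODES = ("drop-term", "set-zero")


def group_categories(categories) -> list[str]:
    """Map admission category names to their physiological-system group."""
    out = []
    for c in categories:
        if c not in CATEGORY_GROUPS:
            raise KeyError(f"unknown admission category {c!r}")
        out.append(CATEGORY_GROUPS[c])
    return out


def remove_exposure(design: LagDesign, exposure: str, lag: int) -> LagDesign:
    """Set-zero counterfactual design: the targeted column zeroed everywhere."""
    column = design.exposure_column(exposure, lag)
    frame = design.frame.copy()
    frame[column] = 0.0
    return LagDesign(
        frame=frame,
        max_lag=design.max_lag,
        include_immediate=design.include_immediate,
        exposure_names=design.exposure_names,
        n_total=design.n_total,
        category=design.category,
        column_roles=design.column_roles,
    )


def counterfactual_expected(
    model: CountGAM,
    design: LagDesign,
    exposure: str,
    lag: int,
    mode: str = "drop-term",
) -> np.ndarray:
    """Expected counts with one exposure-lag term removed."""
    if mode not in REMOVAL_MODES:
        raise ValueError(f"unknown removal mode {mode!r}; choose from {REMOVAL_MODES}")
    column = design.exposure_column(exposure, lag)
    if mode == "drop-term":
        eta = model.linear_predictor(design.frame)
        contrib = model.term_contribution(column, design.frame[column].to_numpy(dtype=float))
        return np.exp(eta - contrib)
    return model.predict(remove_exposure(design, exposure, lag).frame)


def paf_from_counts(observed, expected) -> np.ndarray:
    """Attributable fraction in percent: (observed - expected) / observed * 100."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(observed == 0):
        raise ValueError("PAF undefined where the observed count is zero")
    return (observed - expected) / observed * 100.0


@dataclass
class PAFSeries:
    """Per-week attributable fractions for one category / exposure / lag."""

    category: str | None
    exposure: str
    lag: int
    frame: pd.DataFrame  # week_index, observed, expected, paf_pct
    mode: str
    n_zero_excluded: int = 0

    @property
    def paf(self) -> np.ndarray:
        return self.frame["paf_pct"].to_numpy()


def paf_series(
    model: CountGAM,
    design: LagDesign,
    exposure: str,
    lag: int,
    mode: str = "drop-term",
) -> PAFSeries:
    """Weekly PAF series from counterfactual removal of one exposure-lag term.

    Weeks with an observed count of zero (where the fraction is undefined)
    are excluded and counted in ``n_zero_excluded``.
    """
    observed = design.y
    expected = counterfactual_expected(model, design, exposure, lag, mode)
    ok = observed > 0
    paf = paf_from_counts(observed[ok], expected[ok])
    frame = pd.DataFrame(
        {
            "week_index": design.frame.index.to_numpy()[ok],
            "observed": observed[ok],
            "expected": expected[ok],
            "paf_pct": paf,
        }
    )
    return PAFSeries(
        category=design.category,
        exposure=exposure,
        lag=lag,
        frame=frame,
        mode=mode,
        n_zero_excluded=int((~ok).sum()),
    )


# ---------------------------------------------------------------------------
# loess smoothing of PAF against exposure value
# ---------------------------------------------------------------------------


class LoessSmoother(BaseEstimator):
    """Local-linear regression with tricube weights and pointwise bands.

    At each evaluation point the nearest ``span`` fraction of the data gets
    tricube weights and a weighted straight line is fitted; the fitted
    value is linear in y, so its variance follows from the equivalent
    kernel and a residual variance estimated at the data points.
    """

    def __init__(self, span: float = 0.75):
        self.span = span

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if len(x) < 4:
            raise ValueError("need at least 4 points")
        self.x_ = x
        self.y_ = y
        fitted, trace = self._fit_at(x, want_trace=True)
        resid = y - fitted
        dof = max(len(x) - trace, 1.0)
        self.sigma2_ = float(resid @ resid / dof)
        self.fitted_ = fitted
        self.edf_ = trace
        return self

    def _kernel_row(self, g: float) -> np.ndarray:
        """Equivalent-kernel weights l such that yhat(g) = l @ y."""
        x = self.x_
        d = np.abs(x - g)
        k = max(int(np.ceil(self.span * len(x))), 3)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            h = max(d.max(), 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        if w.sum() == 0:
            w = np.ones_like(w)
        X = np.column_stack([np.ones_like(x), x - g])
        XtW = X.T * w
        M = XtW @ X
        M[np.diag_indices_from(M)] += 1e-12
        return np.linalg.solve(M, XtW)[0]

    def _fit_at(self, grid, want_trace: bool = False):
        grid = np.asarray(grid, dtype=float)
        yhat = np.empty(len(grid))
        trace = 0.0
        for i, g in enumerate(grid):
            l = self._kernel_row(g)
            yhat[i] = l @ self.y_
            if want_trace:
                j = np.argmin(np.abs(self.x_ - g))
                trace += l[j] if np.isclose(self.x_[j], g) else 0.0
        return (yhat, trace) if want_trace else yhat

    def predict(self, grid, return_se: bool = False):
        grid = np.asarray(grid, dtype=float)
        yhat = np.empty(len(grid))
        se = np.empty(len(grid))
        for i, g in enumerate(grid):
            l = self._kernel_row(g)
            yhat[i] = l @ self.y_
            se[i] = np.sqrt(self.sigma2_ * (l @ l))
        return (yhat, se) if return_se else yhat


@dataclass
class SmoothedPAFCurve:
    """Smoothed PAF-vs-exposure trend with a pointwise band."""

    category: str | None
    group: str | None
    exposure: str
    lag: int
    grid: np.ndarray
    trend: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "category": self.category,
                "exposure": self.exposure,
                "lag": self.lag,
                "grid_value": self.grid,
                "paf_trend": self.trend,
                "lo": self.lo,
                "hi": self.hi,
            }
        )


def smooth_paf(
    paf: PAFSeries,
    design: LagDesign,
    span: float = 0.75,
    n_grid: int = 100,
    level: float = 0.95,
) -> SmoothedPAFCurve:
    """Smooth the weekly PAF points against the matching lagged exposure value."""
    column = design.exposure_column(paf.exposure, paf.lag)
    x_all = design.frame[column]
    x = x_all.loc[paf.frame["week_index"]].to_numpy(dtype=float)
    y = paf.paf
    if len(x) < 20:
        raise ValueError("need at least 20 (exposure, PAF) pairs to smooth")
    sm = LoessSmoother(span=span).fit(x, y)
    grid = np.linspace(x.min(), x.max(), n_grid)
    trend, se = sm.predict(grid, return_se=True)
    from scipy import stats as _stats

    z = _stats.norm.ppf(0.5 + level / 2.0)
    group = CATEGORY_GROUPS.get(paf.category) if paf.category else None
    return SmoothedPAFCurve(
        category=paf.category,
        group=group,
        exposure=paf.exposure,
        lag=paf.lag,
        grid=grid,
        trend=trend,
        lo=trend - z * se,
        hi=trend + z * se,
    )
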