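"""Penalized-spline additive count regression (the model engine).

The model for weekly counts Y_t is

    log E[Y_t] = beta0 + sum_n f_n(Y_{t-n}) + sum_{i,n} f_{i,n}(X_{i,t-n})
                 + s_week(Week_t) + s_year(Year_t)

with every f a penalized low-rank spline (see :mod:`edattrib.basis`),
fitted by penalized IRLS with smoothing parameters chosen by restricted
maximum likelihood via Fellner–Schall updates.  Three count families are
supported: Poisson, quasi-Poisson (Poisson point estimates with a
Pearson-dispersion-scaled covariance) and negative binomial with the size
parameter theta profiled out.

The estimator follows scikit-learn conventions: constructor parameters
only store configuration, ``fit(X, y)`` does the work, fitted state lives
in trailing-underscore attributes, and the object composes with sklearn
tooling through ``get_params`` / ``set_params``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .basis import SmoothBasis, SmoothSpec
from .features import LagDesign

FAMILIES = ("poisson", "quasipoisson", "negbin")

_FORMAT_VERSION = 1


@dataclass
class ModelScore:
    """Goodness-of-fit summary for one fitted candidate."""

    family: str
    aic: float | None  # undefined (None) for quasi-Poisson
    rmse: float
    mape: float | None  # None if every observed count is zero
    n_zero_excluded: int = 0
    max_lag: int | None = None
    include_immediate: bool | None = None


class ConvergenceError(RuntimeError):
    """Raised when the penalized IRLS loop fails to converge."""


# ---------------------------------------------------------------------------
# family internals
# ---------------------------------------------------------------------------

def _poisson_loglik(y, mu):
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _negbin_loglik(y, mu, theta):
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _deviance(y, mu, family, theta):
    with np.errstate(divide="ignore", invalid="ignore"):
        yly = np.where(y > 0, y * np.log(y / mu), 0.0)
    if family in ("poisson", "quasipoisson"):
        return float(2.0 * np.sum(yly - (y - mu)))
    t = theta
    return float(2.0 * np.sum(yly - (y + t) * np.log((y + t) / (mu + t))))


class CountGAM(BaseEstimator):
    """Additive penalized-spline regression for weekly count series.

    Parameters
    ----------
    terms : list of :class:`~edattrib.basis.SmoothSpec`
        One smooth per covariate column of the design frame.  Columns not
        listed are ignored; the intercept is always included.
    family : {"poisson", "quasipoisson", "negbin"}
    theta : float, optional
        Fixed negative-binomial size parameter; when None and
        family="negbin", theta is estimated by profile likelihood.
    irls_tol : relative penalized-deviance change declaring the inner
        IRLS loop converged.
    irls_max_iter : inner-loop iteration cap (non-convergence raises).
    reml_tol : max absolute change in log10(lambda) declaring the outer
        REML (Fellner–Schall) loop converged.
    reml_max_iter : outer-loop iteration cap.
    lam_bounds : clip range for estimated smoothing parameters.

    Attributes
    ----------
    coef_ : coefficient vector (intercept first, then per-smooth blocks).
    covariance_ : Bayesian posterior covariance of ``coef_`` (scaled by the
        Pearson dispersion under quasi-Poisson).
    lambda_ : dict column -> estimated smoothing parameter.
    edf_ : dict column -> effective degrees of freedom of that smooth.
    edf_total_ : total effective degrees of freedom (incl. intercept).
    dispersion_ : Pearson dispersion statistic of the fit.
    theta_ : estimated/fixed NB size parameter (negbin only).
    loglik_, aic_ : log-likelihood and AIC (aic_ is None for quasi-Poisson).
    """

    def __init__(
        self,
        terms=None,
        family: str = "poisson",
        theta: float | None = None,
        irls_tol: float = 1e-8,
        irls_max_iter: int = 200,
        reml_tol: float = 2e-3,
        reml_max_iter: int = 60,
        lam_bounds: tuple = (1e-7, 1e9),
    ):
        self.terms = terms
        self.family = family
        self.theta = theta
        self.irls_tol = irls_tol
        self.irls_max_iter = irls_max_iter
        self.reml_tol = reml_tol
        self.reml_max_iter = reml_max_iter
        self.lam_bounds = lam_bounds

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, y=None):
        if isinstance(X, LagDesign):
            if y is not None:
                raise ValueError("y is taken from the LagDesign; do not pass it separately")
            y = X.y
            X = X.frame
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.terms is None:
            raise ValueError("terms must be a list of SmoothSpec (may be empty for intercept-only)")
        y = np.asarray(y, dtype=float)
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("response must be non-negative integer counts")
        n = len(y)

        # build per-term bases and the stacked design
        self.bases_ = []
        blocks = [np.ones((n, 1))]
        slices = [slice(0, 1)]
        start = 1
        for spec in self.terms:
            if spec.column not in X.columns:
                raise KeyError(f"design frame lacks column {spec.column!r}")
            b = SmoothBasis(spec=spec).fit(X[spec.column].to_numpy(dtype=float))
            cols = b.transform(X[spec.column].to_numpy(dtype=float))
            blocks.append(cols)
            slices.append(slice(start, start + cols.shape[1]))
            start += cols.shape[1]
            self.bases_.append(b)
        Xmat = np.hstack(blocks)
        p = Xmat.shape[1]
        self.n_obs_, self.n_coef_ = n, p
        self.term_slices_ = dict(zip([b.spec.column for b in self.bases_], slices[1:]))

        # embedded penalties
        pen_blocks = []
        for b, sl in zip(self.bases_, slices[1:]):
            S = np.zeros((p, p))
            S[sl, sl] = b.penalty_
            rank = b.penalty_rank
            if rank > 0:
                pen_blocks.append((b, sl, S, rank))

        fit_family = "poisson" if self.family == "quasipoisson" else self.family
        theta = self.theta if self.theta is not None else 10.0

        lam = {id(t[0]): (t[0].spec.lam if t[0].spec.lam is not None else 1.0) for t in pen_blocks}
        free = [t for t in pen_blocks if t[0].spec.lam is None]

        def s_lambda():
            S = np.zeros((p, p))
            for b, sl, Sj, _ in pen_blocks:
                S += lam[id(b)] * Sj
            return S

        beta = None
        for outer in range(self.reml_max_iter if free else 1):
            S_l = s_lambda()
            beta, mu, H = self._irls(Xmat, y, S_l, fit_family, theta, beta0=beta)
            if fit_family == "negbin" and self.theta is None:
                theta = self._profile_theta(y, mu, theta)
            if not free:
                break
            A = np.linalg.inv(H + S_l + 1e-12 * np.eye(p))
            max_step = 0.0
            for b, sl, Sj, rank in free:
                lj = lam[id(b)]
                # REML stationarity: beta' S_j beta = rank_j / lam_j - tr(A S_j)
                num = rank / lj - float(np.sum(A * Sj.T))
                den = float(beta @ Sj @ beta)
                if den <= 0.0 or num <= 0.0:
                    new = self.lam_bounds[1] if den <= 0.0 else self.lam_bounds[0]
                else:
                    new = lj * num / den
                new = float(np.clip(new, *self.lam_bounds))
                max_step = max(max_step, abs(np.log10(new) - np.log10(lj)))
                lam[id(b)] = new
            if max_step < self.reml_tol:
                S_l = s_lambda()
                beta, mu, H = self._irls(Xmat, y, S_l, fit_family, theta, beta0=beta)
                break

        # final quantities
        S_l = s_lambda()
        A = np.linalg.inv(H + S_l + 1e-12 * np.eye(p))
        edf_vec = np.sum(A * H.T, axis=1)
        self.coef_ = beta
        self.mu_ = mu
        self.edf_total_ = float(edf_vec.sum())
        self.edf_ = {
            b.spec.column: float(edf_vec[sl].sum()) for b, sl in zip(self.bases_, slices[1:])
        }
        self.lambda_ = {b.spec.column: lam.get(id(b), 0.0) for b, _, _, _ in pen_blocks}
        resid_edf = max(n - self.edf_total_, 1.0)
        var_mu = mu if fit_family == "poisson" else mu + mu**2 / theta
        pearson = float(np.sum((y - mu) ** 2 / var_mu))
        self.dispersion_ = pearson / resid_edf
        phi = self.dispersion_ if self.family == "quasipoisson" else 1.0
        self.covariance_ = phi * (A + A.T) / 2.0
        self.theta_ = theta if fit_family == "negbin" else None
        if fit_family == "poisson":
            self.loglik_ = _poisson_loglik(y, mu)
        else:
            self.loglik_ = _negbin_loglik(y, mu, theta)
        if self.family == "quasipoisson":
            self.aic_ = None
        else:
            extra = 1.0 if (fit_family == "negbin" and self.theta is None) else 0.0
            self.aic_ = -2.0 * self.loglik_ + 2.0 * (self.edf_total_ + extra)
        self.y_train_ = y
        self.X_train_columns_ = list(X.columns)
        self.train_means_ = X.mean(numeric_only=True).to_dict()
        return self

    # ------------------------------------------------------------- internals
    def _irls(self, Xmat, y, S_l, family, theta, beta0=None):
        n, p = Xmat.shape
        if beta0 is None:
            mu = np.maximum(y, 0.5)
            eta = np.log(mu)
        else:
            eta = Xmat @ beta0
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
        beta = beta0
        dev_old = np.inf
        for it in range(self.irls_max_iter):
            w = mu if family == "poisson" else mu / (1.0 + mu / theta)
            z = eta + (y - mu) / mu
            XW = Xmat * w[:, None]
            Hm = Xmat.T @ XW
            rhs = XW.T @ z
            try:
                beta = np.linalg.solve(Hm + S_l, rhs)
            except np.linalg.LinAlgError:
                beta = np.linalg.solve(Hm + S_l + 1e-8 * np.eye(p), rhs)
            eta = np.clip(Xmat @ beta, -30, 30)
            mu = np.exp(eta)
            dev = _deviance(y, mu, family, theta) + float(beta @ S_l @ beta)
            if np.isfinite(dev) and abs(dev_old - dev) < self.irls_tol * (abs(dev) + 0.1):
                return beta, mu, Hm
            dev_old = dev
        raise ConvergenceError(
            f"penalized IRLS did not converge in {self.irls_max_iter} iterations "
            f"(last penalized deviance {dev_old:.6g})"
        )

    @staticmethod
    def _profile_theta(y, mu, theta0):
        res = minimize_scalar(
            lambda lt: -_negbin_loglik(y, mu, np.exp(lt)),
            bounds=(np.log(1e-2), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        return float(np.exp(res.x))

    def _build_matrix(self, X: pd.DataFrame) -> np.ndarray:
        n = len(X)
        blocks = [np.ones((n, 1))]
        for b in self.bases_:
            blocks.append(b.transform(X[b.spec.column].to_numpy(dtype=float)))
        return np.hstack(blocks)

    # ------------------------------------------------------------- predict
    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return self._build_matrix(X) @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Expected counts exp(linear predictor) at new design rows."""
        if isinstance(X, LagDesign):
            X = X.frame
        return np.exp(self.linear_predictor(X))

    def se_linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        B = self._build_matrix(X)
        var = np.einsum("ij,jk,ik->i", B, self.covariance_, B)
        return np.sqrt(np.maximum(var, 0.0))

    def term_contribution(self, column: str, values) -> np.ndarray:
        """Evaluate one fitted smooth f-hat at arbitrary covariate values."""
        for b in self.bases_:
            if b.spec.column == column:
                sl = self.term_slices_[column]
                return b.transform(np.asarray(values, dtype=float)) @ self.coef_[sl]
        raise KeyError(f"no smooth for column {column!r}")

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "family": self.family,
            "theta": self.theta_,
            "coef": self.coef_.tolist(),
            "covariance": self.covariance_.tolist(),
            "lambda": self.lambda_,
            "edf": self.edf_,
            "edf_total": self.edf_total_,
            "dispersion": self.dispersion_,
            "loglik": self.loglik_,
            "aic": self.aic_,
            "bases": [b.to_dict() for b in self.bases_],
            "term_slices": {c: [s.start, s.stop] for c, s in self.term_slices_.items()},
            "train_means": self.train_means_,
            "n_obs": self.n_obs_,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CountGAM":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        bases = [SmoothBasis.from_dict(bd) for bd in d["bases"]]
        model = cls(terms=[b.spec for b in bases], family=d["family"])
        model.bases_ = bases
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.covariance_ = np.asarray(d["covariance"], dtype=float)
        model.lambda_ = d["lambda"]
        model.edf_ = d["edf"]
        model.edf_total_ = d["edf_total"]
        model.dispersion_ = d["dispersion"]
        model.loglik_ = d["loglik"]
        model.aic_ = d["aic"]
        model.theta_ = d["theta"]
        model.term_slices_ = {c: slice(a, b) for c, (a, b) in d["term_slices"].items()}
        model.train_means_ = d["train_means"]
        model.n_obs_ = d["n_obs"]
        model.n_coef_ = len(model.coef_)
        return model

    @classmethod
    def load(cls, path) -> "CountGAM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# module-level conveniences
# ---------------------------------------------------------------------------

def default_terms(
    design: LagDesign,
    k_smooth: int = 8,
    k_week: int = 10,
    k_year: int = 4,
    cyclic_week: bool = True,
) -> list[SmoothSpec]:
    """Smooth specifications mirroring the study model for a lag design.

    One rank-``k_smooth`` thin-plate-type smooth per autoregressive and per
    lagged exposure column, a cyclic rank-``k_week`` smooth of epi-week and
    a rank-``k_year`` smooth of calendar year.
    """
    terms = [SmoothSpec(column=c, k=k_smooth, basis="tps") for c in design.smooth_columns()]
    terms.append(
        SmoothSpec(column="week", k=k_week, basis="cyclic" if cyclic_week else "tps")
    )
    n_years = design.frame["year"].nunique()
    if n_years >= 3:
        terms.append(SmoothSpec(column="year", k=min(k_year, n_years), basis="tps"))
    elif n_years == 2:
        terms.append(SmoothSpec(column="year", basis="linear"))
    return terms


def fit_gam(design: LagDesign, family: str = "poisson", **term_kwargs) -> CountGAM:
    """Fit the study model to one category's lag design."""
    model = CountGAM(terms=default_terms(design, **term_kwargs), family=family)
    return model.fit(design)


def score(model: CountGAM, design: LagDesign | None = None) -> ModelScore:
    """AIC / RMSE / MAPE of a fitted model (in-sample when design is None).

    MAPE excludes (and counts) zero-count weeks, where a percentage error
    is undefined; it is None if every count is zero.
    """
    if design is None:
        y = model.y_train_
        mu = model.mu_
        max_lag = include_immediate = None
    else:
        y = design.y
        mu = model.predict(design.frame)
        max_lag, include_immediate = design.max_lag, design.include_immediate
    rmse = float(np.sqrt(np.mean((y - mu) ** 2)))
    nz = y > 0
    n_zero = int((~nz).sum())
    mape = float(np.mean(np.abs((y[nz] - mu[nz]) / y[nz])) * 100.0) if nz.any() else None
    return ModelScore(
        family=model.family,
        aic=model.aic_,
        rmse=rmse,
        mape=mape,
        n_zero_excluded=n_zero,
        max_lag=max_lag,
        include_immediate=include_immediate,
    )


def dispersion(model: CountGAM) -> float:
    """Pearson dispersion: sum of squared Pearson residuals / residual EDF."""
    return model.dispersion_
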