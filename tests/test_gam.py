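"""Penalized IRLS / REML engine behaviour and oracle agreement."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from edattrib.basis import SmoothSpec
from edattrib.gam import CountGAM, score


class TestBasics:
    def test_intercept_only_constant_response(self):
        y = np.full(60, 7)
        m = CountGAM(terms=[]).fit(pd.DataFrame({"x": np.arange(60.0)}), y)
        assert m.coef_[0] == pytest.approx(np.log(7.0), abs=1e-10)
        assert np.allclose(m.predict(pd.DataFrame({"x": [0.0, 99.0]})), 7.0)

    def test_training_rows_reproduce_fitted_values(self, single_smooth_fit):
        model, X, y = single_smooth_fit
        assert np.allclose(model.predict(X), model.mu_, rtol=1e-12)

    def test_invalid_inputs(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="non-negative integer"):
            CountGAM(terms=[]).fit(X, np.array([1.0, -2.0] * 5))
        with pytest.raises(ValueError, match="family"):
            CountGAM(terms=[], family="gaussian").fit(X, np.ones(10))
        with pytest.raises(KeyError):
            CountGAM(terms=[SmoothSpec("missing")]).fit(X, np.ones(10, dtype=int))


class TestGLMOracle:
    def test_linear_basis_matches_unpenalized_poisson_irls(self):
        """Zero-penalty linear fit must agree with an independent GLM fit."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        n = 261
        x = rng.uniform(0, 1, n)
        w = rng.uniform(-1, 1, n)
        eta = np.log(80) + 0.8 * (x - x.mean()) - 0.5 * (w - w.mean())
        y = rng.poisson(np.exp(eta))
        X = pd.DataFrame({"x": x, "w": w})
        m = CountGAM(terms=[SmoothSpec("x", basis="linear"), SmoothSpec("w", basis="linear")]).fit(X, y)
        Z = np.column_stack([np.ones(n), x - x.mean(), w - w.mean()])
        glm = sm.GLM(y, Z, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(m.coef_ - np.asarray(glm.params))) < 1e-6
        assert np.max(np.abs(m.covariance_ - np.asarray(glm.cov_params()))) < 1e-8


class TestPenaltyLimits:
    def test_infinite_penalty_collapses_to_linear(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 300)
        y = rng.poisson(np.exp(np.log(50) + np.sin(3 * x)))
        m = CountGAM(terms=[SmoothSpec("x", k=8, lam=1e12)]).fit(pd.DataFrame({"x": x}), y)
        grid = np.linspace(0.1, 0.9, 30)
        f = m.term_contribution("x", grid)
        second_diff = np.diff(f, 2)
        assert np.max(np.abs(second_diff)) < 1e-6

    def test_edf_decreases_monotonically_with_lambda(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 261)
        y = rng.poisson(np.exp(np.log(100) + 0.4 * np.sin(2 * np.pi * x)))
        edfs = []
        for lam in [1e-4, 1e-2, 1.0, 1e2, 1e4]:
            m = CountGAM(terms=[SmoothSpec("x", k=8, lam=lam)]).fit(pd.DataFrame({"x": x}), y)
            edfs.append(m.edf_["x"])
        assert all(a > b for a, b in zip(edfs, edfs[1:]))
        assert edfs[-1] >= 1.0 - 1e-6  # the unpenalized linear null space remains

    def test_reml_lambda_finite_positive_on_smooth_truth(self, single_smooth_fit):
        model, _, _ = single_smooth_fit
        lam = model.lambda_["x"]
        assert np.isfinite(lam) and 0 < lam < 1e8


@pytest.fixture(scope="module")
def overdispersed():
    rng = np.random.default_rng(8)
    n = 261
    x = rng.uniform(0, 1, n)
    mu = np.exp(np.log(150) + 0.5 * np.sin(2 * np.pi * x))
    lam = rng.gamma(2.0, mu / 2.0)  # NB theta = 2
    return pd.DataFrame({"x": x}), rng.poisson(lam)


class TestFamilies:
    def test_quasipoisson_point_estimates_equal_poisson(self, overdispersed):
        X, y = overdispersed
        mp = CountGAM(terms=[SmoothSpec("x", k=8)], family="poisson").fit(X, y)
        mq = CountGAM(terms=[SmoothSpec("x", k=8)], family="quasipoisson").fit(X, y)
        assert np.array_equal(mp.coef_, mq.coef_)
        assert np.allclose(mq.covariance_, mq.dispersion_ * mp.covariance_)
        assert mq.aic_ is None and mp.aic_ is not None

    def test_negbin_estimates_theta_near_truth(self, overdispersed):
        X, y = overdispersed
        m = CountGAM(terms=[SmoothSpec("x", k=8)], family="negbin").fit(X, y)
        assert 1.0 < m.theta_ < 4.0
        assert m.aic_ is not None

    def test_poisson_fit_on_nb_data_shows_overdispersion(self, overdispersed):
        X, y = overdispersed
        m = CountGAM(terms=[SmoothSpec("x", k=8)], family="poisson").fit(X, y)
        assert m.dispersion_ > 1.5


class TestPredictVariance:
    def test_variance_grows_under_extrapolation(self, single_smooth_fit):
        model, X, _ = single_smooth_fit
        inside = pd.DataFrame({"x": [float(X["x"].median())]})
        far = pd.DataFrame({"x": [float(X["x"].max() + 2 * np.ptp(X["x"]))]})
        with pytest.warns(UserWarning, match="outside the training range"):
            se_far = model.se_linear_predictor(far)[0]
        se_in = model.se_linear_predictor(inside)[0]
        assert se_far > se_in


class TestScore:
    def test_perfect_and_offset_predictions(self):
        class Stub:
            family = "poisson"
            aic_ = 123.0

        from edattrib.features import LagDesign

        y = np.array([10.0, 20, 40])
        frame = pd.DataFrame({"y": y})
        design = LagDesign(frame=frame, max_lag=1, include_immediate=False,
                           exposure_names=(), n_total=4)
        stub = Stub()
        stub.predict = lambda X: y.copy()
        s = score(stub, design)
        assert s.rmse == 0.0 and s.mape == 0.0
        stub.predict = lambda X: y * 1.1
        s = score(stub, design)
        assert s.mape == pytest.approx(10.0)

    def test_zero_counts_excluded_from_mape(self):
        class Stub:
            family = "poisson"
            aic_ = None

        from edattrib.features import LagDesign

        y = np.array([0.0, 10.0, 10.0])
        design = LagDesign(frame=pd.DataFrame({"y": y}), max_lag=1,
                           include_immediate=False, exposure_names=(), n_total=4)
        stub = Stub()
        stub.predict = lambda X: np.array([1.0, 11.0, 9.0])
        s = score(stub, design)
        assert s.n_zero_excluded == 1
        assert s.mape == pytest.approx(10.0)


class TestSerialization:
    def test_round_trip_identical_predictions(self, single_smooth_fit):
        model, X, _ = single_smooth_fit
        with tempfile.TemporaryDirectory() as td:
            path = Path(td) / "model.json"
            model.save(path)
            loaded = CountGAM.load(path)
        assert np.array_equal(loaded.predict(X), model.predict(X))
        assert loaded.edf_total_ == model.edf_total_


class TestAgainstMgcv:
    def test_fitted_curve_close_to_mgcv_reml(self, tmp_path):
        """Independent cross-check: same data, mgcv thin-plate REML fit."""
        rng = np.random.default_rng(21)
        n = 258
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(np.log(300) + 0.3 * np.sin(2 * np.pi * x)))
        df = pd.DataFrame({"x": x, "y": y})
        m = CountGAM(terms=[SmoothSpec("x", k=8)]).fit(df[["x"]], y)
        csv = tmp_path / "d.csv"
        out = tmp_path / "eta.csv"
        df.to_csv(csv, index=False)
        script = (
            f'd <- read.csv("{csv}"); library(mgcv); '
            'm <- gam(y ~ s(x, k=8, bs="tp"), family=poisson, method="REML", data=d); '
            'g <- seq(0.02, 0.98, length=50); '
            'p <- predict(m, newdata=data.frame(x=g), type="link"); '
            f'write.csv(data.frame(eta=p), "{out}", row.names=FALSE); '
            "cat(sum(m$edf) - 1)"
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=180)
        assert res.returncode == 0, res.stderr
        mgcv_edf = float(res.stdout.strip().split()[-1])
        grid = np.linspace(0.02, 0.98, 50)
        eta_mine = np.log(m.predict(pd.DataFrame({"x": grid})))
        eta_mgcv = pd.read_csv(out)["eta"].to_numpy()
        # different basis parameterisations: expect agreement well inside
        # the statistical uncertainty, not bitwise equality
        assert np.sqrt(np.mean((eta_mine - eta_mgcv) ** 2)) < 0.02
        assert abs(m.edf_["x"] - mgcv_edf) < 0.5
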