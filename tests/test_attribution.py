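"""PAF computation, removal modes, loess trend smoothing, grouping."""

import numpy as np
import pandas as pd
import pytest

import edattrib as ea
from edattrib import attribution
from edattrib.basis import SmoothSpec
from edattrib.features import build_lag_design
from edattrib.gam import CountGAM
from edattrib.validation import single_effect_truth


class TestPAFArithmetic:
    def test_formula_on_count_pairs(self):
        obs = np.array([100.0, 100.0, 80.0])
        exp = np.array([100.0, 50.0, 100.0])
        assert np.allclose(attribution.paf_from_counts(obs, exp), [0.0, 50.0, -25.0])

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError, match="observed count is zero"):
            attribution.paf_from_counts([0.0], [1.0])


@pytest.fixture(scope="module")
def small_fit():
    exp = ea.generate_exposures(n_weeks=200, seed=30)
    truth = single_effect_truth("co_ppm", 1, baseline=300.0, threshold=0.45, slope=1.5)
    adm = ea.generate_admissions(exp, truth, seed=31)
    design = build_lag_design(adm, exp, max_lag=1)
    model = CountGAM(
        terms=[SmoothSpec("co_ppm_lag1", k=8), SmoothSpec("temp_c_lag1", k=8)]
    ).fit(design)
    return truth, exp, design, model


class TestRemoval:
    def test_drop_term_equals_manual_subtraction(self, small_fit):
        _, _, design, model = small_fit
        mu_cf = attribution.counterfactual_expected(model, design, "co_ppm", 1, "drop-term")
        eta = model.linear_predictor(design.frame)
        contrib = model.term_contribution(
            "co_ppm_lag1", design.frame["co_ppm_lag1"].to_numpy()
        )
        assert np.max(np.abs(np.log(mu_cf) - (eta - contrib))) < 1e-12

    def test_drop_term_of_null_smooth_changes_nothing(self, small_fit):
        _, _, design, model = small_fit
        # zero out the temp smooth's coefficients: removal must be a no-op
        sl = model.term_slices_["temp_c_lag1"]
        saved = model.coef_[sl].copy()
        try:
            model.coef_[sl] = 0.0
            mu = model.predict(design.frame)
            mu_cf = attribution.counterfactual_expected(model, design, "temp_c", 1, "drop-term")
            assert np.allclose(mu, mu_cf, rtol=1e-12)
        finally:
            model.coef_[sl] = saved

    def test_set_zero_on_all_zero_column_is_identity(self, small_fit):
        _, _, design, _ = small_fit
        d0 = attribution.remove_exposure(design, "co_ppm", 1)
        d00 = attribution.remove_exposure(d0, "co_ppm", 1)
        pd.testing.assert_frame_equal(d0.frame, d00.frame)

    def test_unknown_mode(self, small_fit):
        _, _, design, model = small_fit
        with pytest.raises(ValueError, match="unknown removal mode"):
            attribution.counterfactual_expected(model, design, "co_ppm", 1, "banish")


class TestPAFSeries:
    def test_paf_below_100_and_oracle_sign(self, small_fit):
        truth, exp, design, model = small_fit
        ps = attribution.paf_series(model, design, "co_ppm", 1)
        assert np.all(ps.paf < 100.0)
        x = design.frame["co_ppm_lag1"]
        hi = ps.frame["week_index"][(x >= x.quantile(0.95)).to_numpy()]
        fitted_hi = ps.frame.set_index("week_index").loc[hi, "paf_pct"].mean()
        oracle_hi = ea.oracle_paf(truth, exp, "co_ppm", 1).loc[hi].mean()
        assert fitted_hi == pytest.approx(oracle_hi, abs=5.0)
        assert fitted_hi > 0

    def test_sign_coherent_with_significant_irr(self, small_fit):
        """Where the IRR is significantly above 1, the PAF trend is positive."""
        from edattrib import effects

        truth, exp, design, model = small_fit
        curve = effects.irr_curve(model, design, "co_ppm", 1)
        sig_up = (curve.lo > 1.0)
        assert sig_up.any()
        ps = attribution.paf_series(model, design, "co_ppm", 1)
        sc = attribution.smooth_paf(ps, design)
        x_sig = curve.grid[sig_up].min()
        assert sc.trend[sc.grid >= x_sig].mean() > 0


class TestLoess:
    def test_constant_paf_gives_flat_curve(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 60)
        sm = attribution.LoessSmoother(span=0.75).fit(x, np.full(60, 5.0))
        yhat = sm.predict(np.linspace(0.1, 0.9, 20))
        assert np.allclose(yhat, 5.0, atol=1e-10)

    def test_reproduces_global_line_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 80)
        y = 3.0 - 0.7 * x
        sm = attribution.LoessSmoother(span=0.75).fit(x, y)
        grid = np.linspace(0.5, 9.5, 25)
        assert np.max(np.abs(sm.predict(grid) - (3.0 - 0.7 * grid))) < 1e-6

    def test_band_shrinks_roughly_sqrt_n(self):
        rng = np.random.default_rng(2)

        def width(n):
            x = rng.uniform(0, 1, n)
            y = np.sin(2 * x) + 0.3 * rng.standard_normal(n)
            sm = attribution.LoessSmoother(span=0.75).fit(x, y)
            _, se = sm.predict(np.array([0.5]), return_se=True)
            return se[0]

        w1 = np.mean([width(100) for _ in range(30)])
        w4 = np.mean([width(400) for _ in range(30)])
        assert 0.35 < w4 / w1 < 0.65

    def test_too_few_pairs(self, small_fit):
        _, _, design, model = small_fit
        ps = attribution.paf_series(model, design, "co_ppm", 1)
        ps.frame = ps.frame.iloc[:10]
        with pytest.raises(ValueError, match="at least 20"):
            attribution.smooth_paf(ps, design)


class TestGrouping:
    @pytest.mark.parametrize(
        "category,group",
        [
            ("Cardiovascular disease", "Cardiorespiratory system disorders"),
            ("Respiratory infection", "Cardiorespiratory system disorders"),
            ("Diabetes mellitus", "Metabolic and digestive system disorders"),
            ("Genitourinary disorders", "Metabolic and digestive system disorders"),
            ("Oral diseases", "Others"),
            ("Skin diseases", "Others"),
        ],
    )
    def test_mapping(self, category, group):
        assert attribution.group_categories([category]) == [group]

    def test_unknown_category(self):
        with pytest.raises(KeyError, match="Astral projection"):
            attribution.group_categories(["Astral projection"])
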