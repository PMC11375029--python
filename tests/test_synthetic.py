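"""Synthetic generator calibration, determinism and closed-form oracles."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from edattrib import synthetic as syn
from edattrib.features import EXPOSURES


class TestGenerateExposures:
    def test_determinism(self):
        a = syn.generate_exposures(n_weeks=60, seed=5)
        b = syn.generate_exposures(n_weeks=60, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_temperature_mean_calibrated(self):
        exp = syn.generate_exposures(n_weeks=261, seed=1)
        assert 27.6 <= exp["temp_c"].mean() <= 28.4

    def test_all_marginals_within_15_percent(self):
        exp = syn.generate_exposures(n_weeks=261, seed=1)
        for name in EXPOSURES:
            spec = syn.DEFAULT_MARGINALS[name]
            assert abs(exp[name].mean() - spec.mean) <= 0.15 * spec.mean, name
            assert abs(exp[name].std() - spec.sd) <= 0.15 * spec.sd, name
            assert exp[name].min() >= spec.min and exp[name].max() <= spec.max, name

    def test_zero_sd_gives_constant_column(self):
        marg = dict(syn.DEFAULT_MARGINALS)
        marg["temp_c"] = syn.MarginalSpec(28.01, 0.0, 25.01, 29.99)
        cfg = syn.ExposureConfig(marginals=marg)
        exp = syn.generate_exposures(cfg, n_weeks=40, seed=0)
        assert (exp["temp_c"] == 28.01).all()

    def test_autocorrelation_is_present(self):
        exp = syn.generate_exposures(n_weeks=500, seed=3)
        x = exp["temp_c"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert 0.3 < r1 < 0.7  # configured rho = 0.5

    def test_invalid_configs(self):
        with pytest.raises(ValueError, match="n_weeks"):
            syn.generate_exposures(n_weeks=4, seed=0)
        with pytest.raises(ValueError, match="min < max"):
            syn.MarginalSpec(1.0, 0.5, 5.0, 2.0)
        with pytest.raises(ValueError, match="autocorrelation"):
            syn.ExposureConfig(autocorrelation=1.0)


class TestStationDaily:
    def test_record_count_and_determinism(self):
        rec, _, stations = syn.generate_station_daily(n_stations=21, n_days=7, seed=3)
        assert len(rec) == 147
        assert len(stations) == 21
        rec2, _, _ = syn.generate_station_daily(n_stations=21, n_days=7, seed=3)
        pd.testing.assert_frame_equal(rec, rec2)

    def test_zero_noise_equals_surface(self):
        rec, surface, _ = syn.generate_station_daily(n_stations=5, n_days=2, seed=1, noise_sd=0.0)
        day0 = rec[rec["date"] == rec["date"].min()]
        truth = surface(day0["x"].to_numpy(), day0["y"].to_numpy(), 0)
        assert np.allclose(day0["value"].to_numpy(), truth)

    def test_too_few_stations(self):
        with pytest.raises(ValueError, match="at least 2"):
            syn.generate_station_daily(n_stations=1, n_days=2, seed=0)


class TestGenerateAdmissions:
    def test_null_truth_mean_near_baseline(self):
        exp = syn.generate_exposures(n_weeks=261, seed=2)
        truth = syn.TruthModel(category="null", intercept=math.log(100.0))
        adm = syn.generate_admissions(exp, truth, seed=4)
        assert 90 <= adm["count"].mean() <= 110
        assert (adm["count"] >= 0).all()
        assert adm["count"].dtype.kind == "i"

    def test_determinism(self):
        exp = syn.generate_exposures(n_weeks=80, seed=2)
        truth = syn.default_truth("Oral diseases")
        a = syn.generate_admissions(exp, truth, seed=9)
        b = syn.generate_admissions(exp, truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_rainfall_step_raises_following_week_counts(self):
        """A positive step in the lag-1 rain smooth must lift post-rain weeks."""
        exp = syn.generate_exposures(n_weeks=1500, seed=6)
        truth = syn.TruthModel(
            category="step",
            intercept=math.log(100.0),
            smooth_shapes={("rain_mm", 1): {"shape": "hockey", "threshold": 15.0, "slope": 0.2}},
        )
        adm = syn.generate_admissions(exp, truth, seed=7)
        rain = exp["rain_mm"].to_numpy()[:-1]
        counts_next = adm["count"].to_numpy()[1:]
        high = counts_next[rain > 15.0]
        low = counts_next[rain < 5.0]
        assert len(high) > 30
        assert high.mean() > low.mean()


class TestOracles:
    def test_irr_is_one_at_the_mean(self):
        truth = syn.default_truth("Respiratory infection")
        xbar = syn.DEFAULT_MARGINALS["wind_kmh"].mean
        assert syn.oracle_irr(truth, "wind_kmh", 1, [xbar]) == pytest.approx([1.0])

    def test_linear_truth_closed_form(self):
        xbar = syn.DEFAULT_MARGINALS["temp_c"].mean
        truth = syn.TruthModel(
            category="lin",
            intercept=0.0,
            smooth_shapes={("temp_c", 2): {"shape": "linear", "slope": 0.1}},
        )
        irr = syn.oracle_irr(truth, "temp_c", 2, [xbar + 1.0])
        assert irr[0] == pytest.approx(math.exp(0.1), rel=1e-12)

    def test_piecewise_truth_matches_direct_evaluation(self):
        truth = syn.TruthModel(
            category="pw",
            intercept=0.0,
            smooth_shapes={("rain_mm", 1): {"shape": "hockey", "threshold": 10.0, "slope": 0.05}},
        )
        grid = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        f = lambda x: 0.05 * np.maximum(x - 10.0, 0.0)
        expected = np.exp(f(grid) - f(syn.DEFAULT_MARGINALS["rain_mm"].mean))
        assert np.allclose(syn.oracle_irr(truth, "rain_mm", 1, grid), expected)

    def test_paf_identities(self):
        exp = syn.generate_exposures(n_weeks=30, seed=0)
        null = syn.TruthModel(category="n", intercept=1.0)
        assert np.allclose(syn.oracle_paf(null, exp, "rain_mm", 1), 0.0)
        # contribution log 2 -> PAF 50%; contribution -log 2 -> PAF -100%
        for slope_sign, expected in [(1.0, 50.0), (-1.0, -100.0)]:
            shift = slope_sign * math.log(2.0)
            truth = syn.TruthModel(
                category="c",
                intercept=1.0,
                smooth_shapes={("temp_c", 1): {"shape": "linear", "slope": 1.0}},
            )
            # evaluate at the exposure value where the centered smooth equals +-log 2
            xbar = syn.DEFAULT_MARGINALS["temp_c"].mean
            f = truth.smooth("temp_c", 1)
            val = f(np.array([xbar + shift]))[0]
            assert val == pytest.approx(shift)
            paf = (1.0 - math.exp(-val)) * 100.0
            assert paf == pytest.approx(expected)


class TestBundle:
    def test_bundle_shapes_and_determinism(self):
        ds = syn.generate_bundle(n_weeks=60, seed=3, categories=("Oral diseases", "Skin diseases"))
        assert set(ds.admissions["category"]) == {"Oral diseases", "Skin diseases"}
        assert len(ds.exposures) == 60
        ds2 = syn.generate_bundle(n_weeks=60, seed=3, categories=("Oral diseases", "Skin diseases"))
        pd.testing.assert_frame_equal(ds.admissions, ds2.admissions)

    def test_save_load_round_trip(self, tmp_path):
        ds = syn.generate_bundle(n_weeks=40, seed=1, categories=("Oral diseases",))
        syn.save_bundle(ds, tmp_path)
        back = syn.load_bundle(tmp_path)
        pd.testing.assert_frame_equal(ds.exposures, back.exposures)
        t1 = ds.truths["Oral diseases"].to_dict()
        t2 = back.truths["Oral diseases"].to_dict()
        assert t1 == t2
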