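"""IDW interpolation, LOO power selection and weekly aggregation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from edattrib import spatial
from edattrib.synthetic import generate_station_daily


def _obs(xy, values):
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "value": values})


class TestIDW:
    def test_single_station_fills_grid_with_its_value(self):
        field = spatial.idw_interpolate(_obs(np.array([[5.0, 5.0]]), [7.0]), power=2.0)
        assert np.allclose(field.values, 7.0)

    def test_midpoint_of_two_stations_is_average(self):
        interp = spatial.IDWInterpolator(power=3.3).fit([[0.0, 0.0], [10.0, 0.0]], [0.0, 10.0])
        assert interp.predict([[5.0, 0.0]])[0] == pytest.approx(5.0)

    def test_exact_at_station_locations(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 50, (8, 2))
        v = rng.normal(20, 5, 8)
        pred = spatial.IDWInterpolator(power=2.0).fit(xy, v).predict(xy)
        assert np.allclose(pred, v, atol=1e-12)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            xy = rng.uniform(0, 50, (6, 2))
            v = rng.normal(0, 10, 6)
            q = rng.uniform(-10, 60, (40, 2))
            p = spatial.IDWInterpolator(power=rng.uniform(0.5, 5)).fit(xy, v).predict(q)
            assert np.all(p >= v.min() - 1e-9) and np.all(p <= v.max() + 1e-9)

    def test_large_power_approaches_nearest_neighbour(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        v = np.array([1.0, 5.0, 9.0])
        q = np.array([[2.0, 1.0]])  # nearest is station 0
        p = spatial.IDWInterpolator(power=60.0).fit(xy, v).predict(q)
        assert p[0] == pytest.approx(1.0, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError, match="positive"):
            spatial.IDWInterpolator(power=0.0).fit([[0, 0]], [1.0])
        with pytest.raises(ValueError, match="empty"):
            spatial.idw_interpolate(pd.DataFrame(columns=["x", "y", "value"]), power=2.0)


class TestLOOPowerSelection:
    def test_matches_bruteforce_loo(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 50, (8, 2))
        v = rng.normal(25, 4, 8)
        obs = _obs(xy, v)
        candidates = [0.5, 1.0, 2.0, 4.0]
        best, table = spatial.fit_idw_power(obs, candidates)
        # independent brute force
        brute = {}
        for p in candidates:
            errs = []
            for i in range(len(v)):
                mask = np.arange(len(v)) != i
                interp = spatial.IDWInterpolator(power=p).fit(xy[mask], v[mask])
                errs.append(interp.predict(xy[i][None, :])[0] - v[i])
            brute[p] = np.sqrt(np.mean(np.square(errs)))
        assert np.allclose(table.set_index("power")["loo_rmse"][candidates], [brute[p] for p in candidates])
        assert best == min(brute, key=lambda p: brute[p])

    def test_surface_generated_with_power_two_prefers_middle_powers(self):
        # stations sampled from an IDW-power-2 surface defined by source nodes
        rng = np.random.default_rng(5)
        src_xy = rng.uniform(0, 50, (6, 2))
        src_v = rng.normal(28, 2, 6)
        surface = spatial.IDWInterpolator(power=2.0).fit(src_xy, src_v)
        xy = rng.uniform(0, 50, (15, 2))
        obs = _obs(xy, surface.predict(xy))
        best, table = spatial.fit_idw_power(obs, [0.5, 2.0, 4.0])
        rmse = table.set_index("power")["loo_rmse"]
        assert rmse[best] <= rmse[0.5] and rmse[best] <= rmse[4.0]

    def test_constant_values_tie_break_to_smallest_power(self):
        xy = np.random.default_rng(0).uniform(0, 10, (5, 2))
        best, table = spatial.fit_idw_power(_obs(xy, np.full(5, 3.0)), [3.0, 1.0, 2.0])
        assert best == 1.0
        assert np.allclose(table["loo_rmse"], 0.0)

    def test_single_candidate_returned(self):
        xy = np.random.default_rng(0).uniform(0, 10, (5, 2))
        best, _ = spatial.fit_idw_power(_obs(xy, np.arange(5.0)), [1.75])
        assert best == 1.75

    def test_too_few_stations(self):
        with pytest.raises(ValueError, match="3 stations"):
            spatial.fit_idw_power(_obs(np.zeros((2, 2)), [1.0, 2.0]), [2.0])


class TestAggregateWeekly:
    def _days(self, start, n):
        return [start + dt.timedelta(days=i) for i in range(n)]

    def test_constant_week_mean(self):
        days = self._days(dt.date(2015, 1, 4), 7)  # EW1 2015 starts Sun Jan 4
        out = spatial.aggregate_weekly(pd.DataFrame({"date": days, "temp_c": 4.0}))
        assert len(out) == 1
        assert out.loc[0, "temp_c"] == 4.0
        assert out.loc[0, "year"] == 2015 and out.loc[0, "epiweek"] == 1

    def test_mean_of_daily_values(self):
        days = self._days(dt.date(2015, 1, 4), 7)
        out = spatial.aggregate_weekly(pd.DataFrame({"date": days, "v": np.arange(1.0, 8.0)}))
        assert out.loc[0, "v"] == 4.0

    def test_missing_day_reported_by_date(self):
        days = self._days(dt.date(2015, 1, 4), 7)
        missing = days.pop(3)
        with pytest.raises(ValueError, match=str(missing)):
            spatial.aggregate_weekly(pd.DataFrame({"date": days, "v": 1.0}))


class TestStationSurfaceRecovery:
    def test_idw_recovers_noiseless_surface_better_than_extreme_powers(self):
        records, surface, stations = generate_station_daily(
            n_stations=21, n_days=1, seed=9, noise_sd=0.0
        )
        obs = records[["x", "y", "value"]]
        best, table = spatial.fit_idw_power(obs, [0.5, 1.0, 2.0, 3.0, 4.0])
        rmse = table.set_index("power")["loo_rmse"]
        assert rmse[best] <= rmse[0.5] and rmse[best] <= rmse[4.0]
        # interpolate and compare against the true surface on the grid
        field = spatial.idw_interpolate(obs, power=best)
        centers = field.grid.cell_centers()
        truth = surface(centers[:, 0], centers[:, 1], 0)
        err = np.sqrt(np.mean((field.values.ravel() - truth) ** 2))
        assert err < np.std(truth)  # interpolation beats the trivial constant field
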