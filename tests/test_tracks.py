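"""Track processing: distances, resampling, winter delimitation, trend fit."""

import numpy as np
import pandas as pd
import pytest

import winterflux as wf
from winterflux.tracks import haversine_km


def fix_frame(rows):
    """rows: (individual, iso_timestamp, lon, lat)."""
    df = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lon", "lat"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


class TestHaversine:
    def test_one_degree_latitude(self):
        # pi/180 * 6371.0088 km
        assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.195, abs=0.005)

    def test_zero_distance(self):
        assert haversine_km(-95.3, 29.1, -95.3, 29.1) == 0.0

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        lon = rng.uniform(-180, 180, (1000, 3))
        lat = rng.uniform(-89, 89, (1000, 3))
        ab = haversine_km(lon[:, 0], lat[:, 0], lon[:, 1], lat[:, 1])
        ba = haversine_km(lon[:, 1], lat[:, 1], lon[:, 0], lat[:, 0])
        bc = haversine_km(lon[:, 1], lat[:, 1], lon[:, 2], lat[:, 2])
        ac = haversine_km(lon[:, 0], lat[:, 0], lon[:, 2], lat[:, 2])
        np.testing.assert_allclose(ab, ba, rtol=1e-12)
        assert np.all(ac <= ab + bc + 1e-9)


class TestResampleHourly:
    def test_halves_30min_scheme(self):
        ts = pd.date_range("2016-12-01", periods=96, freq="30min", tz="UTC")
        fixes = fix_frame([("A", t, -95.0, 29.0) for t in ts])
        out = wf.resample_hourly(fixes)
        assert len(out) == 48  # 2 days at 24 fixes/day from 48/day input

    def test_idempotent_on_hourly_data(self):
        ts = pd.date_range("2016-12-01", periods=30, freq="1h", tz="UTC")
        fixes = fix_frame([("A", t, -95.0 + i * 0.01, 29.0) for i, t in enumerate(ts)])
        once = wf.resample_hourly(fixes)
        twice = wf.resample_hourly(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )
        assert len(once) == 30

    def test_keeps_fix_nearest_hour_mark(self):
        rows = []
        for h in range(3):
            rows.append(("A", f"2016-12-01T{h:02d}:10:00Z", -95.0, 29.0 + h))
            rows.append(("A", f"2016-12-01T{h:02d}:40:00Z", -95.0, 40.0 + h))
        out = wf.resample_hourly(fix_frame(rows))
        # each :10 fix beats the preceding :40 fix for its hour; the final
        # :40 fix keeps the otherwise-empty next hour slot
        assert list(out["lat"]) == [29.0, 30.0, 31.0, 42.0]
        assert out["timestamp"].dt.minute.tolist() == [10, 10, 10, 40]

    def test_duplicate_timestamps_keep_first(self):
        rows = [
            ("A", "2016-12-01T00:00:00Z", -95.0, 29.0),
            ("A", "2016-12-01T00:00:00Z", -95.0, 33.0),
        ]
        out = wf.resample_hourly(fix_frame(rows))
        assert len(out) == 1 and out["lat"].iloc[0] == 29.0


class TestStepLengths:
    def test_identical_coordinates_zero_km(self):
        ts = pd.date_range("2016-12-01", periods=5, freq="1h", tz="UTC")
        steps = wf.step_lengths(fix_frame([("A", t, -95.0, 29.0) for t in ts]))
        assert len(steps) == 4
        np.testing.assert_allclose(steps["km"], 0.0)

    def test_gap_of_4h_or_more_removed(self):
        rows = [
            ("A", "2016-12-01T00:00:00Z", -95.0, 29.0),
            ("A", "2016-12-01T01:00:00Z", -95.1, 29.0),
            ("A", "2016-12-01T06:00:00Z", -95.2, 29.0),  # 5-h gap
            ("A", "2016-12-01T07:00:00Z", -95.3, 29.0),
        ]
        steps = wf.step_lengths(fix_frame(rows))
        assert len(steps) == 2  # the 5-h step is absent

    def test_fewer_than_two_fixes_empty(self):
        steps = wf.step_lengths(fix_frame([("A", "2016-12-01T00:00:00Z", -95.0, 29.0)]))
        assert steps.empty


class TestDailyDistance:
    def _steps(self, day_km: dict):
        """day_km: {(ind, date): [step km,...]} on hourly steps."""
        rows = []
        for (ind, date), kms in day_km.items():
            base = pd.Timestamp(f"{date}T12:00:00Z")
            for i, km in enumerate(kms):
                rows.append(
                    {
                        "individual_id": ind,
                        "t_start": base + pd.Timedelta(hours=i),
                        "t_end": base + pd.Timedelta(hours=i + 1),
                        "km": km,
                    }
                )
        return pd.DataFrame(rows)

    def test_stationary_individual_day_total_zero(self):
        steps = self._steps({(f"I{i}", "2016-12-01"): [0.0, 0.0] for i in range(5)})
        out = wf.daily_distance(steps)
        assert out["mean_km"].iloc[0] == 0.0

    def test_day_with_three_individuals_censored(self):
        steps = self._steps({(f"I{i}", "2016-12-01"): [1.0] for i in range(3)})
        steps2 = self._steps({(f"I{i}", "2016-12-02"): [1.0] for i in range(4)})
        out = wf.daily_distance(pd.concat([steps, steps2]), origin_day="2016-12-01")
        assert list(out["winter_day_index"]) == [2]

    def test_mean_of_individual_totals(self):
        steps = self._steps(
            {(f"I{i}", "2016-12-01"): [km] for i, km in enumerate([10.0, 20.0, 30.0, 40.0])}
        )
        out = wf.daily_distance(steps)
        assert out["mean_km"].iloc[0] == 25.0

    def test_invariant_to_step_order_within_day(self):
        steps = self._steps({(f"I{i}", "2016-12-01"): [1.0, 2.0, 3.0] for i in range(4)})
        shuffled = steps.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(
            wf.daily_distance(steps), wf.daily_distance(shuffled)
        )

    def test_empty_input_empty_series(self):
        assert wf.daily_distance(pd.DataFrame(columns=["individual_id", "t_start", "km"])).empty


class TestDelimitWinter:
    def test_resident_below_40N_start_first_fix_end_28feb(self):
        ts = pd.date_range("2016-11-01", periods=50, freq="12h", tz="UTC")
        fixes = fix_frame([("A", t, -95.0, 30.0) for t in ts])
        out = wf.delimit_winter(fixes)
        assert out["start"].iloc[0] == ts[0]
        assert out["end"].iloc[0].strftime("%m-%d") == "02-28"
        assert out["end"].iloc[0].year == 2017

    def test_southward_hop_resets_winter_start(self):
        # arrive at 35N on day 0; ~60-km southward displacement on day 2
        rows = [
            ("A", "2016-11-01T10:00:00Z", -95.0, 35.0),
            ("A", "2016-11-01T20:00:00Z", -95.0, 35.0),
            ("A", "2016-11-02T10:00:00Z", -95.0, 35.0),
            ("A", "2016-11-03T10:00:00Z", -95.0, 35.0),
            ("A", "2016-11-03T20:00:00Z", -95.0, 34.4),  # > 50 km south
            ("A", "2016-11-04T10:00:00Z", -95.0, 34.4),
            ("A", "2016-11-05T10:00:00Z", -95.0, 34.4),
            ("A", "2016-11-08T10:00:00Z", -95.0, 34.4),
            ("A", "2016-11-09T10:00:00Z", -95.0, 34.4),
            ("A", "2016-11-10T10:00:00Z", -95.0, 34.4),
        ]
        out = wf.delimit_winter(fix_frame(rows))
        assert out["start"].iloc[0] == pd.Timestamp("2016-11-03T10:00:00Z")

    def test_northward_departure_ends_winter(self):
        ts = pd.date_range("2016-12-01", periods=80, freq="1D", tz="UTC")
        rows = [("A", t, -95.0, 30.0) for t in ts[:76]]
        rows.append(("A", "2017-02-15T06:00:00Z", -95.0, 41.0))
        out = wf.delimit_winter(fix_frame(rows))
        assert out["end"].iloc[0] == pd.Timestamp("2017-02-15T06:00:00Z")

    def test_never_below_threshold_excluded(self):
        ts = pd.date_range("2016-12-01", periods=10, freq="1D", tz="UTC")
        fixes = fix_frame([("A", t, -95.0, 45.0) for t in ts])
        assert wf.delimit_winter(fixes).empty


class TestDailyTrend:
    def _series(self, coeffs, noise_sd, seed, n_days=130):
        rng = np.random.default_rng(seed)
        d = np.arange(1, n_days + 1, dtype=float)
        log_mean = sum(c * d**k for k, c in enumerate(coeffs))
        return pd.DataFrame(
            {
                "winter_day_index": d.astype(int),
                "mean_km": np.exp(log_mean + rng.normal(0, noise_sd, n_days)),
                "n_individuals": 10,
            }
        )

    def test_linear_truth_eliminates_higher_terms(self):
        series = self._series([2.0, -0.01], noise_sd=0.1, seed=0)
        fit = wf.fit_daily_trend(series)
        assert fit.degree == 1

    def test_cubic_truth_retains_cubic(self):
        # curvature shaped like an early-winter peak then decline
        coeffs = [1.0, 0.09, -0.0012, 3.5e-6]
        series = self._series(coeffs, noise_sd=0.15, seed=1)
        fit = wf.fit_daily_trend(series)
        assert fit.degree == 3

    def test_peak_day_matches_analytic_argmax(self):
        coeffs = [1.0, 0.09, -0.0012, 3.5e-6]
        series = self._series(coeffs, noise_sd=0.1, seed=2)
        fit = wf.fit_daily_trend(series)
        d = np.arange(1, 131)
        truth_curve = coeffs[0] + coeffs[1] * d + coeffs[2] * d**2 + coeffs[3] * d**3
        assert abs(fit.peak_day - d[np.argmax(truth_curve)]) <= 3

    def test_zero_mean_days_dropped_with_warning(self):
        series = self._series([2.0, -0.01], noise_sd=0.1, seed=3)
        series.loc[5, "mean_km"] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            model = wf.DailyTrendModel(series)
        assert len(model.series) == len(series) - 1

    def test_too_few_days_rejected(self):
        series = self._series([2.0, -0.01], noise_sd=0.1, seed=4, n_days=8)
        with pytest.raises(ValueError, match="at least 10"):
            wf.DailyTrendModel(series)

    def test_summary_mentions_degree_and_r2(self):
        fit = wf.fit_daily_trend(self._series([2.0, -0.01], 0.1, 0))
        text = fit.summary()
        assert "degree: 1" in text and "R^2" in text
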