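"""ODBA computation, calibration, quantile mapping, and the regional
mixed-effects model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import winterflux as wf
from winterflux.energetics import SAMPLE_COLUMNS, ihs
from winterflux.simulate import G, MV_PER_MS2


def burst_frame(arr, device="unbounded", units="G", burst_id=0):
    """(3, 30) array -> long-format burst table."""
    df = pd.DataFrame(arr, columns=SAMPLE_COLUMNS)
    df.insert(0, "burst_id", burst_id)
    df.insert(1, "individual_id", "A")
    df.insert(2, "timestamp", pd.Timestamp("2016-12-01T12:00:00Z"))
    df.insert(3, "device", device)
    df.insert(4, "units", units)
    df.insert(5, "axis", ["x", "y", "z"])
    return df


class TestCalibration:
    def test_identity_calibration_unchanged(self):
        arr = np.random.default_rng(0).normal(size=(3, 30))
        out = wf.calibrate_units(burst_frame(arr), {"unbounded": (1.0, 0.0)})
        np.testing.assert_allclose(out[SAMPLE_COLUMNS].to_numpy(), arr)

    def test_one_g_becomes_9_81(self):
        arr = np.ones((3, 30))
        out = wf.calibrate_units(burst_frame(arr))
        np.testing.assert_allclose(out[SAMPLE_COLUMNS].to_numpy(), G)

    def test_round_trip_with_inverse_calibration(self):
        arr = np.random.default_rng(1).normal(size=(3, 30))
        fwd = wf.calibrate_units(burst_frame(arr), {"unbounded": (2.5, -0.7)})
        back = wf.calibrate_units(fwd, {"unbounded": (1 / 2.5, 0.7 / 2.5)})
        np.testing.assert_allclose(back[SAMPLE_COLUMNS].to_numpy(), arr, atol=1e-12)

    def test_missing_device_named_in_error(self):
        with pytest.raises(KeyError, match="mystery"):
            wf.calibrate_units(burst_frame(np.ones((3, 30)), device="mystery"), {})

    def test_bounded_default_calibration_recovers_ms2(self):
        arr = np.full((3, 30), MV_PER_MS2)  # 1 m/s^2 in mV
        out = wf.calibrate_units(burst_frame(arr, device="bounded", units="mV"))
        np.testing.assert_allclose(out[SAMPLE_COLUMNS].to_numpy(), 1.0)


class TestQuantileMap:
    def test_same_distribution_gives_near_identity(self):
        rng = np.random.default_rng(2)
        src, tgt = rng.normal(size=10_000), rng.normal(size=10_000)
        qm = wf.quantile_map(src, tgt)
        grid = np.linspace(np.quantile(src, 0.05), np.quantile(src, 0.95), 500)
        assert np.max(np.abs(qm(grid) - grid)) < 0.05 * tgt.std()

    def test_clipped_source_tail_restored(self):
        rng = np.random.default_rng(3)
        tgt = rng.normal(0, 1, 20_000)
        src = np.clip(rng.normal(0, 1, 20_000), -1.5, 1.5)
        qm = wf.quantile_map(src, tgt)
        p99_mapped = np.quantile(qm.transform_sample(src), 0.99)
        p99_target = np.quantile(tgt, 0.99)
        assert abs(p99_mapped - p99_target) < 0.10 * abs(p99_target)

    def test_transfer_non_decreasing_on_dense_grid(self):
        rng = np.random.default_rng(4)
        qm = wf.quantile_map(rng.normal(size=2000), rng.gamma(2, 1, 2000))
        grid = np.linspace(-6, 8, 10_001)
        assert np.all(np.diff(qm(grid)) >= -1e-12)

    def test_composition_with_inverse_fit_is_identity(self):
        rng = np.random.default_rng(5)
        src, tgt = rng.normal(2, 1, 10_000), rng.gamma(3, 2, 10_000)
        fwd = wf.quantile_map(src, tgt)
        inv = wf.quantile_map(tgt, src)
        grid = np.linspace(np.quantile(src, 0.05), np.quantile(src, 0.95), 200)
        assert np.max(np.abs(inv(fwd(grid)) - grid)) < 0.05 * src.std()

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wf.quantile_map(np.zeros(2000), np.random.default_rng(0).normal(size=2000))

    def test_diagnostic_table_shape(self):
        rng = np.random.default_rng(6)
        qm = wf.quantile_map(rng.normal(size=2000), rng.normal(size=2000))
        tab = qm.diagnostic_table()
        assert set(tab.columns) == {"prob", "source", "mapped", "target"}


def direct_odba_oracle(samples, window=10):
    """Second, loop-based rendition of the ODBA definition."""
    samples = np.asarray(samples, float)
    n = samples.shape[1]
    half = window // 2
    odba_sum = 0.0
    for j in range(n):
        per_sample = 0.0
        for a in range(3):
            lo = max(0, j - half)
            hi = min(n, j + half)  # centred window [j-5, j+4] truncated
            static = samples[a, lo:hi].mean()
            per_sample += abs(samples[a, j] - static)
        odba_sum += per_sample
    return odba_sum / n


class TestComputeOdba:
    def test_constant_burst_zero(self):
        odba, dyn = wf.compute_odba(np.full((3, 30), 7.7))
        assert odba == 0.0
        np.testing.assert_allclose(dyn, 0.0)

    def test_alternating_axis_unit_dynamic_in_interior(self):
        arr = np.zeros((3, 30))
        arr[0] = np.where(np.arange(30) % 2 == 0, 1.0, -1.0)
        _, dyn = wf.compute_odba(arr)
        # any full 10-sample window of alternating +/-1 averages to 0
        np.testing.assert_allclose(np.abs(dyn[0, 5:25]), 1.0, atol=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            arr = rng.normal(0, 3, size=(3, 30))
            odba, _ = wf.compute_odba(arr)
            assert odba == pytest.approx(direct_odba_oracle(arr), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(offset=st.floats(-20, 20), seed=st.integers(0, 100))
    def test_invariant_to_constant_axis_offset(self, offset, seed):
        arr = np.random.default_rng(seed).normal(size=(3, 30))
        base, _ = wf.compute_odba(arr)
        shifted = arr.copy()
        shifted[1] += offset
        got, _ = wf.compute_odba(shifted)
        assert got == pytest.approx(base, abs=1e-9)

    def test_scales_linearly(self):
        arr = np.random.default_rng(8).normal(size=(3, 30))
        base, _ = wf.compute_odba(arr)
        scaled, _ = wf.compute_odba(3.5 * arr)
        assert scaled == pytest.approx(3.5 * base, rel=1e-12)

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            wf.compute_odba(np.zeros((3, 29)))


class TestDailyOdba:
    def _states(self, rows):
        return pd.DataFrame(rows, columns=["individual_id", "date", "state_code"])

    def _bursts(self, rows):
        df = pd.DataFrame(rows, columns=["burst_id", "individual_id", "timestamp", "odba"])
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        return df

    def test_single_burst_day(self):
        out = wf.daily_odba(
            self._bursts([(0, "A", "2016-12-01T12:00:00Z", 2.4)]),
            self._states([("A", pd.Timestamp("2016-12-01"), 3)]),
        )
        assert out["daily_odba"].iloc[0] == 2.4 and out["n_bursts"].iloc[0] == 1

    def test_mean_of_two_bursts(self):
        out = wf.daily_odba(
            self._bursts(
                [(0, "A", "2016-12-01T12:00:00Z", 1.0), (1, "A", "2016-12-01T13:00:00Z", 3.0)]
            ),
            self._states([("A", pd.Timestamp("2016-12-01"), 3)]),
        )
        assert out["daily_odba"].iloc[0] == 2.0

    def test_unresolved_region_day_dropped(self):
        out = wf.daily_odba(
            self._bursts([(0, "A", "2016-12-01T12:00:00Z", 1.0)]),
            self._states([("A", pd.Timestamp("2016-12-01"), 9)]),
        )
        assert out.empty

    def test_region_change_splits_records(self):
        bursts = self._bursts(
            [(0, "A", "2016-12-01T12:00:00Z", 1.0), (1, "A", "2016-12-02T12:00:00Z", 5.0)]
        )
        states = self._states(
            [("A", pd.Timestamp("2016-12-01"), 3), ("A", pd.Timestamp("2016-12-02"), 4)]
        )
        out = wf.daily_odba(bursts, states)
        assert len(out) == 2
        assert set(out["region_code"]) == {3, 4}


class TestIhs:
    @pytest.mark.parametrize("x", [-2.0, 0.0, 1.0, 10.0])
    def test_closed_form(self, x):
        assert ihs(x) == pytest.approx(np.log(x + np.sqrt(x**2 + 1)), rel=1e-12)


def simulate_odba_records(effects, n_individuals, n_days, seed, sd_ind=0.2, sd_win=0.1, sd_e=0.3):
    """Daily-ODBA records with known region effects on the IHS scale."""
    rng = np.random.default_rng(seed)
    regions = list(effects)
    rows = []
    u_ind = rng.normal(0, sd_ind, n_individuals)
    for w, winter in enumerate(("2016-2017", "2017-2018")):
        u_w = rng.normal(0, sd_win)
        for i in range(n_individuals):
            for d in range(n_days // 2):
                reg = regions[rng.integers(len(regions))]
                y = effects[reg] + u_ind[i] + u_w + rng.normal(0, sd_e)
                # invert the response transform so the model sees raw ODBA
                rows.append(
                    {
                        "individual_id": f"I{i}",
                        "winter": winter,
                        "date": pd.Timestamp("2016-11-01") + pd.Timedelta(days=d),
                        "region_code": reg,
                        "daily_odba": np.sinh(y),
                        "n_bursts": 10,
                    }
                )
    return pd.DataFrame(rows)


class TestRegionOdbaModel:
    def test_recovers_simulated_region_effects(self):
        effects = {2: 0.0, 3: -0.3, 7: -0.5}
        records = simulate_odba_records(effects, n_individuals=40, n_days=50, seed=9)
        fit = wf.RegionOdbaModel(records, transform_order="ihs_then_standardize").fit(seed=0)
        # contrasts on the standardized-IHS scale: rescale back by the SD
        got_3 = fit.region_effect("3") * fit.transform_sd
        got_7 = fit.region_effect("7") * fit.transform_sd
        assert got_3 == pytest.approx(-0.3, abs=0.05)
        assert got_7 == pytest.approx(-0.5, abs=0.05)

    def test_conditional_r2_at_least_marginal(self):
        records = simulate_odba_records({2: 0.0, 3: -0.4}, 20, 30, seed=10)
        fit = wf.RegionOdbaModel(records).fit(seed=0)
        assert fit.conditional_r2 >= fit.marginal_r2

    def test_familywise_error_rate_controlled_under_null(self):
        """With no true region effect, adjusted pairwise p-values rarely
        reject (small-replicate sanity check of the max-|t| adjustment)."""
        false_positives = 0
        n_reps = 20
        for rep in range(n_reps):
            records = simulate_odba_records(
                {2: 0.0, 3: 0.0, 4: 0.0, 7: 0.0}, 15, 20, seed=200 + rep
            )
            fit = wf.RegionOdbaModel(records).fit(adjust_draws=20_000, seed=rep)
            false_positives += (fit.pairwise["p_adj"] <= 0.05).any()
        assert false_positives / n_reps <= 0.2

    def test_reference_region_effect_is_zero(self):
        records = simulate_odba_records({2: 0.0, 3: -0.4}, 15, 20, seed=11)
        fit = wf.RegionOdbaModel(records).fit(seed=0)
        assert fit.region_effect("2") == 0.0
        assert fit.reference == "2"

    def test_single_region_rejected(self):
        records = simulate_odba_records({2: 0.0}, 10, 10, seed=12)
        with pytest.raises(ValueError, match="2 regions"):
            wf.RegionOdbaModel(records)

    def test_back_transformed_contrasts_sign(self):
        records = simulate_odba_records({2: 0.0, 7: -0.5}, 30, 40, seed=13)
        fit = wf.RegionOdbaModel(records).fit(seed=0)
        contrasts = fit.back_transformed_contrasts()
        assert contrasts["7"] < 0  # lower-ODBA region sits below the reference
        assert contrasts["2"] == pytest.approx(0.0, abs=1e-12)

    def test_summary_text(self):
        records = simulate_odba_records({2: 0.0, 3: -0.4}, 15, 20, seed=14)
        text = wf.RegionOdbaModel(records).fit(seed=0).summary()
        assert "marginal R^2" in text and "reference region: 2" in text
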