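from datetime import date

import numpy as np
import pandas as pd
import pytest

from divetag import dives as dv
from divetag import synthetic as syn

from conftest import make_behavior, make_scenario, noiseless, toy_series


# ---------------------------------------------------------------- oracles
def segment_oracle(depth: np.ndarray) -> tuple[int, int]:
    """Exhaustive scan: first and last index at depth >= 0.75 * max."""
    thr = 0.75 * depth.max()
    idx = [i for i, z in enumerate(depth) if z >= thr]
    return idx[0], idx[-1]


def extraction_oracle(depth: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Run-length scan of maximal runs with depth > threshold."""
    runs, start = [], None
    for i, z in enumerate(depth):
        if z > threshold and start is None:
            start = i
        elif z <= threshold and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(depth) - 1))
    return runs


# ---------------------------------------------------------------- MLD
class TestEstimateMLD:
    def test_step_profile(self):
        z = np.tile(np.arange(0.0, 61.0), 3)
        t = np.where(z < 29.0, 15.5, 8.0)
        est = dv.estimate_mld(
            toy_series(z, temp=t).data, delta_t_threshold=0.5, date=date(2019, 6, 15)
        )
        assert abs(est.mld - 29.0) <= 5.0  # bin resolution
        assert not est.flagged

    def test_isothermal_flagged(self):
        z = np.linspace(0, 80, 50)
        t = np.full(50, 14.0)
        est = dv.estimate_mld(toy_series(z, temp=t).data, date=date(2019, 6, 15))
        assert est.flagged
        assert est.mld == pytest.approx(np.floor(80 / 5) * 5 + 2.5)

    def test_tanh_profile_vs_dense_oracle(self):
        center, width, thr = 55.0, 10.0, 0.5

        def temp_of(z):
            return 8.0 + (16.0 - 8.0) * 0.5 * (1 - np.tanh((z - center) / width))

        z = np.tile(np.arange(0.0, 121.0), 2)
        est = dv.estimate_mld(
            toy_series(z, temp=temp_of(z)).data, delta_t_threshold=thr,
            date=date(2019, 6, 15),
        )
        # brute-force scan of the analytic profile on a 1-m grid
        dense = np.arange(0.0, 121.0)
        ref = temp_of(dense[dense <= 10.0]).mean()
        oracle = dense[temp_of(dense) < ref - thr].min()
        assert abs(est.mld - oracle) <= 5.0

    def test_insufficient_data(self):
        z = np.linspace(0, 10, 30)  # span < 30 m
        with pytest.raises(dv.InsufficientDataError):
            dv.estimate_mld(toy_series(z, temp=np.full(30, 12.0)).data)


# ---------------------------------------------------------------- extraction
def _mld_map(series, mld, day=None):
    days = set(series.data["timestamp"].dt.date)
    return {
        d: dv.MLDEstimate(d, mld, "fixed", 100, ml_temp=15.0) for d in days
    }


class TestExtractDives:
    def test_never_below_threshold_empty(self):
        z = np.full(200, 20.0)
        series = toy_series(z)
        assert dv.extract_dives(series, _mld_map(series, 29.0)) == []

    def test_threshold_is_mld_plus_10(self):
        # mld 29 -> dives begin strictly below 39 m
        n = 30
        shallow = np.full(n, 38.9)
        deep = np.concatenate([np.full(5, 20.0), np.full(n, 39.2), np.full(5, 20.0)])
        s1 = toy_series(shallow)
        s2 = toy_series(deep)
        assert dv.extract_dives(s1, _mld_map(s1, 29.0), min_duration_min=1) == []
        found = dv.extract_dives(s2, _mld_map(s2, 29.0), min_duration_min=1)
        assert len(found) == 1

    def test_two_excursions_match_oracle(self):
        z = np.concatenate(
            [
                np.full(10, 20.0),
                np.full(12, 80.0),
                np.full(8, 20.0),
                np.full(30, 120.0),
                np.full(10, 20.0),
            ]
        )
        series = toy_series(z)
        found = dv.extract_dives(series, _mld_map(series, 29.0), min_duration_min=5)
        runs = [r for r in extraction_oracle(z, 39.0) if (r[1] - r[0] + 1) >= 10]
        assert [d.samples for d in found] == runs
        assert len(found) == 2

    def test_day_without_mld_skipped(self, caplog):
        z = np.concatenate([np.full(20, 20.0), np.full(20, 200.0), np.full(20, 20.0)])
        series = toy_series(z)
        with caplog.at_level("WARNING"):
            found = dv.extract_dives(series, {})
        assert found == []
        assert "no MLD" in caplog.text


# ---------------------------------------------------------------- phases
class TestSegmentPhases:
    def _dive_for(self, z, dt_s=30.0):
        series = toy_series(z, dt_s=dt_s)
        d = dv.Dive(
            dive_id=0, fish_id="toy", date=date(2019, 6, 15),
            start_time=series.data["timestamp"].iloc[0],
            end_time=series.data["timestamp"].iloc[-1],
            samples=(0, len(z) - 1),
        )
        return dv.segment_phases(d, series), series

    def test_bottom_threshold_arithmetic(self):
        z = np.array([40.0, 100.0, 151.0, 200.0, 151.0, 100.0, 40.0])
        d, _ = self._dive_for(z)
        # max 200 -> threshold 150; 151-m samples belong to the bottom
        assert d.bottom == (2, 4)

    def test_spike_dive_single_bottom_sample(self):
        z = np.array([40.0, 100.0, 200.0, 100.0, 40.0])
        d, series = self._dive_for(z)
        assert d.bottom == (2, 2)
        assert d.bottom_duration == pytest.approx(series.sampling_interval_s / 60.0)

    def test_eleven_sample_toy_vector(self):
        # threshold 150: samples with depth >= 150 are indices 3..7 (0-based)
        z = np.array([40, 80, 120, 160, 190, 200, 190, 160, 120, 80, 40], float)
        d, _ = self._dive_for(z)
        assert d.bottom == (3, 7)
        assert d.descent == (0, 2)
        assert d.ascent == (8, 10)

    def test_degenerate_max_at_first_sample(self):
        z = np.array([200.0, 150.0, 90.0, 50.0])
        d, _ = self._dive_for(z)
        assert d.degenerate
        assert d.descent is None
        assert d.descent_duration == 0.0

    def test_durations_sum(self):
        z = np.array([40, 80, 120, 160, 190, 200, 190, 160, 120, 80, 40], float)
        d, _ = self._dive_for(z)
        assert d.total_duration == pytest.approx(
            d.descent_duration + d.bottom_duration + d.ascent_duration
        )

    def test_phase_partition_exact_random(self):
        # segmentation equals the exhaustive-scan oracle on 1,000 toy dives
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(3, 60)
            z = rng.uniform(30.0, 400.0, n)
            d, _ = self._dive_for(z)
            b0, b1 = segment_oracle(z)
            assert d.bottom == (b0, b1)
            # partition is exact and ordered
            n_desc = b0
            n_asc = n - 1 - b1
            assert (d.descent is None) == (n_desc == 0)
            assert (d.ascent is None) == (n_asc == 0)
            total = n_desc + (b1 - b0 + 1) + n_asc
            assert total == n


# ---------------------------------------------------------------- filtering
class TestFilterDaytimeDeep:
    def _mk_dive(self, start, end, max_depth, day=date(2019, 6, 15)):
        return dv.Dive(
            dive_id=0, fish_id="f", date=day,
            start_time=pd.Timestamp(start, tz="UTC"),
            end_time=pd.Timestamp(end, tz="UTC"),
            samples=(0, 10), max_depth=max_depth,
        )

    def _positions(self, lat=45.0, lon=230.0, day=date(2019, 6, 15)):
        return pd.DataFrame({"date": [day], "lat": [lat], "lon": [lon]})

    def test_shallow_dive_rejected(self, dcm_table):
        # cutoff at 45N: 70 + 3*18 = 124 m
        d = self._mk_dive("2019-06-15T20:00", "2019-06-15T20:30", 120.0)
        kept, rej = dv.filter_daytime_deep([d], self._positions(), dcm_table)
        assert kept == []
        assert rej["above DCM limit"] == 1

    def test_dive_spanning_sunset_rejected(self, dcm_table):
        from divetag import solar

        ev = solar.solar_events(date(2019, 6, 15), 45.0, 230.0)
        d = self._mk_dive(
            (ev.sunset - pd.Timedelta(minutes=10)).isoformat(),
            (ev.sunset + pd.Timedelta(minutes=20)).isoformat(),
            300.0,
        )
        kept, rej = dv.filter_daytime_deep([d], self._positions(), dcm_table)
        assert kept == []
        assert rej["not daytime"] == 1

    def test_counts_from_generator(self, dcm_table):
        # 3 deep daytime dives retained, 2 shallow rejected
        deep = [
            self._mk_dive("2019-06-15T20:00", "2019-06-15T20:30", 200.0 + i)
            for i in range(3)
        ]
        shallow = [
            self._mk_dive("2019-06-15T21:00", "2019-06-15T21:10", 80.0)
            for _ in range(2)
        ]
        kept, rej = dv.filter_daytime_deep(deep + shallow, self._positions(), dcm_table)
        assert len(kept) == 3
        assert rej["above DCM limit"] == 2

    def test_missing_band_names_band(self):
        table = dv.DCMTable(bands={30: (100.0, 20.0)})
        d = self._mk_dive("2019-06-15T20:00", "2019-06-15T20:30", 300.0)
        with pytest.raises(KeyError, match="40"):
            dv.filter_daytime_deep([d], self._positions(lat=45.0), table)


# ---------------------------------------------------------------- classify
def _dive_stub(bottom_proportion, total_duration):
    d = dv.Dive(
        dive_id=0, fish_id="f", date=date(2019, 6, 15),
        start_time=pd.Timestamp("2019-06-15T20:00", tz="UTC"),
        end_time=pd.Timestamp("2019-06-15T20:30", tz="UTC"),
        samples=(0, 10),
    )
    d.bottom_proportion = bottom_proportion
    d.total_duration = total_duration
    return d


class TestClassifyDives:
    def test_rule_mode_u(self):
        d = _dive_stub(0.65, 20.0)
        assert dv.classify_dive_rule(d) == "U"

    def test_rule_mode_v(self):
        d = _dive_stub(0.10, 6.0)
        assert dv.classify_dive_rule(d) == "V"

    def test_rule_mode_other(self):
        assert dv.classify_dive_rule(_dive_stub(0.9, 3.0)) == "other"

    def test_single_dive_falls_back_to_rule(self):
        with pytest.warns(UserWarning):
            out = dv.classify_dives([_dive_stub(0.7, 25.0)], mode="cluster")
        assert out[0].class_label == "U"

    def _simulated_accuracy(self, bottom_sd, seed=0, n_days=10):
        sc = make_scenario("cold")
        beh = make_behavior(
            n_days=n_days, u_dives_per_day=10, v_dives_per_day=10,
            u_bottom_duration_min=(20.0, bottom_sd), seed=seed,
        )
        series = syn.simulate_tag_series(sc, beh)
        mld = dv.estimate_mld_by_day(series)
        dives = [
            dv.segment_phases(d, series) for d in dv.extract_dives(series, mld)
        ]
        dv.classify_dives(dives, seed=0)
        pairs = [
            (d, t) for d, t in syn.match_dives_to_truth(dives, series.truth)
            if t is not None
        ]
        agree = [d.class_label == t.label for d, t in pairs]
        return float(np.mean(agree)), len(pairs)

    def test_cluster_accuracy_on_simulated_dives(self):
        acc, n = self._simulated_accuracy(bottom_sd=4.0)
        assert n >= 180
        assert acc >= 0.95

    def test_accuracy_degrades_with_bottom_noise(self):
        acc_low, _ = self._simulated_accuracy(bottom_sd=2.0, n_days=5)
        acc_high, _ = self._simulated_accuracy(bottom_sd=25.0, n_days=5)
        assert acc_low >= acc_high - 0.02


# ---------------------------------------------------------------- metrics
class TestDiveMetrics:
    def _segmented(self, z, temp=None, light=None, dt_s=30.0):
        series = toy_series(z, temp=temp, light=light, dt_s=dt_s)
        d = dv.Dive(
            dive_id=0, fish_id="toy", date=date(2019, 6, 15),
            start_time=series.data["timestamp"].iloc[0],
            end_time=series.data["timestamp"].iloc[-1],
            samples=(0, len(z) - 1),
        )
        return dv.segment_phases(d, series), series

    def test_delta_temp(self):
        z = np.array([40.0, 120.0, 200.0, 200.0, 200.0, 120.0, 40.0])
        t = np.where(z > 100.0, 8.0, 16.0)
        d, series = self._segmented(z, temp=t)
        est = dv.MLDEstimate(date(2019, 6, 15), 29.0, "fixed", 100, ml_temp=16.0)
        m = dv.compute_dive_metrics(d, series, est)
        assert m.min_temp == pytest.approx(8.0)
        assert m.delta_temp == pytest.approx(-8.0)

    def test_descent_rate_one_ms(self):
        # uniform descent at 1 m/s from 39 m, hold at 219 m, return
        dt = 30.0
        down = 39.0 + np.arange(7) * 30.0  # 39 .. 219
        z = np.concatenate([down, np.full(6, 219.0), down[::-1]])
        d, series = self._segmented(z, dt_s=dt)
        est = dv.MLDEstimate(date(2019, 6, 15), 29.0, "fixed", 100, ml_temp=16.0)
        m = dv.compute_dive_metrics(d, series, est)
        assert m.descent_rate == pytest.approx(1.0, abs=1e-9)

    def test_delta_light_beer_lambert(self):
        # ln-light = C - 0.04 * z; bottom midpoint 200 m deeper than start
        z = np.concatenate(
            [np.array([39.0, 99.0, 179.0]), np.full(5, 239.0),
             np.array([179.0, 99.0, 39.0])]
        )
        light = 10.0 - 0.04 * z
        d, series = self._segmented(z, light=light)
        est = dv.MLDEstimate(date(2019, 6, 15), 29.0, "fixed", 100, ml_temp=16.0)
        m = dv.compute_dive_metrics(d, series, est)
        assert m.delta_light == pytest.approx(-0.04 * 200.0 / np.log(10.0), rel=1e-9)

    def test_missing_light_flagged(self):
        z = np.array([40.0, 120.0, 200.0, 200.0, 120.0, 40.0])
        d, series = self._segmented(z)
        est = dv.MLDEstimate(date(2019, 6, 15), 29.0, "fixed", 100, ml_temp=16.0)
        m = dv.compute_dive_metrics(d, series, est)
        assert m.light_missing
        assert m.delta_light is None
        assert np.isfinite(m.min_temp)


# ------------------------------------------------- property-based invariants
from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, deadline=None)
@given(
    st.lists(st.floats(min_value=30.0, max_value=500.0, allow_nan=False),
             min_size=3, max_size=40)
)
def test_segmentation_partition_property(depths):
    z = np.asarray(depths)
    series = toy_series(z)
    d = dv.Dive(
        dive_id=0, fish_id="h", date=date(2019, 6, 15),
        start_time=series.data["timestamp"].iloc[0],
        end_time=series.data["timestamp"].iloc[-1],
        samples=(0, z.size - 1),
    )
    d = dv.segment_phases(d, series)
    b0, b1 = segment_oracle(z)
    assert d.bottom == (b0, b1)
    # partition: descent + bottom + ascent cover the dive, disjoint, ordered
    assert d.total_duration == pytest.approx(
        d.descent_duration + d.bottom_duration + d.ascent_duration
    )
    # bottom is the contiguous [first, last] >= threshold span: its
    # endpoints qualify and nothing outside it does (interior dips below
    # the threshold stay part of a wiggly bottom phase)
    thr = 0.75 * z.max()
    assert z[b0] >= thr and z[b1] >= thr
    assert np.all(z[:b0] < thr) and np.all(z[b1 + 1:] < thr)
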