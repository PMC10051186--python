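import numpy as np
import pandas as pd
import pytest

import wearaq as wq
from wearaq.curation import (CurationConfig, apply_range_filter, denoise_gps,
                             detect_peaks, enforce_pm_ordering, floor_bc,
                             fuse, per_minute_speed, trim_warmup)
from wearaq._geo import haversine_km

from conftest import series, utc_minutes


def brute_force_peaks(values, k, f):
    """Independent double-loop oracle for the windowed peak rule."""
    n = len(values)
    mask = np.zeros(n, dtype=bool)
    need = max(k, 2)
    for i in range(n):
        if not np.isfinite(values[i]):
            continue
        nbrs = [values[j] for j in range(max(0, i - k), min(n, i + k + 1))
                if j != i and np.isfinite(values[j])]
        if len(nbrs) < need:
            continue
        mask[i] = values[i] > f * (sum(nbrs) / len(nbrs))
    return mask


class TestPeakDetector:
    def test_constant_series_has_no_peaks(self):
        assert not detect_peaks(series([7.0] * 10), 2, 2.0).any()

    def test_single_spike_flagged(self):
        mask = detect_peaks(series([10, 10, 10, 50, 10, 10, 10]), 2, 2.0)
        assert mask.tolist() == [False, False, False, True,
                                 False, False, False]

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(2.0, 0.8, size=1000)
        vals[rng.random(1000) < 0.05] = np.nan
        s = series(vals)
        np.testing.assert_array_equal(detect_peaks(s, 2, 2.0),
                                      brute_force_peaks(vals, 2, 2.0))

    def test_gappy_windows_unflaggable(self):
        vals = [np.nan, np.nan, 50.0, np.nan, np.nan]
        assert not detect_peaks(series(vals), 2, 2.0).any()


class TestRangeFilter:
    def test_manual_filter(self):
        out, n = apply_range_filter(series([-5, 10, 2000]), (0, 1000))
        assert n == 2
        kept = out.values[np.isfinite(out.values)]
        assert kept.tolist() == [10.0]

    def test_infinite_limits_identity(self):
        s = series([1.0, -50.0, 9e9])
        out, n = apply_range_filter(s, (-np.inf, np.inf))
        assert n == 0 and np.allclose(out.values, s.values)

    def test_everything_out_of_range_is_not_an_error(self):
        out, n = apply_range_filter(series([5000.0, 6000.0]), (0, 1000))
        assert n == 2 and np.isnan(out.values).all()


class TestPmOrdering:
    def test_ordered_triplet_kept(self):
        (p1, p25, p10), n = enforce_pm_ordering(
            series([1.0], "pm1"), series([2.0], "pm25"), series([3.0], "pm10"))
        assert n == 0 and p1.values[0] == 1.0

    def test_disordered_minute_removed_from_all_three(self):
        (p1, p25, p10), n = enforce_pm_ordering(
            series([5.0], "pm1"), series([2.0], "pm25"), series([3.0], "pm10"))
        assert n == 1
        assert np.isnan(p1.values[0]) and np.isnan(p25.values[0]) \
            and np.isnan(p10.values[0])

    def test_matches_brute_force_on_random_triplets(self):
        rng = np.random.default_rng(8)
        a, b, c = rng.lognormal(1, 0.7, (3, 500))
        (p1, p25, p10), n = enforce_pm_ordering(
            series(a, "pm1"), series(b, "pm25"), series(c, "pm10"))
        expect_bad = [(x > y) or (y > z) for x, y, z in zip(a, b, c)]
        assert n == sum(expect_bad)
        np.testing.assert_array_equal(np.isnan(p1.values), expect_bad)


class TestWarmup:
    def test_contiguous_series_loses_first_minutes(self):
        out, n = trim_warmup(series(np.arange(10.0)), 3)
        assert n == 3 and len(out) == 7
        assert out.values[0] == 3.0

    def test_restart_after_gap_trimmed_too(self):
        # manual segmentation oracle: 5 minutes, 2 h gap, 5 minutes
        idx = list(utc_minutes(5)) + list(utc_minutes(5, "2019-11-04T02:05:00Z"))
        s = wq.SensorSeries("no2", pd.Series(np.arange(10.0),
                                             index=pd.DatetimeIndex(idx)))
        out, n = trim_warmup(s, 3)
        assert n == 6 and len(out) == 4

    def test_zero_minutes_is_identity(self):
        s = series(np.arange(5.0))
        out, n = trim_warmup(s, 0)
        assert n == 0 and len(out) == 5


class TestBcFloor:
    def test_manual_filter(self):
        out, n = floor_bc(series([-100, -2000, 500], "bc"), -1500)
        assert n == 1
        kept = out.values[np.isfinite(out.values)]
        assert kept.tolist() == [-100.0, 500.0]

    def test_boundary_value_retained(self):
        out, n = floor_bc(series([-1500.0], "bc"), -1500)
        assert n == 0 and out.values[0] == -1500.0


class TestGps:
    def track(self, lonlat, start="2019-11-04T10:00:00Z"):
        idx = utc_minutes(len(lonlat), start)
        return wq.GpsTrack(pd.DataFrame(lonlat, columns=["lon", "lat"],
                                        index=idx))

    def test_stationary_track_unchanged(self):
        t = self.track([[2.1, 48.8]] * 5)
        out, n = denoise_gps(t, 130)
        assert n == 0 and len(out) == 5

    def test_teleport_removed(self):
        # ~500 km east in one minute (haversine hand-check >> 130 km/h)
        t = self.track([[2.1, 48.8], [8.9, 48.8], [2.1, 48.8]])
        assert haversine_km(2.1, 48.8, 8.9, 48.8) > 400
        out, n = denoise_gps(t, 130)
        assert n == 1
        assert out.data["lon"].tolist() == [2.1, 2.1]

    def test_matches_sequential_brute_force(self):
        rng = np.random.default_rng(4)
        lon = 2.1 + np.cumsum(rng.normal(0, 0.001, 300))
        lat = 48.8 + np.cumsum(rng.normal(0, 0.001, 300))
        lon[rng.integers(0, 300, 5)] += 1.0  # teleports
        t = self.track(np.column_stack([lon, lat]))
        out, _ = denoise_gps(t, 130)
        # independent oracle: explicit sequential pass
        keep = [0]
        for i in range(1, 300):
            j = keep[-1]
            d = haversine_km(lon[j], lat[j], lon[i], lat[i])
            if d / ((i - j) / 60.0) <= 130:
                keep.append(i)
        np.testing.assert_array_equal(out.data["lon"].to_numpy(), lon[keep])

    def test_speed_one_km_per_minute(self):
        t = self.track([[2.1, 48.8], [2.1, 48.8 + 1 / 111.195]])
        s = per_minute_speed(t)
        assert len(s) == 1
        assert s.values[0] == pytest.approx(60.0, rel=0.01)

    def test_single_point_track_empty_speed(self):
        assert len(per_minute_speed(self.track([[2.1, 48.8]]))) == 0


class TestFuse:
    def test_union_of_disjoint_minutes(self):
        a = series([1.0], "no2")
        b = series([2.0], "bc", start="2019-11-04T00:05:00Z")
        table = fuse([a, b])
        assert len(table) == 2
        assert table.frame["no2"].notna().sum() == 1
        assert table.frame["bc"].notna().sum() == 1

    def test_gps_only_minute_makes_no_row(self):
        a = series([1.0], "no2")  # one measured minute at 00:00
        idx = utc_minutes(2)
        gps = wq.GpsTrack(pd.DataFrame({"lon": [2.1, 2.1],
                                        "lat": [48.8, 48.8]}, index=idx))
        table = fuse([a], positions=gps)
        assert len(table) == 1  # 00:01 has GPS but no measurement

    def test_labels_from_annotations(self):
        a = series(np.arange(10.0), "no2")
        ann = wq.AnnotationSet(pd.DataFrame({
            "start": ["2019-11-04T00:00:00Z"],
            "end": ["2019-11-04T00:05:00Z"], "label": ["home"]}))
        table = fuse([a], annotations=ann)
        assert (table.labels[:5] == "home").all()
        assert table.labels[5:].isna().all()


class TestCurate:
    def test_clean_bundle_removal_below_one_percent(self, clean_campaign):
        _, traces = clean_campaign
        table, report = wq.curate(traces.bundle("p"))
        assert report.fraction_removed < 0.01

    def test_per_rule_counts_sum_to_total(self, default_campaign):
        _, _, curated = default_campaign
        for _, report in curated:
            total = sum(sum(rules.values())
                        for rules in report.counts.values())
            assert total == report.total_removed

    def test_idempotent_fixed_point(self, clean_campaign):
        _, traces = clean_campaign
        table, _ = wq.curate(traces.bundle("p"))
        # re-curating the curated channels (missing cells preserved as
        # placeholders) removes nothing further
        chans = [wq.SensorSeries(ch, table.frame[ch])
                 for ch in wq.CHANNELS if table.frame[ch].notna().any()]
        bundle2 = wq.ParticipantBundle(channels=chans)
        _, report2 = wq.curate(bundle2)
        assert report2.total_removed == 0
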