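import numpy as np
import pandas as pd
import pytest

import wearaq as wq
from wearaq.senseval import (AlignedPair, align, evaluate_pair, ipi, kendall,
                             lfe, match_score, pearson, rmse, spearman)
from wearaq.core import ValidationError

from conftest import series, utc_minutes


def pair_from(s_vals, r_vals, step=1):
    s = np.asarray(s_vals, dtype=float)
    r = np.asarray(r_vals, dtype=float)
    idx = utc_minutes(len(s))
    return AlignedPair(sensor=pd.Series(s, index=idx),
                       reference=pd.Series(r, index=idx),
                       step_min=step, presence=1.0)


class TestAlign:
    def test_identical_grids_full_pairing(self):
        ref, deg = wq.generate_reference_pair(1, seed=0)
        pair = align(deg, ref, step=1)
        assert len(pair) == 1440
        assert pair.presence == pytest.approx(1.0)

    def test_block_average_to_reference_step(self):
        # hand-averaged fixture: 1-min sensor vs 15-min reference
        s = series(np.arange(30.0), "pm25")
        r_idx = pd.date_range("2019-11-04T00:00:00Z", periods=2, freq="15min")
        r = wq.SensorSeries("pm25", pd.Series([5.0, 6.0], index=r_idx))
        pair = align(s, r, step=15)
        np.testing.assert_allclose(pair.sensor.to_numpy(),
                                   [np.mean(range(15)), np.mean(range(15, 30))])

    def test_disjoint_spans_error(self):
        a = series([1, 2, 3], "pm25")
        b = series([1, 2, 3], "pm25", start="2019-12-01T00:00:00Z")
        with pytest.raises(ValidationError):
            align(a, b)


class TestMetricSuite:
    def test_identical_series_ideal_values(self):
        p = pair_from([1, 5, 3, 8, 2], [1, 5, 3, 8, 2])
        assert rmse(p) == 0.0
        assert pearson(p) == pytest.approx(1.0)
        assert kendall(p) == pytest.approx(1.0)
        assert spearman(p) == pytest.approx(1.0)

    def test_anticorrelated_pearson(self):
        v = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert pearson(pair_from(-v, v)) == pytest.approx(-1.0)

    def test_constant_series_correlation_undefined(self):
        p = pair_from([3, 3, 3, 3], [1, 2, 3, 4])
        assert np.isnan(pearson(p))

    def test_matches_textbook_formulas_on_random_pair(self):
        rng = np.random.default_rng(12)
        s = rng.normal(10, 3, 100)
        r = s + rng.normal(0, 1, 100)
        p = pair_from(s, r)
        # independent textbook oracles
        assert rmse(p) == pytest.approx(
            np.sqrt(np.sum((s - r) ** 2) / 100), abs=1e-9)
        sc, rc = s - s.mean(), r - r.mean()
        pearson_oracle = np.sum(sc * rc) / np.sqrt(
            np.sum(sc**2) * np.sum(rc**2))
        assert pearson(p) == pytest.approx(pearson_oracle, abs=1e-9)
        ranks = lambda x: np.argsort(np.argsort(x)) + 1.0
        assert spearman(p) == pytest.approx(
            np.corrcoef(ranks(s), ranks(r))[0, 1], abs=1e-9)
        conc = sum(np.sign(s[i] - s[j]) * np.sign(r[i] - r[j])
                   for i in range(100) for j in range(i))
        assert kendall(p) == pytest.approx(conc / (100 * 99 / 2), abs=1e-9)


class TestMatchScore:
    def test_identical_series(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(2, 1, 50)
        assert match_score(pair_from(v, v)) == 1.0

    def test_sensor_never_exceeds(self):
        r = np.concatenate([np.full(90, 1.0), np.full(10, 100.0)])
        s = np.full(100, 1.0)
        assert match_score(pair_from(s, r), threshold=50.0) == 0.9

    def test_anti_aligned_exceedances(self):
        # sensor exceeds on 10 pairs, reference on 10 other pairs
        s = np.concatenate([np.full(10, 100.0), np.full(90, 1.0)])
        r = np.concatenate([np.full(90, 1.0), np.full(10, 100.0)])
        assert match_score(pair_from(s, r), threshold=50.0) == pytest.approx(
            1.0 - 0.2)


class TestLfe:
    def test_identical_series_score_one(self):
        v = np.random.default_rng(1).normal(10, 2, 300)
        assert lfe(pair_from(v, v)) == 1.0

    def test_slow_drift_scores_below_fast_wiggle(self):
        n = 720
        t = np.arange(n)
        r = np.full(n, 10.0)
        slow = r + np.sin(2 * np.pi * t / 360)   # period 6 h >> 1 h cutoff
        fast = r + np.sin(2 * np.pi * t / 10)    # period 10 min
        assert lfe(pair_from(slow, r)) < lfe(pair_from(fast, r))

    def test_white_noise_flat_spectrum_expectation(self):
        rng = np.random.default_rng(5)
        n = 4096
        r = np.full(n, 10.0)
        s = r + rng.normal(0, 1, n)
        got = lfe(pair_from(s, r), cutoff_period_min=60)
        # flat spectrum: expected low fraction = share of bins below 1/60
        freqs = np.fft.rfftfreq(n, d=1.0)[1:]
        expect = 1.0 - np.mean(freqs < 1 / 60)
        assert got == pytest.approx(expect, abs=0.02)


class TestIpi:
    def test_perfect_sensor_fixed_point(self):
        ref, deg = wq.generate_reference_pair(1, seed=3)
        report = wq.evaluate_sensor(deg, ref)
        assert report["rmse"] == 0.0
        for m in ("pearson", "kendall", "spearman", "presence",
                  "match_score", "lfe"):
            assert report[m] == pytest.approx(1.0, abs=1e-9)
        assert report["ipi"] == pytest.approx(1.0, abs=1e-9)

    def test_single_metric_weighting(self):
        metrics = {"pearson": 0.66, "rmse": 5.0}
        got = ipi(metrics, weights={"pearson": 1.0}, rmse_scale=10.0)
        assert got == pytest.approx((0.66 + 1) / 2)

    def test_noise_ladder_monotone(self):
        scores = []
        for sd in (0.0, 0.5, 1.0, 2.0, 4.0):
            ref, deg = wq.generate_reference_pair(
                2, {"noise_sd": sd}, seed=9)
            scores.append(wq.evaluate_sensor(deg, ref)["ipi"])
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_all_metrics_missing_is_error(self):
        with pytest.raises(ValidationError):
            ipi({"pearson": float("nan")})

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(2, 0.5, 200)
        w = v + rng.normal(0, 0.3, 200)
        a = evaluate_pair(pair_from(w, v))
        idxb = utc_minutes(200, start="2019-12-25T06:00:00Z")
        b = evaluate_pair(AlignedPair(pd.Series(w, index=idxb),
                                      pd.Series(v, index=idxb), 1, 1.0))
        for m in a:
            if isinstance(a[m], float) and not np.isnan(a[m]):
                assert a[m] == pytest.approx(b[m], abs=1e-12)
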