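"""Sensor qualification against a collocated reference instrument.

Seven metrics are combined into an integrated performance index (IPI) in
[0, 1], 1 being an ideal sensor:

* RMSE of paired values (channel units);
* Pearson, Kendall and Spearman correlations;
* presence — ratio of recorded to expected samples on the comparison grid;
* match score — agreement on exceeding a high threshold (reference p90 by
  default), the event-detection skill of the sensor;
* low-frequency energy (LFE) — one minus the fraction of the
  sensor-minus-reference error power at periods longer than a cutoff
  (default 60 min), so slow drift scores low and white error scores high.

Match score and LFE have several operational definitions in the
evaluation literature; the ones above are this package's, config-exposed
so an alternative formula can be substituted.  For the IPI each metric is
mapped to [0, 1] (RMSE via 1/(1 + rmse/scale) with scale = reference IQR,
correlations via (r+1)/2, the rest natively bounded) and the IPI is the
weighted mean over the defined metrics (equal weights by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import ConfigError, SensorSeries, ValidationError

METRICS = ("rmse", "pearson", "kendall", "spearman", "presence",
           "match_score", "lfe")


@dataclass
class AlignedPair:
    """Sensor/reference values averaged onto a common time step."""

    sensor: pd.Series
    reference: pd.Series
    step_min: int
    presence: float          # recorded / expected sensor samples

    def __len__(self) -> int:
        return len(self.sensor)


def align(sensor: SensorSeries, reference: SensorSeries,
          step: int = 1) -> AlignedPair:
    """Average both series to ``step``-minute bins and pair common bins.

    Presence is the fraction of expected sensor bins (over the overlap of
    the two spans) that carry at least one recorded sample.
    """
    if step < 1:
        raise ConfigError("step must be >= 1 minute")
    lo = max(sensor.timestamps.min(), reference.timestamps.min())
    hi = min(sensor.timestamps.max(), reference.timestamps.max())
    if pd.isna(lo) or pd.isna(hi) or lo > hi:
        raise ValidationError("sensor and reference spans do not overlap")
    rule = f"{step}min"
    # include every sample of the last bin that both series touch
    end = hi.floor(rule) + pd.Timedelta(minutes=step)

    def to_bins(s: SensorSeries) -> pd.Series:
        data = s.data[(s.timestamps >= lo.floor(rule)) & (s.timestamps < end)]
        return data.groupby(data.index.floor(rule)).mean()

    sb = to_bins(sensor)
    rb = to_bins(reference)
    common = sb.index.intersection(rb.index)
    both = sb.loc[common].notna() & rb.loc[common].notna()
    common = common[both]
    expected = pd.date_range(lo.floor(rule), hi.floor(rule), freq=rule)
    presence = float(sb.notna().sum()) / max(len(expected), 1)
    return AlignedPair(sensor=sb.loc[common], reference=rb.loc[common],
                       step_min=step, presence=min(presence, 1.0))


def _pairs(pair: AlignedPair, min_n: int = 3):
    s = pair.sensor.to_numpy(dtype=float)
    r = pair.reference.to_numpy(dtype=float)
    if len(s) < min_n:
        raise ValidationError(f"need >= {min_n} pairs, got {len(s)}")
    return s, r


def rmse(pair: AlignedPair) -> float:
    s, r = _pairs(pair, 1)
    return float(np.sqrt(np.mean((s - r) ** 2)))


def _corr(fun, pair: AlignedPair) -> float:
    s, r = _pairs(pair)
    if np.std(s) == 0 or np.std(r) == 0:
        return float("nan")  # undefined for a constant series
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(fun(s, r)[0])


def pearson(pair: AlignedPair) -> float:
    return _corr(stats.pearsonr, pair)


def kendall(pair: AlignedPair) -> float:
    return _corr(stats.kendalltau, pair)


def spearman(pair: AlignedPair) -> float:
    return _corr(stats.spearmanr, pair)


def match_score(pair: AlignedPair, threshold: float | None = None) -> float:
    """Fraction of pairs agreeing on exceeding the threshold.

    Default threshold: the reference series' 90th percentile.  If nothing
    exceeds the threshold on either side the score is trivially 1 (warned).
    """
    s, r = _pairs(pair, 1)
    if threshold is None:
        threshold = float(np.percentile(r, 90))
    se = s > threshold
    re = r > threshold
    if not se.any() and not re.any():
        warnings.warn("match_score: threshold above all values; score 1",
                      stacklevel=2)
        return 1.0
    return float(np.mean(se == re))


def lfe(pair: AlignedPair, cutoff_period_min: float = 60.0) -> float:
    """1 − normalized low-frequency power of the error signal.

    The error (sensor − reference) periodogram is integrated below the
    cutoff frequency 1/cutoff_period (DC excluded; a constant offset is
    RMSE's business); zero total error power scores 1.
    """
    s, r = _pairs(pair, 1)
    n = len(s)
    if n < 2 * cutoff_period_min / pair.step_min:
        return float("nan")
    err = s - r
    freqs, power = signal.periodogram(err, fs=1.0 / pair.step_min)
    freqs, power = freqs[1:], power[1:]  # drop DC
    total = power.sum()
    if total == 0:
        return 1.0
    low = power[freqs < 1.0 / cutoff_period_min].sum()
    return float(1.0 - low / total)


def evaluate_pair(pair: AlignedPair,
                  match_threshold: float | None = None,
                  lfe_cutoff_min: float = 60.0) -> dict:
    """All seven metrics for an aligned pair (NaN where undefined)."""
    out = {
        "rmse": rmse(pair),
        "pearson": pearson(pair),
        "kendall": kendall(pair),
        "spearman": spearman(pair),
        "presence": pair.presence,
        "match_score": match_score(pair, match_threshold),
        "lfe": lfe(pair, lfe_cutoff_min),
    }
    return out


def ipi(metrics: dict, weights: dict | None = None,
        rmse_scale: float | None = None) -> float:
    """Aggregate metric dict into the [0, 1] performance index.

    ``rmse_scale`` (default: caller should pass the reference IQR) maps
    RMSE to 1/(1 + rmse/scale); correlations map via (r+1)/2; presence,
    match score and LFE are already in [0, 1].  Undefined (NaN) metrics
    are excluded from the weighted mean.
    """
    weights = {m: weights.get(m, 0.0) for m in METRICS} if weights \
        else {m: 1.0 for m in METRICS}
    mapped = {}
    for m in METRICS:
        v = metrics.get(m, float("nan"))
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if m == "rmse":
            scale = rmse_scale if rmse_scale and rmse_scale > 0 else 1.0
            mapped[m] = 1.0 / (1.0 + v / scale)
        elif m in ("pearson", "kendall", "spearman"):
            mapped[m] = (v + 1.0) / 2.0
        else:
            mapped[m] = float(v)
    wsum = sum(weights[m] for m in mapped)
    if not mapped or wsum == 0:
        raise ValidationError("no defined metrics to aggregate")
    return float(sum(weights[m] * mapped[m] for m in mapped) / wsum)


def evaluate_sensor(sensor: SensorSeries, reference: SensorSeries,
                    step: int = 1, weights: dict | None = None,
                    match_threshold: float | None = None,
                    lfe_cutoff_min: float = 60.0) -> dict:
    """Full qualification report: the seven metrics plus the IPI."""
    pair = align(sensor, reference, step)
    report = evaluate_pair(pair, match_threshold, lfe_cutoff_min)
    ref = pair.reference.to_numpy()
    iqr = float(np.percentile(ref, 75) - np.percentile(ref, 25))
    report["ipi"] = ipi(report, weights=weights,
                        rmse_scale=iqr if iqr > 0 else None)
    report["n_pairs"] = len(pair)
    report["step_min"] = step
    return report
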