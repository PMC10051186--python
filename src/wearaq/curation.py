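"""Pre-processing of raw wearable-sensor data.

The chain removes, in a frozen order, the artifact classes that low-cost
portable monitors exhibit:

1. warm-up trim — electrochemical NO₂ cells read high for the first few
   minutes after power-on, so the first ``warmup_minutes`` after every
   power-on boundary (a gap longer than ``gap_threshold_min``) are dropped;
2. physical range filter per channel;
3. black-carbon floor — filter-based BC readings may go slightly negative
   from reference drift; small negatives are genuine variability and are
   kept, values below the floor (−1500 ng/m³, three times the noise SD at
   background, i.e. the detection limit) are removed;
4. windowed peak rule — a value is an artifact spike when it exceeds
   ``f`` times the mean of its neighbours within ``k`` minutes on each
   side (the value itself excluded); range and floor run first so that
   invalid excursions cannot poison the neighbour mean;
5. PM nesting — minutes where pm1 <= pm25 <= pm10 fails are discarded from
   all three channels;
6. GPS speed filter — a forward pass drops any point implying a travel
   speed above ``gps_vmax`` from the last retained point;
7. per-minute mean speed from the denoised track;
8. fusion into one per-minute table, labels attached from annotations.

Removed values become missing (they are never interpolated); every rule's
count enters a :class:`RemovalReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geo import haversine_km
from .core import (AnnotationSet, CHANNELS, ConfigError, FusedTable,
                   GpsTrack, PM_CHANNELS, SensorSeries, logger)

#: Channels the peak rule is applied to (pollutants; temperature and
#: humidity vary smoothly and their spikes are out-of-range events).
PEAK_CHANNELS = ("pm1", "pm25", "pm10", "no2", "bc")

DEFAULT_RANGE_LIMITS = {
    "no2": (0.0, 1000.0),
    "pm1": (0.0, 2000.0),
    "pm25": (0.0, 2000.0),
    "pm10": (0.0, 2000.0),
    "temperature": (-30.0, 60.0),
    "humidity": (0.0, 100.0),
}

RULES = ("warmup", "range", "peak", "bc_floor", "pm_order")


@dataclass
class CurationConfig:
    """Tunable thresholds of the curation chain."""

    k: int = 2                      # peak window half-width (minutes)
    f: float = 2.0                  # peak factor
    range_limits: dict = field(default_factory=lambda: dict(DEFAULT_RANGE_LIMITS))
    warmup_minutes: int = 3         # NO2 channel only
    gap_threshold_min: int = 10     # gap defining a power-on boundary
    bc_floor: float = -1500.0       # ng/m3
    gps_vmax: float = 130.0         # km/h

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.f <= 1:
            raise ConfigError("f must be > 1")
        if self.warmup_minutes < 0:
            raise ConfigError("warmup_minutes must be >= 0")
        if self.bc_floor >= 0:
            raise ConfigError("bc_floor must be negative")
        if self.gps_vmax <= 0:
            raise ConfigError("gps_vmax must be positive")
        for ch, (lo, hi) in self.range_limits.items():
            if lo >= hi:
                raise ConfigError(f"range limits for {ch}: min >= max")


@dataclass
class RemovalReport:
    """Per-channel, per-rule counts of removed values."""

    counts: dict = field(default_factory=dict)  # channel -> rule -> int
    input_values: int = 0
    gps_removed: int = 0
    gps_input: int = 0

    def add(self, channel: str, rule: str, n: int) -> None:
        if n:
            self.counts.setdefault(channel, {}).setdefault(rule, 0)
            self.counts[channel][rule] += int(n)

    def channel_removed(self, channel: str) -> int:
        return sum(self.counts.get(channel, {}).values())

    @property
    def total_removed(self) -> int:
        return sum(self.channel_removed(ch) for ch in self.counts)

    @property
    def fraction_removed(self) -> float:
        if self.input_values == 0:
            return 0.0
        return self.total_removed / self.input_values

    def to_dict(self) -> dict:
        return {
            "input_values": self.input_values,
            "removed_by_channel": {ch: dict(rules)
                                   for ch, rules in sorted(self.counts.items())},
            "total_removed": self.total_removed,
            "fraction_removed": self.fraction_removed,
            "gps_input": self.gps_input,
            "gps_removed": self.gps_removed,
        }


def detect_peaks(series: SensorSeries, k: int = 2, f: float = 2.0) -> np.ndarray:
    """Boolean mask of spike artifacts under the windowed-mean rule.

    Position ``i`` is flagged when ``s_i > f * mean({s_j : |j-i| <= k,
    j != i})`` over the non-missing in-bounds neighbours.  The rule is
    one-sided (high excursions only).  A position is only flaggable when it
    has at least ``max(k, 2)`` valid neighbours, so series boundaries and
    gappy windows do not produce spurious flags.

    Neighbourhood is positional (array index), which coincides with minutes
    on a contiguous minute grid.
    """
    if k < 1 or f <= 1:
        raise ConfigError("detect_peaks requires k >= 1 and f > 1")
    v = series.values
    n = len(v)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    finite = np.isfinite(v)
    vz = np.where(finite, v, 0.0)
    # windowed sums over [i-k, i+k] via cumulative sums, then remove self
    cs = np.concatenate([[0.0], np.cumsum(vz)])
    cn = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    lo = np.maximum(0, np.arange(n) - k)
    hi = np.minimum(n, np.arange(n) + k + 1)
    wsum = cs[hi] - cs[lo]
    wcnt = cn[hi] - cn[lo]
    nsum = wsum - vz
    ncnt = wcnt - finite.astype(np.int64)
    need = max(k, 2)
    ok = finite & (ncnt >= need)
    with np.errstate(invalid="ignore", divide="ignore"):
        nmean = np.where(ncnt > 0, nsum / np.maximum(ncnt, 1), np.nan)
        mask[ok] = v[ok] > f * nmean[ok]
    return mask


def apply_range_filter(series: SensorSeries,
                       limits: tuple[float, float]) -> tuple[SensorSeries, int]:
    """Remove values outside ``[min, max]`` (inclusive bounds)."""
    lo, hi = limits
    if lo >= hi:
        raise ConfigError("range limits: min >= max")
    v = series.values
    bad = np.isfinite(v) & ((v < lo) | (v > hi))
    out = series.data.copy()
    out[bad] = np.nan
    return series.replace(out), int(bad.sum())


def enforce_pm_ordering(pm1: SensorSeries, pm25: SensorSeries,
                        pm10: SensorSeries):
    """Discard minutes violating pm1 <= pm25 <= pm10 from all three channels.

    The rule fires only where all three values are present; a minute with a
    missing PM channel cannot be checked and is left alone.
    """
    df = pd.concat([pm1.data, pm25.data, pm10.data], axis=1,
                   keys=["pm1", "pm25", "pm10"])
    full = df.notna().all(axis=1)
    bad = full & ~((df["pm1"] <= df["pm25"]) & (df["pm25"] <= df["pm10"]))
    out = []
    for s in (pm1, pm25, pm10):
        data = s.data.copy()
        data[data.index.isin(df.index[bad])] = np.nan
        out.append(s.replace(data))
    return tuple(out), int(bad.sum())


def trim_warmup(series: SensorSeries, n: int,
                gap_threshold_min: int = 10,
                keep_placeholders: bool = False) -> tuple[SensorSeries, int]:
    """Remove the first ``n`` minutes after every power-on boundary.

    A boundary is the series start or any gap longer than
    ``gap_threshold_min`` minutes between consecutive samples.  With
    ``keep_placeholders`` the trimmed minutes stay in the index as missing
    values instead of being dropped — this is what :func:`curate` uses, so
    a second pass over already-curated data sees the same boundaries and
    removes nothing further (the count then only covers values that were
    actually present).
    """
    if n < 0:
        raise ConfigError("warmup minutes must be >= 0")
    if n == 0 or len(series) == 0:
        return series, 0
    ts = series.timestamps.asi8
    gap_ns = gap_threshold_min * 60 * 10**9
    starts = np.concatenate([[True], np.diff(ts) > gap_ns])
    seg_start = np.maximum.accumulate(np.where(starts, ts, np.iinfo(np.int64).min))
    drop = (ts - seg_start) < n * 60 * 10**9
    if keep_placeholders:
        data = series.data.copy()
        removed = int((drop & np.isfinite(series.values)).sum())
        data[drop] = np.nan
        return series.replace(data), removed
    kept = series.data[~drop]
    return series.replace(kept), int(drop.sum())


def floor_bc(series: SensorSeries,
             floor: float = -1500.0) -> tuple[SensorSeries, int]:
    """Remove BC values below the floor; small negatives are retained.

    The floor is inclusive: a value exactly at the floor stays.
    """
    if floor >= 0:
        raise ConfigError("bc floor must be negative")
    v = series.values
    bad = np.isfinite(v) & (v < floor)
    out = series.data.copy()
    out[bad] = np.nan
    return series.replace(out), int(bad.sum())


def denoise_gps(track: GpsTrack, vmax: float = 130.0) -> tuple[GpsTrack, int]:
    """Single forward pass dropping points implying speed > vmax (km/h).

    Speed is the haversine distance from the *last retained* point divided
    by the elapsed time.  A candidate with zero time delta but nonzero
    displacement is dropped (and logged): it cannot be ordered physically.
    """
    df = track.data
    n = len(df)
    if n <= 1:
        return track, 0
    ts = df.index.asi8 / 1e9
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    last = 0
    zero_dt = 0
    for i in range(1, n):
        d_km = float(haversine_km(lon[last], lat[last], lon[i], lat[i]))
        dt_h = (ts[i] - ts[last]) / 3600.0
        if dt_h <= 0:
            if d_km > 0:
                zero_dt += 1
                continue
            # co-located duplicate instant: keep silently
            keep[i] = True
            last = i
            continue
        if d_km / dt_h > vmax:
            continue
        keep[i] = True
        last = i
    if zero_dt:
        logger.info("gps denoise: dropped %d zero-dt displaced points", zero_dt)
    removed = int(n - keep.sum())
    return GpsTrack(df[keep], participant_id=track.participant_id), removed


def per_minute_speed(track: GpsTrack) -> SensorSeries:
    """Mean travel speed (km/h) per minute from consecutive-point segments.

    Each segment's speed is assigned to the minute containing its midpoint;
    minutes without any segment are absent (missing).
    """
    df = track.data
    if len(df) < 2:
        return SensorSeries("speed", pd.Series(dtype=float,
                                               index=pd.DatetimeIndex([], tz="UTC")),
                            participant_id=track.participant_id)
    ts = df.index.asi8
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    d_km = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt_h = np.diff(ts) / 3.6e12
    valid = dt_h > 0
    mid = pd.DatetimeIndex((ts[:-1] + np.diff(ts) // 2)[valid], tz="UTC")
    speed = pd.Series(d_km[valid] / dt_h[valid], index=mid.floor("min"))
    speed = speed.groupby(level=0).mean().sort_index()
    return SensorSeries("speed", speed, participant_id=track.participant_id)


def fuse(channels: list[SensorSeries],
         speed: SensorSeries | None = None,
         positions: GpsTrack | None = None,
         annotations: AnnotationSet | None = None,
         participant_id: str = "") -> FusedTable:
    """Join per-minute channels into one table.

    A row is kept whenever at least one of the seven measured channels has a
    value; speed and GPS position ride along but do not create rows on their
    own.  Labels come from the covering annotation interval.
    """
    if annotations is not None:
        annotations.validate()
    cols = {}
    for s in channels:
        if s.channel in cols:
            raise ConfigError(f"duplicate channel {s.channel}")
        cols[s.channel] = s.data
    df = pd.DataFrame(cols)
    df = df.reindex(columns=list(CHANNELS))
    df = df[df.notna().any(axis=1)]
    if speed is not None and len(speed):
        df["speed"] = speed.data.reindex(df.index)
    if positions is not None and len(positions):
        pos = positions.data.copy()
        pos.index = pos.index.floor("min")
        pos = pos.groupby(level=0).mean()  # sub-minute samples -> centroid
        df["lon"] = pos["lon"].reindex(df.index)
        df["lat"] = pos["lat"].reindex(df.index)
    if annotations is not None:
        df["label"] = annotations.label_minutes(df.index)
    return FusedTable(df, participant_id=participant_id)


@dataclass
class ParticipantBundle:
    """Raw inputs of one participant: channel series, GPS, annotations."""

    channels: list
    gps: GpsTrack | None = None
    annotations: AnnotationSet | None = None
    participant_id: str = ""


def curate(bundle: ParticipantBundle,
           config: CurationConfig | None = None) -> tuple[FusedTable, RemovalReport]:
    """Run the full curation chain on one participant's raw data."""
    config = config or CurationConfig()
    report = RemovalReport()
    curated: dict[str, SensorSeries] = {}
    for s in bundle.channels:
        report.input_values += int(np.isfinite(s.values).sum())
        cur = s
        if s.channel == "no2":
            cur, n = trim_warmup(cur, config.warmup_minutes,
                                 config.gap_threshold_min,
                                 keep_placeholders=True)
            report.add(s.channel, "warmup", n)
        if s.channel in config.range_limits:
            cur, n = apply_range_filter(cur, config.range_limits[s.channel])
            report.add(s.channel, "range", n)
        if s.channel == "bc":
            # the floor precedes the peak rule for the same reason the
            # range filter does: a far-below-floor excursion drags the
            # neighbour mean towards zero and poisons the ratio test
            cur, n = floor_bc(cur, config.bc_floor)
            report.add(s.channel, "bc_floor", n)
        if s.channel in PEAK_CHANNELS:
            mask = detect_peaks(cur, config.k, config.f)
            data = cur.data.copy()
            data[mask] = np.nan
            cur = cur.replace(data)
            report.add(s.channel, "peak", int(mask.sum()))
        curated[s.channel] = cur
    if all(ch in curated for ch in PM_CHANNELS):
        (p1, p25, p10), n = enforce_pm_ordering(curated["pm1"],
                                                curated["pm25"],
                                                curated["pm10"])
        curated.update(pm1=p1, pm25=p25, pm10=p10)
        for ch in PM_CHANNELS:
            report.add(ch, "pm_order", n)
    speed = None
    gps = bundle.gps
    if gps is not None and len(gps):
        report.gps_input = len(gps)
        gps, report.gps_removed = denoise_gps(gps, config.gps_vmax)
        speed = per_minute_speed(gps)
    table = fuse(list(curated.values()), speed=speed, positions=gps,
                 annotations=bundle.annotations,
                 participant_id=bundle.participant_id)
    return table, report
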