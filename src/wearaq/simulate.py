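"""Synthetic multi-sensor campaign generator.

Emulates the data structure of a wearable personal-exposure campaign:
participants carry per-minute PM/NO₂/BC/temperature/humidity sensors plus
GPS while moving through five microenvironments (home, office, indoor,
outdoor, transport).  The generator produces

* a semi-Markov environment schedule whose long-run occupancy matches
  requested fractions (default: home 68%, office 24%, indoor 3%,
  outdoor 1%, transport 4%), with nights (00-06 local) spent at home;
* per-minute channel values drawn from environment-conditional log-normal
  baselines with AR(1) persistence plus occasional decaying pollution
  peaks (cooking, traffic) that are *real* signal, not artifacts;
* PM channels generated jointly (pm25 = pm1·(1+u₁), pm10 = pm25·(1+u₂),
  u ≥ 0) so clean data is nested by construction;
* GPS at one-minute cadence: jittered fixed sites for stationary bouts,
  bridge paths at a target speed for transport, a slow walk outdoors;
* injected sensor artifacts (single-minute spikes, out-of-range glitches,
  PM-order violations, below-floor BC dips, warm-up bias after power-on,
  block dropouts, GPS teleports), each recorded in a ground-truth ledger
  so curation recall is measurable.

All randomness flows from the explicit ``seed``; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geo import offset_lonlat
from .core import (AnnotationSet, CHANNELS, ConfigError, DEFAULT_TZ,
                   ENVIRONMENTS, GpsTrack, SensorSeries)
from .curation import ParticipantBundle

MINUTE = pd.Timedelta(minutes=1)

DEFAULT_OCCUPANCY = {"home": 0.68, "office": 0.24, "indoor": 0.03,
                     "outdoor": 0.01, "transport": 0.04}

DEFAULT_MEAN_BOUT = {"home": 300.0, "office": 240.0, "indoor": 45.0,
                     "outdoor": 30.0, "transport": 25.0}

#: Default campaign start: a Monday midnight, Paris time, autumn.
DEFAULT_START = "2019-11-04 00:00"

#: Versailles town centre.
DEFAULT_ORIGIN = (2.130, 48.801)


@dataclass
class EnvironmentSchedule:
    """Contiguous, non-overlapping labelled intervals covering the span."""

    intervals: pd.DataFrame  # columns start, end, label (UTC)
    tz: str = DEFAULT_TZ

    def __post_init__(self):
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise ConfigError("schedule interval with start >= end")
        if len(df) > 1 and not (df["start"].values[1:] == df["end"].values[:-1]).all():
            raise ConfigError("schedule intervals must be contiguous")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def start(self) -> pd.Timestamp:
        return self.intervals["start"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.intervals["end"].iloc[-1]

    def minute_labels(self) -> pd.Series:
        """Environment of every minute in the span."""
        idx = pd.date_range(self.start, self.end - MINUTE, freq="min")
        out = pd.Series(index=idx, dtype=object)
        for start, end, label in self.intervals.itertuples(index=False):
            out[(idx >= start) & (idx < end)] = label
        return out

    def occupancy(self) -> dict:
        """Realized fraction of time per environment."""
        dur = (self.intervals["end"] - self.intervals["start"]).dt.total_seconds()
        total = dur.sum()
        agg = dur.groupby(self.intervals["label"]).sum() / total
        return agg.to_dict()

    def to_annotations(self, participant_id: str = "") -> AnnotationSet:
        return AnnotationSet(self.intervals.copy(), participant_id=participant_id)


@dataclass
class EmissionModel:
    """Environment-conditional generative model for the measured channels.

    ``baseline_mean[env][channel]`` is the arithmetic mean of the clean
    baseline.  Concentrations are log-normal (log-SD ``sigma_log``) with
    AR(1) persistence ``rho``; temperature and humidity are Gaussian with
    SD ``sigma_abs``.  ``spike_rate[env][channel]`` (events/hour) adds
    decaying pollution peaks of mean relative magnitude ``spike_magnitude``
    and e-folding time ``spike_tau_min`` — genuine exposure, not artifacts.
    ``speed_kmh[env]`` sets the GPS motion regime.
    """

    baseline_mean: dict = field(default_factory=lambda: {
        #            temp   hum   pm1   pm25  pm10  no2    bc
        "home":      {"temperature": 21.0, "humidity": 45.0, "pm1": 5.0,
                      "pm25": 7.0, "pm10": 9.0, "no2": 18.0, "bc": 800.0},
        "office":    {"temperature": 23.0, "humidity": 38.0, "pm1": 4.0,
                      "pm25": 5.5, "pm10": 7.5, "no2": 28.0, "bc": 850.0},
        "indoor":    {"temperature": 19.0, "humidity": 50.0, "pm1": 16.0,
                      "pm25": 24.0, "pm10": 32.0, "no2": 30.0, "bc": 1600.0},
        "outdoor":   {"temperature": 10.0, "humidity": 70.0, "pm1": 9.0,
                      "pm25": 12.0, "pm10": 16.0, "no2": 25.0, "bc": 2000.0},
        "transport": {"temperature": 15.0, "humidity": 55.0, "pm1": 8.0,
                      "pm25": 11.0, "pm10": 15.0, "no2": 45.0, "bc": 1700.0},
    })
    sigma_log: dict = field(default_factory=lambda: {
        "pm1": 0.30, "pm25": 0.30, "pm10": 0.30, "no2": 0.25, "bc": 0.30})
    sigma_abs: dict = field(default_factory=lambda: {
        "temperature": 0.8, "humidity": 3.0})
    rho: float = 0.85
    # the "pm1" key drives one joint event process for all PM sizes
    spike_rate: dict = field(default_factory=lambda: {
        "home": {"pm1": 0.15, "no2": 0.1, "bc": 0.1},
        "office": {"pm1": 0.05, "no2": 0.05, "bc": 0.05},
        "indoor": {"pm1": 0.4, "no2": 0.2, "bc": 0.3},
        "outdoor": {"no2": 0.3, "bc": 0.3},
        "transport": {"no2": 0.5, "bc": 0.5},
    })
    spike_magnitude: float = 1.5    # mean peak height, × baseline mean
    spike_tau_min: float = 8.0
    pm_ratio_25_1: float = 1.45     # mean pm25/pm1
    pm_ratio_10_25: float = 1.30    # mean pm10/pm25
    speed_kmh: dict = field(default_factory=lambda: {
        "home": 0.0, "office": 0.0, "indoor": 0.0,
        "outdoor": 4.0, "transport": 22.0})

    def __post_init__(self):
        if not all(v > 0 for v in self.sigma_log.values()):
            raise ConfigError("sigma_log values must be positive")
        if not all(v > 0 for v in self.sigma_abs.values()):
            raise ConfigError("sigma_abs values must be positive")
        if any(r < 0 for env in self.spike_rate.values() for r in env.values()):
            raise ConfigError("spike rates must be >= 0")
        if self.speed_kmh["transport"] <= self.speed_kmh["outdoor"]:
            raise ConfigError("transport mean speed must exceed outdoor")


@dataclass
class ArtifactModel:
    """Sensor-fault injection parameters; all faults are ledger-recorded.

    The defaults describe a moderately misbehaving low-cost sensor kit and
    drive the curation chain's removal fraction into the percent range.
    """

    spike_rate_per_hour: float = 1.0    # per pollutant channel
    spike_factor: float = 8.0           # multiplicative single-minute spike
    glitch_prob: float = 0.04           # out-of-range electrical glitch
    pm_disorder_prob: float = 0.10      # pm1 > pm10 swap fault
    bc_dip_prob: float = 0.05           # below-floor BC excursion
    bc_noise_sd: float = 150.0          # ng/m3, zero-mean instrument noise
    dropout_rate_per_day: float = 3.0   # block dropouts per channel
    dropout_mean_min: float = 25.0
    warmup_bias: float = 80.0           # ug/m3 added to NO2 after power-on
    warmup_len_min: int = 3
    gps_jitter_m: float = 10.0
    gps_teleport_prob: float = 0.002

    def __post_init__(self):
        for name in ("glitch_prob", "pm_disorder_prob", "bc_dip_prob",
                     "gps_teleport_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.spike_rate_per_hour < 0 or self.dropout_rate_per_day < 0:
            raise ConfigError("rates must be >= 0")
        if self.warmup_len_min < 0 or self.dropout_mean_min < 0:
            raise ConfigError("lengths must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactModel":
        """A perfectly behaved sensor kit (clean limit)."""
        return cls(spike_rate_per_hour=0.0, glitch_prob=0.0,
                   pm_disorder_prob=0.0, bc_dip_prob=0.0, bc_noise_sd=0.0,
                   dropout_rate_per_day=0.0, warmup_bias=0.0,
                   gps_teleport_prob=0.0)


NIGHT_END_MIN = 6 * 60  # forced-home night window: 00:00-06:00 local


def generate_schedule(duration_days: float,
                      occupancy: dict | None = None,
                      mean_bout: dict | None = None,
                      seed: int = 0,
                      start: str = DEFAULT_START,
                      tz: str = DEFAULT_TZ,
                      home_nights: bool = True) -> EnvironmentSchedule:
    """Semi-Markov environment schedule matching requested occupancy.

    Bout durations are Gamma-distributed (shape 2) around per-environment
    means; the next environment is the one with the largest remaining
    time deficit, which makes realized fractions converge to the request.
    With ``home_nights`` the 00:00-06:00 local window is spent at home
    (requires a home fraction of at least 0.25 to stay recoverable).
    """
    occupancy = dict(DEFAULT_OCCUPANCY if occupancy is None else occupancy)
    mean_bout = dict(DEFAULT_MEAN_BOUT if mean_bout is None else mean_bout)
    if abs(sum(occupancy.values()) - 1.0) > 1e-9:
        raise ConfigError("occupancy fractions must sum to 1")
    if any(f < 0 for f in occupancy.values()):
        raise ConfigError("occupancy fractions must be >= 0")
    bad = set(occupancy) - set(ENVIRONMENTS)
    if bad:
        raise ConfigError(f"unknown environments {sorted(bad)}")
    if any(mean_bout.get(e, 1.0) < 1 for e in occupancy):
        raise ConfigError("mean bouts must be >= 1 minute")
    active = [e for e in ENVIRONMENTS if occupancy.get(e, 0.0) > 0]
    if not active:
        raise ConfigError("no environment with positive occupancy")
    rng = np.random.default_rng(seed)
    total = int(round(duration_days * 1440))
    if total < 1:
        raise ConfigError("duration must cover at least one minute")
    home_nights = home_nights and occupancy.get("home", 0.0) > 0
    accrued = {e: 0.0 for e in active}
    bouts: list[tuple[int, str]] = []  # (duration_min, label)
    t = 0
    prev = None
    while t < total:
        tod = t % 1440
        if home_nights and tod < NIGHT_END_MIN:
            dur = min(NIGHT_END_MIN - tod, total - t)
            label = "home"
        else:
            until_night = (1440 - tod) if home_nights else (total - t)
            candidates = [e for e in active if e != prev] or active
            deficits = {e: occupancy[e] * total - accrued[e] for e in candidates}
            label = max(deficits,
                        key=lambda e: (deficits[e], rng.random()))
            draw = rng.gamma(2.0, mean_bout.get(label, 30.0) / 2.0)
            dur = int(round(min(draw, max(deficits[label], 1.0))))
            dur = max(1, min(dur, until_night, total - t))
        accrued[label] = accrued.get(label, 0.0) + dur
        if bouts and bouts[-1][1] == label:
            bouts[-1] = (bouts[-1][0] + dur, label)
        else:
            bouts.append((dur, label))
        prev = label
        t += dur
    t0 = pd.Timestamp(start, tz=tz).tz_convert("UTC")
    edges = np.concatenate([[0], np.cumsum([d for d, _ in bouts])])
    df = pd.DataFrame({
        "start": [t0 + int(a) * MINUTE for a in edges[:-1]],
        "end": [t0 + int(b) * MINUTE for b in edges[1:]],
        "label": [lab for _, lab in bouts],
    })
    return EnvironmentSchedule(df, tz=tz)


@dataclass
class SyntheticTraces:
    """Output bundle of :func:`generate_traces`."""

    channels: list            # list[SensorSeries], clean order = CHANNELS
    gps: GpsTrack
    annotations: AnnotationSet
    artifact_ledger: pd.DataFrame  # columns timestamp, channel, kind
    sites: dict               # env -> (lon, lat) used for GPS

    def bundle(self, participant_id: str = "") -> ParticipantBundle:
        return ParticipantBundle(channels=self.channels, gps=self.gps,
                                 annotations=self.annotations,
                                 participant_id=participant_id)


def _ar1(rng, n, sd, rho):
    if n == 0:
        return np.zeros(0)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov[i - 1]
    return e

def generate_traces(schedule: EnvironmentSchedule,
                    emission: EmissionModel | None = None,
                    artifacts: ArtifactModel | None = None,
                    seed: int = 0,
                    participant_id: str = "p01",
                    origin: tuple[float, float] = DEFAULT_ORIGIN) -> SyntheticTraces:
    """Draw per-minute sensor channels, GPS and annotations for a schedule."""
    emission = emission or EmissionModel()
    artifacts = artifacts or ArtifactModel()
    rng = np.random.default_rng(seed)
    labels = schedule.minute_labels()
    idx = labels.index
    lab = labels.to_numpy()
    n = len(idx)
    ledger_rows: list[tuple] = []

    # --- clean channel baselines -----------------------------------------
    values: dict[str, np.ndarray] = {}
    for ch in ("temperature", "humidity"):
        mean = np.array([emission.baseline_mean[e][ch] for e in lab])
        values[ch] = mean + _ar1(rng, n, emission.sigma_abs[ch], emission.rho)
    for ch in ("pm1", "no2", "bc"):
        mean = np.array([emission.baseline_mean[e][ch] for e in lab])
        sig = emission.sigma_log[ch]
        mu = np.log(mean) - sig**2 / 2.0
        values[ch] = np.exp(mu + _ar1(rng, n, sig, emission.rho))
    # --- environmental pollution peaks (real exposure, kept out of ledger).
    #     PM peaks are attached to pm1 (keyed "pm1") *before* the nested
    #     pm25/pm10 construction, so one cooking event lifts all PM sizes
    #     jointly and nesting survives.
    for ch in ("pm1", "no2", "bc"):
        rate = np.array([emission.spike_rate.get(e, {}).get(ch, 0.0)
                         for e in lab]) / 60.0
        onsets = np.flatnonzero(rng.random(n) < rate)
        if len(onsets) == 0:
            continue
        tau = emission.spike_tau_min
        horizon = int(5 * tau)
        decay = np.exp(-np.arange(horizon + 1) / tau)
        add = np.zeros(n)
        for t0 in onsets:
            amp = (emission.spike_magnitude
                   * emission.baseline_mean[lab[t0]][ch]
                   * rng.lognormal(0.0, 0.4))
            stop = min(n, t0 + horizon + 1)
            add[t0:stop] += amp * decay[:stop - t0]
        values[ch] = values[ch] + add

    # nested PM by construction: pm25 = pm1*(1+u1), pm10 = pm25*(1+u2)
    r25 = np.array([emission.baseline_mean[e]["pm25"]
                    / emission.baseline_mean[e]["pm1"] for e in lab])
    r10 = np.array([emission.baseline_mean[e]["pm10"]
                    / emission.baseline_mean[e]["pm25"] for e in lab])
    g1 = rng.gamma(6.0, 1.0 / 6.0, size=n)
    g2 = rng.gamma(6.0, 1.0 / 6.0, size=n)
    u1 = np.maximum(r25 - 1.0, 0.0) * g1
    u2 = np.maximum(r10 - 1.0, 0.0) * g2
    values["pm25"] = values["pm1"] * (1.0 + u1)
    values["pm10"] = values["pm25"] * (1.0 + u2)

    # --- instrument noise (BC) -------------------------------------------
    if artifacts.bc_noise_sd > 0:
        values["bc"] = values["bc"] + rng.normal(0.0, artifacts.bc_noise_sd, n)

    # --- block dropouts (drawn first: the artifact ledger only records
    #     faults at minutes that actually reach the output) ----------------
    masks: dict[str, np.ndarray] = {}
    p_drop = artifacts.dropout_rate_per_day / 1440.0
    for ch in CHANNELS:
        keep = np.ones(n, dtype=bool)
        if p_drop > 0 and artifacts.dropout_mean_min > 0:
            starts = np.flatnonzero(rng.random(n) < p_drop)
            for t0 in starts:
                ln = 1 + rng.geometric(1.0 / artifacts.dropout_mean_min)
                keep[t0:t0 + ln] = False
        masks[ch] = keep

    # --- artifact injection ----------------------------------------------
    p_spike = artifacts.spike_rate_per_hour / 60.0
    for ch in ("pm1", "pm25", "pm10", "no2", "bc"):
        if p_spike > 0:
            hit = (rng.random(n) < p_spike) & masks[ch]
            values[ch] = np.where(hit, values[ch] * artifacts.spike_factor,
                                  values[ch])
            ledger_rows += [(idx[i], ch, "spike") for i in np.flatnonzero(hit)]
    glitch_value = {"temperature": 99.0, "humidity": 150.0,
                    "no2": 1500.0, "pm1": 3000.0, "pm25": 3000.0,
                    "pm10": 3000.0}
    if artifacts.glitch_prob > 0:
        for ch, gval in glitch_value.items():
            hit = (rng.random(n) < artifacts.glitch_prob) & masks[ch]
            values[ch] = np.where(hit, gval * (1 + rng.random(n)), values[ch])
            ledger_rows += [(idx[i], ch, "glitch") for i in np.flatnonzero(hit)]
    if artifacts.pm_disorder_prob > 0:
        hit = (rng.random(n) < artifacts.pm_disorder_prob) & masks["pm1"]
        values["pm1"] = np.where(hit, values["pm10"] * 1.5, values["pm1"])
        for i in np.flatnonzero(hit):
            ledger_rows.append((idx[i], "pm1", "pm_disorder"))
    if artifacts.bc_dip_prob > 0:
        hit = (rng.random(n) < artifacts.bc_dip_prob) & masks["bc"]
        dips = -2000.0 - rng.exponential(500.0, n)
        values["bc"] = np.where(hit, dips, values["bc"])
        ledger_rows += [(idx[i], "bc", "bc_dip") for i in np.flatnonzero(hit)]
    if artifacts.warmup_bias > 0 and artifacts.warmup_len_min > 0:
        keep = masks["no2"]
        kept_idx = np.flatnonzero(keep)
        if len(kept_idx):
            gaps = np.diff(kept_idx)
            starts = kept_idx[np.concatenate([[True], gaps > 10])]
            for t0 in starts:
                sel = kept_idx[(kept_idx >= t0)
                               & (kept_idx < t0 + artifacts.warmup_len_min)]
                values["no2"][sel] += artifacts.warmup_bias
                ledger_rows += [(idx[i], "no2", "warmup") for i in sel]

    channels = []
    for ch in CHANNELS:
        data = pd.Series(values[ch][masks[ch]], index=idx[masks[ch]])
        channels.append(SensorSeries(ch, data, participant_id=participant_id,
                                     sensor_id=f"sim-{ch}"))

    gps, sites = _generate_gps(schedule, emission, artifacts, rng,
                               participant_id, origin, ledger_rows)
    ledger = pd.DataFrame(ledger_rows, columns=["timestamp", "channel", "kind"])
    return SyntheticTraces(channels=channels, gps=gps,
                           annotations=schedule.to_annotations(participant_id),
                           artifact_ledger=ledger, sites=sites)


def _generate_gps(schedule, emission, artifacts, rng, participant_id,
                  origin, ledger_rows):
    """Per-minute positions: jittered sites, bridge paths, teleport faults."""
    lon0, lat0 = origin
    sites = {
        "home": offset_lonlat(lon0, lat0, rng.uniform(-800, 800),
                              rng.uniform(-800, 800)),
        "office": offset_lonlat(lon0, lat0, rng.uniform(2000, 4000),
                                rng.uniform(-1500, 1500)),
        "indoor": offset_lonlat(lon0, lat0, rng.uniform(-1500, 0),
                                rng.uniform(500, 1500)),
        "outdoor": offset_lonlat(lon0, lat0, rng.uniform(-1200, 1200),
                                 rng.uniform(-2500, -1000)),
    }
    iv = schedule.intervals
    anchor = []  # stationary site per interval (transport bridges later)
    for _, _, label in iv.itertuples(index=False):
        anchor.append(sites.get(label))
    xs, ys, ts = [], [], []
    for i, (start, end, label) in enumerate(iv.itertuples(index=False)):
        m = int((end - start) / MINUTE)
        times = pd.date_range(start, periods=m, freq="min")
        if label in ("home", "office", "indoor"):
            site = anchor[i]
            dx = rng.normal(0.0, artifacts.gps_jitter_m, m)
            dy = rng.normal(0.0, artifacts.gps_jitter_m, m)
            lon, lat = offset_lonlat(site[0], site[1], dx, dy)
        elif label == "outdoor":
            site = sites["outdoor"]
            step = emission.speed_kmh["outdoor"] * 1000.0 / 60.0
            walk = np.cumsum(rng.normal(0.0, step / np.sqrt(2), (m, 2)), axis=0)
            lon, lat = offset_lonlat(site[0], site[1],
                                     walk[:, 0] + rng.normal(0, artifacts.gps_jitter_m, m),
                                     walk[:, 1] + rng.normal(0, artifacts.gps_jitter_m, m))
        else:  # transport: bridge from previous to next stationary site
            a = next((anchor[j] for j in range(i - 1, -1, -1)
                      if anchor[j] is not None), sites["home"])
            b = next((anchor[j] for j in range(i + 1, len(anchor))
                      if anchor[j] is not None), sites["home"])
            lon, lat = _bridge_path(a, b, m, emission.speed_kmh["transport"],
                                    rng, artifacts.gps_jitter_m)
        xs.append(lon); ys.append(lat); ts.append(times)
    lon = np.concatenate(xs)
    lat = np.concatenate(ys)
    times = pd.DatetimeIndex(np.concatenate([t.asi8 for t in ts]), tz="UTC")
    if artifacts.gps_teleport_prob > 0:
        hit = rng.random(len(lon)) < artifacts.gps_teleport_prob
        tl, tlat = offset_lonlat(lon[hit], lat[hit],
                                 rng.uniform(8000, 30000, hit.sum())
                                 * rng.choice([-1, 1], hit.sum()),
                                 rng.uniform(8000, 30000, hit.sum())
                                 * rng.choice([-1, 1], hit.sum()))
        lon[hit], lat[hit] = tl, tlat
        ledger_rows += [(times[i], "gps", "teleport")
                        for i in np.flatnonzero(hit)]
    track = GpsTrack(pd.DataFrame({"lon": lon, "lat": lat}, index=times),
                     participant_id=participant_id)
    return track, sites


def _bridge_path(a, b, m, speed_kmh, rng, jitter_m):
    """m positions from a to b whose per-minute step length matches speed.

    A straight interpolation plus a lateral Brownian bridge sized so the
    travelled path length approximates speed × duration even when the two
    endpoints are close together.
    """
    from ._geo import local_xy_m
    ax, ay = 0.0, 0.0
    bx, by = local_xy_m(b[0], b[1], a[0], a[1])
    step_target = speed_kmh * 1000.0 / 60.0
    tgrid = np.linspace(0.0, 1.0, m + 1)[:m]
    base = np.stack([ax + (bx - ax) * tgrid, ay + (by - ay) * tgrid], axis=1)
    direct_step = np.hypot(bx - ax, by - ay) / max(m, 1)
    lat_sd = np.sqrt(max(step_target**2 - direct_step**2, 0.0))
    walk = np.cumsum(rng.normal(0.0, lat_sd, m))
    bridge = walk - tgrid * (walk[-1] if m else 0.0)
    # lateral unit vector
    norm = np.hypot(bx - ax, by - ay)
    if norm > 0:
        ux, uy = -(by - ay) / norm, (bx - ax) / norm
    else:
        ux, uy = 1.0, 0.0
    x = base[:, 0] + bridge * ux + rng.normal(0, jitter_m, m)
    y = base[:, 1] + bridge * uy + rng.normal(0, jitter_m, m)
    return offset_lonlat(a[0], a[1], x, y)


def generate_reference_pair(duration_days: float,
                            degradation: dict | None = None,
                            seed: int = 0,
                            channel: str = "pm25",
                            mean: float = 12.0) -> tuple[SensorSeries, SensorSeries]:
    """A collocation pair: reference instrument vs degraded sensor.

    degraded = gain·reference + bias + N(0, noise_sd), with a fraction
    ``missing_frac`` of minutes removed at random.
    """
    deg = {"bias": 0.0, "gain": 1.0, "noise_sd": 0.0, "missing_frac": 0.0}
    deg.update(degradation or {})
    if not 0.0 <= deg["missing_frac"] < 1.0:
        raise ConfigError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_days * 1440))
    idx = pd.date_range(pd.Timestamp(DEFAULT_START, tz=DEFAULT_TZ),
                        periods=n, freq="min").tz_convert("UTC")
    sig = 0.4
    ref = np.exp(np.log(mean) - sig**2 / 2 + _ar1(rng, n, sig, 0.95))
    reference = SensorSeries(channel, pd.Series(ref, index=idx),
                             sensor_id="reference")
    noisy = deg["gain"] * ref + deg["bias"]
    if deg["noise_sd"] > 0:
        noisy = noisy + rng.normal(0.0, deg["noise_sd"], n)
    keep = rng.random(n) >= deg["missing_frac"]
    degraded = SensorSeries(channel, pd.Series(noisy[keep], index=idx[keep]),
                            sensor_id="sensor")
    return reference, degraded


def generate_campaign(n_participants: int = 5,
                      duration_days: float = 7.0,
                      occupancy: dict | None = None,
                      emission: EmissionModel | None = None,
                      artifacts: ArtifactModel | None = None,
                      seed: int = 0):
    """Generate a list of participant bundles plus per-participant truths.

    Returns ``(bundles, truths)`` where each truth is the participant's
    :class:`SyntheticTraces` (schedule annotations, artifact ledger, sites).
    """
    root = np.random.SeedSequence(seed)
    bundles, truths = [], []
    for p, ss in enumerate(root.spawn(n_participants)):
        s1, s2 = ss.spawn(2)
        pid = f"p{p + 1:02d}"
        sched = generate_schedule(duration_days, occupancy=occupancy,
                                  seed=s1.generate_state(1)[0] % (2**31))
        traces = generate_traces(sched, emission=emission, artifacts=artifacts,
                                 seed=s2.generate_state(1)[0] % (2**31),
                                 participant_id=pid)
        bundles.append(traces.bundle(pid))
        truths.append(traces)
    return bundles, truths
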