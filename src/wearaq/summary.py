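"""Exposure statistics: multi-resolution summaries, per-environment
distributions, time budgets and 24-h guideline comparison.

Conventions pinned here (and config-exposed where sensible):

* percentiles use linear interpolation between order statistics;
* a participant-day enters daily statistics only when *more than*
  ``min_completeness`` (default 20%) of its 1440 minutes carry data —
  the boundary is excluded;
* hour-level statistics are two-stage: hourly means are computed first
  (any hour with >= 1 observation counts) and the Hour row's mean/SD/median
  are taken over those hourly means;
* daily statistics pool all participants' qualifying days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigError, FusedTable, ValidationError, logger

#: WHO 2021 24-hour ambient air quality guideline levels.
WHO_24H_GUIDELINES = {"no2": 25.0, "pm25": 15.0, "pm10": 45.0}


@dataclass
class GuidelineSet:
    """Channel -> 24-h guideline value (same units as the channel)."""

    values: dict = field(default_factory=lambda: dict(WHO_24H_GUIDELINES))

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise ConfigError("guideline values must be positive")


def daily_means(table: FusedTable, channel: str,
                min_completeness: float = 0.2) -> pd.Series:
    """Mean per (participant-)day over days with enough data.

    A day qualifies when observed_minutes / 1440 > min_completeness
    (strict).  Index: normalized day timestamps.
    """
    if not 0 < min_completeness <= 1:
        raise ConfigError("min_completeness must be in (0, 1]")
    s = table.frame[channel].dropna()
    if s.empty:
        return pd.Series(dtype=float)
    by_day = s.groupby(s.index.normalize())
    counts = by_day.count()
    means = by_day.mean()
    ok = counts / 1440.0 > min_completeness
    return means[ok]


def resolution_stats(table: FusedTable, channel: str,
                     min_completeness: float = 0.2) -> dict:
    """Day / Hour / Minute summary for one channel.

    * day_mean: mean of qualifying daily means;
    * hour_mean, hour_sd, hour_median: over hourly means;
    * minute_p95: 95th percentile of raw minute values.
    """
    s = table.frame[channel].dropna()
    if s.empty:
        raise ValidationError(f"no observations for {channel}")
    days = daily_means(table, channel, min_completeness)
    hourly = s.groupby(s.index.floor("h")).mean()
    return {
        "day_mean": float(days.mean()) if len(days) else float("nan"),
        "n_days": int(len(days)),
        "hour_mean": float(hourly.mean()),
        "hour_sd": float(hourly.std(ddof=1)) if len(hourly) > 1 else 0.0,
        "hour_median": float(hourly.median()),
        "minute_p95": float(np.percentile(s.to_numpy(), 95)),
        "n_minutes": int(len(s)),
    }


BOX_PERCENTILES = (10, 25, 50, 75, 90)


def box_stats(values: np.ndarray, labels: np.ndarray, channel: str,
              low_support: int = 30) -> pd.DataFrame:
    """Boxplot statistics per label over paired value/label arrays."""
    vals = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=object)
    ok = np.isfinite(vals) & pd.notna(lab)
    if not ok.any():
        raise ValidationError("no labelled observations")
    rows = []
    for env in sorted(set(lab[ok])):
        sub = vals[ok & (lab == env)]
        pcts = np.percentile(sub, BOX_PERCENTILES)
        rows.append({"env": env, "channel": channel, "n": len(sub),
                     **{f"p{p}": float(v) for p, v in zip(BOX_PERCENTILES, pcts)},
                     "mean": float(sub.mean()),
                     "low_support": len(sub) < low_support})
    return pd.DataFrame(rows).set_index("env")


def environment_stats(table: FusedTable, channel: str,
                      labels: pd.Series | None = None,
                      low_support: int = 30) -> pd.DataFrame:
    """Boxplot statistics (p10/p25/p50/p75/p90 + mean) per environment.

    ``labels`` overrides the table's own label column (e.g. to use final
    post-processed labels).  Environments with fewer than ``low_support``
    minutes are flagged.
    """
    df = table.frame
    lab = (labels.reindex(df.index) if labels is not None
           else df["label"]).astype(object)
    return box_stats(df[channel].to_numpy(), lab.to_numpy(), channel,
                     low_support)


def time_budget(labels: pd.Series) -> dict:
    """Fraction of labelled minutes per environment (sums to 1)."""
    lab = labels.dropna()
    if lab.empty:
        raise ValidationError("no labelled minutes")
    return (lab.value_counts(normalize=True)).to_dict()


def who_compare(daily: dict | pd.DataFrame,
                guidelines: GuidelineSet | None = None) -> dict:
    """Exceedance counts/fractions of daily means vs 24-h guidelines.

    ``daily`` maps channel -> Series of daily means (see
    :func:`daily_means`).  Channels without a guideline (pm1, bc — not
    regulated) are skipped with a note.
    """
    guidelines = guidelines or GuidelineSet()
    out = {}
    for channel, series in daily.items():
        if channel not in guidelines.values:
            out[channel] = {"skipped": True,
                            "note": "no 24-h guideline for this channel"}
            logger.info("who_compare: %s skipped (not regulated)", channel)
            continue
        g = guidelines.values[channel]
        flags = series > g
        out[channel] = {
            "guideline": g,
            "n_days": int(len(series)),
            "n_exceed": int(flags.sum()),
            "fraction_exceed": float(flags.mean()) if len(series) else 0.0,
        }
    return out


def exposure_summary(table: FusedTable, channels: list | None = None,
                     labels: pd.Series | None = None,
                     min_completeness: float = 0.2) -> dict:
    """One-stop summary: resolution stats, per-environment boxplot stats,
    time budget and guideline comparison, as a JSON-serializable dict."""
    from .core import CHANNELS
    channels = channels or [c for c in CHANNELS
                            if table.frame[c].notna().any()]
    lab = labels if labels is not None else table.frame["label"]
    out = {"channels": {}, "time_budget": {}, "who": {}}
    daily = {}
    for ch in channels:
        try:
            out["channels"][ch] = resolution_stats(table, ch, min_completeness)
        except ValidationError:
            continue
        daily[ch] = daily_means(table, ch, min_completeness)
        try:
            env = environment_stats(table, ch, labels=lab)
            out["channels"][ch]["by_environment"] = {
                str(e): {k: (v if not isinstance(v, np.bool_) else bool(v))
                         for k, v in row.items() if k != "channel"}
                for e, row in env.to_dict("index").items()}
        except ValidationError:
            pass
    if lab is not None and lab.notna().any():
        out["time_budget"] = {str(k): float(v)
                              for k, v in time_budget(lab).items()}
    out["who"] = who_compare(daily)
    return out


def pooled_exposure_summary(tables: dict, labels: dict | None = None,
                            channels: list | None = None,
                            min_completeness: float = 0.2) -> dict:
    """Campaign-wide summary pooling several participants' tables.

    Daily means pool participant-days; hour statistics pool per-participant
    hourly means; minute percentiles and per-environment stats pool raw
    minutes.  ``tables``/``labels`` map participant id -> FusedTable /
    final label Series (labels default to each table's own column).
    """
    from .core import CHANNELS
    if not tables:
        raise ValidationError("no tables to summarize")
    channels = channels or [
        c for c in CHANNELS
        if any(t.frame[c].notna().any() for t in tables.values())]
    out = {"channels": {}, "time_budget": {}, "who": {},
           "n_participants": len(tables)}
    daily = {}
    all_labels = []
    for pid, table in tables.items():
        lab = (labels[pid] if labels is not None
               else table.labels).reindex(table.frame.index)
        all_labels.append(lab)
    for ch in channels:
        days, hourly, minutes, env_vals, env_labs = [], [], [], [], []
        for (pid, table), lab in zip(tables.items(), all_labels):
            s = table.frame[ch].dropna()
            if s.empty:
                continue
            days.append(daily_means(table, ch, min_completeness))
            hourly.append(s.groupby(s.index.floor("h")).mean())
            minutes.append(s.to_numpy())
            l = lab.reindex(s.index)
            keep = l.notna().to_numpy()
            env_vals.append(s.to_numpy()[keep])
            env_labs.append(l.to_numpy()[keep])
        if not minutes:
            continue
        days_all = pd.concat(days) if days else pd.Series(dtype=float)
        hours_all = pd.concat(hourly)
        mins_all = np.concatenate(minutes)
        stats = {
            "day_mean": float(days_all.mean()) if len(days_all) else float("nan"),
            "n_days": int(len(days_all)),
            "hour_mean": float(hours_all.mean()),
            "hour_sd": float(hours_all.std(ddof=1)) if len(hours_all) > 1 else 0.0,
            "hour_median": float(hours_all.median()),
            "minute_p95": float(np.percentile(mins_all, 95)),
            "n_minutes": int(len(mins_all)),
        }
        ev = np.concatenate(env_vals) if env_vals else np.array([])
        el = np.concatenate(env_labs) if env_labs else np.array([])
        if len(ev):
            env = box_stats(ev, el, ch)
            stats["by_environment"] = {
                str(e): {k: (bool(v) if isinstance(v, np.bool_) else v)
                         for k, v in row.items() if k != "channel"}
                for e, row in env.to_dict("index").items()}
        out["channels"][ch] = stats
        daily[ch] = days_all
    pooled_lab = pd.concat(all_labels)
    if pooled_lab.notna().any():
        counts = pooled_lab.dropna().value_counts(normalize=True)
        out["time_budget"] = {str(k): float(v) for k, v in counts.items()}
    out["who"] = who_compare(daily)
    return out
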