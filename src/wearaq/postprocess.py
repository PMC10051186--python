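"""Rule-based correction of model-assigned environment labels.

Free-living classifier output is noisy at minute level even when bouts are
predicted correctly on the whole.  Three spatial/temporal rules clean it:

1. *Stop segmentation*: per-minute positions are binned on a local grid
   (default 100 m cells); minutes in high-density cells moving slowly are
   stop candidates, and runs of candidates become stop segments.  Within a
   stop segment the modal model label is propagated to every minute.
2. *Home rule*: the cell(s) with the highest position density between
   2 a.m. and 5 a.m. local time over the whole record define the home
   site; stop segments at the home site are relabelled ``home``.  (A
   participant sleeping elsewhere — a hotel week — would have that site
   identified as home; the rule is density-based, not semantic.)
3. *Label smoothing*: label runs shorter than ``min_bout`` minutes are
   absorbed into the adjoining longer run (earlier run on ties) until the
   series is stable.

Every rule reports how many minutes it changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geo import local_xy_m
from .core import DEFAULT_TZ, FusedTable, ValidationError


@dataclass
class PostprocessConfig:
    cell_m: float = 100.0
    stop_quantile: float = 0.9
    stop_speed_kmh: float = 5.0
    min_stop_min: int = 5
    min_bout_min: int = 3
    night_start_hour: int = 2
    night_end_hour: int = 5
    tz: str = DEFAULT_TZ


@dataclass
class DensityGrid:
    """Point counts per cell of a local equirectangular grid."""

    cell_m: float
    origin: tuple            # (lon, lat) of the projection origin
    counts: pd.Series        # index: MultiIndex (ix, iy), values: counts
    cell_of_minute: pd.Series  # minute -> (ix, iy); NaN-position minutes absent

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())


@dataclass
class Segment:
    start: pd.Timestamp
    end: pd.Timestamp        # exclusive
    label: object            # modal model label within the segment
    kind: str                # "stop" | "move"
    mean_lon: float = np.nan
    mean_lat: float = np.nan
    cell: tuple | None = None


def build_grid(table: FusedTable, cell_m: float = 100.0) -> DensityGrid:
    """Bin the table's located minutes on a cell_m grid around the centroid."""
    df = table.frame
    located = df[["lon", "lat"]].dropna()
    if located.empty:
        raise ValidationError("no located minutes to grid")
    origin = (float(located["lon"].mean()), float(located["lat"].mean()))
    x, y = local_xy_m(located["lon"], located["lat"], *origin)
    ix = np.floor(x / cell_m).astype(int)
    iy = np.floor(y / cell_m).astype(int)
    cells = pd.Series(list(zip(ix, iy)), index=located.index)
    counts = cells.value_counts().sort_index()
    return DensityGrid(cell_m=cell_m, origin=origin, counts=counts,
                       cell_of_minute=cells)


def _runs(values: np.ndarray):
    """(start, stop) index pairs of constant runs (stop exclusive)."""
    n = len(values)
    if n == 0:
        return []
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    edges = np.concatenate([[0], change, [n]])
    return list(zip(edges[:-1], edges[1:]))


def segment_stops(table: FusedTable, grid: DensityGrid,
                  config: PostprocessConfig | None = None) -> list[Segment]:
    """Tile the table's span into stop and move segments."""
    config = config or PostprocessConfig()
    df = table.frame
    idx = df.index
    dense_cut = grid.counts.quantile(config.stop_quantile)
    cell_count = grid.cell_of_minute.map(grid.counts).reindex(idx)
    in_dense = cell_count >= dense_cut
    speed = df["speed"]
    slow = speed.isna() | (speed <= config.stop_speed_kmh)
    candidate = (in_dense.fillna(False) & slow).to_numpy()
    segments: list[Segment] = []
    for a, b in _runs(candidate):
        is_stop = bool(candidate[a]) and (b - a) >= config.min_stop_min
        sub = df.iloc[a:b]
        labels = sub["label"].dropna()
        modal = labels.mode().iloc[0] if len(labels) else None
        cells = grid.cell_of_minute.reindex(sub.index).dropna()
        cell = cells.mode().iloc[0] if len(cells) else None
        segments.append(Segment(
            start=idx[a], end=idx[b - 1] + pd.Timedelta(minutes=1),
            label=modal, kind="stop" if is_stop else "move",
            mean_lon=float(sub["lon"].mean()), mean_lat=float(sub["lat"].mean()),
            cell=cell))
    # merge adjacent same-kind segments so stops/moves tile cleanly
    merged: list[Segment] = []
    for seg in segments:
        if merged and merged[-1].kind == seg.kind:
            prev = merged[-1]
            prev.end = seg.end
            if prev.label is None:
                prev.label = seg.label
        else:
            merged.append(seg)
    return merged


def night_home_cell(table: FusedTable, grid: DensityGrid,
                    config: PostprocessConfig | None = None):
    """Densest grid cell(s) between the night hours, local clock time."""
    config = config or PostprocessConfig()
    local = table.frame.index.tz_convert(config.tz)
    night = ((local.hour >= config.night_start_hour)
             & (local.hour < config.night_end_hour))
    cells = grid.cell_of_minute.reindex(table.frame.index)[night].dropna()
    if cells.empty:
        return []
    counts = cells.value_counts()
    return list(counts[counts == counts.max()].index)


def apply_home_rule(segments: list[Segment], table: FusedTable,
                    config: PostprocessConfig | None = None,
                    grid: DensityGrid | None = None) -> tuple[list[Segment], int]:
    """Relabel stop segments at the night-dense (home) cell(s).

    Returns the updated segments and the number of segments relabelled.
    If the record has no night-window positions the rule is skipped.
    """
    config = config or PostprocessConfig()
    if grid is None:
        grid = build_grid(table, config.cell_m)
    home_cells = night_home_cell(table, grid, config)
    if not home_cells:
        from .core import logger
        logger.warning("home rule skipped: no night-window positions")
        return segments, 0
    def at_home(cell) -> bool:
        # adjacency-tolerant match: a site jittering across a cell edge
        # still counts as the same place
        if cell is None:
            return False
        return any(max(abs(cell[0] - hx), abs(cell[1] - hy)) <= 1
                   for hx, hy in home_cells)

    changed = 0
    out = []
    for seg in segments:
        seg = Segment(**vars(seg))
        if seg.kind == "stop" and at_home(seg.cell) and seg.label != "home":
            seg.label = "home"
            changed += 1
        out.append(seg)
    return out, changed


def smooth_labels(labels: pd.Series, min_bout: int = 3) -> pd.Series:
    """Absorb label runs shorter than ``min_bout`` into the adjoining
    longer run (the earlier run on ties); iterated to a fixed point."""
    vals = labels.to_numpy(dtype=object).copy()
    while True:
        runs = _runs(vals)
        if len(runs) <= 1:
            break
        short = [(b - a, i) for i, (a, b) in enumerate(runs)
                 if b - a < min_bout]
        if not short:
            break
        # absorb the shortest offending run first (earliest on ties) so a
        # short run between two longer neighbours disappears before the
        # neighbours themselves are considered
        _, i = min(short)
        a, b = runs[i]
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i < len(runs) - 1 else None
        llen = left[1] - left[0] if left else -1
        rlen = right[1] - right[0] if right else -1
        target = left if llen >= rlen else right
        vals[a:b] = vals[target[0]]
    return pd.Series(vals, index=labels.index, dtype=object)


def postprocess(model_labels: pd.Series, table: FusedTable,
                config: PostprocessConfig | None = None):
    """Full correction pipeline; returns (final labels, change report).

    Stops are segmented from GPS density, each stop segment's modal model
    label is propagated within the segment, the home rule relabels the
    night-dense site, and short label runs are smoothed away.  Tables
    without GPS skip the spatial rules and only smooth.
    """
    config = config or PostprocessConfig()
    labels = model_labels.reindex(table.frame.index).copy()
    report = {"stop_segmentation": 0, "home_rule": 0, "smoothing": 0}
    has_gps = table.frame[["lon", "lat"]].notna().all(axis=1).any()
    if has_gps:
        grid = build_grid(table, config.cell_m)
        work = table.with_labels(labels)
        segments = segment_stops(work, grid, config)

        def propagate(segs, base):
            new = base.copy()
            for seg in segs:
                if seg.kind == "stop" and seg.label is not None:
                    sel = (new.index >= seg.start) & (new.index < seg.end)
                    new[sel & new.notna()] = seg.label
            return new

        after_stops = propagate(segments, labels)
        report["stop_segmentation"] = int(
            (after_stops != labels).fillna(False).sum())
        segments, _ = apply_home_rule(segments, work, config, grid)
        after_home = propagate(segments, after_stops)
        report["home_rule"] = int(
            (after_home != after_stops).fillna(False).sum())
        labels = after_home
    smoothed = smooth_labels(labels, config.min_bout_min)
    report["smoothing"] = int((smoothed != labels).fillna(False).sum())
    return smoothed, report
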