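"""Microenvironment classification by multi-view stacking.

Each of the eight per-minute channels (temperature, humidity, pm1, pm25,
pm10, no2, bc, speed) is a *view*.  For every minute, a trailing window of
W minutes of one channel is summarized into eight features (mean, SD, min,
max, median, IQR, slope, fraction missing).  A first-level learner is
trained per view on its feature block; a meta-learner is then trained on
the concatenation of every view's (predicted class, probability) pair —
16 numbers for 8 views — and emits the final environment label with a
confidence.  Meta-training uses out-of-fold first-level predictions
(K-fold stacking) so the meta-learner never sees resubstitution outputs.

A view with no observation in a minute's window is *absent*: at prediction
time it contributes a sentinel class index and a uniform probability.
Minutes where every view is absent get no label.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .core import (AnnotationSet, ConfigError, FUSED_CHANNELS, FusedTable,
                   ValidationError, logger)

VIEWS = FUSED_CHANNELS
VIEW_FEATURES = ("mean", "sd", "min", "max", "median", "iqr", "slope",
                 "frac_missing")


def _window_features(series: pd.Series, grid: pd.DatetimeIndex,
                     W: int) -> np.ndarray:
    """(len(grid), 8) feature matrix of trailing W-minute windows."""
    y = series.reindex(grid).to_numpy(dtype=float)
    pad = np.full(W - 1, np.nan)
    wins = sliding_window_view(np.concatenate([pad, y]), W)  # (n, W)
    finite = np.isfinite(wins)
    cnt = finite.sum(axis=1)
    out = np.full((len(grid), len(VIEW_FEATURES)), np.nan)
    has = cnt > 0
    if not has.any():
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out[has, 0] = np.nanmean(wins[has], axis=1)
        out[has, 1] = np.nanstd(wins[has], axis=1)
        out[has, 2] = np.nanmin(wins[has], axis=1)
        out[has, 3] = np.nanmax(wins[has], axis=1)
        out[has, 4] = np.nanmedian(wins[has], axis=1)
        q75, q25 = np.nanpercentile(wins[has], [75, 25], axis=1)
        out[has, 5] = q75 - q25
    # OLS slope over available points at their in-window offsets
    x = np.arange(W, dtype=float)
    xm = np.where(finite, x, 0.0)
    ym = np.where(finite, wins, 0.0)
    sx = xm.sum(axis=1)
    sy = ym.sum(axis=1)
    sxx = (xm * xm).sum(axis=1)
    sxy = (xm * ym).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = sxx - sx * sx / np.maximum(cnt, 1)
        slope = np.where((cnt >= 2) & (denom > 0),
                         (sxy - sx * sy / np.maximum(cnt, 1))
                         / np.where(denom > 0, denom, 1.0), 0.0)
    out[has, 6] = slope[has]
    out[has, 7] = 1.0 - cnt[has] / W
    return out


def extract_views(table: FusedTable, W: int = 15) -> pd.DataFrame:
    """Per-minute view features for every row of the fused table.

    Columns are ``{view}__{feature}``; an absent view (no observation in
    the trailing window) has all eight of its columns NaN.
    """
    if W < 1:
        raise ConfigError("window length W must be >= 1")
    df = table.frame
    if len(df) == 0:
        cols = [f"{v}__{f}" for v in VIEWS for f in VIEW_FEATURES]
        return pd.DataFrame(columns=cols, index=df.index)
    grid = pd.date_range(df.index.min(), df.index.max(), freq="min")
    pos = grid.get_indexer(df.index)
    blocks = []
    for view in VIEWS:
        feats = _window_features(df[view], grid, W)[pos]
        blocks.append(pd.DataFrame(
            feats, index=df.index,
            columns=[f"{view}__{f}" for f in VIEW_FEATURES]))
    return pd.concat(blocks, axis=1)


@dataclass
class ModelConfig:
    """Learner family and stacking hyper-parameters."""

    family: str = "rf"          # "rf" (random forest) or "gbt"
    n_estimators: int = 80
    max_depth: int | None = None
    window_minutes: int = 15
    stacking_folds: int = 5

    def __post_init__(self):
        if self.family not in ("rf", "gbt"):
            raise ConfigError("family must be 'rf' or 'gbt'")
        if self.stacking_folds < 2:
            raise ConfigError("stacking needs >= 2 folds")


def _make_learner(config: ModelConfig, seed: int):
    if config.family == "rf":
        return RandomForestClassifier(n_estimators=config.n_estimators,
                                      max_depth=config.max_depth,
                                      random_state=seed, n_jobs=1)
    return HistGradientBoostingClassifier(max_iter=config.n_estimators,
                                          max_depth=config.max_depth,
                                          random_state=seed)


@dataclass
class EnvironmentModel:
    """Fitted first-level view learners + meta-learner."""

    view_learners: dict                 # view -> fitted classifier
    meta_learner: object
    classes: list
    config: ModelConfig
    seed: int
    class_counts: dict = field(default_factory=dict)
    version: str = "1"

    @property
    def sentinel(self) -> int:
        """Class index reserved for an absent view."""
        return len(self.classes)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "EnvironmentModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ValidationError("file does not contain an EnvironmentModel")
        return model


def _meta_inputs(features: pd.DataFrame, view_learners: dict,
                 classes: list) -> np.ndarray:
    """Concatenated (class index, probability) per view; sentinel where absent."""
    n = len(features)
    n_classes = len(classes)
    out = np.empty((n, 2 * len(VIEWS)))
    for j, view in enumerate(VIEWS):
        cols = [f"{view}__{f}" for f in VIEW_FEATURES]
        X = features[cols].to_numpy()
        present = np.isfinite(X).all(axis=1)
        cls_idx = np.full(n, float(n_classes))       # sentinel
        prob = np.full(n, 1.0 / n_classes)           # uniform
        learner = view_learners.get(view)
        if learner is not None and present.any():
            p = learner.predict_proba(X[present])
            k = np.argmax(p, axis=1)
            # map the learner's class order into the global vocabulary
            remap = np.array([classes.index(c) for c in learner.classes_])
            cls_idx[present] = remap[k].astype(float)
            prob[present] = p[np.arange(len(k)), k]
        out[:, 2 * j] = cls_idx
        out[:, 2 * j + 1] = prob
    return out


def train(features: pd.DataFrame, labels: pd.Series,
          config: ModelConfig | None = None, seed: int = 0) -> EnvironmentModel:
    """Fit the stacked model on (balanced) labelled window features.

    First-level learners fit per view on the rows where that view is
    present; the meta-learner fits on out-of-fold first-level outputs.
    """
    config = config or ModelConfig()
    labels = labels.reset_index(drop=True)
    features = features.reset_index(drop=True)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ConfigError("training needs at least two classes")
    rng = np.random.default_rng(seed)

    def fit_views(feat, lab):
        learners = {}
        for view in VIEWS:
            cols = [f"{view}__{f}" for f in VIEW_FEATURES]
            X = feat[cols].to_numpy()
            present = np.isfinite(X).all(axis=1)
            if present.sum() == 0 or lab[present].nunique() < 2:
                logger.warning("view %s has no usable training data; excluded",
                               view)
                continue
            lr = _make_learner(config, int(rng.integers(2**31)))
            lr.fit(X[present], lab[present])
            learners[view] = lr
        if not learners:
            raise ConfigError("no view has any training data")
        return learners

    # out-of-fold meta-training inputs
    skf = StratifiedKFold(n_splits=config.stacking_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    meta_X = np.empty((len(features), 2 * len(VIEWS)))
    for tr, va in skf.split(features, labels):
        fold_learners = fit_views(features.iloc[tr], labels.iloc[tr])
        meta_X[va] = _meta_inputs(features.iloc[va], fold_learners, classes)
    meta = _make_learner(config, int(rng.integers(2**31)))
    meta.fit(meta_X, labels)
    # final first-level learners on all rows
    view_learners = fit_views(features, labels)
    return EnvironmentModel(view_learners=view_learners, meta_learner=meta,
                            classes=classes, config=config, seed=seed,
                            class_counts=labels.value_counts().to_dict())


def predict(model: EnvironmentModel, table: FusedTable) -> pd.DataFrame:
    """Per-minute labels + confidence for a fused table.

    Returns a DataFrame (index = table minutes) with columns ``label``
    (None where no view has data) and ``confidence``.
    """
    features = extract_views(table, model.config.window_minutes)
    out = pd.DataFrame(index=table.frame.index,
                       columns=["label", "confidence"], dtype=object)
    out["label"] = None
    out["confidence"] = np.nan
    if len(features) == 0:
        return out
    any_view = np.zeros(len(features), dtype=bool)
    for view in VIEWS:
        cols = [f"{view}__{f}" for f in VIEW_FEATURES]
        any_view |= np.isfinite(features[cols].to_numpy()).all(axis=1)
    if not any_view.any():
        return out
    meta_X = _meta_inputs(features[any_view], model.view_learners,
                          model.classes)
    proba = model.meta_learner.predict_proba(meta_X)
    k = np.argmax(proba, axis=1)
    pred = np.asarray(model.meta_learner.classes_)[k]
    out.loc[features.index[any_view], "label"] = pred
    out.loc[features.index[any_view], "confidence"] = proba[
        np.arange(len(k)), k]
    return out


def evaluate(predicted: pd.Series, truth) -> dict:
    """Minute-level accuracy, per-class recall and confusion matrix.

    ``truth`` is an :class:`AnnotationSet` or a label Series on the same
    index.  Only minutes where both a prediction and a true label exist
    enter the score.
    """
    if isinstance(truth, AnnotationSet):
        truth = truth.label_minutes(predicted.index)
    truth = truth.reindex(predicted.index)
    ok = (predicted.notna() & truth.notna()).to_numpy()
    if not ok.any():
        raise ValidationError("no overlap between predictions and truth")
    p = pd.Series(predicted.to_numpy()[ok]).astype(str)
    t = pd.Series(truth.to_numpy()[ok]).astype(str)
    confusion = pd.crosstab(t, p, dropna=False)
    confusion.index.name = "truth"
    confusion.columns.name = "predicted"
    recall = {}
    for cls in confusion.index:
        row = confusion.loc[cls]
        recall[cls] = float(row.get(cls, 0)) / float(row.sum())
    return {
        "accuracy": float((p == t).mean()),
        "n_minutes": int(ok.sum()),
        "per_class_recall": recall,
        "confusion": confusion,
    }
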