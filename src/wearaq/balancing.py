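"""Class balancing for environment-classifier training sets.

Stationary environments (home, office) dominate a free-living campaign by
an order of magnitude over transport or outdoor minutes, which biases any
classifier toward the majority class.  The remedy combines uniform random
undersampling of majority classes with SMOTE oversampling of minorities:
each synthetic row is ``x + λ·(x_nn − x)`` for a random minority point
``x``, one of its k nearest minority neighbours ``x_nn`` and λ ~ U(0, 1).

Balancing operates on window-feature rows (the classifier's input space),
never on raw minutes, so synthetic samples stay meaningful.  Original rows
are never modified; provenance is tracked per row.  The augmenter is
pluggable: any callable with the :func:`smote_oversample` signature can
stand in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core import ConfigError, logger


@dataclass
class BalancedSet:
    """Feature rows + labels with per-row provenance (original/synthetic)."""

    features: pd.DataFrame
    labels: pd.Series
    provenance: pd.Series  # "original" | "synthetic"
    report: dict

    def __len__(self) -> int:
        return len(self.features)


def undersample_majority(rows: pd.DataFrame, labels: pd.Series,
                         target_count: int, seed: int = 0):
    """Reduce every class above ``target_count`` by uniform sampling
    without replacement; classes at or below the target are untouched."""
    if target_count <= 0:
        raise ConfigError("target_count must be positive")
    counts = labels.value_counts()
    if target_count > counts.max():
        raise ConfigError("target_count exceeds the largest class")
    rng = np.random.default_rng(seed)
    keep_pos: list[np.ndarray] = []
    lab = labels.to_numpy()
    for cls in counts.index:
        pos = np.flatnonzero(lab == cls)
        if len(pos) > target_count:
            pos = rng.choice(pos, size=target_count, replace=False)
            pos.sort()
        keep_pos.append(pos)
    keep = np.sort(np.concatenate(keep_pos))
    return rows.iloc[keep], labels.iloc[keep]


def smote_oversample(minority: pd.DataFrame, n_new: int,
                     k_neighbors: int = 5, seed: int = 0) -> pd.DataFrame:
    """Generate ``n_new`` synthetic rows by minority-neighbour interpolation.

    Rows may carry missing cells (e.g. a sensor view absent for the whole
    window): neighbours are found on a column-median-imputed copy, while
    the interpolation itself uses the raw values, so a synthetic cell is
    missing whenever either parent's cell is missing.
    """
    if n_new < 0:
        raise ConfigError("n_new must be >= 0")
    m = len(minority)
    if m < 2:
        raise ConfigError("SMOTE needs at least 2 minority points")
    if n_new == 0:
        return minority.iloc[:0].copy()
    k = k_neighbors
    if m <= k:
        k = m - 1
        warnings.warn(f"minority size {m} <= k_neighbors {k_neighbors}; "
                      f"reducing k to {k}", stacklevel=2)
    X = minority.to_numpy(dtype=float)
    finite = np.isfinite(X)
    if finite.all():
        Xq = X
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cols
            med = np.nanmedian(np.where(finite, X, np.nan), axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        Xq = np.where(finite, X, med)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xq)
    _, nbr = nn.kneighbors(Xq)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, m, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    lam = rng.random(n_new)
    partner = nbr[base, pick]
    synth = X[base] + lam[:, None] * (X[partner] - X[base])
    return pd.DataFrame(synth, columns=minority.columns)


def balance(rows: pd.DataFrame, labels: pd.Series,
            target: int | str = "median", k_neighbors: int = 5,
            seed: int = 0,
            augmenter=smote_oversample) -> BalancedSet:
    """Bring every class to a common count (default: the median class count).

    Majority classes are undersampled, minority classes receive synthetic
    rows from ``augmenter`` (SMOTE by default).
    """
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ConfigError("balancing needs at least two classes")
    if target == "median":
        tgt = int(np.median(counts.to_numpy()))
    else:
        tgt = int(target)
    if tgt <= 0:
        raise ConfigError("target count must be positive")
    rng = np.random.default_rng(seed)
    kept_rows, kept_labels = undersample_majority(
        rows, labels, tgt, seed=int(rng.integers(2**31)))
    parts_f = [kept_rows.reset_index(drop=True)]
    parts_l = [kept_labels.reset_index(drop=True)]
    parts_p = [pd.Series(["original"] * len(kept_rows))]
    report = {}
    for cls, cnt in counts.items():
        report[cls] = {"original": int(cnt), "final": tgt}
        deficit = tgt - min(int(cnt), tgt)
        if deficit > 0:
            minority = rows[labels == cls]
            synth = augmenter(minority, deficit, k_neighbors=k_neighbors,
                              seed=int(rng.integers(2**31)))
            parts_f.append(synth.reset_index(drop=True))
            parts_l.append(pd.Series([cls] * len(synth)))
            parts_p.append(pd.Series(["synthetic"] * len(synth)))
            logger.info("balance: %s += %d synthetic rows", cls, deficit)
    features = pd.concat(parts_f, ignore_index=True)
    return BalancedSet(features=features,
                       labels=pd.concat(parts_l, ignore_index=True),
                       provenance=pd.concat(parts_p, ignore_index=True),
                       report=report)
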