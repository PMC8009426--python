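"""General regression neural network (Gaussian-kernel regression) trials.

A GRNN is one-pass kernel regression: training memorizes the (feature,
force) patterns, and a prediction is the Gaussian-kernel-weighted average of
training targets,

    ŷ(x) = Σ_i y_i exp(-d_i² / (2σ²)) / Σ_i exp(-d_i² / (2σ²)),

with d_i the Euclidean distance from the query to pattern i in standardized
feature space. σ (the spread) interpolates between nearest-neighbor
(σ → 0) and the global training mean (σ → ∞); predictions are always convex
combinations of training targets. Features are standardized per column on
the training fold so large-scale features (IEMG) do not dominate the
distance.

Trials: for each (MPS, FS) pair and each repeat, actions are split 4/5 train
vs 1/5 test (whole actions, never individual windows, so overlapping windows
cannot leak across the split), the model is fit, and NRMS / NMAE / CC are
computed on the test windows against the experiment-wide force range.
Per-trial random streams are derived deterministically from the master seed
and the trial's (spec index, repeat) key, so results do not depend on
execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import metrics
from .combinatorics import SubsetSpec
from .features import META_COLUMNS, feature_columns
from .io import RunConfig
from .metrics import UndefinedCorrelationError

logger = logging.getLogger(__name__)

DEFAULT_SPREAD_GRID = tuple(np.logspace(-2.0, 1.0, 8))


@dataclass
class GrnnModel:
    """Fitted GRNN: standardized training patterns, targets and spread."""

    patterns: np.ndarray
    targets: np.ndarray
    sigma: float
    center: np.ndarray
    scale: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.center) / self.scale
        d2 = cdist(Z, self.patterns, metric="sqeuclidean")
        # Subtract the row-wise minimum before exponentiating so the largest
        # weight is exactly 1 and far queries cannot underflow to 0/0.
        d2 -= d2.min(axis=1, keepdims=True)
        w = np.exp(-d2 / (2.0 * self.sigma**2))
        return w @ self.targets / w.sum(axis=1)


def _as_arrays(train) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(train, pd.DataFrame):
        X = train[feature_columns(train)].to_numpy(dtype=float)
        y = train["force"].to_numpy(dtype=float)
        return X, y
    raise TypeError("fit expects a feature table DataFrame; use fit_arrays for ndarrays")


def fit_arrays(X: np.ndarray, y: np.ndarray, sigma: float) -> GrnnModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("training set is empty")
    if X.shape[0] != y.shape[0]:
        raise ValueError("pattern/target length mismatch")
    if not sigma > 0:
        raise ValueError(f"spread must be positive, got {sigma}")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns carry no distance information
    return GrnnModel(
        patterns=(X - center) / scale,
        targets=y,
        sigma=float(sigma),
        center=center,
        scale=scale,
    )


def fit(train: pd.DataFrame, sigma: float) -> GrnnModel:
    """Fit a GRNN from a feature table (feature columns + 'force' target)."""
    X, y = _as_arrays(train)
    return fit_arrays(X, y, sigma)


def _holdout_rmse(
    X: np.ndarray, y: np.ndarray, train_mask: np.ndarray, sigma: float
) -> float:
    model = fit_arrays(X[train_mask], y[train_mask], sigma)
    pred = model.predict(X[~train_mask])
    return float(np.sqrt(np.mean((pred - y[~train_mask]) ** 2)))


def select_spread_arrays(
    X: np.ndarray,
    y: np.ndarray,
    action_ids: np.ndarray,
    candidates,
    rng: np.random.Generator,
) -> float:
    """Pick the spread minimizing inner hold-out RMSE.

    With >= 5 actions a single action-wise ~1/5 hold-out is used; with fewer,
    leave-one-action-out. Ties (including duplicate grid values) keep the
    first occurrence.
    """
    candidates = [float(s) for s in candidates]
    if not candidates:
        raise ValueError("spread candidate grid is empty")
    if len(candidates) == 1:
        return candidates[0]
    actions = np.unique(action_ids)
    if actions.size < 2:
        # No inner split possible: fall back to the grid midpoint.
        return candidates[len(candidates) // 2]

    if actions.size >= 5:
        perm = rng.permutation(actions)
        n_val = max(1, round(actions.size / 5))
        folds = [np.isin(action_ids, perm[:n_val])]
    else:
        folds = [action_ids == a for a in actions]

    best_sigma, best_score = None, np.inf
    for sigma in candidates:
        score = float(
            np.mean([_holdout_rmse(X, y, ~val, sigma) for val in folds])
        )
        if score < best_score - 1e-15:
            best_sigma, best_score = sigma, score
    return best_sigma


def select_spread(
    train: pd.DataFrame,
    candidates=DEFAULT_SPREAD_GRID,
    rng: np.random.Generator | None = None,
) -> float:
    X, y = _as_arrays(train)
    action_ids = train["action_id"].to_numpy()
    if rng is None:
        rng = np.random.default_rng(0)
    return select_spread_arrays(X, y, action_ids, candidates, rng)


def split_actions(
    actions: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random action-wise split; the test side gets round((1-frac)*n) >= 1."""
    perm = rng.permutation(actions)
    n_test = int(np.clip(round((1.0 - train_fraction) * actions.size), 1, actions.size - 1))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def run_trials(
    table: pd.DataFrame,
    specs: list[SubsetSpec],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Repeated-split GRNN evaluation of every (MPS, FS) spec.

    Returns one row per (spec, repeat): canonical MPS/FS names, repeat index,
    NRMS, NMAE, CC and the spread used. CC is NaN (logged) when the test
    targets are constant. Result count = len(specs) * cfg.n_repeats.
    """
    actions = np.unique(table["action_id"].to_numpy())
    if actions.size < 5:
        raise ValueError(
            f"need at least 5 actions for a 4/5 vs 1/5 split, got {actions.size}"
        )
    feat_cols = feature_columns(table)
    col_idx = {c: i for i, c in enumerate(feat_cols)}
    X_all = table[feat_cols].to_numpy(dtype=float)
    y_all = table["force"].to_numpy(dtype=float)
    action_ids = table["action_id"].to_numpy()
    f_max, f_min = float(y_all.max()), float(y_all.min())
    if not f_max > f_min:
        raise ValueError("force target is constant over the whole table")

    rows = []
    for si, spec in enumerate(specs):
        missing = [c for c in spec.columns if c not in col_idx]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        cols = np.array([col_idx[c] for c in spec.columns])
        X_spec = X_all[:, cols]
        for rep in range(cfg.n_repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed), si, rep])
            )
            train_a, test_a = split_actions(actions, cfg.train_fraction, rng)
            tr = np.isin(action_ids, train_a)
            te = ~tr
            if cfg.grnn_spread == "auto":
                sigma = select_spread_arrays(
                    X_spec[tr], y_all[tr], action_ids[tr], cfg.spread_grid, rng
                )
            else:
                sigma = float(cfg.grnn_spread)
            model = fit_arrays(X_spec[tr], y_all[tr], sigma)
            pred = model.predict(X_spec[te])
            try:
                r = metrics.cc(pred, y_all[te])
            except UndefinedCorrelationError:
                logger.warning(
                    "CC undefined for %s repeat %d; recorded as NaN",
                    spec.canonical_name, rep,
                )
                r = np.nan
            rows.append(
                {
                    "mps": spec.mps_name,
                    "fs": spec.fs_name,
                    "repeat": rep,
                    "nrms": metrics.nrms(pred, y_all[te], f_max, f_min),
                    "nmae": metrics.nmae(pred, y_all[te], f_max, f_min),
                    "cc": r,
                    "spread": sigma,
                }
            )
    return pd.DataFrame(rows)
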