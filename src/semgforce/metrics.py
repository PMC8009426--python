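"""Normalized error metrics for force estimation.

NRMS = sqrt( sum (f̂_i - f_i)^2 / (N - 1) ) / (f_max - f_min)
NMAE = sum |f̂_i - f_i| / ( N * (f_max - f_min) )
CC   = Pearson correlation between estimate and measurement.

``f_max`` and ``f_min`` are the extreme measured forces over the whole
experiment, not per test fold, so errors across folds share one scale.
"""

from __future__ import annotations

import numpy as np


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a zero-variance sequence."""


def _validate(f_est: np.ndarray, f_act: np.ndarray, f_max: float, f_min: float):
    f_est = np.asarray(f_est, dtype=float)
    f_act = np.asarray(f_act, dtype=float)
    if f_est.shape != f_act.shape or f_est.ndim != 1:
        raise ValueError("estimated and actual force must be 1-D of equal length")
    if f_est.size < 2:
        raise ValueError("need at least two samples")
    if not f_max > f_min:
        raise ValueError(f"f_max ({f_max}) must exceed f_min ({f_min})")
    return f_est, f_act


def nrms(f_est, f_act, f_max: float, f_min: float) -> float:
    f_est, f_act = _validate(f_est, f_act, f_max, f_min)
    n = f_est.size
    return float(
        np.sqrt(np.sum((f_est - f_act) ** 2) / (n - 1)) / (f_max - f_min)
    )


def nmae(f_est, f_act, f_max: float, f_min: float) -> float:
    f_est, f_act = _validate(f_est, f_act, f_max, f_min)
    n = f_est.size
    return float(np.sum(np.abs(f_est - f_act)) / (n * (f_max - f_min)))


def cc(f_est, f_act) -> float:
    """Pearson correlation; raises on a zero-variance input sequence."""
    f_est = np.asarray(f_est, dtype=float)
    f_act = np.asarray(f_act, dtype=float)
    if f_est.shape != f_act.shape or f_est.ndim != 1 or f_est.size < 2:
        raise ValueError("estimated and actual force must be 1-D of equal length >= 2")
    if np.ptp(f_est) == 0 or np.ptp(f_act) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: a sequence has zero variance"
        )
    r = np.corrcoef(f_est, f_act)[0, 1]
    return float(np.clip(r, -1.0, 1.0))
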