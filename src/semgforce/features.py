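"""Time-domain sEMG features over sliding windows.

Four classic myoelectric features are computed per window of each channel:

* ``V`` — variance-style power density, ``VAR = (1/N) * sum(x_j^2)``;
* ``Z`` — zero crossings: adjacent pairs with a sign change whose amplitude
  difference exceeds a guard threshold (default 30 µV), suppressing
  crossings caused by baseline noise;
* ``I`` — integrated EMG, ``IEMG = sum(|x_j|)``;
* ``W`` — Willison amplitude: adjacent pairs whose absolute difference
  exceeds a threshold (default 150 µV), a proxy for contraction level.

Windows are 200 ms with 50% overlap by default and never straddle a segment
boundary; each window's regression target is the mean force over the same
samples. The canonical feature-letter order is V, I, W, Z, so a feature-set
name like ``"IW"`` or ``"VIWZ"`` lists letters in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import Recording
from .segment import ActionSegment

logger = logging.getLogger(__name__)

#: Canonical order of feature letters in set names ("VIWZ", "IW", ...).
FEATURE_ORDER = ("V", "I", "W", "Z")

#: Metadata columns of a feature table (everything else is a feature column).
META_COLUMNS = ("force", "segment_id", "action_id")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry in samples."""

    n: int
    step: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"window length must be >= 2 samples, got {self.n}")
        if not 1 <= self.step <= self.n:
            raise ValueError(f"step must lie in [1, {self.n}], got {self.step}")

    @classmethod
    def from_ms(cls, window_ms: float, overlap_fraction: float, fs: float) -> "WindowConfig":
        n = int(round(window_ms * fs / 1000.0))
        step = int(round(n * (1.0 - overlap_fraction)))
        return cls(n=n, step=max(step, 1))

    def n_windows(self, length: int) -> int:
        """Number of full windows in a segment of ``length`` samples."""
        if length < self.n:
            return 0
        return (length - self.n) // self.step + 1


def var_feature(window: np.ndarray) -> float:
    """Mean of squared samples (µV²) — the power density of the window."""
    x = np.asarray(window, dtype=float)
    return float(np.mean(x * x))


def zc_feature(window: np.ndarray, threshold: float = 30.0) -> int:
    """Guarded zero-crossing count.

    Counts adjacent pairs with ``x_j * x_{j-1} < 0`` and
    ``|x_j - x_{j-1}| > threshold``.
    """
    x = np.asarray(window, dtype=float)
    d = np.diff(x)
    return int(np.count_nonzero((x[1:] * x[:-1] < 0) & (np.abs(d) > threshold)))


def iemg_feature(window: np.ndarray) -> float:
    """Integrated EMG: sum of absolute sample values (µV·samples)."""
    return float(np.sum(np.abs(np.asarray(window, dtype=float))))


def wamp_feature(window: np.ndarray, threshold: float = 150.0) -> int:
    """Willison amplitude: adjacent-pair differences exceeding ``threshold``."""
    x = np.asarray(window, dtype=float)
    return int(np.count_nonzero(np.abs(np.diff(x)) > threshold))


def _windowed_features(
    x: np.ndarray, wcfg: WindowConfig, zc_threshold: float, wamp_threshold: float
) -> dict[str, np.ndarray]:
    """All four features for every window of one channel, vectorized."""
    w = sliding_window_view(x, wcfg.n)[:: wcfg.step]
    d = np.diff(w, axis=1)
    return {
        "V": np.mean(w * w, axis=1),
        "I": np.sum(np.abs(w), axis=1),
        "W": np.count_nonzero(np.abs(d) > wamp_threshold, axis=1).astype(float),
        "Z": np.count_nonzero(
            (w[:, 1:] * w[:, :-1] < 0) & (np.abs(d) > zc_threshold), axis=1
        ).astype(float),
    }


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def column_name(channel: str, feature: str) -> str:
    return f"{channel}_{feature}"


def extract_table(
    segments: list[ActionSegment],
    rec: Recording,
    wcfg: WindowConfig,
    features: tuple[str, ...] = FEATURE_ORDER,
    channels: tuple[str, ...] | None = None,
    zc_threshold: float = 30.0,
    wamp_threshold: float = 150.0,
) -> pd.DataFrame:
    """Build the per-window feature table for a list of segments.

    One row per window; feature columns are named ``<channel>_<letter>`` with
    channels in recording order and letters in canonical V, I, W, Z order.
    Windows lie fully inside a segment's kept span (trailing partial windows
    dropped); segments shorter than one window are skipped with a warning.
    """
    if channels is None:
        channels = rec.channel_labels
    unknown = set(channels) - set(rec.channel_labels)
    if unknown:
        raise ValueError(f"unknown channel labels {sorted(unknown)}")
    unknown_f = set(features) - set(FEATURE_ORDER)
    if unknown_f:
        raise ValueError(f"unknown feature letters {sorted(unknown_f)}")
    features = tuple(f for f in FEATURE_ORDER if f in features)
    ch_index = {lbl: i for i, lbl in enumerate(rec.channel_labels)}

    blocks: list[pd.DataFrame] = []
    for seg_id, seg in enumerate(segments):
        lo, hi = seg.kept_span
        length = hi - lo
        nwin = wcfg.n_windows(length)
        if nwin == 0:
            logger.warning(
                "segment %d (%d samples) shorter than one window (%d); skipped",
                seg_id, length, wcfg.n,
            )
            continue
        cols: dict[str, np.ndarray] = {}
        for lbl in channels:
            x = rec.emg[lo:hi, ch_index[lbl]]
            feats = _windowed_features(x, wcfg, zc_threshold, wamp_threshold)
            for f in features:
                cols[column_name(lbl, f)] = feats[f]
        fwin = sliding_window_view(rec.force[lo:hi], wcfg.n)[:: wcfg.step]
        cols["force"] = np.mean(fwin, axis=1)
        cols["segment_id"] = np.full(nwin, seg_id)
        cols["action_id"] = np.full(nwin, seg_id)
        blocks.append(pd.DataFrame(cols))

    if not blocks:
        names = [column_name(c, f) for c in channels for f in features]
        return pd.DataFrame(columns=names + list(META_COLUMNS))
    return pd.concat(blocks, ignore_index=True)
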