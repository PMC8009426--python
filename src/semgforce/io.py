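"""Recording / results / configuration I/O.

All artifacts are delimited text (CSV) so they remain inspectable; floats are
serialized with full round-trip precision (repr). The run configuration lives
in YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Default electrode labels for the six forearm measurement positions
#: (extensor carpi ulnaris, flexor carpi ulnaris, flexor digitorum
#: superficialis, flexor carpi radialis, brachioradialis, extensor digitorum).
DEFAULT_CHANNEL_LABELS = ("P1", "P2", "P3", "P4", "P5", "P6")

RESULT_COLUMNS = ("mps", "fs", "repeat", "nrms", "nmae", "cc")


class ParseError(ValueError):
    """A recording or results file failed validation."""


@dataclass
class Recording:
    """Synchronized multi-channel sEMG (µV) and grasp force (N) traces.

    ``emg`` has shape (n_samples, n_channels); ``force`` has shape
    (n_samples,). Both are uniformly sampled at ``fs`` Hz.
    """

    fs: float
    emg: np.ndarray
    force: np.ndarray
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.emg.ndim != 2:
            raise ValueError("emg must be 2-D (n_samples, n_channels)")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.emg.shape[0] != self.force.shape[0]:
            raise ValueError(
                f"emg has {self.emg.shape[0]} samples but force has "
                f"{self.force.shape[0]}"
            )
        if self.emg.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.channel_labels:
            if self.n_channels == len(DEFAULT_CHANNEL_LABELS):
                self.channel_labels = DEFAULT_CHANNEL_LABELS
            else:
                self.channel_labels = tuple(
                    f"P{i + 1}" for i in range(self.n_channels)
                )
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RunConfig:
    """Analysis parameters for the full estimation pipeline.

    Defaults follow the study conditions: 200 ms windows with 50% overlap,
    zero-crossing guard threshold 30 µV, Willison-amplitude threshold 150 µV,
    4/5 vs 1/5 action-wise splits repeated ten times, significance level 0.05.
    """

    window_ms: float = 200.0
    overlap_fraction: float = 0.5
    zc_threshold: float = 30.0
    wamp_threshold: float = 150.0
    train_fraction: float = 0.8
    n_repeats: int = 10
    grnn_spread: float | str = "auto"
    spread_grid: tuple[float, ...] = tuple(np.logspace(-2.0, 1.0, 8))
    alpha: float = 0.05
    force_threshold_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction < 1:
            raise ValueError(
                f"overlap_fraction must lie in (0, 1), got {self.overlap_fraction}"
            )
        if not 0 < self.train_fraction < 1:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if self.zc_threshold < 0 or self.wamp_threshold < 0:
            raise ValueError("feature thresholds must be non-negative")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.grnn_spread != "auto":
            self.grnn_spread = float(self.grnn_spread)
            if self.grnn_spread <= 0:
                raise ValueError("grnn_spread must be positive or 'auto'")
        self.spread_grid = tuple(float(s) for s in self.spread_grid)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: expected a mapping of config keys")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["spread_grid"] = list(self.spread_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV: time, one column per channel, force."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for i, label in enumerate(rec.channel_labels):
        df[label] = rec.emg[:, i]
    df["force"] = rec.force
    df.to_csv(path, index=False, float_format="%.17g")


def read_recording(path: str | Path) -> Recording:
    """Read a recording CSV written by :func:`write_recording`.

    The sampling rate is recovered from the time column. Non-numeric or
    missing cells raise :class:`ParseError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # ragged rows, empty file, ...
        raise ParseError(f"{path}: {exc}") from exc
    expected = {"time", "force"}
    if not expected <= set(df.columns):
        raise ParseError(f"{path}: missing required columns {expected - set(df.columns)}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric or missing value in data row {row} "
            f"(file line {row + 2})"
        )
    channel_labels = tuple(c for c in df.columns if c not in ("time", "force"))
    if not channel_labels:
        raise ParseError(f"{path}: no sEMG channel columns found")
    t = coerced["time"].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
        raise ParseError(f"{path}: time column is not uniformly increasing")
    fs = 1.0 / dt[0]
    return Recording(
        fs=round(fs, 9),
        emg=coerced[list(channel_labels)].to_numpy(),
        force=coerced["force"].to_numpy(),
        channel_labels=channel_labels,
    )


def write_results(results: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write trial results (mps, fs, repeat, nrms, nmae, cc) to CSV.

    An empty collection produces a valid header-only file.
    """
    df = pd.DataFrame(results)
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=list(RESULT_COLUMNS))
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results missing columns {sorted(missing)}")
    ordered = list(RESULT_COLUMNS) + [c for c in df.columns if c not in RESULT_COLUMNS]
    df[ordered].to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"results file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing result columns {sorted(missing)}")
    if len(df):
        dupes = df.duplicated(subset=["mps", "fs", "repeat"])
        if dupes.any():
            key = df.loc[dupes.idxmax(), ["mps", "fs", "repeat"]].tolist()
            raise ParseError(f"{path}: duplicate (mps, fs, repeat) key {key}")
    return df


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
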