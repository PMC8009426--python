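"""Enumeration of measurement-position sets (MPS) and feature sets (FS).

With six electrode positions and four features there are 2^6 - 1 = 63
non-empty position sets, 2^4 - 1 = 15 non-empty feature sets, and 945
(MPS, FS) data sets in the full product. Enumeration order is deterministic:
by subset size, then lexicographically within a size, so result keys are
stable across runs. Canonical names join position labels with "+" sorted by
position index ("P1+P2+P5") and concatenate feature letters in V, I, W, Z
order ("IW", "VIWZ").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import pandas as pd

from .features import FEATURE_ORDER, META_COLUMNS, column_name


@dataclass(frozen=True)
class SubsetSpec:
    """One (measurement-position set, feature set) pair."""

    mps: tuple[str, ...]
    fs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.mps:
            raise ValueError("measurement-position set must be non-empty")
        if not self.fs:
            raise ValueError("feature set must be non-empty")
        bad = set(self.fs) - set(FEATURE_ORDER)
        if bad:
            raise ValueError(f"unknown feature letters {sorted(bad)}")

    @property
    def mps_name(self) -> str:
        return "+".join(self.mps)

    @property
    def fs_name(self) -> str:
        return "".join(self.fs)

    @property
    def canonical_name(self) -> str:
        return f"{self.mps_name}:{self.fs_name}"

    @property
    def input_dimension(self) -> int:
        return len(self.mps) * len(self.fs)

    @property
    def columns(self) -> list[str]:
        return [column_name(c, f) for c in self.mps for f in self.fs]


def _ordered_subsets(items: tuple[str, ...]) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for size in range(1, len(items) + 1):
        out.extend(combinations(items, size))
    return out


def enumerate_mps(channels: Iterable[str]) -> list[tuple[str, ...]]:
    """All non-empty position subsets, ordered by size then lexicographically."""
    channels = tuple(channels)
    if len(set(channels)) != len(channels):
        raise ValueError("channel labels must be distinct")
    return _ordered_subsets(channels)


def enumerate_fs(features: Iterable[str] = FEATURE_ORDER) -> list[tuple[str, ...]]:
    """All non-empty feature subsets in canonical V, I, W, Z letter order."""
    features = tuple(f for f in FEATURE_ORDER if f in tuple(features))
    return _ordered_subsets(features)


def enumerate_specs(
    channels: Iterable[str],
    features: Iterable[str] = FEATURE_ORDER,
) -> list[SubsetSpec]:
    """The full (MPS, FS) product in deterministic order (MPS-major)."""
    return [
        SubsetSpec(mps=m, fs=f)
        for m in enumerate_mps(channels)
        for f in enumerate_fs(features)
    ]


def spec_from_name(name: str) -> SubsetSpec:
    """Parse "P4+P5+P6:IW" into a :class:`SubsetSpec`."""
    try:
        mps_part, fs_part = name.split(":")
    except ValueError as exc:
        raise ValueError(f"spec name {name!r} must look like 'P1+P2:IW'") from exc
    mps = tuple(sorted(mps_part.split("+")))
    fs = tuple(f for f in FEATURE_ORDER if f in fs_part)
    if len(fs) != len(fs_part):
        raise ValueError(f"spec name {name!r} has unknown feature letters")
    return SubsetSpec(mps=mps, fs=fs)


def project(table: pd.DataFrame, spec: SubsetSpec) -> pd.DataFrame:
    """Column-subset of a feature table for one (MPS, FS) pair."""
    missing = [c for c in spec.columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    meta = [c for c in META_COLUMNS if c in table.columns]
    return table[spec.columns + meta]
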