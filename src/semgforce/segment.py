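"""Action segmentation: find grasp bursts in the force trace and trim rest.

Each detected action span (the active phase, length T2) keeps a relaxation
flank of floor(T2/4) samples on each side, so a kept segment is roughly 1.5x
the action length. Flanks are clipped at the recording boundaries and, when
two actions sit close together, truncated at the midpoint between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActionSegment:
    """One grasp action: active-phase span plus trimmed relaxation flanks."""

    action_span: tuple[int, int]
    kept_span: tuple[int, int]
    level_label: float | None = None

    @property
    def action_length(self) -> int:
        return self.action_span[1] - self.action_span[0]

    @property
    def kept_length(self) -> int:
        return self.kept_span[1] - self.kept_span[0]


def detect_actions(
    rec: Recording,
    force_threshold_fraction: float = 0.05,
    merge_gap_ms: float = 100.0,
    min_duration_ms: float = 200.0,
) -> list[tuple[int, int]]:
    """Locate action spans where force exceeds a fraction of its maximum.

    Spans separated by gaps shorter than ``merge_gap_ms`` are merged; spans
    shorter than ``min_duration_ms`` are discarded. An all-zero (or constant
    non-positive) force trace yields an empty list.
    """
    force = rec.force
    fmax = force.max()
    if fmax <= 0:
        return []
    above = force > force_threshold_fraction * fmax
    if not above.any():
        return []

    padded = np.concatenate(([0], above.astype(np.int8), [0]))
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)

    merge_gap = int(round(merge_gap_ms * rec.fs / 1000.0))
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    min_len = int(round(min_duration_ms * rec.fs / 1000.0))
    return [(s, e) for s, e in merged if e - s >= min_len]


def trim_segments(
    spans: list[tuple[int, int]],
    rec: Recording,
    levels: list[float] | None = None,
) -> list[ActionSegment]:
    """Attach floor(T2/4) relaxation flanks to each action span.

    Flanks are clipped silently at the recording boundaries (logged) and
    truncated at the midpoint between adjacent actions so kept spans never
    overlap. Trimming already-trimmed action spans is idempotent.
    """
    n = rec.n_samples
    for i, (s, e) in enumerate(spans):
        if not 0 <= s < e <= n:
            raise ValueError(f"span {i} = [{s}, {e}) outside recording bounds")
        if i and s < spans[i - 1][1]:
            raise ValueError(f"spans {i - 1} and {i} overlap or are unordered")

    segments = []
    for i, (s, e) in enumerate(spans):
        flank = (e - s) // 4
        ks, ke = s - flank, e + flank
        if ks < 0 or ke > n:
            logger.debug("segment %d flank clipped at recording boundary", i)
        ks, ke = max(ks, 0), min(ke, n)
        if i > 0:
            mid = (spans[i - 1][1] + s) // 2
            ks = max(ks, mid)
        if i + 1 < len(spans):
            mid = (e + spans[i + 1][0]) // 2
            ke = min(ke, mid)
        segments.append(
            ActionSegment(
                action_span=(s, e),
                kept_span=(ks, ke),
                level_label=levels[i] if levels is not None else None,
            )
        )
    return segments


def segments_to_rows(segments: list[ActionSegment]) -> list[dict]:
    """Flatten segments for CSV export."""
    return [
        {
            "action": i,
            "start": seg.action_span[0],
            "end": seg.action_span[1],
            "kept_start": seg.kept_span[0],
            "kept_end": seg.kept_span[1],
            "level": seg.level_label,
        }
        for i, seg in enumerate(segments)
    ]
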