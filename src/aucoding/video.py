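"""Temporal coding of expression episodes in video.

An expression episode is delimited by three key frames: onset (the face
departs from neutral), apex (greatest extent of the movement) and offset
(return to neutral). The episode duration, onset→offset in seconds,
separates micro-expressions — involuntary flashes lasting 1/25 to 1/5 of a
second — from ordinary macro-expressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "ExpressionInterval",
    "MICRO_MIN_SECONDS",
    "MICRO_MAX_SECONDS",
    "duration_seconds",
    "is_micro_expression",
    "read_episodes",
    "write_episodes",
]

#: Micro-expression duration band, boundaries inclusive.
MICRO_MIN_SECONDS = 1.0 / 25.0
MICRO_MAX_SECONDS = 1.0 / 5.0

_EPS = 1e-12  # absorb float noise at the band boundaries


@dataclass(frozen=True)
class ExpressionInterval:
    """Onset/apex/offset frame indices (0-based) at a given frame rate."""

    onset_frame: int
    apex_frame: int
    offset_frame: int
    fps: float

    def __post_init__(self) -> None:
        if self.onset_frame < 0:
            raise ValueError(f"onset_frame must be >= 0: {self.onset_frame}")
        if not (self.onset_frame <= self.apex_frame <= self.offset_frame):
            raise ValueError(
                "frames must satisfy onset <= apex <= offset, got "
                f"{self.onset_frame} <= {self.apex_frame} <= {self.offset_frame}"
            )
        if not self.fps > 0:
            raise ValueError(f"fps must be positive: {self.fps}")


def duration_seconds(iv: ExpressionInterval) -> float:
    """Episode duration: (offset − onset) / fps. The apex plays no part."""
    return (iv.offset_frame - iv.onset_frame) / iv.fps


def is_micro_expression(iv: ExpressionInterval) -> tuple[bool, float]:
    """Whether the episode falls in the micro-expression duration band.

    Returns ``(is_micro, duration_seconds)``; the band [1/25, 1/5] s is
    inclusive at both ends.
    """
    d = duration_seconds(iv)
    return (MICRO_MIN_SECONDS - _EPS <= d <= MICRO_MAX_SECONDS + _EPS, d)


_EPISODE_COLUMNS = ("sample_id", "onset", "apex", "offset", "fps", "au_combination")


def read_episodes(path: str | Path) -> list[tuple[str, ExpressionInterval, str]]:
    """Read an episode TSV: sample_id, onset, apex, offset, fps, au_combination."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _EPISODE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    episodes = []
    for row in frame.itertuples(index=False):
        iv = ExpressionInterval(
            onset_frame=int(row.onset),
            apex_frame=int(row.apex),
            offset_frame=int(row.offset),
            fps=float(row.fps),
        )
        episodes.append((str(row.sample_id), iv, str(row.au_combination)))
    return episodes


def write_episodes(
    episodes: Sequence[tuple[str, ExpressionInterval, str]], path: str | Path
) -> None:
    """Write episodes in the TSV dialect read by :func:`read_episodes`."""
    rows = [
        {
            "sample_id": sid,
            "onset": iv.onset_frame,
            "apex": iv.apex_frame,
            "offset": iv.offset_frame,
            "fps": iv.fps,
            "au_combination": aus,
        }
        for sid, iv, aus in episodes
    ]
    pd.DataFrame(rows, columns=list(_EPISODE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
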