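"""Inter-coder reliability for emotion (or AU) label sets.

Annotation of spontaneous expressions requires at least two coders; their
agreement is summarized by the intersection-over-union statistic scaled by
the panel size:

    R = N * |C_1 ∩ ... ∩ C_N| / |C_1 ∪ ... ∪ C_N|

where C_i is coder i's label set. R ranges over [0, N]: it equals N when all
coders agree exactly (non-empty sets) and 0 when no label is common to all.
The normalized form R/N in [0, 1] is reported alongside, since the raw
statistic's "proper range" depends on N. Set elements are opaque, so the
same statistic serves emotion labels or AU numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

__all__ = [
    "CoderLabelSet",
    "ReliabilityReport",
    "compute_reliability",
    "load_panel",
    "save_panel",
    "per_sample_reliability",
    "pooled_reliability",
]


@dataclass(frozen=True)
class CoderLabelSet:
    """One coder's set of labels (for a sample, or pooled over samples)."""

    coder_id: str
    labels: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass(frozen=True)
class ReliabilityReport:
    """Agreement report: raw R in [0, N] and normalized R/N in [0, 1]."""

    n_coders: int
    r_raw: float
    r_normalized: float
    intersection_size: int
    union_size: int


def compute_reliability(panel: Sequence[CoderLabelSet]) -> ReliabilityReport:
    """Compute R = N * |∩ C_i| / |∪ C_i| over a panel of coders.

    Requires at least two coders with unique ids and a non-empty union
    (all-empty sets leave the statistic undefined).
    """
    if len(panel) < 2:
        raise ValueError(f"need at least 2 coders, got {len(panel)}")
    ids = [c.coder_id for c in panel]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate coder ids in panel: {ids}")
    sets = [c.labels for c in panel]
    union = frozenset.union(*sets)
    if not union:
        raise ValueError("all coder label sets are empty: R undefined")
    intersection = frozenset.intersection(*sets)
    n = len(panel)
    r_raw = n * len(intersection) / len(union)
    return ReliabilityReport(
        n_coders=n,
        r_raw=r_raw,
        r_normalized=r_raw / n,
        intersection_size=len(intersection),
        union_size=len(union),
    )


def save_panel(
    panel: Mapping[str, Sequence[CoderLabelSet]], path: str | Path
) -> None:
    """Write a per-sample coder panel as JSON: {sample: {coder: [labels]}}."""
    payload = {
        sample_id: {
            c.coder_id: sorted(str(x) for x in c.labels) for c in coders
        }
        for sample_id, coders in panel.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_panel(path: str | Path) -> dict[str, list[CoderLabelSet]]:
    """Read a per-sample coder panel from JSON."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        sample_id: [
            CoderLabelSet(coder_id=cid, labels=frozenset(labels))
            for cid, labels in coders.items()
        ]
        for sample_id, coders in payload.items()
    }


def per_sample_reliability(
    panel: Mapping[str, Sequence[CoderLabelSet]]
) -> dict[str, ReliabilityReport]:
    """Eq. R per sample over the panel's coders."""
    return {
        sample_id: compute_reliability(list(coders))
        for sample_id, coders in panel.items()
    }


def pooled_reliability(
    panel: Mapping[str, Sequence[CoderLabelSet]]
) -> ReliabilityReport:
    """One pooled report: each coder's set is its (sample, label) pairs.

    Pooling over (sample, label) pairs keeps identical labels on different
    samples distinct, so the pooled statistic measures agreement across the
    whole annotation run, not label-vocabulary overlap.
    """
    pooled: dict[str, set[tuple[str, Hashable]]] = {}
    for sample_id, coders in panel.items():
        for coder in coders:
            pooled.setdefault(coder.coder_id, set()).update(
                (sample_id, label) for label in coder.labels
            )
    return compute_reliability(
        [
            CoderLabelSet(coder_id=cid, labels=frozenset(labels))
            for cid, labels in sorted(pooled.items())
        ]
    )
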