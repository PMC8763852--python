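"""AU→emotion contribution scoring over crowdsourced annotation records.

Two accumulation methods quantify how much each action unit contributes to
each of the six basic emotions:

``max_dedup``
    Each sample is assigned the single emotion with the highest crowdsourced
    score (neutral excluded; canonical-order tie-break). The first time a
    given (AU combination, emotion) pair appears, that emotion's score is
    added to every AU of the combination; exact repeats of the pair are
    skipped to damp the dominance of frequent sample types. Each emotion row
    is finally normalized to sum to 1.

``weighted_sum``
    Every sample adds its full basic-emotion score vector to every AU of its
    combination — no deduplication, no normalization. Repetitions count.

Both produce a sparse emotion × AU matrix; :func:`top_k` ranks each row for
the familiar "Top-10 AUs per emotion" table layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotations import (
    BASIC_EMOTIONS,
    AnnotationRecord,
    Emotion,
)

__all__ = [
    "ContributionMatrix",
    "RankedContributionTable",
    "compute_contribution_max",
    "compute_contribution_weighted",
    "top_k",
    "write_contribution_table",
    "read_contribution_table",
]

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ContributionMatrix:
    """Sparse emotion × AU contribution matrix.

    ``values[e][au]`` is the (nonnegative) contribution of AU ``au`` to basic
    emotion ``e``; AUs never observed simply do not appear. For the
    ``max_dedup`` method every row sums to 1 (or is empty/all-zero).
    """

    values: dict[Emotion, dict[int, float]]
    method: str
    n_samples: int

    def row(self, emotion: Emotion) -> dict[int, float]:
        return dict(self.values.get(emotion, {}))

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view, emotions as rows, AU numbers as columns."""
        aus = sorted({au for row in self.values.values() for au in row})
        data = {
            e.value: [self.values.get(e, {}).get(au, 0.0) for au in aus]
            for e in BASIC_EMOTIONS
        }
        return pd.DataFrame(data, index=aus).T


@dataclass(frozen=True)
class RankedContributionTable:
    """Per-emotion descending (AU, score) rankings, at most k entries each."""

    rows: dict[Emotion, list[tuple[int, float]]]
    method: str
    k: int


def _argmax_basic(record: AnnotationRecord) -> Emotion | None:
    """Highest-scoring basic emotion; canonical order breaks ties.

    Returns ``None`` when every basic score is zero (the sample carries no
    basic-emotion evidence, e.g. a fully neutral crowd).
    """
    basic = record.scores.basic()
    best = max(basic.values())
    if best == 0.0:
        return None
    winners = [e for e in BASIC_EMOTIONS if basic[e] == best]
    if len(winners) > 1:
        logger.info(
            "sample %s: argmax tie among %s, keeping %s",
            record.sample_id,
            [e.value for e in winners],
            winners[0].value,
        )
    return winners[0]


def compute_contribution_max(
    records: Sequence[AnnotationRecord],
) -> ContributionMatrix:
    """Max-score, deduplicated contribution matrix (``max_dedup``).

    For each record the dominant basic emotion E is taken (neutral never
    competes). Only the first occurrence of each (canonical AU combination,
    E) pair contributes: E's score is added to every AU in the combination.
    Rows are normalized to proportions at the end.

    Records whose basic scores are all zero are skipped with a warning; an
    empty input collection is an error.
    """
    if not records:
        raise ValueError("no annotation records")
    values: dict[Emotion, dict[int, float]] = {e: {} for e in BASIC_EMOTIONS}
    seen: set[tuple[str, Emotion]] = set()
    for record in records:
        emotion = _argmax_basic(record)
        if emotion is None:
            logger.warning(
                "sample %s: all-zero basic scores, skipped", record.sample_id
            )
            continue
        key = (record.au_combination, emotion)
        if key in seen:
            continue
        seen.add(key)
        score = record.scores[emotion]
        row = values[emotion]
        for au in record.au_numbers:
            row[au] = row.get(au, 0.0) + score
    for row in values.values():
        total = sum(row.values())
        if total > 0.0:
            for au in row:
                row[au] /= total
    return ContributionMatrix(
        values=values, method="max_dedup", n_samples=len(records)
    )


def compute_contribution_weighted(
    records: Sequence[AnnotationRecord], *, normalize: bool = False
) -> ContributionMatrix:
    """Weighted-sum contribution matrix (``weighted_sum``).

    Every record adds score(e) to C[e][au] for each of its AUs and each basic
    emotion e — repetitions included, no normalization. ``normalize=True``
    additionally rescales each row to sum to 1 (an optional variant; the raw
    sums are the definition).
    """
    if not records:
        raise ValueError("no annotation records")
    values: dict[Emotion, dict[int, float]] = {e: {} for e in BASIC_EMOTIONS}
    for record in records:
        basic = record.scores.basic()
        for au in record.au_numbers:
            for emotion, score in basic.items():
                if score:
                    row = values[emotion]
                    row[au] = row.get(au, 0.0) + score
    if normalize:
        for row in values.values():
            total = sum(row.values())
            if total > 0.0:
                for au in row:
                    row[au] /= total
    return ContributionMatrix(
        values=values, method="weighted_sum", n_samples=len(records)
    )


def top_k(matrix: ContributionMatrix, k: int) -> RankedContributionTable:
    """The k highest-contribution AUs per emotion, descending.

    Ties break by ascending AU number; rows with fewer than k AUs return all
    of them.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rows: dict[Emotion, list[tuple[int, float]]] = {}
    for emotion in BASIC_EMOTIONS:
        ranked = sorted(
            matrix.values.get(emotion, {}).items(),
            key=lambda item: (-item[1], item[0]),
        )
        rows[emotion] = ranked[:k]
    return RankedContributionTable(rows=rows, method=matrix.method, k=k)


def write_contribution_table(
    table: RankedContributionTable, path: str | Path
) -> None:
    """Write a ranked table as TSV: emotion, then alternating AU / score.

    Scores are printed to 4 decimals, matching the conventional table layout
    for top-AU-per-emotion reports.
    """
    header = ["Emotion"]
    for i in range(1, table.k + 1):
        header += [f"AU{i}", f"Score{i}"]
    lines = ["\t".join(header)]
    for emotion in BASIC_EMOTIONS:
        ranked = table.rows.get(emotion, [])
        if not ranked:
            continue
        cells = [emotion.value.capitalize()]
        for au, score in ranked:
            cells += [str(au), f"{score:.4f}"]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_contribution_table(path: str | Path) -> dict[Emotion, list[tuple[int, float]]]:
    """Read back a TSV written by :func:`write_contribution_table`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows: dict[Emotion, list[tuple[int, float]]] = {}
    for line in lines[1:]:
        cells = line.split("\t")
        emotion = Emotion(cells[0].lower())
        pairs = [
            (int(cells[i]), float(cells[i + 1]))
            for i in range(1, len(cells) - 1, 2)
        ]
        rows[emotion] = pairs
    return rows
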