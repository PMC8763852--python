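"""Domain types and I/O for FACS action-unit annotated face samples.

A sample is a face image (or video episode) annotated with a combination of
FACS action units (AUs) — written in the usual ``"1+4+25"`` notation — plus a
crowdsourced emotion score vector: the proportion of independent raters who
assigned each of the six basic emotions or neutral to the sample.

AU tokens may carry an intensity letter (A–E) and a laterality prefix
(``L``/``R``); both are retained as metadata but never enter equality or set
membership, which is by AU number alone — the downstream contribution and
rule analyses operate on bare AU numbers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Emotion",
    "BASIC_EMOTIONS",
    "SCORE_LABELS",
    "AUCode",
    "EmotionScoreVector",
    "AnnotationRecord",
    "AUParseError",
    "AnnotationError",
    "parse_au_combination",
    "format_au_set",
    "read_annotations",
    "write_annotations",
]


class Emotion(str, Enum):
    """The six basic emotions, neutral, and the catch-all ``other``.

    The member order of the six basic emotions is canonical: it fixes matrix
    row order and breaks argmax ties deterministically.
    """

    HAPPINESS = "happiness"
    SURPRISE = "surprise"
    ANGER = "anger"
    FEAR = "fear"
    DISGUST = "disgust"
    SADNESS = "sadness"
    NEUTRAL = "neutral"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical order of the six basic emotions (tie-break and row order).
BASIC_EMOTIONS: tuple[Emotion, ...] = (
    Emotion.HAPPINESS,
    Emotion.SURPRISE,
    Emotion.ANGER,
    Emotion.FEAR,
    Emotion.DISGUST,
    Emotion.SADNESS,
)

#: The seven labels a rater may vote for (basic emotions + neutral).
SCORE_LABELS: tuple[Emotion, ...] = BASIC_EMOTIONS + (Emotion.NEUTRAL,)

_SCORE_SUM_TOL = 1e-6

_INTENSITIES = frozenset("ABCDE")
_LATERALITIES = frozenset({"left", "right", "bilateral"})
_TOKEN_RE = re.compile(r"^(?P<lat>[LR])?(?P<num>\d+)(?P<int>[A-E])?$")


class AUParseError(ValueError):
    """Raised for malformed AU combination strings; names the bad token."""


class AnnotationError(ValueError):
    """Raised for invalid annotation records or annotation files."""


@dataclass(frozen=True)
class AUCode:
    """One FACS action unit.

    Equality and hashing use the AU number only; intensity (A–E) and
    laterality are carried as metadata so that a parsed ``"R12B"`` survives a
    round-trip but compares equal to plain AU 12 in set operations.
    """

    number: int
    intensity: str | None = None
    laterality: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.number <= 64):
            raise AUParseError(f"AU number out of range 1-64: {self.number}")
        if self.intensity is not None and self.intensity not in _INTENSITIES:
            raise AUParseError(f"invalid AU intensity: {self.intensity!r}")
        if self.laterality is not None and self.laterality not in _LATERALITIES:
            raise AUParseError(f"invalid AU laterality: {self.laterality!r}")

    def __eq__(self, other: object) -> bool:
        if isinstance(other, AUCode):
            return self.number == other.number
        if isinstance(other, int):
            return self.number == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.number)

    def __str__(self) -> str:
        prefix = {"left": "L", "right": "R"}.get(self.laterality or "", "")
        suffix = self.intensity or ""
        return f"{prefix}{self.number}{suffix}"


def parse_au_combination(text: str) -> frozenset[AUCode]:
    """Parse a ``"+"``-separated FACS AU combination string.

    Each token is an optional ``L``/``R`` laterality prefix, the AU number,
    and an optional A–E intensity suffix. Duplicate AU numbers collapse to a
    single member; parsing is order-insensitive.

    Raises
    ------
    AUParseError
        For an empty string, an empty or non-numeric token, or an AU number
        outside 1–64. The message names the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise AUParseError("empty AU combination string")
    codes: dict[int, AUCode] = {}
    for token in text.strip().split("+"):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if not m:
            raise AUParseError(f"malformed AU token: {token!r} in {text!r}")
        number = int(m.group("num"))
        if not (1 <= number <= 64):
            raise AUParseError(f"AU number out of range 1-64: {token!r}")
        laterality = {"L": "left", "R": "right"}.get(m.group("lat") or "")
        code = AUCode(number, intensity=m.group("int"), laterality=laterality)
        codes.setdefault(number, code)
    return frozenset(codes.values())


def format_au_set(aus: Iterable[AUCode | int]) -> str:
    """Canonical string form: ascending AU numbers joined by ``"+"``.

    Metadata (laterality prefix, intensity suffix) is preserved per token so
    that writing and re-reading an annotation file keeps it. Round-trips with
    :func:`parse_au_combination` (by AU number).
    """
    codes = [au if isinstance(au, AUCode) else AUCode(au) for au in aus]
    if not codes:
        raise AnnotationError("cannot format an empty AU set")
    return "+".join(str(c) for c in sorted(codes, key=lambda c: c.number))


@dataclass(frozen=True)
class EmotionScoreVector:
    """Vote proportions over the six basic emotions plus neutral.

    Each score lies in [0, 1]. The sum may fall below 1 (raters can be
    excluded) but never exceeds it beyond floating tolerance, matching the
    vote-proportion semantics of crowdsourced emotion annotation.
    """

    scores: Mapping[Emotion, float]

    def __post_init__(self) -> None:
        clean: dict[Emotion, float] = {}
        for label in SCORE_LABELS:
            value = float(self.scores.get(label, 0.0))
            if not (0.0 <= value <= 1.0) or math.isnan(value):
                raise AnnotationError(
                    f"score for {label.value} outside [0, 1]: {value}"
                )
            clean[label] = value
        extra = set(self.scores) - set(SCORE_LABELS)
        if extra:
            raise AnnotationError(f"unexpected score labels: {sorted(extra)}")
        total = sum(clean.values())
        if total > 1.0 + _SCORE_SUM_TOL:
            raise AnnotationError(f"scores sum to {total} > 1")
        object.__setattr__(self, "scores", clean)

    def __getitem__(self, label: Emotion) -> float:
        return self.scores[label]

    def basic(self) -> dict[Emotion, float]:
        """Scores restricted to the six basic emotions (neutral dropped)."""
        return {e: self.scores[e] for e in BASIC_EMOTIONS}


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated sample: id, AU set, and crowdsourced score vector."""

    sample_id: str
    au_set: frozenset[AUCode]
    scores: EmotionScoreVector

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise AnnotationError("sample_id must be non-empty")
        if not self.au_set:
            raise AnnotationError(f"sample {self.sample_id}: empty AU set")
        object.__setattr__(self, "au_set", frozenset(self.au_set))

    @property
    def au_numbers(self) -> frozenset[int]:
        return frozenset(c.number for c in self.au_set)

    @property
    def au_combination(self) -> str:
        return format_au_set(self.au_set)


#: Column order of the annotation CSV carrier format.
ANNOTATION_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "au_combination",
    *(e.value for e in SCORE_LABELS),
)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation CSV (see :data:`ANNOTATION_COLUMNS`).

    Errors (missing column, score outside [0, 1], duplicate sample_id,
    malformed AU combination) are reported with the 1-based data row number.
    """
    frame = pd.read_csv(path, dtype={"sample_id": str, "au_combination": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    records: list[AnnotationRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            sample_id = str(row.sample_id)
            if sample_id in seen:
                raise AnnotationError(f"duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            scores = EmotionScoreVector(
                {e: getattr(row, e.value) for e in SCORE_LABELS}
            )
            records.append(
                AnnotationRecord(
                    sample_id=sample_id,
                    au_set=parse_au_combination(row.au_combination),
                    scores=scores,
                )
            )
        except ValueError as exc:
            raise AnnotationError(f"{path} row {i}: {exc}") from exc
    return records


def write_annotations(
    records: Sequence[AnnotationRecord], path: str | Path
) -> None:
    """Write records as CSV in the fixed carrier dialect (UTF-8, comma)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "au_combination": r.au_combination,
            **{e.value: r.scores[e] for e in SCORE_LABELS},
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    frame.to_csv(path, index=False)
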