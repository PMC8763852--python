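"""The emotion ↔ action-unit knowledge layer.

Holds the consolidated emotion→AU association table for the six basic
emotions, derives each emotion's *exclusive* AUs (those appearing in exactly
one emotion's set — their presence alone licenses coding that emotion), and
implements the rule-based coder that maps an observed AU combination to an
emotion label and a micro-expression class. Also carries static anatomy
metadata: which facial muscles and facial-nerve (CN VII) branch produce each
AU, and which face region a coder should watch for a given valence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping, Sequence

from .annotations import BASIC_EMOTIONS, Emotion

__all__ = [
    "EmotionAUTable",
    "ExclusiveAUMap",
    "CodingRule",
    "ClassificationResult",
    "AUAnatomyEntry",
    "set_difference",
    "derive_exclusive_sets",
    "builtin_emotion_au_table",
    "default_rules",
    "load_rules",
    "save_rules",
    "load_emotion_au_table",
    "classify_emotion",
    "map_to_me_class",
    "au_anatomy",
    "coder_focus_region",
    "NERVE_BRANCHES",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmotionAUTable:
    """Per-emotion AU association sets (S_i for each basic emotion i)."""

    sets: Mapping[Emotion, frozenset[int]]

    def __post_init__(self) -> None:
        clean: dict[Emotion, frozenset[int]] = {}
        for emotion, aus in self.sets.items():
            emotion = Emotion(emotion)
            aus = frozenset(int(a) for a in aus)
            if any(a < 1 for a in aus):
                raise ValueError(f"{emotion.value}: AU numbers must be >= 1")
            clean[emotion] = aus
        object.__setattr__(self, "sets", clean)

    def __getitem__(self, emotion: Emotion) -> frozenset[int]:
        return self.sets[emotion]

    @property
    def emotions(self) -> tuple[Emotion, ...]:
        return tuple(self.sets)


@dataclass(frozen=True)
class ExclusiveAUMap:
    """Exclusive AU sets Q_i: each a subset of S_i, pairwise disjoint."""

    exclusive: Mapping[Emotion, frozenset[int]]

    def __getitem__(self, emotion: Emotion) -> frozenset[int]:
        return self.exclusive[emotion]


def set_difference(a: AbstractSet[int], b: AbstractSet[int]) -> frozenset[int]:
    """Asymmetric set difference a \\ b: members of ``a`` not in ``b``.

    E.g. {3, 9, 14} \\ {1, 2, 3} = {9, 14}.
    """
    return frozenset(a) - frozenset(b)


def derive_exclusive_sets(
    table: EmotionAUTable, *, literal: bool = False
) -> ExclusiveAUMap:
    """Derive each emotion's exclusive AU set from the association table.

    The operative definition removes from S_i every AU that appears in any
    other emotion's set::

        Q_i = S_i \\ (union of S_j, j != i)

    so Q_i contains exactly the AUs belonging to emotion i alone. With
    ``literal=True`` the subtrahend is instead the *intersection* of the
    other sets — kept for auditability; on the built-in table that
    intersection is empty for every i, so the literal form degenerates to
    Q_i = S_i and distinguishes nothing.
    """
    exclusive: dict[Emotion, frozenset[int]] = {}
    for emotion in table.emotions:
        others = [table[e] for e in table.emotions if e != emotion]
        if not others:
            combined: frozenset[int] = frozenset()
        elif literal:
            combined = frozenset.intersection(*others)
        else:
            combined = frozenset.union(*others)
        exclusive[emotion] = set_difference(table[emotion], combined)
    return ExclusiveAUMap(exclusive=exclusive)


# Consolidated emotion→AU association table (data-driven contribution
# rankings reconciled with professional coding experience).
_BUILTIN_SETS: dict[Emotion, frozenset[int]] = {
    Emotion.HAPPINESS: frozenset({1, 6, 12, 14, 26, 27, 28}),
    Emotion.SURPRISE: frozenset({1, 2, 5, 25, 26, 27}),
    Emotion.ANGER: frozenset({4, 5, 9, 10, 16, 22, 23}),
    Emotion.FEAR: frozenset({1, 4, 5, 20, 25}),
    Emotion.DISGUST: frozenset({1, 4, 7, 9, 10, 14, 15, 17, 24, 25}),
    Emotion.SADNESS: frozenset({1, 4, 14, 15, 17, 43}),
}


def builtin_emotion_au_table() -> EmotionAUTable:
    """The built-in six-emotion AU association table."""
    return EmotionAUTable(sets=dict(_BUILTIN_SETS))


def load_emotion_au_table(path: str | Path) -> EmotionAUTable:
    """Load an emotion→AU table from JSON: ``{"happiness": [1, 6, ...], ...}``."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not data:
        raise ValueError(f"{path}: empty emotion-AU table")
    return EmotionAUTable(
        sets={Emotion(k): frozenset(v) for k, v in data.items()}
    )


@dataclass(frozen=True)
class CodingRule:
    """One coding rule: if all required AUs are present, code the outcome.

    Lower priority fires first. ``valence`` annotates rules whose outcome is
    only a polarity (e.g. the generic brow-furrow rule codes "a negative
    emotion", not a specific one).
    """

    required_aus: frozenset[int]
    outcome: Emotion
    priority: int
    description: str = ""
    valence: str | None = None

    def __post_init__(self) -> None:
        if not self.required_aus:
            raise ValueError("coding rule requires at least one AU")
        object.__setattr__(
            self, "required_aus", frozenset(int(a) for a in self.required_aus)
        )

    def matches(self, aus: AbstractSet[int]) -> bool:
        return self.required_aus <= frozenset(aus)


def default_rules() -> list[CodingRule]:
    """The built-in rule base, ordered by priority.

    Exclusive-AU rules fire first (most specific evidence), then multi-AU
    combination rules in decreasing pattern size, then the generic
    single-AU valence rule. Specificity-first ordering prevents the generic
    brow-furrow (AU4) rule from shadowing the fear and sadness combinations.
    """
    exclusive_outcomes: list[tuple[int, Emotion, str]] = [
        (12, Emotion.HAPPINESS, "lip corners pulled up: positive, happy"),
        (6, Emotion.HAPPINESS, "cheek raise: happiness-specific"),
        (28, Emotion.HAPPINESS, "lip suck: happiness-specific"),
        (2, Emotion.SURPRISE, "outer brow rise: surprise"),
        (16, Emotion.ANGER, "lower lip depress (gnashing): anger-specific"),
        (22, Emotion.ANGER, "lip funnel (gnashing): anger-specific"),
        (23, Emotion.ANGER, "lip tighten (gnashing): anger-specific"),
        (20, Emotion.FEAR, "lip stretch: fear-specific"),
        (7, Emotion.DISGUST, "lower eyelid rise: disgust-specific"),
        (24, Emotion.DISGUST, "lips pressed: disgust-specific"),
        (43, Emotion.SADNESS, "eyes closed: sadness-specific"),
    ]
    rules = [
        CodingRule(
            required_aus=frozenset({au}),
            outcome=outcome,
            priority=10 + i,
            description=desc,
        )
        for i, (au, outcome, desc) in enumerate(exclusive_outcomes)
    ]
    rules.append(
        CodingRule(
            required_aus=frozenset({1, 4, 5, 25}),
            outcome=Emotion.FEAR,
            priority=30,
            description="brows (AU1+AU4), eyes (AU5) and mouth (AU25) together: fear",
        )
    )
    rules.append(
        CodingRule(
            required_aus=frozenset({4, 5}),
            outcome=Emotion.SADNESS,
            priority=31,
            description="frown (AU4) with eyes wide open (AU5): sadness",
        )
    )
    rules.append(
        CodingRule(
            required_aus=frozenset({4}),
            outcome=Emotion.OTHER,
            priority=40,
            description="frown (AU4): a negative emotion, unspecified",
            valence="negative",
        )
    )
    return sorted(rules, key=lambda r: r.priority)


def save_rules(rules: Sequence[CodingRule], path: str | Path) -> None:
    """Serialize a rule base to JSON."""
    payload = [
        {
            "aus": sorted(r.required_aus),
            "outcome": r.outcome.value,
            "priority": r.priority,
            "description": r.description,
            **({"valence": r.valence} if r.valence else {}),
        }
        for r in rules
    ]
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_rules(path: str | Path) -> list[CodingRule]:
    """Load a rule base from JSON; priorities must be unique."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    rules = [
        CodingRule(
            required_aus=frozenset(item["aus"]),
            outcome=Emotion(item["outcome"]),
            priority=int(item["priority"]),
            description=item.get("description", ""),
            valence=item.get("valence"),
        )
        for item in payload
    ]
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError(f"{path}: duplicate rule priorities")
    return sorted(rules, key=lambda r: r.priority)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of rule-based coding of one AU combination."""

    label: Emotion
    rule: CodingRule | None
    conflict: tuple[Emotion, ...] = ()
    valence: str | None = None

    @property
    def me_class(self) -> str:
        return map_to_me_class(self.label)


def classify_emotion(
    aus: Iterable[int],
    rules: Sequence[CodingRule] | None = None,
    table: EmotionAUTable | None = None,
) -> ClassificationResult:
    """Code an AU combination with the rule base.

    Exclusive AUs of two or more different emotions present simultaneously
    is a contradiction: the outcome is ``other`` with the conflicting
    emotions reported. Otherwise the first rule (by priority) whose required
    AUs are all present fires; if no rule fires the label is ``other``.
    """
    au_numbers = frozenset(int(a) for a in aus)
    if not au_numbers:
        raise ValueError("cannot classify an empty AU set")
    if rules is None:
        rules = default_rules()
    exclusive = derive_exclusive_sets(table or builtin_emotion_au_table())
    conflicted = tuple(
        e for e in exclusive.exclusive if exclusive[e] & au_numbers
    )
    if len(conflicted) > 1:
        logger.info(
            "AU set %s carries exclusive AUs of %s: coded as other",
            sorted(au_numbers),
            [e.value for e in conflicted],
        )
        return ClassificationResult(
            label=Emotion.OTHER, rule=None, conflict=conflicted
        )
    for rule in sorted(rules, key=lambda r: r.priority):
        if rule.matches(au_numbers):
            return ClassificationResult(
                label=rule.outcome, rule=rule, valence=rule.valence
            )
    return ClassificationResult(label=Emotion.OTHER, rule=None)


#: Micro-expression classes.
ME_CLASSES = ("positive", "negative", "surprise", "other")


def map_to_me_class(emotion: Emotion) -> str:
    """Map an emotion label to its micro-expression class.

    Micro-expressions are conventionally grouped into four classes:
    happiness is positive; disgust, sadness, fear and anger are negative;
    surprise stands alone (interpretable only from context); neutral and
    ambiguous labels fall into other.
    """
    emotion = Emotion(emotion)
    if emotion is Emotion.HAPPINESS:
        return "positive"
    if emotion in (Emotion.DISGUST, Emotion.SADNESS, Emotion.FEAR, Emotion.ANGER):
        return "negative"
    if emotion is Emotion.SURPRISE:
        return "surprise"
    return "other"


#: The five terminal motor branches of the facial nerve (CN VII).
NERVE_BRANCHES = (
    "temporal",
    "zygomatic",
    "buccal",
    "marginal mandibular",
    "cervical",
)


@dataclass(frozen=True)
class AUAnatomyEntry:
    """Muscular and innervation metadata for one AU.

    ``nerve_branch`` is always one of the five CN VII branches. A few AUs
    (upper-lid raising, jaw movements) involve muscles innervated by other
    cranial nerves; for those the entry records the CN VII branch of the
    surrounding facial territory, since the table's purpose is to tell a
    coder where on the face to look.
    """

    au: int
    muscles: tuple[str, ...]
    nerve_branch: str
    face_region: str  # upper | mid | lower

    def __post_init__(self) -> None:
        if self.nerve_branch not in NERVE_BRANCHES:
            raise ValueError(f"unknown nerve branch: {self.nerve_branch!r}")
        if self.face_region not in ("upper", "mid", "lower"):
            raise ValueError(f"unknown face region: {self.face_region!r}")


_ANATOMY: dict[int, AUAnatomyEntry] = {
    e.au: e
    for e in [
        AUAnatomyEntry(1, ("frontalis, pars medialis",), "temporal", "upper"),
        AUAnatomyEntry(2, ("frontalis, pars lateralis",), "temporal", "upper"),
        AUAnatomyEntry(
            4,
            ("corrugator supercilii", "depressor supercilii"),
            "temporal",
            "upper",
        ),
        AUAnatomyEntry(5, ("levator palpebrae superioris",), "temporal", "upper"),
        AUAnatomyEntry(
            6, ("orbicularis oculi, pars orbitalis",), "zygomatic", "mid"
        ),
        AUAnatomyEntry(
            7, ("orbicularis oculi, pars palpebralis",), "zygomatic", "upper"
        ),
        AUAnatomyEntry(
            9, ("levator labii superioris alaeque nasi",), "buccal", "mid"
        ),
        AUAnatomyEntry(10, ("levator labii superioris",), "buccal", "mid"),
        AUAnatomyEntry(12, ("zygomaticus major",), "zygomatic", "mid"),
        AUAnatomyEntry(14, ("buccinator",), "buccal", "lower"),
        AUAnatomyEntry(
            15, ("depressor anguli oris",), "marginal mandibular", "lower"
        ),
        AUAnatomyEntry(
            16, ("depressor labii inferioris",), "marginal mandibular", "lower"
        ),
        AUAnatomyEntry(17, ("mentalis",), "marginal mandibular", "lower"),
        AUAnatomyEntry(20, ("risorius", "platysma"), "buccal", "lower"),
        AUAnatomyEntry(22, ("orbicularis oris",), "buccal", "lower"),
        AUAnatomyEntry(23, ("orbicularis oris",), "buccal", "lower"),
        AUAnatomyEntry(24, ("orbicularis oris",), "buccal", "lower"),
        AUAnatomyEntry(
            25,
            ("depressor labii inferioris", "orbicularis oris (relaxed)"),
            "buccal",
            "lower",
        ),
        AUAnatomyEntry(
            26, ("masseter (relaxed)", "digastric"), "marginal mandibular", "lower"
        ),
        AUAnatomyEntry(
            27, ("pterygoids", "digastric"), "marginal mandibular", "lower"
        ),
        AUAnatomyEntry(28, ("orbicularis oris",), "buccal", "lower"),
        AUAnatomyEntry(
            43,
            ("orbicularis oculi", "levator palpebrae superioris (relaxed)"),
            "temporal",
            "upper",
        ),
    ]
}


def au_anatomy(au: int) -> AUAnatomyEntry:
    """Muscle, nerve-branch and face-region metadata for an AU.

    Covers exactly the AUs of the built-in emotion table; anything else
    raises ``KeyError`` rather than guessing.
    """
    try:
        return _ANATOMY[int(au)]
    except KeyError:
        raise KeyError(f"no anatomy metadata for AU {au}") from None


_FOCUS_REGIONS = {
    "positive": "mid-face and mouth (zygomatic region, cheekbones)",
    "negative": "eyebrows and upper face (forehead, corrugator region)",
}


def coder_focus_region(valence: str) -> str:
    """Where a coder should look for expressions of a given valence.

    Positive expressions are driven mainly by zygomaticus activity, so the
    coder watches the mid-face and mouth; negative expressions by corrugator
    activity, so the coder watches the brows and forehead.
    """
    try:
        return _FOCUS_REGIONS[valence]
    except KeyError:
        raise ValueError(
            f"valence must be 'positive' or 'negative', got {valence!r}"
        ) from None
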