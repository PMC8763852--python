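"""Synthetic crowdsourced AU-annotation datasets with known ground truth.

Emulates a crowdsourced in-the-wild AU database: each sample has one latent
true emotion; its AU combination is the true emotion's association-table AUs
thinned by an emission rate plus spurious AUs; its emotion score vector is
the vote proportions of a panel of simulated raters, each voting the true
emotion with a fixed accuracy and otherwise uniformly among the remaining
six labels (including neutral).

Defaults mirror the annotation protocol the generator emulates: ~40 raters
per image, moderately reliable raters (accuracy 0.9), most true AUs visible
(emission 0.9), sparse spurious AUs (rate 0.05 per AU over 1–30), and a
uniform prior over the six basic emotions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    BASIC_EMOTIONS,
    SCORE_LABELS,
    AnnotationRecord,
    AUCode,
    Emotion,
    EmotionScoreVector,
)
from .relations import EmotionAUTable, builtin_emotion_au_table
from .reliability import CoderLabelSet

__all__ = [
    "SynthConfig",
    "generate_annotations",
    "generate_coder_panel",
    "write_truth",
    "read_truth",
]

#: Spurious AUs are drawn from this pool (overlaps the observed AU range).
NOISE_AU_POOL: tuple[int, ...] = tuple(range(1, 31))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the emulated study conditions."""

    n_samples: int
    n_raters: int = 40
    rater_accuracy: float = 0.9
    emission_rate: float = 0.9
    noise_au_rate: float = 0.05
    emotion_prior: Mapping[Emotion, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be >= 0: {self.n_samples}")
        if self.n_raters < 1:
            raise ValueError(f"n_raters must be >= 1: {self.n_raters}")
        for name in ("rater_accuracy", "emission_rate", "noise_au_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]: {p}")
        if self.emotion_prior is not None:
            prior = {Emotion(k): float(v) for k, v in self.emotion_prior.items()}
            if any(p < 0 for p in prior.values()):
                raise ValueError("emotion_prior probabilities must be >= 0")
            total = sum(prior.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"emotion_prior sums to {total}, not 1")
            object.__setattr__(self, "emotion_prior", prior)

    def prior_vector(self) -> np.ndarray:
        if self.emotion_prior is None:
            return np.full(len(BASIC_EMOTIONS), 1.0 / len(BASIC_EMOTIONS))
        return np.array(
            [self.emotion_prior.get(e, 0.0) for e in BASIC_EMOTIONS]
        )


def generate_annotations(
    cfg: SynthConfig, table: EmotionAUTable | None = None
) -> tuple[list[AnnotationRecord], dict[str, Emotion]]:
    """Generate annotation records plus the latent truth map.

    Per sample: the true emotion is drawn from the prior; each AU of the
    true emotion's association set is kept with probability
    ``emission_rate`` (at least one is forced, so the AU set is never
    empty); each AU of the 1–30 noise pool is added with probability
    ``noise_au_rate``; rater votes over the seven labels are one multinomial
    draw with probability ``rater_accuracy`` on the true emotion and the
    remainder spread uniformly over the other six labels. A fixed seed gives
    bit-identical output.
    """
    table = table or builtin_emotion_au_table()
    rng = np.random.default_rng(cfg.seed)
    prior = cfg.prior_vector()
    records: list[AnnotationRecord] = []
    truth: dict[str, Emotion] = {}
    width = max(4, len(str(max(cfg.n_samples, 1))))
    for i in range(cfg.n_samples):
        sample_id = f"s{i + 1:0{width}d}"
        true_emotion = BASIC_EMOTIONS[rng.choice(len(BASIC_EMOTIONS), p=prior)]
        true_aus = sorted(table[true_emotion])
        keep = rng.random(len(true_aus)) < cfg.emission_rate
        kept = [au for au, k in zip(true_aus, keep) if k]
        if not kept:  # a record must carry at least one true AU
            kept = [true_aus[rng.integers(len(true_aus))]]
        aus = set(kept)
        noise = rng.random(len(NOISE_AU_POOL)) < cfg.noise_au_rate
        aus.update(au for au, n in zip(NOISE_AU_POOL, noise) if n)
        # Rater votes: true label w.p. accuracy, else uniform over the rest.
        p = np.full(
            len(SCORE_LABELS), (1.0 - cfg.rater_accuracy) / (len(SCORE_LABELS) - 1)
        )
        p[SCORE_LABELS.index(true_emotion)] = cfg.rater_accuracy
        votes = rng.multinomial(cfg.n_raters, p)
        scores = EmotionScoreVector(
            {
                label: votes[j] / cfg.n_raters
                for j, label in enumerate(SCORE_LABELS)
            }
        )
        records.append(
            AnnotationRecord(
                sample_id=sample_id,
                au_set=frozenset(AUCode(a) for a in aus),
                scores=scores,
            )
        )
        truth[sample_id] = true_emotion
    return records, truth


def generate_coder_panel(
    records: Sequence[AnnotationRecord],
    truth: Mapping[str, Emotion],
    n_coders: int = 2,
    coder_accuracy: float = 0.9,
    seed: int = 0,
) -> dict[str, list[CoderLabelSet]]:
    """Simulate a coder panel for reliability analysis.

    Each coder labels each sample with its true emotion with probability
    ``coder_accuracy``, otherwise with one of the other six labels drawn
    uniformly. Deterministic under the seed.
    """
    if n_coders < 2:
        raise ValueError(f"need at least 2 coders, got {n_coders}")
    if not (0.0 <= coder_accuracy <= 1.0):
        raise ValueError(f"coder_accuracy must be in [0, 1]: {coder_accuracy}")
    rng = np.random.default_rng(seed)
    panel: dict[str, list[CoderLabelSet]] = {}
    labels = list(SCORE_LABELS)
    for record in records:
        true_emotion = truth[record.sample_id]
        others = [e for e in labels if e is not true_emotion]
        coders = []
        for c in range(n_coders):
            if rng.random() < coder_accuracy:
                label = true_emotion
            else:
                label = others[rng.integers(len(others))]
            coders.append(
                CoderLabelSet(
                    coder_id=f"coder{c + 1}", labels=frozenset({label.value})
                )
            )
        panel[record.sample_id] = coders
    return panel


def write_truth(truth: Mapping[str, Emotion], path: str | Path) -> None:
    """Write the latent truth map as CSV (sample_id, true_emotion)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "true_emotion"])
        for sample_id, emotion in truth.items():
            writer.writerow([sample_id, emotion.value])


def read_truth(path: str | Path) -> dict[str, Emotion]:
    """Read a truth map written by :func:`write_truth`."""
    truth: dict[str, Emotion] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            truth[row["sample_id"]] = Emotion(row["true_emotion"])
    return truth
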