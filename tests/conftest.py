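import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aucoding import (
    BASIC_EMOTIONS,
    SCORE_LABELS,
    AnnotationRecord,
    AUCode,
    Emotion,
    EmotionScoreVector,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(sample_id, aus, **scores):
    """Record with the given AU numbers and keyword scores (others 0)."""
    vec = {e: 0.0 for e in SCORE_LABELS}
    for name, value in scores.items():
        vec[Emotion(name)] = value
    return AnnotationRecord(
        sample_id=sample_id,
        au_set=frozenset(AUCode(a) for a in aus),
        scores=EmotionScoreVector(vec),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_records(rng):
    """Small random but valid annotation dataset for oracle comparisons."""

    def build(n, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        records = []
        for i in range(n):
            aus = local.choice(
                np.arange(1, 31),
                size=local.integers(1, 6),
                replace=False,
            )
            raw = local.dirichlet(np.ones(len(SCORE_LABELS)))
            scores = EmotionScoreVector(
                dict(zip(SCORE_LABELS, (float(x) for x in raw)))
            )
            records.append(
                AnnotationRecord(
                    sample_id=f"r{i}",
                    au_set=frozenset(AUCode(int(a)) for a in aus),
                    scores=scores,
                )
            )
        return records

    return build
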