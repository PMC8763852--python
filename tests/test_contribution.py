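"""Contribution-scoring algorithms against independent brute-force oracles."""

import math

import pytest

from aucoding import (
    BASIC_EMOTIONS,
    Emotion,
    compute_contribution_max,
    compute_contribution_weighted,
    top_k,
    write_contribution_table,
)
from aucoding.contribution import read_contribution_table
from conftest import make_record


def oracle_weighted(records):
    """Naive triple loop: every record, every AU, every basic emotion."""
    c = {e: {} for e in BASIC_EMOTIONS}
    for r in records:
        for au in sorted(r.au_numbers):
            for e in BASIC_EMOTIONS:
                s = r.scores[e]
                if s:
                    c[e][au] = c[e].get(au, 0.0) + s
    return c


def oracle_max(records):
    """Independent accumulation: argmax emotion, first-appearance dedup,
    then row normalization."""
    c = {e: {} for e in BASIC_EMOTIONS}
    seen = set()
    for r in records:
        basic = r.scores.basic()
        best = max(basic.values())
        if best == 0.0:
            continue
        emotion = next(e for e in BASIC_EMOTIONS if basic[e] == best)
        combo = "+".join(str(a) for a in sorted(r.au_numbers))
        if (combo, emotion) in seen:
            continue
        seen.add((combo, emotion))
        for au in r.au_numbers:
            c[emotion][au] = c[emotion].get(au, 0.0) + basic[emotion]
    for row in c.values():
        total = sum(row.values())
        for au in row:
            row[au] /= total
    return c


def rows_close(a, b, tol=1e-12):
    for e in BASIC_EMOTIONS:
        if set(a[e]) != set(b[e]):
            return False
        if any(abs(a[e][au] - b[e][au]) > tol for au in a[e]):
            return False
    return True


class TestMaxDedup:
    def test_single_record_row_normalizes_to_one(self):
        m = compute_contribution_max([make_record("a", [12], happiness=0.8)])
        assert m.values[Emotion.HAPPINESS] == {12: 1.0}
        assert all(not m.values[e] for e in BASIC_EMOTIONS if e is not Emotion.HAPPINESS)

    def test_two_record_accumulation_matches_hand_oracle(self):
        # r1 adds 0.6 to AUs {12,25}; r2 adds 0.9 to AU 12; row sum 2.1.
        records = [
            make_record("r1", [12, 25], happiness=0.6, surprise=0.2),
            make_record("r2", [12], happiness=0.9),
        ]
        m = compute_contribution_max(records)
        row = m.values[Emotion.HAPPINESS]
        assert math.isclose(row[12], 1.5 / 2.1)
        assert math.isclose(row[25], 0.6 / 2.1)

    def test_duplicate_combination_emotion_pair_is_ignored(self):
        r1 = make_record("r1", [12, 25], happiness=0.6)
        r1_dup = make_record("r1b", [12, 25], happiness=0.6)
        base = compute_contribution_max([r1])
        with_dup = compute_contribution_max([r1, r1_dup])
        assert base.values == with_dup.values

    def test_rows_sum_to_one_or_zero(self, random_records):
        m = compute_contribution_max(random_records(40))
        for e in BASIC_EMOTIONS:
            total = sum(m.values[e].values())
            assert total == 0.0 or math.isclose(total, 1.0, abs_tol=1e-9)

    def test_neutral_never_wins_argmax(self):
        # neutral 0.9 dominates but only basic emotions compete
        m = compute_contribution_max(
            [make_record("a", [4], neutral=0.9, sadness=0.1)]
        )
        assert m.values[Emotion.SADNESS] == {4: 1.0}

    def test_argmax_tie_breaks_in_canonical_order(self):
        m = compute_contribution_max(
            [make_record("a", [5], surprise=0.4, anger=0.4)]
        )
        assert m.values[Emotion.SURPRISE] == {5: 1.0}
        assert not m.values[Emotion.ANGER]

    def test_all_zero_basic_record_skipped_not_fatal(self):
        records = [
            make_record("a", [12], neutral=1.0),
            make_record("b", [12], happiness=0.5),
        ]
        m = compute_contribution_max(records)
        assert m.values[Emotion.HAPPINESS] == {12: 1.0}

    def test_matches_independent_oracle_on_random_data(self, random_records):
        records = random_records(50)
        assert rows_close(
            compute_contribution_max(records).values, oracle_max(records)
        )

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            compute_contribution_max([])


class TestWeightedSum:
    def test_single_record_accumulates_full_vector(self):
        m = compute_contribution_weighted(
            [make_record("a", [12], happiness=0.5, surprise=0.3)]
        )
        assert m.values[Emotion.HAPPINESS][12] == 0.5
        assert m.values[Emotion.SURPRISE][12] == 0.3

    def test_repetitions_double_entries(self):
        r = make_record("a", [12], happiness=0.5, surprise=0.3)
        r2 = make_record("b", [12], happiness=0.5, surprise=0.3)
        m = compute_contribution_weighted([r, r2])
        assert m.values[Emotion.HAPPINESS][12] == 1.0
        assert m.values[Emotion.SURPRISE][12] == 0.6

    def test_matches_triple_loop_oracle_exactly(self, random_records):
        records = random_records(20)
        assert compute_contribution_weighted(records).values == oracle_weighted(
            records
        )

    def test_order_invariant(self, random_records):
        records = random_records(30)
        forward = compute_contribution_weighted(records).values
        backward = compute_contribution_weighted(records[::-1]).values
        assert rows_close(forward, backward)

    def test_adding_record_never_decreases_entries(self, random_records):
        records = random_records(10)
        before = compute_contribution_weighted(records).values
        extra = make_record("extra", [12], happiness=0.4)
        after = compute_contribution_weighted(records + [extra]).values
        for e in BASIC_EMOTIONS:
            for au, v in before[e].items():
                assert after[e][au] >= v - 1e-15

    def test_normalize_flag_rescales_rows(self, random_records):
        m = compute_contribution_weighted(random_records(20), normalize=True)
        for e in BASIC_EMOTIONS:
            if m.values[e]:
                assert math.isclose(sum(m.values[e].values()), 1.0, abs_tol=1e-9)


class TestTopK:
    def test_selects_highest(self):
        m = compute_contribution_weighted(
            [make_record("a", [12, 25], happiness=0.7)]
        )
        t = top_k(m, 1)
        assert t.rows[Emotion.HAPPINESS] == [(12, 0.7)]

    def test_k_larger_than_row_returns_all_sorted(self):
        m = compute_contribution_weighted(
            [
                make_record("a", [25], happiness=0.3),
                make_record("b", [12], happiness=0.7),
            ]
        )
        assert top_k(m, 10).rows[Emotion.HAPPINESS] == [(12, 0.7), (25, 0.3)]

    def test_ties_break_by_ascending_au(self):
        m = compute_contribution_weighted(
            [make_record("a", [2, 1], happiness=0.5)]
        )
        assert top_k(m, 2).rows[Emotion.HAPPINESS] == [(1, 0.5), (2, 0.5)]

    def test_k_below_one_rejected(self):
        m = compute_contribution_weighted([make_record("a", [1], happiness=0.5)])
        with pytest.raises(ValueError):
            top_k(m, 0)


class TestTableIO:
    def test_row_formatting_four_decimals(self, tmp_path):
        m = compute_contribution_weighted(
            [make_record("a", [12], happiness=0.23119)]
        )
        path = tmp_path / "t.tsv"
        write_contribution_table(top_k(m, 10), path)
        lines = path.read_text().splitlines()
        assert lines[1] == "Happiness\t12\t0.2312"

    def test_round_trip_at_four_decimals(self, tmp_path, random_records):
        m = compute_contribution_weighted(random_records(30))
        table = top_k(m, 5)
        path = tmp_path / "t.tsv"
        write_contribution_table(table, path)
        back = read_contribution_table(path)
        for e, ranked in table.rows.items():
            expected = [(au, round(s, 4)) for au, s in ranked]
            assert [(au, round(s, 4)) for au, s in back.get(e, [])] == expected

    def test_empty_table_writes_header_only(self, tmp_path):
        from aucoding import RankedContributionTable

        table = RankedContributionTable(rows={}, method="weighted_sum", k=3)
        path = tmp_path / "e.tsv"
        write_contribution_table(table, path)
        assert len(path.read_text().strip().splitlines()) == 1
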