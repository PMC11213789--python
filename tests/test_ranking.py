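"""Merge-insertion ranking engine: correctness, comparison bounds,
session semantics and persistence."""

import itertools
import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iqrank import (
    ComparisonSession,
    ProtocolError,
    SessionStateError,
    ValidationError,
    fj_rank,
    fj_worst_case,
    pair_count,
)
from .conftest import truthful_oracle


class TestCountingFormulas:
    @pytest.mark.parametrize(
        "n,expected", [(1, 0), (2, 1), (3, 3), (4, 5), (5, 7), (10, 22), (50, 219)]
    )
    def test_worst_case_closed_form(self, n, expected):
        assert fj_worst_case(n) == expected

    @pytest.mark.parametrize("n,expected", [(1, 0), (2, 1), (7, 21), (50, 1225)])
    def test_round_robin_pair_count(self, n, expected):
        assert pair_count(n) == expected

    @pytest.mark.parametrize("bad", [0, -3, 1.5, "x"])
    def test_invalid_n_rejected(self, bad):
        with pytest.raises(ValidationError):
            fj_worst_case(bad)
        with pytest.raises(ValidationError):
            pair_count(bad)

    def test_worst_case_below_round_robin(self):
        # the whole point of the algorithm: far fewer than all pairs
        assert fj_worst_case(50) <= 220 < pair_count(50)


def run_truthful(n, perm, seed=0):
    values = dict(zip(range(n), perm))
    return fj_rank(list(range(n)), truthful_oracle(values), seed=seed), values


class TestSortingCorrectness:
    def test_single_item_needs_no_comparison(self):
        ranking, records = fj_rank(["a"], lambda l, r: l)
        assert ranking.item_ids == ("a",) and records == []

    def test_three_items_exhaustive(self):
        # true order c < b < a under every input permutation
        values = {"c": 0, "b": 1, "a": 2}
        worst = 0
        for perm in itertools.permutations("abc"):
            ranking, records = fj_rank(list(perm), truthful_oracle(values))
            assert ranking.item_ids == ("c", "b", "a")
            assert len(records) <= 3
            worst = max(worst, len(records))
        assert worst == 3

    @pytest.mark.parametrize("n", range(1, 7))
    def test_exhaustive_small_n(self, n):
        """Every permutation sorts correctly, never repeats a pair, and
        the max comparison count attains the closed-form bound."""
        worst = 0
        for perm in itertools.permutations(range(n)):
            (ranking, records), values = run_truthful(n, perm)
            assert [values[i] for i in ranking.item_ids] == sorted(perm)
            pairs = {frozenset((r.left_id, r.right_id)) for r in records}
            assert len(pairs) == len(records), "a pair was asked twice"
            assert len(records) <= fj_worst_case(n)
            worst = max(worst, len(records))
        if n > 1:
            assert worst == fj_worst_case(n)

    def test_fifty_items_within_bound(self, rng):
        ids = [f"s{i:02d}" for i in range(50)]
        for _ in range(20):
            perm = rng.permutation(50)
            values = dict(zip(ids, perm.tolist()))
            ranking, records = fj_rank(ids, truthful_oracle(values), seed=3)
            assert len(records) <= fj_worst_case(50) == 219
            assert [values[i] for i in ranking.item_ids] == sorted(values.values())

    @given(st.permutations(list(range(12))), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_property_correct_bounded_norepeat(self, perm, seed):
        n = len(perm)
        (ranking, records), values = run_truthful(n, tuple(perm), seed=seed)
        assert [values[i] for i in ranking.item_ids] == sorted(perm)
        pairs = {frozenset((r.left_id, r.right_id)) for r in records}
        assert len(pairs) == len(records) <= min(fj_worst_case(n), pair_count(n))

    def test_rank_direction_low_to_high(self):
        values = {"worst": 0, "mid": 1, "best": 2}
        ranking, _ = fj_rank(["mid", "best", "worst"], truthful_oracle(values))
        assert ranking.rank_of["worst"] == 1 and ranking.rank_of["best"] == 3


class TestSessionProtocol:
    def test_two_items_forced_outcome(self):
        s = ComparisonSession(["a", "b"])
        assert set(s.next_pair()) == {"a", "b"}
        s.submit_choice("b")
        assert s.status == "complete"
        assert s.ranking().rank_of == {"a": 1, "b": 2}

    def test_third_pair_compares_within_pair_winners(self):
        # first step of merge-insertion on n=4: two bouts, then the
        # winners meet in the recursive ranking of the main chain
        s = ComparisonSession(["a", "b", "c", "d"], seed=0)
        winners = []
        for _ in range(2):
            left, right = s.next_pair()
            winners.append(left)
            s.submit_choice(left)
        assert set(s.next_pair()) == set(winners)

    def test_next_pair_is_pure(self):
        s = ComparisonSession(list("abcde"), seed=9)
        assert s.next_pair() == s.next_pair()

    def test_duplicate_items_rejected(self):
        with pytest.raises(ValidationError):
            ComparisonSession(["a", "a", "b"])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ComparisonSession([])

    def test_choice_outside_pair_is_protocol_error(self):
        s = ComparisonSession(list("abcd"))
        with pytest.raises(ProtocolError) as err:
            s.submit_choice("zzz")
        assert err.value.record_index == 1

    def test_complete_session_refuses_further_moves(self):
        s = ComparisonSession(["a", "b"])
        s.submit_choice(s.next_pair()[0])
        with pytest.raises(SessionStateError):
            s.next_pair()
        with pytest.raises(SessionStateError):
            s.submit_choice("a")
        with pytest.raises(SessionStateError):
            ComparisonSession(["a", "b"]).ranking()

    def test_oracle_returning_foreign_id_names_record(self):
        with pytest.raises(ProtocolError) as err:
            fj_rank(list("abcd"), lambda l, r: "nope")
        assert err.value.record_index == 1


class TestDeterminismAndPersistence:
    def make_driver(self, ids, values, seed):
        s = ComparisonSession(ids, seed=seed)
        oracle = truthful_oracle(values)
        while s.status == "pending":
            left, right = s.next_pair()
            s.submit_choice(oracle(left, right))
        return s

    def test_interactive_equals_batch(self, rng):
        ids = [f"s{i:02d}" for i in range(50)]
        values = dict(zip(ids, rng.permutation(50).tolist()))
        batch_ranking, batch_records = fj_rank(ids, truthful_oracle(values), seed=42)
        s = self.make_driver(ids, values, seed=42)
        assert s.ranking().item_ids == batch_ranking.item_ids
        assert s.records == batch_records

    def test_same_seed_same_pair_sequence(self, rng):
        ids = list("abcdefghij")
        values = dict(zip(ids, range(10)))
        _, rec1 = fj_rank(ids, truthful_oracle(values), seed=5)
        _, rec2 = fj_rank(ids, truthful_oracle(values), seed=5)
        assert rec1 == rec2

    def test_seed_controls_presentation_sides(self):
        ids = list("abcdefgh")
        values = dict(zip(ids, range(8)))
        logs = {
            seed: fj_rank(ids, truthful_oracle(values), seed=seed)[1]
            for seed in range(20)
        }
        sides = {tuple((r.left_id, r.right_id) for r in rec) for rec in logs.values()}
        assert len(sides) > 1, "presentation sides never varied with the seed"

    def test_serialize_resume_midway(self, rng, tmp_path):
        ids = [f"s{i}" for i in range(20)]
        values = dict(zip(ids, rng.permutation(20).tolist()))
        oracle = truthful_oracle(values)

        full = self.make_driver(ids, values, seed=7)

        s = ComparisonSession(ids, seed=7)
        for _ in range(15):
            left, right = s.next_pair()
            s.submit_choice(oracle(left, right))
        path = tmp_path / "session.json"
        s.save(path)

        resumed = ComparisonSession.load(path)
        assert resumed.next_pair() == s.next_pair()
        while resumed.status == "pending":
            left, right = resumed.next_pair()
            resumed.submit_choice(oracle(left, right))
        assert resumed.ranking().item_ids == full.ranking().item_ids
        assert resumed.records == full.records

    def test_session_json_schema(self, tmp_path):
        s = ComparisonSession(["a", "b"], seed=1)
        s.submit_choice(s.next_pair()[1])
        path = tmp_path / "done.json"
        s.save(path)
        data = json.loads(path.read_text())
        assert set(data) == {"items", "seed", "records", "status"}
        assert data["status"] == "complete"
        assert set(data["records"][0]) == {"index", "left", "right", "chosen"}

    def test_tampered_log_rejected(self, tmp_path):
        s = ComparisonSession(list("abcd"), seed=2)
        left, right = s.next_pair()
        s.submit_choice(left)
        data = s.to_dict()
        data["records"][0]["left"] = "zzz"
        data["records"][0]["right"] = "qqq"
        with pytest.raises((ValidationError, ProtocolError)):
            ComparisonSession.from_dict(data)

    def test_ranking_csv_export(self, tmp_path):
        s = ComparisonSession(["a", "b"])
        s.submit_choice("b")
        path = tmp_path / "ranking.csv"
        s.ranking().to_csv(path)
        assert path.read_text() == "item_id,rank\na,1\nb,2\n"
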