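"""Comparison-minimizing pairwise ranking via merge-insertion sort.

Ranking a set of items by forced-choice pairwise comparisons is the core
of the pairwise-comparison (PC) protocol for subjective image-quality
assessment: an observer is repeatedly shown two scans and must pick the
one with the higher quality, until a complete ranking (rank 1 = lowest,
rank n = highest) is determined.  Because a human answers every
comparison, the number of comparisons is the cost that matters, and the
Ford-Johnson algorithm (merge-insertion sort) is the classical scheme
that minimizes the worst case: for n = 50 it needs at most 219
comparisons instead of the 1225 of a full round robin.

The algorithm proceeds in three phases:

1. pair the items and compare within each pair (the odd item, if any,
   is set aside as a "straggler");
2. recursively rank the pair winners, which forms the main chain;
3. binary-insert each loser into the chain, processing losers in groups
   delimited by the Jacobsthal numbers 1, 3, 5, 11, 21, ... and in
   descending index order within a group, so every binary search scans
   a window of at most 2^t - 1 chain elements and therefore costs at
   most t comparisons.

The worst-case total is F(n) = sum_{k=1..n} ceil(log2(3k/4)).

Two entry points are provided: :func:`fj_rank` runs a comparison oracle
(a callable) to completion in one call, and :class:`ComparisonSession`
exposes the same algorithm one pair at a time so a human observer can
answer interactively, stop, serialize the session to JSON and resume
later.  The comparison log is the source of truth for a session: the
internal sorting state is reconstructed by replaying the log, which
makes persisted sessions robust to refactors of the sorter itself.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Generator, Hashable, Iterable, Sequence

from .errors import ProtocolError, SessionStateError, ValidationError

__all__ = [
    "ComparisonRecord",
    "ComparisonSession",
    "Ranking",
    "fj_rank",
    "fj_worst_case",
    "pair_count",
]

ItemId = Hashable
Oracle = Callable[[ItemId, ItemId], ItemId]


@dataclass(frozen=True)
class ComparisonRecord:
    """One logged forced-choice comparison.

    ``left_id``/``right_id`` are the presentation sides actually shown;
    ``chosen_id`` is the side the oracle preferred (higher quality).
    """

    index: int
    left_id: ItemId
    right_id: ItemId
    chosen_id: ItemId

    def __post_init__(self):
        if self.left_id == self.right_id:
            raise ValidationError("a comparison needs two distinct items")
        if self.chosen_id not in (self.left_id, self.right_id):
            raise ProtocolError(
                f"chosen id {self.chosen_id!r} is not in the offered pair "
                f"({self.left_id!r}, {self.right_id!r}) at record {self.index}",
                record_index=self.index,
            )


@dataclass(frozen=True)
class Ranking:
    """A strict total order: ``item_ids[0]`` is rank 1 = lowest quality."""

    item_ids: tuple
    rank_of: dict = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "rank_of", {it: i + 1 for i, it in enumerate(self.item_ids)}
        )

    def __len__(self) -> int:
        return len(self.item_ids)

    def to_csv(self, path) -> None:
        """Write ``item_id,rank`` rows (rank 1 = lowest quality)."""
        with open(path, "w") as fh:
            fh.write("item_id,rank\n")
            for i, item in enumerate(self.item_ids, start=1):
                fh.write(f"{item},{i}\n")


def pair_count(n: int) -> int:
    """Number of unordered pairs among n items: the full round-robin cost."""
    if not isinstance(n, int) or n < 1:
        raise ValidationError(f"n must be a positive integer, got {n!r}")
    return n * (n - 1) // 2


def fj_worst_case(n: int) -> int:
    """Worst-case comparisons of merge-insertion: sum of ceil(log2(3k/4)).

    Computed in exact integer arithmetic: ceil(log2(3k/4)) equals
    ``max(0, bit_length(3k - 1) - 2)``.
    """
    if not isinstance(n, int) or n < 1:
        raise ValidationError(f"n must be a positive integer, got {n!r}")
    return sum(max(0, (3 * k - 1).bit_length() - 2) for k in range(1, n + 1))


def _jacobsthal_insertion_order(m: int) -> list[int]:
    """Loser indices 2..m in canonical merge-insertion order.

    Groups end at 3, 5, 11, 21, ... (t_k = (2^{k+1} + (-1)^k) / 3) and
    are processed in descending index order, which keeps every binary
    search window at 2^k - 1 elements or fewer.
    """
    order: list[int] = []
    prev, k = 1, 2
    while prev < m:
        t = (2 ** (k + 1) + (-1) ** k) // 3
        order.extend(range(min(t, m), prev, -1))
        prev, k = t, k + 1
    return order


def _merge_insertion(items: Sequence[ItemId]) -> Generator:
    """Generator-based merge-insertion sort (ascending).

    Yields the unordered pair to compare; the caller sends back the id
    of the preferred (greater) item.  Returns the sorted list via
    StopIteration.value, so recursion composes with ``yield from``.
    """
    n = len(items)
    if n == 1:
        return [items[0]]

    winners: list[ItemId] = []
    loser_of: dict[ItemId, ItemId] = {}
    for i in range(0, n - 1, 2):
        x, y = items[i], items[i + 1]
        chosen = yield (x, y)
        w, l = (x, y) if chosen == x else (y, x)
        winners.append(w)
        loser_of[w] = l
    straggler = items[-1] if n % 2 else None

    chain_winners = yield from _merge_insertion(winners)

    # main chain: b1 < a1 <= a2 <= ... ; b1 needs no comparison
    losers = [loser_of[w] for w in chain_winners]
    chain: list[ItemId] = [losers[0], *chain_winners]

    m_total = len(losers) + (1 if straggler is not None else 0)
    for j in _jacobsthal_insertion_order(m_total):
        if j <= len(losers):
            elem = losers[j - 1]
            # search strictly below the partner a_j: b_j < a_j is known
            hi = chain.index(chain_winners[j - 1])
        else:
            elem = straggler
            hi = len(chain)
        lo = 0
        while lo < hi:
            mid = (lo + hi) // 2
            chosen = yield (elem, chain[mid])
            if chosen == elem:
                lo = mid + 1
            else:
                hi = mid
        chain.insert(lo, elem)
    return chain


class ComparisonSession:
    """Resumable interactive state of one observer's ranking run.

    Drives :func:`_merge_insertion` one comparison at a time.  The side
    on which each item is presented (left vs right) is randomized from
    ``seed`` to control presentation-order bias; the randomization is
    part of the logged record so replays are exact.

    The session serializes to JSON holding ``items``, ``seed``, the full
    comparison log and ``status``; on load the sorter is rebuilt by
    replaying the log, and the replayed pair sequence is checked against
    the logged one.
    """

    def __init__(self, item_ids: Iterable[ItemId], seed: int = 0):
        items = list(item_ids)
        if len(items) < 1:
            raise ValidationError("need at least one item")
        if len(set(items)) != len(items):
            raise ValidationError("item identifiers must be distinct")
        self.item_ids = items
        self.seed = int(seed)
        self.records: list[ComparisonRecord] = []
        self._sides = random.Random(self.seed)
        self._gen = _merge_insertion(self.item_ids)
        self._current: tuple[ItemId, ItemId] | None = None
        self._ranking: Ranking | None = None
        self._advance(None)

    # -- state machine ------------------------------------------------

    @property
    def status(self) -> str:
        return "complete" if self._ranking is not None else "pending"

    def _advance(self, chosen: ItemId | None) -> None:
        try:
            pair = self._gen.send(chosen)
        except StopIteration as stop:
            self._current = None
            self._ranking = Ranking(tuple(stop.value))
            return
        # presentation side drawn once per issued pair
        if self._sides.getrandbits(1):
            pair = (pair[1], pair[0])
        self._current = pair

    def next_pair(self) -> tuple[ItemId, ItemId]:
        """The pair to present now, as (left_id, right_id).

        Pure: repeated calls without :meth:`submit_choice` return the
        same pair.
        """
        if self._ranking is not None:
            raise SessionStateError("session is complete; no further pairs")
        assert self._current is not None
        return self._current

    def submit_choice(self, chosen_id: ItemId) -> "ComparisonSession":
        """Record the observer's choice for the outstanding pair."""
        if self._ranking is not None:
            raise SessionStateError("session is complete; no outstanding pair")
        left, right = self._current
        index = len(self.records) + 1
        if chosen_id not in (left, right):
            raise ProtocolError(
                f"chosen id {chosen_id!r} is not in the offered pair "
                f"({left!r}, {right!r}) at record {index}",
                record_index=index,
            )
        self.records.append(ComparisonRecord(index, left, right, chosen_id))
        self._advance(chosen_id)
        return self

    def ranking(self) -> Ranking:
        if self._ranking is None:
            raise SessionStateError("session is not complete")
        return self._ranking

    # -- persistence --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "items": list(self.item_ids),
            "seed": self.seed,
            "records": [
                {
                    "index": r.index,
                    "left": r.left_id,
                    "right": r.right_id,
                    "chosen": r.chosen_id,
                }
                for r in self.records
            ],
            "status": self.status,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, data: dict) -> "ComparisonSession":
        session = cls(data["items"], seed=data["seed"])
        for rec in data["records"]:
            pair = session.next_pair()
            if {pair[0], pair[1]} != {rec["left"], rec["right"]} or pair != (
                rec["left"],
                rec["right"],
            ):
                raise ValidationError(
                    f"log replay diverged at record {rec['index']}: "
                    f"expected pair {pair!r}, log has "
                    f"({rec['left']!r}, {rec['right']!r})"
                )
            session.submit_choice(rec["chosen"])
        if data.get("status") == "complete" and session.status != "complete":
            raise ValidationError("session file claims complete but log is short")
        return session

    @classmethod
    def load(cls, path) -> "ComparisonSession":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fj_rank(
    item_ids: Iterable[ItemId], oracle: Oracle, seed: int = 0
) -> tuple[Ranking, list[ComparisonRecord]]:
    """Rank items by querying ``oracle`` with merge-insertion pairs.

    ``oracle(left_id, right_id)`` must return the preferred
    (higher-quality) member of the pair.  With a consistent (strict,
    transitive) oracle the result is the oracle's true total order and
    the number of comparisons never exceeds :func:`fj_worst_case`.

    Returns the :class:`Ranking` (rank 1 = lowest quality) and the full
    comparison log.
    """
    session = ComparisonSession(item_ids, seed=seed)
    while session.status == "pending":
        left, right = session.next_pair()
        session.submit_choice(oracle(left, right))
    return session.ranking(), session.records
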