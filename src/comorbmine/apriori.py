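"""Level-wise Apriori frequent-itemset mining over the transaction database.

Classic algorithm: F1 from a single item scan; candidate k-itemsets from
joining (k-1)-itemsets that share a (k-2)-prefix; candidates with any
infrequent (k-1)-subset pruned before counting (downward closure). Support
counting intersects per-item transaction-id sets, so all counts are exact
integers — no sampling, no approximation. Ordering is fully deterministic:
itemsets are sorted tuples, output is sorted by (size, support descending,
lexicographic itemset).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .transactions import TransactionDB

__all__ = [
    "Itemset",
    "FrequentItemset",
    "itemset_support",
    "itemset_support_count",
    "find_frequent_itemsets",
    "write_itemsets_csv",
]

Itemset = tuple[str, ...]


def _as_itemset(members: Iterable[str]) -> Itemset:
    t = tuple(sorted(set(members)))
    return t


@dataclass(frozen=True)
class FrequentItemset:
    """An itemset together with its exact support in the source database."""

    itemset: Itemset
    support_count: int
    support: float

    def __post_init__(self) -> None:
        if self.support_count < 1:
            raise ValueError("frequent itemset must occur at least once")
        members = self.itemset
        if any(members[i] >= members[i + 1] for i in range(len(members) - 1)):
            raise ValueError(f"itemset {members!r} is not strictly sorted")


def _tidsets(db: TransactionDB) -> dict[str, frozenset[str]]:
    tids: dict[str, set[str]] = {item: set() for item in db.items}
    for pid, cats in db.transactions.items():
        for c in cats:
            tids[c].add(pid)
    return {k: frozenset(v) for k, v in tids.items()}


def itemset_support_count(db: TransactionDB, itemset: Iterable[str]) -> int:
    """Exact number of transactions containing every member of *itemset*.

    The empty itemset is contained in every transaction.
    """
    members = _as_itemset(itemset)
    universe = set(db.items)
    for m in members:
        if m not in universe:
            raise KeyError(f"item {m!r} is not in the transaction item universe")
    if not members:
        return db.n_transactions
    return sum(
        1 for cats in db.transactions.values() if all(m in cats for m in members)
    )


def itemset_support(db: TransactionDB, itemset: Iterable[str]) -> float:
    """Support fraction of *itemset*: count / n_transactions."""
    return itemset_support_count(db, itemset) / db.n_transactions


def find_frequent_itemsets(
    db: TransactionDB, min_support: float, max_len: int = 3
) -> list[FrequentItemset]:
    """All itemsets of size <= max_len with support >= min_support (inclusive).

    Returns every qualifying itemset with its exact support count, sorted by
    (size, support descending, lexicographic itemset).
    """
    if not (0 < min_support <= 1):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    n = db.n_transactions
    if n == 0:
        raise ValueError("transaction database is empty")

    tids = _tidsets(db)
    # F1: single item scan.
    level: dict[Itemset, frozenset[str]] = {
        (item,): tids[item]
        for item in db.items
        if len(tids[item]) / n >= min_support
    }
    frequent: dict[Itemset, int] = {s: len(t) for s, t in level.items()}

    k = 2
    while level and k <= max_len:
        prev_keys = sorted(level)
        prev_set = set(prev_keys)
        candidates: list[Itemset] = []
        # Prefix join: two (k-1)-itemsets sharing their first k-2 items.
        for i, a in enumerate(prev_keys):
            for b in prev_keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted order: no later b shares the prefix
                cand = a + (b[-1],)
                # Downward-closure pruning before counting.
                if all(
                    sub in prev_set for sub in combinations(cand, k - 1)
                ):
                    candidates.append(cand)
        next_level: dict[Itemset, frozenset[str]] = {}
        for cand in candidates:
            tid = level[cand[:-1]] & tids[cand[-1]]
            if len(tid) / n >= min_support:
                next_level[cand] = tid
        frequent.update({s: len(t) for s, t in next_level.items()})
        level = next_level
        k += 1

    out = [
        FrequentItemset(itemset=s, support_count=c, support=c / n)
        for s, c in frequent.items()
    ]
    out.sort(key=lambda f: (len(f.itemset), -f.support_count, f.itemset))
    return out


def write_itemsets_csv(itemsets: Sequence[FrequentItemset], path: str | Path) -> None:
    pd.DataFrame(
        {
            "itemset": [";".join(f.itemset) for f in itemsets],
            "size": [len(f.itemset) for f in itemsets],
            "support_count": [f.support_count for f in itemsets],
            "support": [f.support for f in itemsets],
        }
    ).to_csv(path, index=False)
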