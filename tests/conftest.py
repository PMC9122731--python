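"""Shared fixtures and independent brute-force oracles.

The brute-force functions enumerate every candidate itemset / rule by
direct scanning of the transactions; they share no code with the level-wise
miner they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from comorbmine import AssociationRule, TransactionDB, from_binary_matrix

# ---------------------------------------------------------------------------
# Published 11-patient sample of the structured TRUE/FALSE dataset.
# The six unnamed placeholder columns of the printed sample carry TRUE cells
# too; they are re-entered here under synthetic in-range names (A03, B03,
# C04, C98, T03, T99) so the matrix is complete. Hand counts used by the
# tests touch only the named columns (A02, B01, C03).

TABLE1_COLUMNS = [
    "A00", "A01", "A02", "A03", "A99", "B01", "B02", "B03", "B99",
    "C01", "C02", "C03", "C04", "C97", "C98",
    "T01", "T02", "T03", "T98", "T99", "U85",
]

TABLE1_ROWS = {
    "Pi+00": "001000010000010000000",
    "Pi+01": "000100000001000000000",
    "Pi+02": "000001000001000100010",
    "Pi+03": "100000001100001000000",
    "Pi+04": "001000010000000000000",
    "Pi+05": "001000000000001000000",
    "Pi+06": "000001100011000000000",
    "Pi+07": "000010000000000000010",
    "Pi+08": "010000000000000010100",
    "Pi+09": "000000000100000001000",
    "Pi+10": "000000000011000000000",
}


def table1_matrix() -> pd.DataFrame:
    data = np.array(
        [[c == "1" for c in row] for row in TABLE1_ROWS.values()], dtype=bool
    )
    return pd.DataFrame(data, index=list(TABLE1_ROWS), columns=TABLE1_COLUMNS)


@pytest.fixture(scope="session")
def table1_db() -> TransactionDB:
    return from_binary_matrix(table1_matrix())


# ---------------------------------------------------------------------------
# The 13 published cross-chapter rules (support, confidence as fractions;
# lift as printed), already in confidence-descending order.

TABLE2_RULES = [
    (("E11", "N18"), ("I10",), 0.0108, 0.8361, 1.98),
    (("G20",), ("I63",), 0.0101, 0.8355, 2.16),
    (("E11", "G45"), ("I63",), 0.0105, 0.8318, 2.15),
    (("G45",), ("I63",), 0.0380, 0.7897, 2.17),
    (("G81",), ("I10",), 0.0108, 0.7321, 1.77),
    (("N18",), ("I10",), 0.0290, 0.7028, 1.81),
    (("E11", "G45"), ("I10",), 0.0105, 0.7022, 1.35),
    (("M50",), ("I63",), 0.0174, 0.6827, 1.91),
    (("M47",), ("I63",), 0.0215, 0.6625, 1.85),
    (("E14",), ("I10",), 0.0204, 0.6274, 1.61),
    (("E11", "J18"), ("I63",), 0.0101, 0.6213, 1.57),
    (("E11",), ("I10",), 0.1173, 0.6149, 1.58),
    (("E02",), ("I63",), 0.0102, 0.6079, 1.49),
]


@pytest.fixture(scope="session")
def table2_rules() -> list[AssociationRule]:
    return [
        AssociationRule(
            antecedent=a, consequent=c, support=s, confidence=conf, lift=lift
        )
        for a, c, s, conf, lift in TABLE2_RULES
    ]


# ---------------------------------------------------------------------------
# Brute-force oracles: exhaustive enumeration by direct transaction scans.

def brute_force_frequent(
    db: TransactionDB, min_support: float, max_len: int
) -> dict[tuple[str, ...], int]:
    """All itemsets up to max_len with support >= min_support, by scanning
    every transaction for every candidate combination."""
    n = db.n_transactions
    sets = list(db.transactions.values())
    out: dict[tuple[str, ...], int] = {}
    for k in range(1, max_len + 1):
        for cand in combinations(sorted(db.items), k):
            needed = set(cand)
            count = sum(1 for t in sets if needed <= t)
            if count > 0 and count / n >= min_support:
                out[cand] = count
    return out


def brute_force_rules(
    db: TransactionDB, frequent: dict[tuple[str, ...], int]
) -> dict[tuple[tuple[str, ...], tuple[str, ...]], tuple[float, float, float]]:
    """(support, confidence, lift) for every ordered partition of every
    frequent itemset of size >= 2, recomputed from raw transaction scans."""
    n = db.n_transactions
    sets = list(db.transactions.values())

    def count(itemset: tuple[str, ...]) -> int:
        needed = set(itemset)
        return sum(1 for t in sets if needed <= t)

    out = {}
    for itemset, ab in frequent.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(itemset, r):
                cons = tuple(m for m in itemset if m not in set(ante))
                a, b = count(ante), count(cons)
                out[(ante, cons)] = (ab / n, ab / a, ab * n / (a * b))
    return out


def random_db(rng: np.random.Generator, max_items: int = 12, max_trans: int = 200) -> TransactionDB:
    """A random small transaction database for oracle-equivalence checks."""
    n_items = int(rng.integers(2, max_items + 1))
    n_trans = int(rng.integers(2, max_trans + 1))
    letters = "ABCDEFGHIJKLMNOPQRSTU"
    items = sorted(
        {f"{letters[int(rng.integers(0, len(letters)))]}{int(rng.integers(0, 100)):02d}"
         for _ in range(n_items)}
    )
    transactions = {}
    for i in range(n_trans):
        mask = rng.random(len(items)) < rng.uniform(0.1, 0.7)
        if not mask.any():
            mask[int(rng.integers(0, len(items)))] = True
        transactions[f"P{i:04d}"] = frozenset(
            it for it, m in zip(items, mask) if m
        )
    return TransactionDB(
        items=items,
        transactions=transactions,
        n_codes_ingested=sum(len(t) for t in transactions.values()),
    )
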