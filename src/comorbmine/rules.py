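"""Association-rule generation, scoring, filtering, sorting, and partition.

For a rule A -> B over N patient transactions with exact co-occurrence
counts n(.):

    support    = n(A and B) / N          (joint prevalence)
    confidence = n(A and B) / n(A)       (comorbidity of B given A)
    lift       = support / (P(A) * P(B)) (dependence; symmetric in A, B)

Filtering uses inclusive thresholds for support and confidence and a
*strict* threshold for lift (> 1 by default). Rules are sorted by
confidence descending; the chapter partition splits rules into
within-chapter (all categories share one chapter letter) and cross-chapter
sets.

The symmetric-pair identity: for a pair A -> B, B -> A with shared support
s and confidences c_f, c_b, the marginals are P(A) = s / c_f and
P(B) = s / c_b, hence lift = c_f * c_b / s. This lets lift be recomputed
from a published rule pair without the underlying database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .apriori import FrequentItemset, Itemset, itemset_support_count
from .transactions import TransactionDB

__all__ = [
    "AssociationRule",
    "MiningConfig",
    "generate_rules",
    "filter_rules",
    "sort_rules",
    "partition_by_chapter",
    "lift_from_rule_pair",
    "prune_redundant",
    "rules_to_frame",
    "write_rules_csv",
    "write_rules_json",
]


@dataclass(frozen=True)
class AssociationRule:
    """A scored rule antecedent -> consequent."""

    antecedent: Itemset
    consequent: Itemset
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if set(self.antecedent) & set(self.consequent):
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def chapters(self) -> frozenset[str]:
        return frozenset(c[0] for c in self.antecedent + self.consequent)

    def __str__(self) -> str:
        return (
            f"{';'.join(self.antecedent)} -> {';'.join(self.consequent)} "
            f"(s={self.support:.4f}, c={self.confidence:.4f}, l={self.lift:.2f})"
        )


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and size limits for rule selection.

    Defaults: support >= 0.001, confidence >= 0.60, lift strictly > 1,
    antecedent of at most two categories, consequent of exactly one.
    """

    min_support: float = 0.001
    min_confidence: float = 0.60
    min_lift: float = 1.0
    max_antecedent_size: int = 2
    consequent_size: int = 1
    max_len: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")
        if not (0 <= self.min_confidence <= 1):
            raise ValueError(
                f"min_confidence must be in [0, 1], got {self.min_confidence}"
            )
        if self.min_lift < 0:
            raise ValueError(f"min_lift must be >= 0, got {self.min_lift}")
        if self.max_antecedent_size < 1 or self.consequent_size < 1:
            raise ValueError("antecedent/consequent size limits must be >= 1")
        if self.max_len < self.max_antecedent_size + self.consequent_size:
            raise ValueError(
                "max_len must cover max_antecedent_size + consequent_size"
            )


def generate_rules(
    frequent: Sequence[FrequentItemset], db: TransactionDB
) -> list[AssociationRule]:
    """Every ordered partition of every frequent itemset of size >= 2.

    Metrics are computed from exact integer counts. Sub-itemset supports
    come from the mined table when present (guaranteed by downward closure
    for a complete mining run) and are otherwise recounted exactly from the
    database.
    """
    n = db.n_transactions
    counts: dict[Itemset, int] = {f.itemset: f.support_count for f in frequent}

    def count_of(itemset: Itemset) -> int:
        if itemset in counts:
            return counts[itemset]
        counts[itemset] = itemset_support_count(db, itemset)
        return counts[itemset]

    out: list[AssociationRule] = []
    for f in frequent:
        members = f.itemset
        if len(members) < 2:
            continue
        ab = f.support_count
        for r in range(1, len(members)):
            for ante in _combinations_sorted(members, r):
                cons = tuple(m for m in members if m not in set(ante))
                a = count_of(ante)
                b = count_of(cons)
                if a == 0 or b == 0:
                    raise ValueError(
                        f"inconsistent supports for rule {ante} -> {cons}"
                    )
                out.append(
                    AssociationRule(
                        antecedent=ante,
                        consequent=cons,
                        support=ab / n,
                        confidence=ab / a,
                        lift=(ab * n) / (a * b),
                    )
                )
    return out


def _combinations_sorted(members: Itemset, r: int):
    from itertools import combinations

    return combinations(members, r)


def filter_rules(
    rules: Sequence[AssociationRule], config: MiningConfig | None = None
) -> list[AssociationRule]:
    """Apply thresholds: support and confidence inclusive (>=), lift strict
    (>), antecedent size <= max, consequent size == consequent_size."""
    if config is None:
        config = MiningConfig()
    return [
        r
        for r in rules
        if r.support >= config.min_support
        and r.confidence >= config.min_confidence
        and r.lift > config.min_lift
        and len(r.antecedent) <= config.max_antecedent_size
        and len(r.consequent) == config.consequent_size
    ]


def sort_rules(rules: Sequence[AssociationRule]) -> list[AssociationRule]:
    """Confidence descending; ties by lift desc, support desc, then
    lexicographic (antecedent, consequent). Stable and deterministic."""
    return sorted(
        rules,
        key=lambda r: (-r.confidence, -r.lift, -r.support, r.antecedent, r.consequent),
    )


def partition_by_chapter(
    rules: Sequence[AssociationRule],
) -> tuple[list[AssociationRule], list[AssociationRule]]:
    """Split into (cross_chapter, within_chapter).

    A rule is within-chapter iff every antecedent and consequent category
    shares one chapter letter; any mixture makes it cross-chapter.
    """
    cross = [r for r in rules if len(r.chapters) > 1]
    within = [r for r in rules if len(r.chapters) == 1]
    return cross, within


def lift_from_rule_pair(
    support: float, conf_forward: float, conf_backward: float
) -> float:
    """Lift implied by a symmetric rule pair A -> B, B -> A.

    With shared support s and the two confidences, P(A) = s/conf_forward
    and P(B) = s/conf_backward, so lift = conf_forward*conf_backward/s.
    """
    if support <= 0:
        raise ValueError(f"support must be positive, got {support}")
    if not (support <= conf_forward <= 1 and support <= conf_backward <= 1):
        raise ValueError(
            "confidences must lie between the support and 1 "
            f"(support={support}, conf_forward={conf_forward}, "
            f"conf_backward={conf_backward})"
        )
    return conf_forward * conf_backward / support


def prune_redundant(rules: Sequence[AssociationRule]) -> list[AssociationRule]:
    """Optional redundancy heuristic (off by default in the pipeline).

    Drops a rule when a proper sub-antecedent rule with the same consequent
    achieves confidence at least as high — a crude automated stand-in for
    manual de-duplication of nested rules; it is NOT a validated expert
    review.
    """
    best: dict[tuple[Itemset, Itemset], float] = {
        (r.antecedent, r.consequent): r.confidence for r in rules
    }
    kept = []
    for r in rules:
        dominated = False
        for (ante, cons), conf in best.items():
            if (
                cons == r.consequent
                and set(ante) < set(r.antecedent)
                and conf >= r.confidence
            ):
                dominated = True
                break
        if not dominated:
            kept.append(r)
    return kept


def _pct(x: float) -> str:
    # Half-even rounding to 2 dp, rendered as a percentage.
    q = (Decimal(repr(x)) * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    return f"{q}%"


def _2dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def rules_to_frame(
    rules: Sequence[AssociationRule], *, rendered: bool = False
) -> pd.DataFrame:
    """Tabulate rules; ``rendered=True`` formats support/confidence as
    2-dp percentages and lift to 2 dp (half-even), the published layout."""
    cross, within = partition_by_chapter(rules)
    cross_set = {id(r) for r in cross}
    rows = []
    for i, r in enumerate(rules, start=1):
        rows.append(
            {
                "no": i,
                "antecedent": ";".join(r.antecedent),
                "consequent": ";".join(r.consequent),
                "support": _pct(r.support) if rendered else r.support,
                "confidence": _pct(r.confidence) if rendered else r.confidence,
                "lift": _2dp(r.lift) if rendered else r.lift,
                "partition": "cross" if id(r) in cross_set else "within",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "no",
            "antecedent",
            "consequent",
            "support",
            "confidence",
            "lift",
            "partition",
        ],
    )


def write_rules_csv(
    rules: Sequence[AssociationRule], path: str | Path, *, rendered: bool = False
) -> None:
    rules_to_frame(rules, rendered=rendered).to_csv(path, index=False)


def write_rules_json(rules: Sequence[AssociationRule], path: str | Path) -> None:
    # JSON always carries raw fractions at full precision.
    frame = rules_to_frame(rules, rendered=False)
    Path(path).write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
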