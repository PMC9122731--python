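"""Rule generation, metric identities, filtering, sorting, and partition."""

import numpy as np
import pytest

from comorbmine import (
    AssociationRule,
    MiningConfig,
    filter_rules,
    find_frequent_itemsets,
    generate_rules,
    lift_from_rule_pair,
    partition_by_chapter,
    prune_redundant,
    rules_to_frame,
    sort_rules,
)

from conftest import brute_force_frequent, brute_force_rules, random_db


def make_rule(ante, cons, support, confidence, lift):
    return AssociationRule(
        antecedent=ante, consequent=cons, support=support,
        confidence=confidence, lift=lift,
    )


class TestGenerateRules:
    def test_table1_b01_c03(self, table1_db):
        frequent = find_frequent_itemsets(table1_db, 2 / 11, 3)
        rules = generate_rules(frequent, table1_db)
        r = next(
            r for r in rules
            if r.antecedent == ("B01",) and r.consequent == ("C03",)
        )
        assert r.support == pytest.approx(2 / 11)
        assert r.confidence == 1.0
        assert r.lift == pytest.approx(11 / 4)  # 2.75

    def test_lift_is_one_when_consequent_universal(self):
        from comorbmine import TransactionDB

        db = TransactionDB(
            items=["A00", "B00"],
            transactions={
                "P1": frozenset({"A00", "B00"}),
                "P2": frozenset({"B00"}),
            },
            n_codes_ingested=3,
        )
        frequent = find_frequent_itemsets(db, 0.5, 2)
        r = next(
            r for r in generate_rules(frequent, db)
            if r.antecedent == ("A00",) and r.consequent == ("B00",)
        )
        assert r.lift == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        db = random_db(rng, max_items=10, max_trans=120)
        frequent = find_frequent_itemsets(db, 0.05, 3)
        mined = {
            (r.antecedent, r.consequent): (r.support, r.confidence, r.lift)
            for r in generate_rules(frequent, db)
        }
        oracle = brute_force_rules(db, brute_force_frequent(db, 0.05, 3))
        assert mined.keys() == oracle.keys()
        for key, (s, c, l) in oracle.items():
            ms, mc, ml = mined[key]
            assert ms == pytest.approx(s, abs=1e-9)
            assert mc == pytest.approx(c, abs=1e-9)
            assert ml == pytest.approx(l, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_identities(self, seed):
        """support and lift are symmetric under antecedent<->consequent swap;
        confidence * P(antecedent) recovers the joint support; and the
        symmetric-pair identity reproduces the stored lift exactly."""
        rng = np.random.default_rng(300 + seed)
        db = random_db(rng, max_items=9, max_trans=100)
        frequent = find_frequent_itemsets(db, 0.05, 3)
        rules = {
            (r.antecedent, r.consequent): r
            for r in generate_rules(frequent, db)
        }
        for (ante, cons), r in rules.items():
            mirror = rules[(cons, ante)]
            assert r.support == pytest.approx(mirror.support, abs=1e-12)
            assert r.lift == pytest.approx(mirror.lift, abs=1e-12)
            p_ante = r.support / r.confidence
            assert r.confidence * p_ante == pytest.approx(r.support, abs=1e-12)
            assert lift_from_rule_pair(
                r.support, r.confidence, mirror.confidence
            ) == pytest.approx(r.lift, abs=1e-9)

    def test_superset_antecedent_never_has_higher_support(self, table1_db):
        frequent = find_frequent_itemsets(table1_db, 1 / 11, 3)
        rules = {
            (r.antecedent, r.consequent): r.support
            for r in generate_rules(frequent, table1_db)
        }
        for (ante, cons), support in rules.items():
            if len(ante) == 2:
                for single in ante:
                    sub = rules.get(((single,), cons))
                    if sub is not None:
                        assert support <= sub + 1e-12


FILTER_FIXTURE = [
    # (rule, kept?) hand-labelled against the default thresholds
    (make_rule(("A00",), ("B00",), 0.01, 0.60, 1.5), True),    # conf == 0.60 kept
    (make_rule(("A00",), ("B00",), 0.01, 0.80, 1.0), False),   # lift == 1 dropped
    (make_rule(("A00", "B00", "C00"), ("D00",), 0.01, 0.9, 2.0), False),  # 3-item antecedent
    (make_rule(("A00",), ("B00",), 0.001, 0.9, 2.0), True),    # support == floor kept
    (make_rule(("A00",), ("B00",), 0.0009, 0.9, 2.0), False),  # below support floor
    (make_rule(("A00",), ("B00",), 0.01, 0.59, 2.0), False),   # below confidence floor
    (make_rule(("A00",), ("B00", "C00"), 0.01, 0.9, 2.0), False),  # 2-item consequent
    (make_rule(("A00", "B00"), ("C00",), 0.01, 0.7, 1.01), True),
]


def test_filter_rules_hand_labelled_fixture():
    rules = [r for r, _ in FILTER_FIXTURE]
    expected = [r for r, keep in FILTER_FIXTURE if keep]
    assert filter_rules(rules, MiningConfig()) == expected


def test_filter_threshold_config_validation():
    with pytest.raises(ValueError):
        MiningConfig(min_support=0)
    with pytest.raises(ValueError):
        MiningConfig(min_confidence=1.2)
    with pytest.raises(ValueError):
        MiningConfig(max_antecedent_size=3, max_len=3)


class TestSortRules:
    def test_confidence_descending(self):
        rules = [
            make_rule(("A00",), ("B00",), 0.1, c, 1.5) for c in (0.7, 0.9, 0.8)
        ]
        assert [r.confidence for r in sort_rules(rules)] == [0.9, 0.8, 0.7]

    def test_tie_broken_by_lift(self):
        a = make_rule(("A00",), ("B00",), 0.1, 0.8, 2.0)
        b = make_rule(("C00",), ("D00",), 0.1, 0.8, 1.5)
        assert sort_rules([b, a]) == [a, b]

    def test_published_cross_chapter_table_is_a_fixed_point(self, table2_rules):
        assert sort_rules(table2_rules) == table2_rules
        confs = [r.confidence for r in table2_rules]
        assert confs[0] == 0.8361 and confs[-1] == 0.6079
        assert all(x >= y for x, y in zip(confs, confs[1:]))


class TestPartitionByChapter:
    def test_examples(self):
        cross1 = make_rule(("E11", "N18"), ("I10",), 0.0108, 0.8361, 1.98)
        within = make_rule(("I66",), ("I63",), 0.0594, 0.9605, 1.46)
        cross2 = make_rule(("E11", "G45"), ("I63",), 0.0105, 0.8318, 2.15)
        cross, same = partition_by_chapter([cross1, within, cross2])
        assert cross == [cross1, cross2]
        assert same == [within]

    def test_partition_covers_input(self, table2_rules):
        cross, within = partition_by_chapter(table2_rules)
        assert len(cross) + len(within) == len(table2_rules)
        assert within == []  # every published cross-chapter rule mixes chapters


class TestLiftFromRulePair:
    @pytest.mark.parametrize(
        "support, cf, cb, expected",
        [
            (0.4868, 0.7386, 0.6792, 1.03),  # cerebral infarction <-> hypertension
            (0.1989, 0.9727, 0.9640, 4.71),  # hepatobiliary malformation <-> cystic kidney
            (0.1215, 0.9091, 0.7718, 5.77),  # dysphagia <-> speech disturbance
        ],
    )
    def test_published_symmetric_pairs(self, support, cf, cb, expected):
        assert round(lift_from_rule_pair(support, cf, cb), 2) == expected

    def test_certain_conditionals_give_reciprocal_support(self):
        for s in (0.1, 0.25, 0.5, 1.0):
            assert lift_from_rule_pair(s, 1, 1) == pytest.approx(1 / s)

    def test_rejects_zero_support_and_impossible_confidences(self):
        with pytest.raises(ValueError):
            lift_from_rule_pair(0, 0.5, 0.5)
        with pytest.raises(ValueError):
            lift_from_rule_pair(0.5, 0.4, 0.9)  # confidence below support


def test_prune_redundant_drops_dominated_supersets():
    base = make_rule(("A00",), ("C00",), 0.1, 0.9, 2.0)
    dominated = make_rule(("A00", "B00"), ("C00",), 0.05, 0.85, 2.0)
    better = make_rule(("A00", "D00"), ("C00",), 0.05, 0.95, 2.0)
    assert prune_redundant([base, dominated, better]) == [base, better]


def test_rules_frame_rendering(table2_rules):
    frame = rules_to_frame(table2_rules, rendered=True)
    assert list(frame.columns) == [
        "no", "antecedent", "consequent", "support", "confidence", "lift", "partition"
    ]
    top = frame.iloc[0]
    assert top["antecedent"] == "E11;N18"
    assert top["support"] == "1.08%"
    assert top["confidence"] == "83.61%"
    assert top["lift"] == 1.98
    assert set(frame["partition"]) == {"cross"}
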