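"""Apriori mining, rule metrics, filtering, ranking and the brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from comorbid_arm.mining import (
    AprioriMiner,
    AssociationRule,
    Itemset,
    MiningConfig,
    RuleMetrics,
    apriori,
    bidirectional_pairs,
    brute_force_itemsets,
    compute_metrics,
    filter_rules,
    generate_rules,
    rank_rules,
)


def as_dict(itemsets):
    return {it.items: it.count for it in itemsets}


class TestApriori:
    def test_four_transaction_instance(self, four_transactions):
        # Exhaustively enumerable by hand: n=4, min_support 0.5 -> count >= 2.
        got = as_dict(apriori(four_transactions, 0.5))
        assert got == {
            ("A",): 3,
            ("B",): 3,
            ("C",): 2,
            ("A", "B"): 2,
            ("B", "C"): 2,
        }

    def test_single_transaction_full_support(self):
        assert as_dict(apriori([{"A"}], 1.0)) == {("A",): 1}

    def test_empty_transactions_only_count_in_denominator(self):
        got = as_dict(apriori([{"A"}, set(), set(), set()], 0.25))
        assert got == {("A",): 1}
        assert as_dict(apriori([{"A"}, set(), set(), set()], 0.26)) == {}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            apriori([], 0.5)

    def test_downward_closure(self, four_transactions):
        itemsets = apriori(four_transactions, 0.25)
        counts = as_dict(itemsets)
        for items, count in counts.items():
            for drop in items:
                sub = tuple(x for x in items if x != drop)
                if sub:
                    assert counts[sub] >= count

    def test_reconstructed_cohort_joint_itemset(self, pooled_exact_tset):
        counts = as_dict(apriori(pooled_exact_tset, 0.01))
        assert counts[("E10-E14", "I10-I15")] == 262


class TestBruteForceEquivalence:
    def test_matches_on_random_instances(self):
        """Oracle equivalence on 200 random small instances."""
        rng = np.random.default_rng(20_210_901)
        universe = list("ABCDEFGH")
        for _ in range(200):
            n = int(rng.integers(1, 51))
            n_items = int(rng.integers(1, 9))
            p = rng.uniform(0.05, 0.6)
            transactions = [
                {it for it in universe[:n_items] if rng.random() < p}
                for _ in range(n)
            ]
            min_support = float(rng.uniform(0.02, 0.8))
            assert as_dict(apriori(transactions, min_support)) == as_dict(
                brute_force_itemsets(transactions, min_support)
            )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.sets(st.sampled_from("ABCDE"), max_size=5),
            min_size=1,
            max_size=30,
        ),
        st.floats(min_value=0.05, max_value=1.0),
    )
    def test_matches_on_generated_instances(self, transactions, min_support):
        assert as_dict(apriori(transactions, min_support)) == as_dict(
            brute_force_itemsets(transactions, min_support)
        )

    def test_guard_rails(self):
        with pytest.raises(ValueError):
            brute_force_itemsets([set()] * 201, 0.5)
        with pytest.raises(ValueError):
            brute_force_itemsets([set("ABCDEFGHIJKLM")], 0.5)

    def test_all_empty_transactions(self):
        assert brute_force_itemsets([set(), set()], 0.5) == []


class TestMetrics:
    def test_reconstructed_diabetes_hypertension_row(self):
        m = compute_metrics(262, 520, 838, 7709)
        assert round(m.support, 3) == 0.034
        assert round(m.confidence, 3) == 0.504
        assert round(m.lift, 3) == 4.635
        assert round(m.is_scale, 3) == 0.397

    def test_single_cooccurrence_in_small_subgroup(self):
        m = compute_metrics(1, 1, 1, 45)
        assert (round(m.support, 3), m.confidence, m.lift, m.is_scale) == (
            0.022,
            1.0,
            45.0,
            1.0,
        )

    @pytest.mark.parametrize("k", [1, 7, 100])
    def test_saturated_identity(self, k):
        m = compute_metrics(k, k, k, k)
        assert (m.support, m.confidence, m.lift, m.is_scale) == (1.0, 1.0, 1.0, 1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 1, 1, 10)
        with pytest.raises(ValueError):
            compute_metrics(5, 3, 10, 10)
        with pytest.raises(ValueError):
            compute_metrics(1, 0, 1, 10)

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_metric_identities(self, data):
        n = data.draw(st.integers(min_value=1, max_value=10_000))
        ca = data.draw(st.integers(min_value=1, max_value=n))
        cb = data.draw(st.integers(min_value=1, max_value=n))
        nj = data.draw(st.integers(min_value=1, max_value=min(ca, cb)))
        fwd = compute_metrics(nj, ca, cb, n)
        rev = compute_metrics(nj, cb, ca, n)
        assert math.isclose(fwd.is_scale**2, fwd.support * fwd.lift, rel_tol=1e-12)
        assert math.isclose(fwd.lift, rev.lift, rel_tol=1e-12)
        assert math.isclose(
            fwd.is_scale, nj / math.sqrt(ca * cb), rel_tol=1e-12
        )
        assert math.isclose(fwd.confidence * ca, rev.confidence * cb, rel_tol=1e-12)
        assert fwd.support <= fwd.confidence


class TestRuleGeneration:
    def test_four_transaction_rule(self, four_transactions):
        itemsets = apriori(four_transactions, 0.5)
        rules = {
            (r.antecedent, r.consequent): r.metrics
            for r in generate_rules(itemsets, 4)
        }
        m = rules[(("A",), "B")]
        assert m.support == pytest.approx(0.5)
        assert m.confidence == pytest.approx(2 / 3)
        assert m.lift == pytest.approx(8 / 9)
        assert m.is_scale == pytest.approx(2 / 3)

    def test_multi_item_antecedents_enumerated(self):
        itemsets = apriori([{"A", "B", "C"}], 1.0)
        rules = generate_rules(itemsets, 1)
        assert (("A", "B"), "C") in {(r.antecedent, r.consequent) for r in rules}

    def test_degenerate_saturated_rule(self):
        rules = generate_rules(apriori([{"A", "B"}], 1.0), 1)
        for r in rules:
            if len(r.antecedent) == 1:
                assert r.metrics == RuleMetrics(1, 1.0, 1.0, 1.0, 1.0)

    def test_min_confidence_is_inclusive(self, four_transactions):
        itemsets = apriori(four_transactions, 0.5)
        rules = generate_rules(itemsets, 4, min_confidence=2 / 3)
        assert (("A",), "B") in {(r.antecedent, r.consequent) for r in rules}


def rule(a, b, N, ca, cb, n):
    return AssociationRule(
        antecedent=(a,) if isinstance(a, str) else tuple(a),
        consequent=b,
        metrics=compute_metrics(N, ca, cb, n),
    )


class TestFilterRank:
    def test_lift_exactly_one_removed(self):
        r = rule("A", "B", 10, 50, 20, 100)  # lift == 1.0
        assert r.metrics.lift == pytest.approx(1.0)
        assert filter_rules([r], MiningConfig()) == []

    def test_surviving_rule_kept(self):
        r = rule("I10-I15", "K20-K31", 96, 838, 485, 7709)
        assert filter_rules([r], MiningConfig()) == [r]

    def test_empty_input(self):
        assert filter_rules([], MiningConfig()) == []

    def test_rank_by_is_then_support_then_label(self):
        r1 = rule("E10-E14", "I10-I15", 262, 520, 838, 7709)
        r2 = rule("I10-I15", "E10-E14", 262, 838, 520, 7709)
        r3 = rule("E70-E90", "I10-I15", 96, 201, 838, 7709)
        r4 = rule("I10-I15", "K20-K31", 96, 838, 485, 7709)
        ranked = rank_rules([r4, r3, r2, r1])
        assert ranked == [r1, r2, r3, r4]  # IS ties broken lexicographically
        assert rank_rules([r1, r2], top_k=0) == []

    def test_bidirectional_pairs(self):
        fwd = rule("E10-E14", "I10-I15", 262, 520, 838, 7709)
        rev = rule("I10-I15", "E10-E14", 262, 838, 520, 7709)
        lone = rule("E70-E90", "I10-I15", 96, 201, 838, 7709)
        multi = rule(("E10-E14", "I10-I15"), "G20-G26", 2, 3, 2, 117)
        pairs = bidirectional_pairs([fwd, rev, lone, multi])
        assert pairs == [(fwd, rev)]
        a, b = pairs[0]
        assert math.isclose(a.metrics.lift, b.metrics.lift, rel_tol=1e-12)
        assert math.isclose(a.metrics.is_scale, b.metrics.is_scale, rel_tol=1e-12)


class TestAprioriMiner:
    def test_fit_on_transaction_set(self, pooled_exact_tset):
        miner = AprioriMiner().fit(pooled_exact_tset)
        assert miner.n_transactions_ == 7709
        assert [r.label for r in miner.rules_] == [
            "E10-E14→I10-I15",
            "I10-I15→E10-E14",
        ]
        (pair,) = miner.bidirectional_pairs_()
        assert round(pair[0].metrics.is_scale, 3) == 0.397

    def test_rules_frame_rounding(self, pooled_exact_tset):
        frame = AprioriMiner().fit(pooled_exact_tset).rules_frame(decimals=3)
        top = frame.iloc[0]
        assert list(top[["N", "support", "confidence", "lift", "IS"]]) == [
            262,
            0.034,
            0.504,
            4.635,
            0.397,
        ]

    def test_sklearn_params_and_clone(self):
        miner = AprioriMiner(min_support=0.05, top_k=3)
        params = miner.get_params()
        assert params["min_support"] == 0.05 and params["top_k"] == 3
        cloned = clone(miner)
        assert cloned.get_params() == params
        cloned.set_params(min_lift=2.0)
        assert cloned.min_lift == 2.0

    def test_fit_all_empty_transactions(self):
        miner = AprioriMiner().fit([set(), set()])
        assert miner.itemsets_ == [] and miner.rules_ == []
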