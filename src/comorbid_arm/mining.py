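"""Apriori frequent-itemset mining and association-rule metrics.

The miner is written from scratch: level-wise candidate generation by
sorted-prefix joining, subset pruning via downward closure, and support
counting by transaction scan.  The item universe here is small (at most
a few dozen ICD-10 blocks) so this is fast without specialised data
structures.

Rule metrics for A -> B over n transactions, with N transactions
containing both sides:

* support    = N / n
* confidence = N / count(A)
* lift       = support / (P(A) P(B)) = N n / (count(A) count(B))
* IS scale   = sqrt(support * lift)  = N / sqrt(count(A) count(B))

The IS (interest-support) scale is algebraically the cosine similarity
of the two indicator vectors; it is symmetric in rule direction, as is
lift.  Rules are filtered by support and confidence (inclusive minima)
and lift (strictly greater than the threshold by default), then ranked
by descending IS.

:func:`brute_force_itemsets` is an independent enumeration oracle used
by the test suite to validate the miner on small instances; it is not a
code path of the miner itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .transactions import TransactionSet

__all__ = [
    "Itemset",
    "RuleMetrics",
    "AssociationRule",
    "MiningConfig",
    "apriori",
    "generate_rules",
    "compute_metrics",
    "filter_rules",
    "rank_rules",
    "bidirectional_pairs",
    "brute_force_itemsets",
    "rules_to_frame",
    "AprioriMiner",
]


class Itemset(NamedTuple):
    items: tuple  # sorted tuple of block ids
    count: int


@dataclass(frozen=True)
class RuleMetrics:
    N: int
    support: float
    confidence: float
    lift: float
    is_scale: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: tuple  # sorted tuple, size >= 1
    consequent: str
    metrics: RuleMetrics

    @property
    def label(self) -> str:
        return f"{','.join(self.antecedent)}→{self.consequent}"


@dataclass
class MiningConfig:
    """Thresholds and report sizes for a mining run.

    Support and confidence minima are applied inclusively; the lift
    threshold is strict (``lift > min_lift``) unless ``strict_lift`` is
    cleared — positive association only.
    """

    min_support: float = 0.01
    min_confidence: float = 0.10
    min_lift: float = 1.0
    strict_lift: bool = True
    max_antecedent_size: int = 2
    top_k: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_support", "min_confidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_lift < 0:
            raise ValueError("min_lift must be non-negative")
        if self.max_antecedent_size < 1:
            raise ValueError("max_antecedent_size must be >= 1")


def _itemlists(tset) -> tuple[list[frozenset], int]:
    if isinstance(tset, TransactionSet):
        return tset.itemlists(), tset.n
    items = [frozenset(t) for t in tset]
    return items, len(items)


def apriori(
    tset: TransactionSet | Iterable,
    min_support: float,
    max_len: int | None = None,
) -> list[Itemset]:
    """All itemsets with support >= ``min_support`` (sizes 1..max_len).

    Empty transactions contribute only to the denominator ``n``.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError(f"min_support must be in (0,1], got {min_support}")
    transactions, n = _itemlists(tset)
    if n == 0:
        raise ValueError("empty input: no transactions")
    min_count = min_support * n

    counts: dict = {}
    for t in transactions:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    frequent: dict[frozenset, int] = {
        frozenset({i}): c for i, c in counts.items() if c >= min_count
    }
    result = dict(frequent)

    level = sorted(frequent, key=lambda s: tuple(s))
    k = 2
    while level and (max_len is None or k <= max_len):
        # Sorted-prefix join: two (k-1)-sets sharing their first k-2 items.
        prefixes: dict[tuple, list[tuple]] = {}
        for s in level:
            t = tuple(sorted(s))
            prefixes.setdefault(t[:-1], []).append(t)
        candidates = set()
        level_set = set(level)
        for group in prefixes.values():
            group.sort()
            for a, b in combinations(group, 2):
                cand = frozenset(a) | frozenset(b)
                # Downward-closure pruning: every (k-1)-subset frequent.
                if all(cand - {x} in level_set for x in cand):
                    candidates.add(cand)
        if not candidates:
            break
        cand_counts = dict.fromkeys(candidates, 0)
        for t in transactions:
            if len(t) < k:
                continue
            for sub in combinations(sorted(t), k):
                fs = frozenset(sub)
                if fs in cand_counts:
                    cand_counts[fs] += 1
        level = [c for c, cnt in cand_counts.items() if cnt >= min_count]
        for c in level:
            result[c] = cand_counts[c]
        k += 1

    return sorted(
        (Itemset(tuple(sorted(s)), c) for s, c in result.items()),
        key=lambda it: (len(it.items), it.items),
    )


def compute_metrics(
    count_joint: int, count_antecedent: int, count_consequent: int, n: int
) -> RuleMetrics:
    """Rule metrics from unrounded integer counts."""
    if n <= 0 or count_antecedent <= 0 or count_consequent <= 0:
        raise ValueError("counts and n must be positive")
    if count_joint <= 0 or count_joint > min(count_antecedent, count_consequent):
        raise ValueError(
            f"joint count {count_joint} outside (0, min(count_A, count_B)]"
        )
    support = count_joint / n
    confidence = count_joint / count_antecedent
    lift = count_joint * n / (count_antecedent * count_consequent)
    is_scale = count_joint / math.sqrt(count_antecedent * count_consequent)
    return RuleMetrics(
        N=count_joint, support=support, confidence=confidence, lift=lift, is_scale=is_scale
    )


def generate_rules(
    itemsets: Sequence[Itemset],
    n: int,
    min_confidence: float = 0.0,
) -> list[AssociationRule]:
    """Single-consequent rules from frequent itemsets of size >= 2.

    For every frequent itemset and every choice of one item as the
    consequent, emits the rule when its confidence reaches
    ``min_confidence``.  Antecedent/consequent counts come from the
    itemset list itself (all subsets are present by downward closure).
    """
    counts = {frozenset(it.items): it.count for it in itemsets}
    rules = []
    for it in itemsets:
        if len(it.items) < 2:
            continue
        whole = frozenset(it.items)
        for consequent in it.items:
            antecedent = whole - {consequent}
            count_a = counts.get(antecedent)
            count_b = counts.get(frozenset({consequent}))
            if count_a is None or count_b is None:
                raise ValueError(
                    f"itemset list is not downward closed around {it.items}"
                )
            if it.count / count_a < min_confidence:
                continue
            rules.append(
                AssociationRule(
                    antecedent=tuple(sorted(antecedent)),
                    consequent=consequent,
                    metrics=compute_metrics(it.count, count_a, count_b, n),
                )
            )
    return rules


def filter_rules(
    rules: Iterable[AssociationRule], config: MiningConfig
) -> list[AssociationRule]:
    """Apply the support/confidence/lift thresholds."""
    kept = []
    for r in rules:
        m = r.metrics
        if m.support < config.min_support or m.confidence < config.min_confidence:
            continue
        if config.strict_lift:
            if m.lift <= config.min_lift:
                continue
        elif m.lift < config.min_lift:
            continue
        if len(r.antecedent) > config.max_antecedent_size:
            continue
        kept.append(r)
    return kept


def rank_rules(
    rules: Iterable[AssociationRule], top_k: int | None = None
) -> list[AssociationRule]:
    """Descending IS; ties by descending support, then by rule label."""
    ranked = sorted(
        rules,
        key=lambda r: (-r.metrics.is_scale, -r.metrics.support, r.antecedent, r.consequent),
    )
    return ranked if top_k is None else ranked[: max(top_k, 0)]


def bidirectional_pairs(
    rules: Iterable[AssociationRule],
) -> list[tuple[AssociationRule, AssociationRule]]:
    """Pairs (A->B, B->A) both present among single-antecedent rules.

    Lift and IS are symmetric, so both members of a pair share them;
    pairs are returned once (ordered by the lexicographically smaller
    direction) sorted by descending IS.
    """
    singles = {
        (r.antecedent[0], r.consequent): r for r in rules if len(r.antecedent) == 1
    }
    pairs = []
    for (a, b), fwd in singles.items():
        if a < b and (b, a) in singles:
            pairs.append((fwd, singles[(b, a)]))
    pairs.sort(key=lambda p: (-p[0].metrics.is_scale, p[0].antecedent, p[0].consequent))
    return pairs


def brute_force_itemsets(
    tset: TransactionSet | Iterable, min_support: float
) -> list[Itemset]:
    """Test oracle: enumerate every subset of the observed item universe.

    Guard-railed to tiny instances (<= 12 distinct items, <= 200
    transactions); independent of :func:`apriori`.
    """
    transactions, n = _itemlists(tset)
    if n == 0:
        raise ValueError("empty input: no transactions")
    if n > 200:
        raise ValueError(f"brute force limited to 200 transactions, got {n}")
    universe = sorted(set().union(*transactions)) if transactions else []
    if len(universe) > 12:
        raise ValueError(f"brute force limited to 12 items, got {len(universe)}")
    min_count = min_support * n
    out = []
    for size in range(1, len(universe) + 1):
        for subset in combinations(universe, size):
            fs = frozenset(subset)
            count = sum(1 for t in transactions if fs <= t)
            if count >= min_count:
                out.append(Itemset(subset, count))
    return sorted(out, key=lambda it: (len(it.items), it.items))


def rules_to_frame(rules: Sequence[AssociationRule], decimals: int | None = None) -> pd.DataFrame:
    """Rule table with the report columns (optionally rounded for display)."""
    df = pd.DataFrame(
        {
            "rule": [r.label for r in rules],
            "antecedent": [",".join(r.antecedent) for r in rules],
            "consequent": [r.consequent for r in rules],
            "N": [r.metrics.N for r in rules],
            "support": [r.metrics.support for r in rules],
            "confidence": [r.metrics.confidence for r in rules],
            "lift": [r.metrics.lift for r in rules],
            "IS": [r.metrics.is_scale for r in rules],
        }
    )
    if decimals is not None:
        for col in ("support", "confidence", "lift", "IS"):
            df[col] = df[col].round(decimals)
    return df


class AprioriMiner(BaseEstimator):
    """Scikit-learn style estimator around the Apriori pipeline.

    ``fit`` accepts a :class:`~comorbid_arm.transactions.TransactionSet`
    or any iterable of item collections, mines frequent itemsets,
    generates single-consequent rules, filters them by the thresholds
    and ranks them by IS.

    Attributes (after ``fit``)
    --------------------------
    itemsets_ : list[Itemset]
        Frequent itemsets up to size ``max_antecedent_size + 1``.
    rules_ : list[AssociationRule]
        Filtered rules in IS rank order (truncated to ``top_k`` if set).
    n_transactions_ : int
        Denominator used for support (includes empty transactions).
    item_counts_ : dict
        Per-item transaction counts.
    """

    def __init__(
        self,
        min_support: float = 0.01,
        min_confidence: float = 0.10,
        min_lift: float = 1.0,
        strict_lift: bool = True,
        max_antecedent_size: int = 2,
        top_k: int | None = None,
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.min_lift = min_lift
        self.strict_lift = strict_lift
        self.max_antecedent_size = max_antecedent_size
        self.top_k = top_k

    def _config(self) -> MiningConfig:
        return MiningConfig(
            min_support=self.min_support,
            min_confidence=self.min_confidence,
            min_lift=self.min_lift,
            strict_lift=self.strict_lift,
            max_antecedent_size=self.max_antecedent_size,
            top_k=self.top_k,
        )

    def fit(self, X: TransactionSet | Iterable, y=None) -> "AprioriMiner":
        config = self._config()
        transactions, n = _itemlists(X)
        self.n_transactions_ = n
        self.itemsets_ = apriori(
            transactions, config.min_support, max_len=config.max_antecedent_size + 1
        ) if n else []
        self.item_counts_ = {
            it.items[0]: it.count for it in self.itemsets_ if len(it.items) == 1
        }
        rules = generate_rules(self.itemsets_, n, config.min_confidence)
        self.rules_ = rank_rules(filter_rules(rules, config), config.top_k)
        return self

    def bidirectional_pairs_(self) -> list[tuple[AssociationRule, AssociationRule]]:
        return bidirectional_pairs(self.rules_)

    def rules_frame(self, decimals: int | None = None) -> pd.DataFrame:
        return rules_to_frame(self.rules_, decimals=decimals)
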