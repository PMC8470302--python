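"""Synthetic discharge-record cohorts.

The national discharge survey this package targets is restricted, so
every downstream stage is exercised on generated cohorts that share its
structure: adults with a principal mood-disorder diagnosis (F30-F39),
0-20 additional diagnoses, demographic strata, and block-level
comorbidity structure.  Two generators are provided.

**Exact mode** (:func:`generate_exact_cohort`) deterministically lays
out records so that block marginal counts and joint (co-occurrence)
counts over the emitted cohort match a specification *bit-exactly*.
This is how published rule rows — which pin down integer co-occurrence
and marginal counts — are reconstructed as runnable inputs.  Placement
is greedy: joint itemsets largest-first, then remaining singletons,
then empty records; output ordering is canonical (sorted by content) so
identical specs give identical files.

**Stochastic mode** (:func:`generate_random_cohort`) draws each
record's blocks independently from base prevalences and then lets each
*planted association* inject its block pair with probability
``p_pair`` (a latent Bernoulli factor).  The induced marginals, joint
probability and lift have closed forms (:func:`expected_pair_stats`)
that serve as oracles for recovery tests.

Marginal counts that publications leave implicit can be recovered from
printed ratios with :func:`marginals_from_rule_row`, which searches the
rounding interval of a printed confidence for the integer count
consistent with the printed lift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .icd import MoodSubgroup, default_block_table
from .records import MAX_ADDITIONAL, DischargeRecord

__all__ = [
    "ExactCohortSpec",
    "PlantedAssociation",
    "StochasticCohortConfig",
    "FeasibilityError",
    "generate_exact_cohort",
    "generate_random_cohort",
    "expected_pair_stats",
    "marginals_from_rule_row",
    "DEFAULT_SUBGROUP_SIZES",
    "DEFAULT_DEMOGRAPHICS",
    "DEFAULT_BLOCK_PREVALENCE",
    "DEFAULT_PLANTED",
]


class FeasibilityError(ValueError):
    """An exact-cohort specification that no record layout can satisfy."""


# Subgroup sizes of the emulated inpatient cohort (sum 7709).
DEFAULT_SUBGROUP_SIZES: dict[MoodSubgroup, int] = {
    MoodSubgroup.MANIC: 45,
    MoodSubgroup.BIPOLAR: 2414,
    MoodSubgroup.DEPRESSIVE: 4245,
    MoodSubgroup.RECURRENT_DEPRESSIVE: 827,
    MoodSubgroup.PERSISTENT: 117,
    MoodSubgroup.OTHER: 7,
    MoodSubgroup.UNSPECIFIED: 54,
}

# Demographic strata of the emulated cohort, as probabilities
# (stratum sizes 2362/5347 male/female etc., each summing to 7709).
_N_TOTAL = 7709
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"male": 2362 / _N_TOTAL, "female": 5347 / _N_TOTAL},
    "age_group": {
        "19-44": 3452 / _N_TOTAL,
        "45-64": 2551 / _N_TOTAL,
        "65-74": 1108 / _N_TOTAL,
        ">=75": 598 / _N_TOTAL,
    },
    "insurance": {
        "national_health": 6991 / _N_TOTAL,
        "medicaid_1": 488 / _N_TOTAL,
        "medicaid_2": 102 / _N_TOTAL,
        "others": 128 / _N_TOTAL,
    },
    "admission_route": {
        "emergency": 2171 / _N_TOTAL,
        "outpatient": 5537 / _N_TOTAL,
        "others": 1 / _N_TOTAL,
    },
    "outcome": {
        "improved": 7069 / _N_TOTAL,
        "not_improved": 617 / _N_TOTAL,
        "death": 8 / _N_TOTAL,
        "others": 15 / _N_TOTAL,
    },
    "bed_tier": {
        "100-299": 867 / _N_TOTAL,
        "300-499": 946 / _N_TOTAL,
        "500-999": 4346 / _N_TOTAL,
        ">=1000": 1550 / _N_TOTAL,
    },
}

# Base block prevalences roughly matching the leading comorbidity
# profile of the emulated cohort (hypertension > neurotic disorders >
# diabetes > upper-GI diseases, plus rarer blocks used by rule tests).
DEFAULT_BLOCK_PREVALENCE: dict[str, float] = {
    "I10-I15": 0.100,
    "F40-F48": 0.080,
    "E10-E14": 0.058,
    "K20-K31": 0.050,
    "E70-E90": 0.024,
    "F00-F09": 0.020,
    "G30-G32": 0.008,
}


@dataclass(frozen=True)
class PlantedAssociation:
    """A latent factor injecting both blocks with probability p_pair."""

    block_a: str
    block_b: str
    p_pair: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_pair <= 1.0:
            raise ValueError(f"p_pair must be in [0,1], got {self.p_pair}")
        if self.block_a == self.block_b:
            raise ValueError("planted association needs two distinct blocks")


DEFAULT_PLANTED: tuple[PlantedAssociation, ...] = (
    PlantedAssociation("E10-E14", "I10-I15", 0.020),
    PlantedAssociation("E70-E90", "I10-I15", 0.008),
)


def expected_pair_stats(p_a: float, p_b: float, p_pair: float) -> dict[str, float]:
    """Closed-form marginals/joint/lift of one planted pair.

    With base prevalences ``p_a``, ``p_b`` and an independent injection
    with probability ``p_pair`` adding both blocks:

    * P(A) = 1 - (1 - p_a)(1 - p_pair)  (and symmetrically for B)
    * P(A and B) = p_pair + (1 - p_pair) p_a p_b
    * lift = P(A and B) / (P(A) P(B))

    Valid when neither block participates in any other planted pair.
    """
    pa = 1.0 - (1.0 - p_a) * (1.0 - p_pair)
    pb = 1.0 - (1.0 - p_b) * (1.0 - p_pair)
    pj = p_pair + (1.0 - p_pair) * p_a * p_b
    return {"p_a": pa, "p_b": pb, "p_joint": pj, "lift": pj / (pa * pb)}


# ---------------------------------------------------------------------------
# Exact mode


def _as_itemset(key) -> frozenset:
    if isinstance(key, str):
        raise TypeError("joint_counts keys must be iterables of block ids")
    fs = frozenset(key)
    if len(fs) < 2:
        raise ValueError(f"joint itemset needs at least 2 distinct blocks: {key!r}")
    return fs


@dataclass(frozen=True)
class ExactCohortSpec:
    """Target block marginals and joint co-occurrence counts.

    ``joint_counts`` keys are iterables of block ids; pairs are the
    common case but any itemset size is accepted (a printed rule with a
    two-block antecedent implies a triple co-occurrence).  Every block
    referenced in a joint must also have a marginal in ``block_counts``.
    """

    n: int
    subgroup: MoodSubgroup = MoodSubgroup.ALL
    block_counts: Mapping[str, int] = field(default_factory=dict)
    joint_counts: Mapping = field(default_factory=dict)

    def normalized_joints(self) -> dict[frozenset, int]:
        return {_as_itemset(k): int(v) for k, v in self.joint_counts.items()}

    def validate(self) -> None:
        if self.n <= 0:
            raise FeasibilityError(f"n must be positive, got {self.n}")
        for b, c in self.block_counts.items():
            if not 0 <= c <= self.n:
                raise FeasibilityError(f"marginal count of {b} ({c}) outside [0, n={self.n}]")
        for items, c in self.normalized_joints().items():
            for b in items:
                if b not in self.block_counts:
                    raise FeasibilityError(
                        f"joint itemset {sorted(items)} references {b} with no marginal count"
                    )
            cap = min(self.block_counts[b] for b in items)
            if c > cap:
                raise FeasibilityError(
                    f"joint count {c} of {sorted(items)} exceeds smallest marginal {cap}"
                )


_EXACT_DEMOGRAPHICS = {
    "sex": "female",
    "age_group": "19-44",
    "insurance": "national_health",
    "admission_route": "outpatient",
    "outcome": "improved",
    "bed_tier": "500-999",
}


def _principal_for(subgroup: MoodSubgroup) -> str:
    return "F32" if subgroup is MoodSubgroup.ALL else subgroup.value


def generate_exact_cohort(spec: ExactCohortSpec) -> list[DischargeRecord]:
    """Emit records whose block marginal/joint counts equal the spec exactly.

    Greedy layout: joint itemsets (largest first) become records
    carrying exactly that itemset, minus whatever larger placements
    already cover; remaining marginal mass becomes single-block
    records; the rest of the ``n`` records carry no additional
    diagnoses.  A final recount guards against specs the greedy layout
    cannot satisfy.
    """
    spec.validate()
    joints = spec.normalized_joints()
    table = default_block_table()
    code_of = {b: table[b].start for b in spec.block_counts}  # representative category

    itemsets: list[frozenset] = []  # one entry per record with >= 1 block
    for items, target in sorted(
        joints.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
    ):
        already = sum(1 for placed in itemsets if items <= placed)
        if already > target:
            raise FeasibilityError(
                f"joint count {target} of {sorted(items)} already exceeded by "
                f"higher-order placements ({already})"
            )
        itemsets.extend([items] * (target - already))

    for block in sorted(spec.block_counts):
        placed = sum(1 for placed_items in itemsets if block in placed_items)
        remaining = spec.block_counts[block] - placed
        if remaining < 0:
            raise FeasibilityError(
                f"marginal count of {block} ({spec.block_counts[block]}) exceeded "
                f"by joint placements ({placed})"
            )
        itemsets.extend([frozenset({block})] * remaining)

    if len(itemsets) > spec.n:
        raise FeasibilityError(
            f"layout needs {len(itemsets)} records but n={spec.n}"
        )
    itemsets.sort(key=lambda s: tuple(sorted(s)))

    principal = _principal_for(spec.subgroup)
    records = []
    for i in range(spec.n):
        items = itemsets[i] if i < len(itemsets) else frozenset()
        records.append(
            DischargeRecord(
                record_id=f"{principal}-{i:06d}",
                principal=principal,
                additional=tuple(code_of[b] for b in sorted(items)),
                **_EXACT_DEMOGRAPHICS,
            )
        )

    _verify_exact(records, spec, code_of)
    return records


def _verify_exact(records, spec: ExactCohortSpec, code_of) -> None:
    block_of_code = {v: k for k, v in code_of.items()}
    sets = [frozenset(block_of_code[c] for c in r.additional) for r in records]
    for b, target in spec.block_counts.items():
        got = sum(1 for s in sets if b in s)
        if got != target:
            raise FeasibilityError(f"unreachable marginal for {b}: got {got}, spec {target}")
    for items, target in spec.normalized_joints().items():
        got = sum(1 for s in sets if items <= s)
        if got != target:
            raise FeasibilityError(
                f"unreachable joint count for {sorted(items)}: got {got}, spec {target}"
            )


# ---------------------------------------------------------------------------
# Stochastic mode


@dataclass
class StochasticCohortConfig:
    """Seeded generative model of a discharge cohort.

    Demographics are drawn independently of diagnosis content; blocks
    are independent Bernoulli draws plus planted-pair injections.
    """

    seed: int
    n_per_subgroup: Mapping[MoodSubgroup, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_SIZES)
    )
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    base_block_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_PREVALENCE)
    )
    planted_associations: Sequence[PlantedAssociation] = DEFAULT_PLANTED
    max_additional: int = MAX_ADDITIONAL

    def validate(self) -> None:
        if self.max_additional > MAX_ADDITIONAL:
            raise ValueError(f"max_additional cannot exceed {MAX_ADDITIONAL}")
        for name, dist in self.demographics.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"demographic distribution {name!r} sums to {total}")
            if any(not 0.0 <= p <= 1.0 for p in dist.values()):
                raise ValueError(f"demographic distribution {name!r} has p outside [0,1]")
        for b, p in self.base_block_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {b} outside [0,1]: {p}")
        for sg, n in self.n_per_subgroup.items():
            if MoodSubgroup(sg) is MoodSubgroup.ALL:
                raise ValueError("n_per_subgroup must use concrete subgroups, not ALL")
            if n < 0:
                raise ValueError(f"negative subgroup size for {sg}")


def generate_random_cohort(config: StochasticCohortConfig) -> list[DischargeRecord]:
    """Draw a cohort; identical config + seed gives an identical cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    table = default_block_table()

    blocks = sorted(
        set(config.base_block_prevalence)
        | {a.block_a for a in config.planted_associations}
        | {a.block_b for a in config.planted_associations}
    )
    code_of = {b: table[b].start for b in blocks}
    base_p = np.array([config.base_block_prevalence.get(b, 0.0) for b in blocks])
    col = {b: i for i, b in enumerate(blocks)}

    records: list[DischargeRecord] = []
    demo_fields = list(config.demographics)
    for sg in sorted(config.n_per_subgroup, key=lambda s: MoodSubgroup(s).value):
        sg = MoodSubgroup(sg)
        n = config.n_per_subgroup[sg]
        if n == 0:
            continue
        demo = {}
        for name in demo_fields:
            cats = list(config.demographics[name])
            probs = np.array([config.demographics[name][c] for c in cats])
            demo[name] = rng.choice(cats, size=n, p=probs / probs.sum())
        present = rng.random((n, len(blocks))) < base_p
        for assoc in config.planted_associations:
            inject = rng.random(n) < assoc.p_pair
            present[inject, col[assoc.block_a]] = True
            present[inject, col[assoc.block_b]] = True

        for i in range(n):
            items = [blocks[j] for j in np.flatnonzero(present[i])]
            if len(items) > config.max_additional:
                items = items[: config.max_additional]
            records.append(
                DischargeRecord(
                    record_id=f"{sg.value}-{i:06d}",
                    sex=str(demo["sex"][i]),
                    age_group=str(demo["age_group"][i]),
                    insurance=str(demo["insurance"][i]),
                    admission_route=str(demo["admission_route"][i]),
                    outcome=str(demo["outcome"][i]),
                    bed_tier=str(demo["bed_tier"][i]),
                    principal=sg.value,
                    additional=tuple(code_of[b] for b in items),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Reconstruction of integer marginals from printed ratios


def _confidence_candidates(count_joint: int, confidence: float, n: int, decimals: int = 3):
    """Integer antecedent counts whose confidence rounds to the printed value."""
    half = 0.5 * 10 ** (-decimals)
    lo = math.ceil(count_joint / (confidence + half))
    hi = math.floor(count_joint / max(confidence - half, 1e-12))
    return [
        x
        for x in range(max(lo, count_joint), max(hi, count_joint) + 1)
        if x <= n and round(count_joint / x, decimals) == round(confidence, decimals)
    ]


def marginals_from_rule_row(
    n: int,
    count_joint: int,
    confidence_forward: float,
    confidence_reverse: float | None = None,
    lift: float | None = None,
    decimals: int = 3,
) -> tuple[int, int]:
    """Recover (count_A, count_B) from a printed rule row.

    ``confidence_forward`` pins count_A to the integers in its rounding
    interval; count_B comes from ``confidence_reverse`` when printed,
    otherwise from ``lift``.  Among candidate pairs the one whose
    recomputed lift matches the printed lift at ``decimals`` is chosen
    (ties broken by closeness to the unrounded ratio).
    """
    cand_a = _confidence_candidates(count_joint, confidence_forward, n, decimals)
    if not cand_a:
        raise ValueError("no integer count_A consistent with the printed confidence")
    if confidence_reverse is not None:
        cand_b = _confidence_candidates(count_joint, confidence_reverse, n, decimals)
        if not cand_b:
            raise ValueError("no integer count_B consistent with the printed confidence")
    elif lift is not None:
        cand_b = sorted(
            {int(round(count_joint * n / (a * lift))) for a in cand_a}
        )
    else:
        raise ValueError("need confidence_reverse or lift to pin down count_B")

    def score(pair):
        a, b = pair
        s = 0.0
        if lift is not None:
            s += abs(round(count_joint * n / (a * b), decimals) - round(lift, decimals)) * 1e6
        s += abs(a - count_joint / confidence_forward)
        if confidence_reverse is not None:
            s += abs(b - count_joint / confidence_reverse)
        return s

    return min(((a, b) for a in cand_a for b in cand_b), key=score)
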