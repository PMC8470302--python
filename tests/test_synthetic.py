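"""Exact and stochastic cohort generators and record CSV round-trips."""

import numpy as np
import pytest

from comorbid_arm import (
    ExactCohortSpec,
    MoodSubgroup,
    PlantedAssociation,
    StochasticCohortConfig,
    build_transactions,
    generate_exact_cohort,
    generate_random_cohort,
    read_records,
    write_records,
)
from comorbid_arm.records import RecordParseError
from comorbid_arm.synthetic import (
    FeasibilityError,
    expected_pair_stats,
    marginals_from_rule_row,
)
from conftest import make_record


def recount(records):
    tset = build_transactions(records)
    joint = {}
    for t in tset.transactions:
        for a in sorted(t.items):
            for b in sorted(t.items):
                if a < b:
                    joint[(a, b)] = joint.get((a, b), 0) + 1
    return tset.item_counts, joint


class TestExactMode:
    def test_reconstructed_pooled_rule_counts(self, pooled_exact_cohort):
        counts, joint = recount(pooled_exact_cohort)
        assert counts == {"E10-E14": 520, "I10-I15": 838}
        assert joint == {("E10-E14", "I10-I15"): 262}
        assert len(pooled_exact_cohort) == 7709
        # layout: 262 both, 258 diabetes only, 576 hypertension only, 6613 empty
        sizes = [len(r.additional) for r in pooled_exact_cohort]
        assert sizes.count(2) == 262 and sizes.count(1) == 258 + 576
        assert sizes.count(0) == 6613

    def test_saturated_marginal(self):
        records = generate_exact_cohort(
            ExactCohortSpec(n=4, block_counts={"I10-I15": 4})
        )
        assert all(r.additional == ("I10",) for r in records)

    def test_infeasible_cases(self):
        with pytest.raises(FeasibilityError):
            generate_exact_cohort(
                ExactCohortSpec(
                    n=10,
                    block_counts={"A00-A09": 2, "B00-B09": 5},
                    joint_counts={("A00-A09", "B00-B09"): 3},
                )
            )
        with pytest.raises(FeasibilityError):
            generate_exact_cohort(
                ExactCohortSpec(n=3, block_counts={"A00-A09": 2, "B00-B09": 2})
            )
        with pytest.raises(FeasibilityError):
            generate_exact_cohort(ExactCohortSpec(n=0))

    def test_triple_joint_layout(self):
        spec = ExactCohortSpec(
            n=117,
            subgroup=MoodSubgroup.PERSISTENT,
            block_counts={"E10-E14": 6, "I10-I15": 3, "G20-G26": 2},
            joint_counts={
                ("E10-E14", "I10-I15", "G20-G26"): 2,
                ("E10-E14", "I10-I15"): 3,
            },
        )
        records = generate_exact_cohort(spec)
        counts, joint = recount(records)
        assert counts == {"E10-E14": 6, "I10-I15": 3, "G20-G26": 2}
        assert joint[("E10-E14", "I10-I15")] == 3
        triples = sum(1 for r in records if len(r.additional) == 3)
        assert triples == 2

    def test_canonical_ordering_is_deterministic(self):
        spec = ExactCohortSpec(
            n=20,
            block_counts={"E10-E14": 5, "I10-I15": 7},
            joint_counts={("E10-E14", "I10-I15"): 2},
        )
        assert generate_exact_cohort(spec) == generate_exact_cohort(spec)


class TestStochasticMode:
    def test_seed_determinism(self):
        cfg = StochasticCohortConfig(seed=11)
        assert generate_random_cohort(cfg) == generate_random_cohort(cfg)

    def test_different_seeds_differ(self):
        a = generate_random_cohort(StochasticCohortConfig(seed=1))
        b = generate_random_cohort(StochasticCohortConfig(seed=2))
        assert a != b

    def test_all_zero_prevalence_gives_empty_transactions(self):
        cfg = StochasticCohortConfig(
            seed=3,
            n_per_subgroup={MoodSubgroup.DEPRESSIVE: 200},
            base_block_prevalence={},
            planted_associations=(),
        )
        records = generate_random_cohort(cfg)
        assert len(records) == 200
        assert all(r.additional == () for r in records)

    def test_without_planting_lift_is_near_one(self):
        cfg = StochasticCohortConfig(
            seed=5,
            n_per_subgroup={MoodSubgroup.DEPRESSIVE: 50_000},
            base_block_prevalence={"E10-E14": 0.1, "I10-I15": 0.1},
            planted_associations=(),
        )
        tset = build_transactions(generate_random_cohort(cfg))
        counts = tset.item_counts
        joint = sum(
            1 for t in tset.transactions if {"E10-E14", "I10-I15"} <= t.items
        )
        lift = (joint / tset.n) / (
            (counts["E10-E14"] / tset.n) * (counts["I10-I15"] / tset.n)
        )
        assert lift == pytest.approx(1.0, abs=0.15)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            StochasticCohortConfig(
                seed=1, demographics={"sex": {"male": 0.7, "female": 0.7}}
            ).validate()
        with pytest.raises(ValueError):
            StochasticCohortConfig(seed=1, max_additional=21).validate()

    def test_expected_pair_stats_closed_form(self):
        stats = expected_pair_stats(0.05, 0.05, 0.05)
        assert stats["p_a"] == pytest.approx(1 - 0.95 * 0.95)
        assert stats["p_joint"] == pytest.approx(0.05 + 0.95 * 0.0025)
        assert stats["lift"] == pytest.approx(
            stats["p_joint"] / (stats["p_a"] * stats["p_b"])
        )


class TestRecordsIO:
    def test_round_trip(self, tmp_path):
        cfg = StochasticCohortConfig(seed=9)
        records = generate_random_cohort(cfg)[:100]
        path = tmp_path / "cohort.csv"
        write_records(records, path)
        assert read_records(path) == records

    def test_empty_additional_column(self, tmp_path):
        path = tmp_path / "one.csv"
        write_records([make_record()], path)
        (rec,) = read_records(path)
        assert rec.additional == ()

    def test_too_many_additional_codes(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_records([make_record()], path)
        text = path.read_text().splitlines()
        text[1] = text[1][:-0] + ";".join(["I10"] * 21)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(RecordParseError, match=":2:"):
            read_records(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_records([make_record(), make_record("r1")], path)
        lines = path.read_text().splitlines()
        lines[2] = "only,three,fields"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(RecordParseError, match=":3:"):
            read_records(path)


class TestMarginalReconstruction:
    @pytest.mark.parametrize(
        "n, N, conf_f, conf_r, lift, expected",
        [
            (7709, 262, 0.504, 0.313, 4.635, (520, 838)),
            (2414, 38, 0.309, 0.355, 6.970, (123, 107)),
            (4245, 54, 0.844, 0.292, 19.361, (64, 185)),
            (827, 13, 0.867, 0.394, 21.719, (15, 33)),
            (117, 2, 0.667, None, 39.0, (3, 2)),
        ],
    )
    def test_recovers_counts_consistent_with_printed_row(
        self, n, N, conf_f, conf_r, lift, expected
    ):
        assert marginals_from_rule_row(n, N, conf_f, conf_r, lift) == expected

    def test_reconstructed_counts_reproduce_all_printed_ratios(self):
        a, b = marginals_from_rule_row(7709, 262, 0.504, 0.313, 4.635)
        assert round(262 / a, 3) == 0.504
        assert round(262 / b, 3) == 0.313
        assert round(262 * 7709 / (a * b), 3) == 4.635
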