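import pytest

from comorbid_arm import (
    DischargeRecord,
    ExactCohortSpec,
    MoodSubgroup,
    build_transactions,
    generate_exact_cohort,
)

DEMO = dict(
    sex="female",
    age_group="19-44",
    insurance="national_health",
    admission_route="outpatient",
    outcome="improved",
    bed_tier="500-999",
)


def make_record(record_id="r0", principal="F32", additional=(), **overrides):
    fields = {**DEMO, **overrides}
    return DischargeRecord(
        record_id=record_id, principal=principal, additional=tuple(additional), **fields
    )


@pytest.fixture
def four_transactions():
    """The hand-checked 4-transaction instance {A,B},{A},{B,C},{A,B,C}."""
    return [{"A", "B"}, {"A"}, {"B", "C"}, {"A", "B", "C"}]


@pytest.fixture(scope="session")
def pooled_exact_cohort():
    """Exact cohort reconstructing the pooled diabetes-hypertension rule:
    n=7709, marginals 520 / 838, joint 262."""
    spec = ExactCohortSpec(
        n=7709,
        block_counts={"E10-E14": 520, "I10-I15": 838},
        joint_counts={("E10-E14", "I10-I15"): 262},
    )
    return generate_exact_cohort(spec)


@pytest.fixture(scope="session")
def pooled_exact_tset(pooled_exact_cohort):
    return build_transactions(pooled_exact_cohort, MoodSubgroup.ALL)
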