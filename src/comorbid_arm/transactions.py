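"""Discharge records -> block-level transactions.

A *transaction* is the deduplicated set of comorbidity blocks of one
discharge.  Records with no comorbidity stay in the set as empty
transactions — the support denominator is the full subgroup size, not
just the patients with at least one comorbidity.

The principal diagnosis code itself is excluded from its record's
transaction, but other additional codes that happen to map into the
principal's own block are kept by default: a recurrent-depression
inpatient with an additional F31 diagnosis genuinely carries the mood
block F30-F39 as a comorbidity.  Set ``same_block_policy="drop_block"``
to exclude the principal's whole block instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .icd import (
    BlockTable,
    ComorbidityClass,
    MoodSubgroup,
    comorbidity_class,
    default_block_table,
    mood_subgroup,
    normalize_code,
)
from .records import DischargeRecord

__all__ = [
    "Transaction",
    "TransactionSet",
    "PresenceFlags",
    "build_transactions",
    "comorbidity_presence",
    "write_transactions",
    "BlockTransactionizer",
]


class Transaction(NamedTuple):
    record_id: str
    items: frozenset


class PresenceFlags(NamedTuple):
    has_psychiatric: bool
    has_physical: bool
    has_any: bool


@dataclass
class TransactionSet:
    """Per-subgroup bag of transactions; ``n`` includes empty ones."""

    subgroup: MoodSubgroup
    transactions: list[Transaction] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def item_counts(self) -> dict[str, int]:
        counts: Counter = Counter()
        for t in self.transactions:
            counts.update(t.items)
        return dict(counts)

    def itemlists(self) -> list[frozenset]:
        return [t.items for t in self.transactions]


def _record_items(
    record: DischargeRecord,
    table: BlockTable,
    unknown: str,
    same_block_policy: str,
) -> frozenset:
    principal = normalize_code(record.principal)
    principal_block = table.block_of_or_none(principal, policy="skip")
    items = set()
    for raw in record.additional:
        code = normalize_code(raw)
        if code.category == principal.category:
            continue  # the principal code itself is never its own comorbidity
        block = table.block_of_or_none(code, policy=unknown)
        if block is None:
            continue
        if (
            same_block_policy == "drop_block"
            and principal_block is not None
            and block.block_id == principal_block.block_id
        ):
            continue
        items.add(block.block_id)
    return frozenset(items)


def build_transactions(
    records: Iterable[DischargeRecord],
    subgroup: MoodSubgroup = MoodSubgroup.ALL,
    *,
    table: BlockTable | None = None,
    unknown: str = "error",
    same_block_policy: str = "keep",
) -> TransactionSet:
    """Filter records to ``subgroup`` and convert each to a block set.

    ``n`` counts every record passing the subgroup filter, including
    those whose transaction ends up empty.
    """
    if same_block_policy not in ("keep", "drop_block"):
        raise ValueError(f"unknown same_block_policy {same_block_policy!r}")
    table = table or default_block_table()
    tset = TransactionSet(subgroup=subgroup)
    for record in records:
        sg = mood_subgroup(normalize_code(record.principal))
        if subgroup is not MoodSubgroup.ALL and sg is not subgroup:
            continue
        tset.transactions.append(
            Transaction(
                record_id=record.record_id,
                items=_record_items(record, table, unknown, same_block_policy),
            )
        )
    return tset


def comorbidity_presence(
    record: DischargeRecord,
    *,
    table: BlockTable | None = None,
    unknown: str = "error",
) -> PresenceFlags:
    """Whether the record has any psychiatric / physical comorbidity."""
    table = table or default_block_table()
    items = _record_items(record, table, unknown, same_block_policy="keep")
    has_psych = any(
        comorbidity_class(table[b]) is ComorbidityClass.PSYCHIATRIC for b in items
    )
    has_phys = any(
        comorbidity_class(table[b]) is ComorbidityClass.PHYSICAL for b in items
    )
    return PresenceFlags(has_psych, has_phys, has_psych or has_phys)


def write_transactions(tset: TransactionSet, path) -> None:
    """One row per record: record_id, semicolon-joined block ids."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("record_id,blocks\n")
        for t in tset.transactions:
            fh.write(f"{t.record_id},{';'.join(sorted(t.items))}\n")


class BlockTransactionizer(TransformerMixin, BaseEstimator):
    """Stateless transformer wrapping :func:`build_transactions`.

    Lets the records -> transactions step sit inside a scikit-learn
    pipeline in front of :class:`~comorbid_arm.mining.AprioriMiner`.
    """

    def __init__(
        self,
        subgroup: MoodSubgroup = MoodSubgroup.ALL,
        unknown: str = "error",
        same_block_policy: str = "keep",
    ):
        self.subgroup = subgroup
        self.unknown = unknown
        self.same_block_policy = same_block_policy

    def fit(self, X: Sequence[DischargeRecord], y=None):
        return self

    def transform(self, X: Sequence[DischargeRecord]) -> TransactionSet:
        return build_transactions(
            X,
            self.subgroup,
            unknown=self.unknown,
            same_block_policy=self.same_block_policy,
        )
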