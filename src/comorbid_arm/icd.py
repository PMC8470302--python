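"""ICD-10 / KCD-7 code normalization and block (middle-classification) mapping.

All analysis in this package operates at the level of ICD-10 *blocks*
(middle classification), e.g. ``I10-I15`` "Hypertensive diseases".  A
diagnosis code such as ``I11.0`` is first normalized to its 3-character
category ``I11`` and then mapped to the block whose inclusive
``[start, end]`` range contains it, ordering categories by (letter,
number).

The block vocabulary ships as a packaged CSV (WHO ICD-10, 2016 edition)
covering A00-Z99 plus the U chapter.  Korea-specific KCD-7 codes map
normally when their category falls inside a listed range; anything else
is governed by the *unknown-code policy*: ``"error"`` raises (strict
mode, the default for library calls) while ``"skip"`` drops the code
with a logged warning (the default inside the pipeline, where real-world
dumps routinely contain local codes).

Comorbidity blocks are classified *psychiatric* when the whole block
lies within F00-F69, otherwise *physical* — so F70-F99 blocks count as
physical comorbidity.
"""

from __future__ import annotations

import csv
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass
from enum import Enum
from importlib.resources import files
from functools import lru_cache

__all__ = [
    "ICDCode",
    "ICDBlock",
    "ComorbidityClass",
    "MoodSubgroup",
    "BlockTable",
    "CodeError",
    "BlockLookupError",
    "NotInCohortError",
    "normalize_code",
    "block_of",
    "comorbidity_class",
    "mood_subgroup",
    "default_block_table",
]

logger = logging.getLogger(__name__)

_CATEGORY_RE = re.compile(r"^([A-Z])([0-9]{2})")


class CodeError(ValueError):
    """A diagnosis code string that cannot be normalized."""


class BlockLookupError(KeyError):
    """A normalized category not covered by the shipped block table."""


class NotInCohortError(ValueError):
    """A principal diagnosis outside the mood-disorder range F30-F39."""


@dataclass(frozen=True)
class ICDCode:
    """A diagnosis code: the raw input string and its 3-character category."""

    raw: str
    category: str

    def __post_init__(self) -> None:
        if not _CATEGORY_RE.fullmatch(self.category):
            raise CodeError(f"invalid ICD category {self.category!r}")


@dataclass(frozen=True)
class ICDBlock:
    """An ICD-10 middle-classification range, e.g. I10-I15."""

    block_id: str
    start: str
    end: str
    chapter: str
    label: str

    def __post_init__(self) -> None:
        if _cat_key(self.start) > _cat_key(self.end):
            raise ValueError(f"block {self.block_id}: start > end")

    def __contains__(self, category: str) -> bool:
        return _cat_key(self.start) <= _cat_key(category) <= _cat_key(self.end)


class ComorbidityClass(str, Enum):
    PSYCHIATRIC = "psychiatric"
    PHYSICAL = "physical"


class MoodSubgroup(str, Enum):
    """Principal-diagnosis subgroups of the mood-disorder cohort.

    F35-F37 are not assigned in ICD-10 and are rejected; ``ALL`` pools
    every principal diagnosis in F30-F39.
    """

    MANIC = "F30"
    BIPOLAR = "F31"
    DEPRESSIVE = "F32"
    RECURRENT_DEPRESSIVE = "F33"
    PERSISTENT = "F34"
    OTHER = "F38"
    UNSPECIFIED = "F39"
    ALL = "ALL"

    @property
    def label(self) -> str:
        return _SUBGROUP_LABELS[self]


_SUBGROUP_LABELS = {
    MoodSubgroup.MANIC: "Manic episode (F30)",
    MoodSubgroup.BIPOLAR: "Bipolar affective disorders (F31)",
    MoodSubgroup.DEPRESSIVE: "Depressive episode (F32)",
    MoodSubgroup.RECURRENT_DEPRESSIVE: "Recurrent depressive disorders (F33)",
    MoodSubgroup.PERSISTENT: "Persistent mood disorders (F34)",
    MoodSubgroup.OTHER: "Other mood disorders (F38)",
    MoodSubgroup.UNSPECIFIED: "Unspecified mood disorders (F39)",
    MoodSubgroup.ALL: "Mood disorders (F30-F39)",
}


def _cat_key(category: str) -> tuple[str, int]:
    return category[0], int(category[1:3])


def normalize_code(raw: str) -> ICDCode:
    """Normalize a raw diagnosis string to its 3-character category.

    Uppercases, strips whitespace and dots, and keeps the leading
    letter + two digits (4th and later characters are subcategory
    detail, irrelevant at block granularity).

    >>> normalize_code("i10.0").category
    'I10'
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CodeError(f"empty or non-string diagnosis code: {raw!r}")
    compact = raw.strip().upper().replace(".", "")
    m = _CATEGORY_RE.match(compact)
    if m is None:
        raise CodeError(f"malformed diagnosis code {raw!r}: expected letter + 2 digits")
    return ICDCode(raw=raw, category=m.group(0))


class BlockTable:
    """The ICD-10 block vocabulary with category -> block lookup.

    Lookup is by binary search over block start categories; ranges are
    validated to be ordered and non-overlapping at load time.
    """

    def __init__(self, blocks: list[ICDBlock]):
        self.blocks = sorted(blocks, key=lambda b: _cat_key(b.start))
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if _cat_key(cur.start) <= _cat_key(prev.end):
                raise ValueError(
                    f"overlapping blocks {prev.block_id} and {cur.block_id}"
                )
        self._starts = [_cat_key(b.start) for b in self.blocks]
        self._by_id = {b.block_id: b for b in self.blocks}

    @classmethod
    def from_csv(cls, path) -> "BlockTable":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            [
                ICDBlock(
                    block_id=r["block_id"],
                    start=r["start"],
                    end=r["end"],
                    chapter=r["chapter"],
                    label=r["label"],
                )
                for r in rows
            ]
        )

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, block_id: str) -> ICDBlock:
        return self._by_id[block_id]

    def block_of(self, code: ICDCode | str) -> ICDBlock:
        """Map a (normalized) code to its unique containing block."""
        category = code.category if isinstance(code, ICDCode) else code
        if not _CATEGORY_RE.fullmatch(category):
            raise CodeError(f"not a normalized category: {category!r}")
        i = bisect_right(self._starts, _cat_key(category)) - 1
        if i >= 0 and category in self.blocks[i]:
            return self.blocks[i]
        raise BlockLookupError(f"category {category} not covered by the block table")

    def block_of_or_none(self, code: ICDCode | str, policy: str = "error"):
        """Lookup honouring the unknown-code policy ('error' or 'skip')."""
        try:
            return self.block_of(code)
        except BlockLookupError:
            if policy == "skip":
                cat = code.category if isinstance(code, ICDCode) else code
                logger.warning("skipping unknown diagnosis category %s", cat)
                return None
            raise


@lru_cache(maxsize=1)
def default_block_table() -> BlockTable:
    """The packaged WHO ICD-10 (2016) block table."""
    resource = files("comorbid_arm.data").joinpath("icd10_blocks.csv")
    with resource.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return BlockTable(
        [
            ICDBlock(
                block_id=r["block_id"],
                start=r["start"],
                end=r["end"],
                chapter=r["chapter"],
                label=r["label"],
            )
            for r in rows
        ]
    )


def block_of(code: ICDCode | str, table: BlockTable | None = None) -> ICDBlock:
    """Map a normalized code to its block using the packaged table."""
    return (table or default_block_table()).block_of(code)


def comorbidity_class(block: ICDBlock) -> ComorbidityClass:
    """Psychiatric iff the block lies entirely within F00-F69."""
    if _cat_key("F00") <= _cat_key(block.start) and _cat_key(block.end) <= _cat_key("F69"):
        return ComorbidityClass.PSYCHIATRIC
    return ComorbidityClass.PHYSICAL


_MOOD_CATEGORIES = {
    "F30": MoodSubgroup.MANIC,
    "F31": MoodSubgroup.BIPOLAR,
    "F32": MoodSubgroup.DEPRESSIVE,
    "F33": MoodSubgroup.RECURRENT_DEPRESSIVE,
    "F34": MoodSubgroup.PERSISTENT,
    "F38": MoodSubgroup.OTHER,
    "F39": MoodSubgroup.UNSPECIFIED,
}


def mood_subgroup(principal: ICDCode | str) -> MoodSubgroup:
    """Subgroup of a principal diagnosis; rejects anything outside F30-F39.

    F35-F37 do not exist in ICD-10 and are rejected too.
    """
    category = principal.category if isinstance(principal, ICDCode) else principal
    try:
        return _MOOD_CATEGORIES[category]
    except KeyError:
        raise NotInCohortError(
            f"principal diagnosis {category} is not a mood disorder (F30-F34, F38, F39)"
        ) from None
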