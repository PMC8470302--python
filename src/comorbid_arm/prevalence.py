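"""Prevalence tables, Pearson chi-square tests and frequency profiles.

Prevalence is tabulated per demographic stratum (or per principal-
diagnosis subgroup) as the count and percentage of inpatients carrying
at least one psychiatric / physical / any comorbidity.  Independence of
comorbidity presence from the stratifier is tested with Pearson's
chi-square on the stratum x presence contingency table, without
continuity correction.  Computation is on unrounded ratios throughout;
the conventional display rounding (percentages to 2 dp, statistics to
3 dp) is applied only when tables are formatted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency

from .icd import MoodSubgroup, mood_subgroup, normalize_code
from .records import DischargeRecord
from .transactions import TransactionSet, comorbidity_presence

__all__ = [
    "ChiSquareResult",
    "DegenerateTableError",
    "pearson_chi_square",
    "prevalence_table",
    "prevalence_chi_square",
    "block_relative_frequency",
    "format_p",
]


class DegenerateTableError(ValueError):
    """Contingency table with an all-zero row or column marginal."""


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    valid: bool


def pearson_chi_square(table, *, allow_degenerate: bool = False) -> ChiSquareResult:
    """Pearson chi-square without continuity correction.

    A zero row/column marginal raises :class:`DegenerateTableError`
    unless ``allow_degenerate`` is set, in which case zero-expected
    cells are skipped and the result is flagged ``valid=False``
    (mirroring the "N/A" convention of published tables).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if (rows == 0).any() or (cols == 0).any():
        if not allow_degenerate:
            raise DegenerateTableError("table has an all-zero row or column marginal")
        expected = np.outer(rows, cols) / obs.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
        stat = float(terms.sum())
        return ChiSquareResult(stat, df, float(chi2.sf(stat, df)), valid=False)
    stat, p, dof, _ = chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(stat), int(dof), float(p), valid=True)


_FLAG_INDEX = {"psychiatric": 0, "physical": 1, "any": 2}


def _stratum_of(record: DischargeRecord, stratifier: str) -> str:
    if stratifier == "subgroup":
        return mood_subgroup(normalize_code(record.principal)).label
    return getattr(record, stratifier)


def prevalence_table(
    records: Sequence[DischargeRecord],
    stratifier: str,
    flag: str = "any",
    *,
    unknown: str = "error",
) -> pd.DataFrame:
    """Per-stratum comorbidity prevalence plus a totals row.

    ``stratifier`` is a demographic field name or ``"subgroup"``;
    ``flag`` selects the comorbidity class (psychiatric / physical /
    any).  ``pct`` is NaN for empty strata.
    """
    if not records:
        raise ValueError("records must be non-empty")
    idx = _FLAG_INDEX[flag]
    strata: dict[str, list[int]] = {}
    for r in records:
        key = _stratum_of(r, stratifier)
        n_flag = int(comorbidity_presence(r, unknown=unknown)[idx])
        cell = strata.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += n_flag
    rows = [
        {
            "stratum": key,
            "n": size,
            "count": count,
            "pct": 100.0 * count / size if size else math.nan,
        }
        for key, (size, count) in sorted(strata.items())
    ]
    total_n = sum(r["n"] for r in rows)
    total_count = sum(r["count"] for r in rows)
    rows.append(
        {
            "stratum": "Total",
            "n": total_n,
            "count": total_count,
            "pct": 100.0 * total_count / total_n,
        }
    )
    return pd.DataFrame(rows)


def prevalence_chi_square(
    records: Sequence[DischargeRecord],
    stratifier: str,
    flag: str = "any",
    *,
    unknown: str = "error",
    allow_degenerate: bool = False,
) -> ChiSquareResult:
    """Chi-square of the stratum x comorbidity-presence table."""
    table = prevalence_table(records, stratifier, flag, unknown=unknown)
    body = table[table["stratum"] != "Total"]
    counts = np.column_stack([body["count"], body["n"] - body["count"]])
    return pearson_chi_square(counts, allow_degenerate=allow_degenerate)


def block_relative_frequency(
    tset: TransactionSet, threshold: float = 0.05
) -> list[tuple[str, float]]:
    """Blocks with support above ``threshold``, sorted descending.

    Support here is the fraction of all transactions (empty included)
    containing the block; ties break lexicographically.
    """
    if tset.n == 0:
        raise ValueError("transaction set is empty")
    freq = [
        (block, count / tset.n)
        for block, count in tset.item_counts.items()
        if count / tset.n > threshold
    ]
    return sorted(freq, key=lambda bf: (-bf[1], bf[0]))


def format_p(p: float) -> str:
    """Report-style p-value: '<0.001' below that, else 3 dp."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"
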