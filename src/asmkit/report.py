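"""Comparison arithmetic and reporting.

Centralized half-up rounding makes printed-figure reproduction
deterministic: percent changes are reported to one decimal with the OLD
value as denominator, correction-type percentages to two decimals.
Negative changes keep an explicit sign; prose rendering uses the magnitude
with a direction word ("decreased by ...").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    value_old: float
    value_new: float
    difference: float
    pct_change: float | None  # one decimal, half-up; None when old value is 0


@dataclass(frozen=True)
class CorrectionSummary:
    n_insertions: int
    n_substitutions: int
    n_deletions: int
    total: int
    pct_insertions: float
    pct_substitutions: float
    pct_deletions: float


def _row(label: str, old: float, new: float) -> ComparisonRow:
    diff = new - old
    pct = None if old == 0 else round_half_up(100.0 * diff / old, 1)
    return ComparisonRow(label, old, new, diff, pct)


def compare_table(
    old: dict[str, float], new: dict[str, float], total_label: str = "Total"
) -> list[ComparisonRow]:
    """Old-vs-new comparison over shared labels plus a Total row of sums."""
    labels = [k for k in old if k in new]
    rows = [_row(label, old[label], new[label]) for label in labels]
    rows.append(
        _row(total_label, sum(old[k] for k in labels), sum(new[k] for k in labels))
    )
    return rows


def annotation_compare(
    old: dict[str, float], new: dict[str, float], total: bool = False
) -> list[ComparisonRow]:
    """Category-by-category annotation comparison (no Total row unless the
    categories are genuinely additive)."""
    rows = compare_table(old, new)
    return rows if total else rows[:-1]


def correction_summary(
    n_insertions: int, n_substitutions: int, n_deletions: int
) -> CorrectionSummary:
    """Polishing-correction breakdown with percentages of the total
    (two decimals, half-up)."""
    total = n_insertions + n_substitutions + n_deletions
    if total <= 0:
        raise ValueError("no corrections")
    return CorrectionSummary(
        n_insertions,
        n_substitutions,
        n_deletions,
        total,
        round_half_up(100.0 * n_insertions / total, 2),
        round_half_up(100.0 * n_substitutions / total, 2),
        round_half_up(100.0 * n_deletions / total, 2),
    )


def gap_report(agp: pd.DataFrame) -> tuple[int, int, float]:
    """(n_gaps, gap_bp, percent N of the anchored assembly) from an AGP
    table; percent to two decimals."""
    gaps = agp[agp["component_type"] == "N"]
    n_gaps = len(gaps)
    gap_bp = int(gaps["component_id"].astype(int).sum()) if n_gaps else 0
    total = int(agp.groupby("object")["object_end"].max().sum())
    pct = round_half_up(100.0 * gap_bp / total, 2) if total else 0.0
    return n_gaps, gap_bp, pct


def rows_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def render_change(row: ComparisonRow) -> str:
    """Prose rendering: direction word plus magnitude percent."""
    if row.pct_change is None:
        return f"{row.label}: changed by {row.difference:+,.0f} (NA)"
    word = "increased" if row.difference >= 0 else "decreased"
    return (
        f"{row.label}: {word} by {abs(row.difference):,.0f} "
        f"({abs(row.pct_change):g}%)"
    )


def write_provenance(path: str | Path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, default=str))
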