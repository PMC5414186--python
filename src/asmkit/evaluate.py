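"""Candidate-assembly comparison: BAC-end pair classification, per-library
likelihood-score rank averaging, standardized PCA of assembly metrics, and
the selection rule.

Likelihood (ALE-style) scores, core-gene counts and mapped-exon totals are
consumed as numbers from a metric table; computing them is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_E_THRESHOLD = 1e-150
DEFAULT_SPAN_RANGE = (50_000, 400_000)

METRIC_COLUMNS = [
    "ale_fragment", "ale_3kbp", "ale_6_7kbp", "ale_40kbp", "ale_pacbio",
    "complete_cegs", "longest_contig", "ng50", "total_bp", "exon_bp_mapped",
]


def read_metric_table(path) -> pd.DataFrame:
    """Read a per-assembly metric TSV (assembly id index), validating that
    the expected metric columns are present."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    return df


@dataclass(frozen=True)
class BacHit:
    contig: str
    pos: int
    strand: str
    e_value: float


def classify_bac_pair(
    hits_end1: Sequence[BacHit],
    hits_end2: Sequence[BacHit],
    span_range: tuple[int, int] = DEFAULT_SPAN_RANGE,
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> str:
    """Classify a clone-end pair against an assembly.

    'unaligned' — no end with an alignment below ``e_threshold``;
    '1' — exactly one end aligns; '4' — top hits on different contigs;
    '2' — same contig, convergent orientation, outer span within
    ``span_range``; '3' — same contig but wrong orientation or span.
    """
    pass1 = [h for h in hits_end1 if h.e_value < e_threshold]
    pass2 = [h for h in hits_end2 if h.e_value < e_threshold]
    if not pass1 and not pass2:
        return "unaligned"
    if not pass1 or not pass2:
        return "1"
    top1 = min(pass1, key=lambda h: h.e_value)
    top2 = min(pass2, key=lambda h: h.e_value)
    if top1.contig != top2.contig:
        return "4"
    left, right = (top1, top2) if top1.pos <= top2.pos else (top2, top1)
    convergent = left.strand == "+" and right.strand == "-"
    span = right.pos - left.pos
    if convergent and span_range[0] <= span <= span_range[1]:
        return "2"
    return "3"


def classify_bac_table(
    table: pd.DataFrame,
    span_range: tuple[int, int] = DEFAULT_SPAN_RANGE,
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> pd.Series:
    """Vector version over a clone table with per-end hit columns."""
    out = []
    for row in table.itertuples(index=False):
        h1 = (
            [BacHit(row.contig1, int(row.pos1), row.strand1, float(row.evalue1))]
            if row.contig1 is not None
            else []
        )
        h2 = (
            [BacHit(row.contig2, int(row.pos2), row.strand2, float(row.evalue2))]
            if row.contig2 is not None
            else []
        )
        out.append(classify_bac_pair(h1, h2, span_range, e_threshold))
    return pd.Series(out, index=table.index, name="class")


def rank_average(scores: pd.DataFrame) -> pd.DataFrame:
    """Average of per-library dense ranks (higher score = rank 1).

    Returns the score table augmented with per-library rank columns and an
    ``avg_rank`` column, sorted by average rank then assembly id. Invariant
    to any monotone per-library transform of the scores.
    """
    if scores.empty:
        raise ValueError("empty score table")
    ranks = scores.rank(ascending=False, method="dense")
    out = scores.copy()
    for col in scores.columns:
        out[f"rank_{col}"] = ranks[col]
    out["avg_rank"] = ranks.mean(axis=1)
    # stable: ties in average rank fall back to assembly id order
    return out.sort_index().sort_values("avg_rank", kind="stable")


def pca_metrics(
    vectors: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of z-scored assembly metrics (centered, unit variance, ddof=1).

    Constant columns are dropped with a warning. Scores x loadingsᵀ
    reconstructs the z-scored input; each component's sign is fixed so its
    largest-magnitude loading is positive. Explained variances sum to the
    number of retained columns when the assembly count exceeds it.
    """
    if len(vectors) < 3:
        raise ValueError("PCA requires at least 3 assemblies")
    x = vectors.astype(float)
    std = x.std(ddof=1)
    constant = std[std == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant metric column(s): {constant}", stacklevel=2)
        x = x.drop(columns=constant)
        std = std.drop(constant)
    z = (x - x.mean()) / std
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    for j in range(len(s)):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    pcs = [f"PC{j + 1}" for j in range(len(s))]
    scores = pd.DataFrame(u * s, index=x.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=x.columns, columns=pcs)
    explained = s**2 / (len(x) - 1)
    return scores, loadings, explained


def select_assembly(
    ranked: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    constraints: dict | None = None,
) -> tuple[str, dict]:
    """Best average-rank assembly satisfying optional metric constraints.

    ``constraints`` maps metric column -> (lo, hi) inclusive band. Returns
    the winner and a report with the runner-up margin and any assemblies
    excluded by constraints.
    """
    eligible = ranked
    excluded: list[str] = []
    if constraints:
        if metrics is None:
            raise ValueError("constraints given without a metric table")
        keep = pd.Series(True, index=ranked.index)
        for col, (lo, hi) in constraints.items():
            vals = metrics.loc[ranked.index, col]
            keep &= (vals >= lo) & (vals <= hi)
        excluded = ranked.index[~keep].tolist()
        eligible = ranked[keep]
    if eligible.empty:
        raise ValueError("no assembly satisfies the constraints")
    order = eligible.sort_values("avg_rank", kind="stable")
    winner = order.index[0]
    report = {
        "winner": winner,
        "avg_rank": float(order["avg_rank"].iloc[0]),
        "runner_up": order.index[1] if len(order) > 1 else None,
        "runner_up_margin": (
            float(order["avg_rank"].iloc[1] - order["avg_rank"].iloc[0])
            if len(order) > 1
            else None
        ),
        "excluded_by_constraints": excluded,
    }
    return winner, report
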