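"""Map-based anchoring of contigs into linkage-group pseudomolecules.

A contig is assigned to the linkage group holding a plurality of its marker
hits, provided that group contributes at least two markers (the >= 2-marker
rule); contigs with two or more qualifying groups are flagged as problem
contigs but still assigned to the plurality group, with the conflict
recorded. Within each linkage group contigs are ordered by the median map
position of their hits and oriented by the sign of the Spearman rank
correlation between contig position and map position — ambiguous when all
map positions tie. Anchored sequences join contigs with fixed 10 kbp 'N'
gaps and are described by an AGP v2.1 file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ContigRecord, ContigSet

DEFAULT_JOIN_GAP = 10_000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Placement:
    contig: str
    orientation: str  # '+', '-', or 'ambiguous'
    median_position: float


@dataclass
class ChromosomeLayout:
    linkage_group: str
    placements: list[Placement] = field(default_factory=list)


def assign_contigs(
    hits: pd.DataFrame, min_markers: int = 2
) -> tuple[dict[str, str], list[str], list[tuple[str, list[str]]]]:
    """Assign each contig to a linkage group by plurality of hits.

    Returns ``(assignments, unanchored, problem)``. A contig needs at least
    ``min_markers`` hits on its plurality group to anchor; a tie between
    top groups leaves it unanchored. Contigs with >= ``min_markers`` hits
    on two or more groups are recorded as problem contigs (with the list of
    conflicting groups) but still assigned to the plurality group.
    """
    assignments: dict[str, str] = {}
    unanchored: list[str] = []
    problem: list[tuple[str, list[str]]] = []
    if hits is None or len(hits) == 0:
        return assignments, unanchored, problem
    for contig, sub in hits.groupby("contig", sort=True):
        counts = sub.groupby("linkage_group").size().sort_values(ascending=False)
        eligible = counts[counts >= min_markers]
        if eligible.empty:
            unanchored.append(contig)
            continue
        top = counts.iloc[0]
        tied = counts[counts == top]
        if len(tied) > 1:
            unanchored.append(contig)
            if len(eligible) >= 2:
                problem.append((contig, sorted(eligible.index)))
            continue
        assignments[contig] = counts.index[0]
        if len(eligible) >= 2:
            problem.append((contig, sorted(eligible.index)))
    return assignments, unanchored, problem


def _orientation(sub: pd.DataFrame) -> str:
    if len(sub) < 2 or sub["map_position"].nunique() < 2:
        return "ambiguous"
    rho = stats.spearmanr(
        sub["contig_pos"].to_numpy(), sub["map_position"].to_numpy()
    ).statistic
    if np.isnan(rho) or rho == 0:
        return "ambiguous"
    return "+" if rho > 0 else "-"


def order_orient(
    assignments: dict[str, str], hits: pd.DataFrame
) -> list[ChromosomeLayout]:
    """Order contigs within each linkage group by median map position and
    orient them by rank correlation; deterministic (contig id on ties)."""
    layouts: dict[str, list[Placement]] = {}
    for contig, lg in assignments.items():
        sub = hits[(hits["contig"] == contig) & (hits["linkage_group"] == lg)]
        median = float(sub["map_position"].median())
        layouts.setdefault(lg, []).append(
            Placement(contig, _orientation(sub), median)
        )
    out = []
    for lg in sorted(layouts):
        placements = sorted(
            layouts[lg], key=lambda p: (p.median_position, p.contig)
        )
        out.append(ChromosomeLayout(lg, placements))
    return out


def build_chromosomes(
    layouts: Sequence[ChromosomeLayout],
    contigs: ContigSet,
    gap: int = DEFAULT_JOIN_GAP,
) -> tuple[ContigSet, pd.DataFrame]:
    """Assemble linkage-group sequences and the matching AGP v2.1 table.

    Contigs are joined in layout order with ``gap`` 'N' bases between
    placements ('-' placements reverse-complemented; ambiguous placements
    written forward with AGP orientation '?'). Gap count per group is
    placements - 1.
    """
    agp_rows = []
    records: list[ContigRecord] = []
    for layout in layouts:
        chunks: list[str] = []
        pos = 0
        part = 0
        for i, pl in enumerate(layout.placements):
            seq = contigs.sequence_of(pl.contig)
            if pl.orientation == "-":
                seq = _revcomp(seq)
            part += 1
            agp_rows.append(
                (
                    layout.linkage_group,
                    pos + 1,
                    pos + len(seq),
                    part,
                    "W",
                    pl.contig,
                    1,
                    len(seq),
                    {"+": "+", "-": "-", "ambiguous": "?"}[pl.orientation],
                )
            )
            chunks.append(seq)
            pos += len(seq)
            if i < len(layout.placements) - 1:
                part += 1
                agp_rows.append(
                    (
                        layout.linkage_group,
                        pos + 1,
                        pos + gap,
                        part,
                        "N",
                        gap,
                        "map",
                        "yes",
                        "map",
                    )
                )
                chunks.append("N" * gap)
                pos += gap
        records.append(
            ContigRecord(layout.linkage_group, pos, "".join(chunks))
        )
    agp = pd.DataFrame(
        agp_rows,
        columns=[
            "object", "object_beg", "object_end", "part_number",
            "component_type", "component_id", "component_beg",
            "component_end", "orientation",
        ],
    )
    return ContigSet(records), agp


def count_problem_contigs(hits: pd.DataFrame, min_markers: int = 2) -> int:
    """Number of contigs whose markers map to two or more linkage groups
    with >= ``min_markers`` hits each — a per-assembly misassembly metric."""
    _, _, problem = assign_contigs(hits, min_markers=min_markers)
    return len(problem)


def write_agp(agp: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in agp.itertuples(index=False):
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_agp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] == "N":
                rows.append(
                    (f[0], int(f[1]), int(f[2]), int(f[3]), "N",
                     int(f[5]), f[6], f[7], f[8])
                )
            else:
                rows.append(
                    (f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                     f[5], int(f[6]), int(f[7]), f[8])
                )
    return pd.DataFrame(
        rows,
        columns=[
            "object", "object_beg", "object_end", "part_number",
            "component_type", "component_id", "component_beg",
            "component_end", "orientation",
        ],
    )


def reconstruct_from_agp(agp: pd.DataFrame, contigs: ContigSet) -> ContigSet:
    """Rebuild anchored sequences from an AGP table plus component contigs
    (the inverse of :func:`build_chromosomes`)."""
    records = []
    for obj, sub in agp.groupby("object", sort=False):
        chunks = []
        for row in sub.sort_values("part_number").itertuples(index=False):
            if row.component_type == "N":
                chunks.append("N" * int(row.component_id))
            else:
                seq = contigs.sequence_of(row.component_id)[
                    int(row.component_beg) - 1 : int(row.component_end)
                ]
                if row.orientation == "-":
                    seq = _revcomp(seq)
                chunks.append(seq)
        seq = "".join(chunks)
        records.append(ContigRecord(obj, len(seq), seq))
    return ContigSet(records)


def anchoring_summary(layouts: Sequence[ChromosomeLayout], gap: int = DEFAULT_JOIN_GAP):
    """Gap bookkeeping: (n_placements, n_gaps, gap_bp)."""
    n_placements = sum(len(l.placements) for l in layouts)
    n_gaps = sum(max(len(l.placements) - 1, 0) for l in layouts)
    return n_placements, n_gaps, n_gaps * gap
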