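"""Repeat-annotation parsing, family summaries, breakpoint enrichment, and
divergence landscapes.

Input is RepeatMasker ``.out``-style annotation (1-based inclusive on disk,
converted to 0-based half-open in memory). Family statistics count each
record fully, matching how masker outputs are conventionally totalled;
region "percent repetitive" deduplicates overlapping records by union
first. Divergence values are read from the annotation (the per-copy
substitution level column, or a supplied override) — they are never
computed here.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import ContigSet, GenomicInterval, merge_intervals

_OUT_HEADER = """\
   SW   perc perc perc  query     position in query     matching  repeat        position in repeat
score   div. del. ins.  sequence  begin end   (left)    repeat    class/family  begin end  (left)  ID

"""


@dataclass(frozen=True)
class RepeatRecord:
    interval: GenomicInterval
    order: str
    family: str
    divergence_pct: float | None = None

    def __post_init__(self) -> None:
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise ValueError("divergence_pct must be >= 0")

    @property
    def length(self) -> int:
        return self.interval.length


def read_repeatmasker_out(path: str | Path) -> list[RepeatRecord]:
    """Parse RepeatMasker ``.out`` (whitespace-delimited, 3-line header)."""
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[3:]:
        fields = line.split()
        if not fields:
            continue
        div = float(fields[1])
        contig = fields[4]
        start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
        end = int(fields[6])
        class_family = fields[10]
        order, _, family = class_family.partition("/")
        records.append(
            RepeatRecord(
                GenomicInterval(contig, start, end), order, family or order, div
            )
        )
    return records


def write_repeatmasker_out(records: Sequence[RepeatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, r in enumerate(records, start=1):
            div = r.divergence_pct if r.divergence_pct is not None else 0.0
            fh.write(
                f"  500 {div:5.1f}  0.0  0.0  {r.interval.contig} "
                f"{r.interval.start + 1} {r.interval.end} (0) + "
                f"{r.family} {r.order}/{r.family} 1 {r.length} (0) {i}\n"
            )


def family_summary(
    records: Sequence[RepeatRecord], genome_bp: int
) -> pd.DataFrame:
    """Per-(order, family) count, total bp, percent of genome and mean length."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    acc: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for r in records:
        acc[(r.order, r.family)][0] += 1
        acc[(r.order, r.family)][1] += r.length
    rows = [
        {
            "order": order,
            "family": family,
            "count": count,
            "total_bp": bp,
            "pct_of_genome": 100.0 * bp / genome_bp,
            "mean_length": bp / count,
        }
        for (order, family), (count, bp) in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["order", "family", "count", "total_bp", "pct_of_genome", "mean_length"],
    )


def breakpoint_regions(
    breakpoints: Sequence[tuple[str, int]],
    contig_lengths: dict[str, int],
    flank: int = 75_000,
) -> list[GenomicInterval]:
    """Union of ±``flank`` windows around breakpoints, clipped to contigs."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    ivs = []
    for contig, pos in breakpoints:
        length = contig_lengths[contig]
        ivs.append(
            GenomicInterval(contig, max(0, pos - flank), min(length, pos + flank))
        )
    return merge_intervals(ivs, 0)


def _clip_records(
    records: Sequence[RepeatRecord], regions: Sequence[GenomicInterval], clip: bool
) -> list[RepeatRecord]:
    by_contig: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in regions:
        by_contig[iv.contig].append(iv)
    out = []
    for r in records:
        for iv in by_contig.get(r.interval.contig, ()):
            if r.interval.overlaps(iv):
                if clip:
                    out.append(
                        RepeatRecord(
                            GenomicInterval(
                                r.interval.contig,
                                max(r.interval.start, iv.start),
                                min(r.interval.end, iv.end),
                            ),
                            r.order,
                            r.family,
                            r.divergence_pct,
                        )
                    )
                else:
                    out.append(r)
                break
    return out


def region_enrichment(
    records: Sequence[RepeatRecord],
    breakpoints: Sequence[tuple[str, int]],
    contig_lengths: dict[str, int],
    genome_bp: int,
    flank: int = 75_000,
    clip: bool = True,
) -> pd.DataFrame:
    """Per-family repeat statistics inside breakpoint regions vs genome-wide.

    ``ratio_pct`` is 100 x region-percent / genome-percent (100 means no
    enrichment) and ``delta_mean`` is the region mean length minus the
    genome mean length. With ``clip=True`` records are truncated at region
    boundaries before computing region statistics; ``clip=False`` counts
    whole records that touch a region.
    """
    regions = breakpoint_regions(breakpoints, contig_lengths, flank)
    region_bp = sum(iv.length for iv in regions)
    genome = family_summary(records, genome_bp).set_index(["order", "family"])
    if not regions:
        out = genome.reset_index()
        for col in ["region_count", "region_bp", "region_pct", "region_mean",
                    "ratio_pct", "delta_mean"]:
            out[col] = np.nan
        return out.rename(
            columns={
                "count": "genome_count",
                "total_bp": "genome_bp",
                "pct_of_genome": "genome_pct",
                "mean_length": "genome_mean",
            }
        )
    clipped = _clip_records(records, regions, clip)
    region = family_summary(clipped, region_bp).set_index(["order", "family"]) if clipped else None
    rows = []
    for key, g in genome.iterrows():
        row = {
            "order": key[0],
            "family": key[1],
            "genome_count": int(g["count"]),
            "genome_bp": int(g["total_bp"]),
            "genome_pct": g["pct_of_genome"],
            "genome_mean": g["mean_length"],
        }
        if region is not None and key in region.index:
            r = region.loc[key]
            row.update(
                region_count=int(r["count"]),
                region_bp=int(r["total_bp"]),
                region_pct=r["pct_of_genome"],
                region_mean=r["mean_length"],
                ratio_pct=enrichment_ratio(g["pct_of_genome"], r["pct_of_genome"]),
                delta_mean=r["mean_length"] - g["mean_length"],
            )
        else:
            row.update(
                region_count=0, region_bp=0, region_pct=0.0,
                region_mean=np.nan, ratio_pct=0.0, delta_mean=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def enrichment_ratio(genome_pct: float, region_pct: float) -> float:
    """100 x region density / genome density (the 'ratio of genome to
    breakpoint regions' comparison, in percent)."""
    if genome_pct == 0:
        return float("nan")
    return 100.0 * region_pct / genome_pct


def divergence_landscape(
    records: Sequence[RepeatRecord],
    genome_bp: int,
    bin_width_pct: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Percent-of-genome per (order, family) x divergence bin.

    Each record's bp falls in the bin of its divergence value; records
    without a divergence value are excluded and their count returned.
    """
    if bin_width_pct <= 0:
        raise ValueError("bin_width_pct must be > 0")
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    acc: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    n_excluded = 0
    max_bin = 0
    for r in records:
        if r.divergence_pct is None:
            n_excluded += 1
            continue
        b = int(r.divergence_pct // bin_width_pct)
        acc[(r.order, r.family)][b] += r.length
        max_bin = max(max_bin, b)
    index = sorted(acc)
    bins = list(range(max_bin + 1))
    data = np.zeros((len(index), len(bins)))
    for i, key in enumerate(index):
        for b, bp in acc[key].items():
            data[i, b] = 100.0 * bp / genome_bp
    df = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(index, names=["order", "family"]),
        columns=[b * bin_width_pct for b in bins],
    )
    return df, n_excluded


def pct_repetitive(
    records: Sequence[RepeatRecord], regions: Sequence[GenomicInterval]
) -> float:
    """Percent of region bp covered by the union of repeat records."""
    region_union = merge_intervals(list(regions), 0)
    total = sum(iv.length for iv in region_union)
    if total == 0:
        return 0.0
    repeat_union = merge_intervals([r.interval for r in records], 0)
    covered = 0
    for iv in region_union:
        for r in repeat_union:
            covered += iv.overlap_len(r)
    return 100.0 * covered / total
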