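"""Coordinate conventions, interval arithmetic, and assembly summary metrics.

All internal coordinates are 0-based, half-open ``[start, end)``. One-based
inclusive coordinates appear only at file-format boundaries (VCF, sync, AGP,
RepeatMasker ``.out``), where the reader/writer converts exactly once.

The interval operations mirror the semantics of ``bedtools merge -d`` and
``bedtools intersect -f``: merging joins intervals whose gap is at most
``max_gap``, and fraction-intersection keeps an interval when at least
``min_frac`` of its length is covered by the union of the other set.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span ``[start, end)`` on a named contig (0-based, half-open)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ContigRecord:
    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


class ContigSet:
    """Ordered collection of contigs with unique ids and optional sequence."""

    def __init__(self, records: Iterable[ContigRecord]):
        self._records: dict[str, ContigRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate contig id {rec.id!r}")
            self._records[rec.id] = rec

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "ContigSet":
        return cls(ContigRecord(name, len(s), s) for name, s in seqs.items())

    @classmethod
    def from_lengths(cls, lengths: dict[str, int]) -> "ContigSet":
        return cls(ContigRecord(name, n) for name, n in lengths.items())

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ContigRecord]:
        return iter(self._records.values())

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._records

    def __getitem__(self, contig_id: str) -> ContigRecord:
        return self._records[contig_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def length_of(self, contig_id: str) -> int:
        return self._records[contig_id].length

    def sequence_of(self, contig_id: str) -> str:
        seq = self._records[contig_id].sequence
        if seq is None:
            raise ValueError(f"contig {contig_id!r} carries no sequence")
        return seq

    @property
    def lengths(self) -> dict[str, int]:
        return {rec.id: rec.length for rec in self}

    @property
    def total_bp(self) -> int:
        return sum(rec.length for rec in self)

    @property
    def has_sequences(self) -> bool:
        return all(rec.sequence is not None for rec in self)


@dataclass(frozen=True)
class AssemblyMetrics:
    """Standard contiguity summary (N50/NG50, gap content, size stats)."""

    total_bp: int
    non_gap_bp: int
    gap_bp: int
    n_contigs: int
    longest: int
    mean_len: float
    n50: int
    ng50: int
    pct_n: float


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``max_gap`` (``bedtools merge -d``).

    Returns per-contig sorted, disjoint intervals whose union covers the
    union of the inputs. ``max_gap=0`` merges overlapping and abutting
    intervals.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    by_contig: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_contig[iv.contig].append(iv)
    out: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(contig, cur_start, cur_end))
    return out


def intersect_fraction(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_frac: float,
) -> list[GenomicInterval]:
    """Keep intervals of ``a`` covered >= ``min_frac`` of their length by
    the union of ``b`` (``bedtools intersect -f``)."""
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    union_b = merge_intervals(list(b), 0) if b else []
    by_contig: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in union_b:
        by_contig[iv.contig].append(iv)
    kept = []
    for iv in a:
        covered = sum(iv.overlap_len(u) for u in by_contig.get(iv.contig, ()))
        # covered and length are integers: compare exactly at the boundary
        if covered * 1.0 >= min_frac * iv.length - 1e-9:
            kept.append(iv)
    return kept


def subtract_intervals(
    region: GenomicInterval, blockers: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Closed integer position ranges of ``region`` not strictly inside any
    blocker. A position ``p`` is blocked when ``s < p < e`` for a blocker
    ``[s, e)`` — boundaries of a blocker remain legal cut positions."""
    # each record blocks only its own open interior (b.start, b.end); the
    # boundary position shared by two abutting records remains legal
    blocked = sorted(
        (b.start + 1, b.end - 1)
        for b in blockers
        if b.contig == region.contig and b.overlaps(region) and b.length >= 2
    )
    merged_blocked: list[list[int]] = []
    for lo, hi in blocked:
        if merged_blocked and lo <= merged_blocked[-1][1] + 1:
            merged_blocked[-1][1] = max(merged_blocked[-1][1], hi)
        else:
            merged_blocked.append([lo, hi])
    ranges: list[tuple[int, int]] = []
    cursor = region.start
    for lo, hi in merged_blocked:
        if lo > cursor:
            ranges.append((cursor, min(lo - 1, region.end)))
        cursor = max(cursor, hi + 1)
        if cursor > region.end:
            break
    if cursor <= region.end:
        ranges.append((cursor, region.end))
    return ranges


def _nx(sorted_desc: Sequence[int], half: float) -> int:
    cum = 0
    for length in sorted_desc:
        cum += length
        if cum >= half:
            return length
    return 0


def count_gap_bp(sequence: str) -> int:
    """Gap bases are 'N'/'n' runs of any length."""
    return sequence.count("N") + sequence.count("n")


def assembly_metrics(contigs: ContigSet, genome_size_estimate: int) -> AssemblyMetrics:
    """Contiguity and gap summary of an assembly.

    N50 is the length at which cumulative descending-sorted contig lengths
    reach half the assembly size; NG50 uses half of ``genome_size_estimate``
    instead. When half the genome estimate exceeds the assembly total, NG50
    is reported as 0 with a warning (downstream ranking treats 0 as worst).
    """
    if len(contigs) == 0:
        raise ValueError("empty ContigSet")
    if genome_size_estimate <= 0:
        raise ValueError("genome_size_estimate must be > 0")
    lengths = sorted((rec.length for rec in contigs), reverse=True)
    total = sum(lengths)
    n50 = _nx(lengths, total / 2)
    if genome_size_estimate / 2 > total:
        warnings.warn(
            "half the genome size estimate exceeds the assembly total; "
            "NG50 undefined, reported as 0",
            stacklevel=2,
        )
        ng50 = 0
    else:
        ng50 = _nx(lengths, genome_size_estimate / 2)
    gap_bp = 0
    if contigs.has_sequences:
        gap_bp = sum(count_gap_bp(rec.sequence) for rec in contigs)  # type: ignore[arg-type]
    return AssemblyMetrics(
        total_bp=total,
        non_gap_bp=total - gap_bp,
        gap_bp=gap_bp,
        n_contigs=len(lengths),
        longest=lengths[0],
        mean_len=total / len(lengths),
        n50=n50,
        ng50=ng50,
        pct_n=100.0 * gap_bp / total,
    )
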