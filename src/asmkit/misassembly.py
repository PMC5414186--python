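"""Dual-evidence misassembly detection and contig breaking.

A chimeric join in a long-read assembly leaves two sequence-level
signatures: a local excess of residual variants in the raw-read alignments,
and a dip to (near) zero in the spanning physical coverage of a large-insert
mate-pair library, because no genuine fragment bridges the join. The scan
flags 10 kbp windows with more than 1 variant per kbp (QUAL > 10 only),
flags regions under 20x physical coverage (outside a 200 kbp contig-end
exclusion), merges each signal within 20 kbp, and keeps variant regions
covered at least 80% by low-coverage regions. Candidates are then
adjudicated against two independent marker maps: map-order conflicts are
accepted outright, dual-signal regions spanned by concordant markers on
both maps are rejected, and dual-signal regions with no markers at all are
accepted. Break positions are chosen near the region midpoint but never
inside a transcript alignment or a single repeat record.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    ContigRecord,
    ContigSet,
    GenomicInterval,
    intersect_fraction,
    merge_intervals,
    subtract_intervals,
)

DEFAULT_WINDOW = 10_000
DEFAULT_MIN_QUAL = 10.0
DEFAULT_DENSITY = 1.0  # variants per kbp
DEFAULT_MIN_COV = 20
DEFAULT_END_EXCLUSION = 200_000
DEFAULT_MERGE_GAP = 20_000
DEFAULT_MIN_FRAC = 0.8


@dataclass(frozen=True)
class VariantSite:
    contig: str
    pos: int
    qual: float

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError("qual must be >= 0")


@dataclass(frozen=True)
class DensityWindow:
    interval: GenomicInterval
    variant_count: int
    flagged: bool


@dataclass
class PhysicalCoverageTrack:
    """Per-contig spanning-fragment counts with an end-exclusion mask."""

    coverage: dict[str, np.ndarray]
    end_exclusion: int

    def unmasked_bounds(self, contig: str) -> tuple[int, int]:
        n = len(self.coverage[contig])
        return self.end_exclusion, n - self.end_exclusion


@dataclass
class CandidateMisassembly:
    interval: GenomicInterval
    evidence: set[str] = field(default_factory=set)
    verdict: str = "accepted"  # accepted | map_only | rejected_by_maps

    @property
    def is_accepted(self) -> bool:
        return self.verdict in ("accepted", "map_only")


@dataclass(frozen=True)
class Breakpoint:
    contig: str
    pos: int
    provenance: str = ""


class NoLegalBreakpointError(ValueError):
    def __init__(self, region: GenomicInterval, blockers: list[GenomicInterval]):
        self.region = region
        self.blockers = blockers
        super().__init__(
            f"no legal break position in {region.contig}:{region.start}-{region.end}; "
            f"blocked by {len(blockers)} annotation interval(s): "
            + ", ".join(f"{b.start}-{b.end}" for b in blockers[:5])
        )


def _as_variant_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    return pd.DataFrame(
        [(s.contig, s.pos, s.qual) for s in sites],
        columns=["contig", "pos", "qual"],
    )


def variant_density_windows(
    sites,
    contigs: ContigSet,
    window: int = DEFAULT_WINDOW,
    min_qual: float = DEFAULT_MIN_QUAL,
    density_threshold: float = DEFAULT_DENSITY,
) -> list[DensityWindow]:
    """Tile each contig with fixed windows and flag high variant density.

    Only sites with QUAL strictly greater than ``min_qual`` count. A window
    is flagged when its count strictly exceeds ``density_threshold`` per
    kbp scaled to the window's true width (the last window of a contig may
    be partial), i.e. > 10 variants per full 10 kbp window at defaults.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    df = _as_variant_frame(sites)
    out: list[DensityWindow] = []
    for contig in contigs.ids:
        length = contigs.length_of(contig)
        sub = df[df["contig"] == contig]
        bad = sub[sub["pos"] >= length]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"variant at {row['contig']}:{int(row['pos'])} beyond contig "
                f"length {length}"
            )
        qualifying = sub.loc[sub["qual"] > min_qual, "pos"].to_numpy()
        n_windows = (length + window - 1) // window
        counts = np.bincount(qualifying // window, minlength=n_windows)
        for i in range(n_windows):
            start = i * window
            end = min(start + window, length)
            width = end - start
            threshold = density_threshold * width / 1000
            count = int(counts[i])
            out.append(
                DensityWindow(
                    GenomicInterval(contig, start, end), count, count > threshold
                )
            )
    return out


def flagged_intervals(windows: Sequence[DensityWindow]) -> list[GenomicInterval]:
    return [w.interval for w in windows if w.flagged]


def physical_coverage(
    pairs: pd.DataFrame,
    contigs: ContigSet,
    end_exclusion: int = DEFAULT_END_EXCLUSION,
    insert_range: tuple[int, int] | None = None,
    proper_only: bool = True,
) -> PhysicalCoverageTrack:
    """Spanning (outer-span) coverage of concordant pairs, per contig.

    Coverage at base ``b`` counts concordant pairs whose outer span
    ``[min_start, max_end)`` contains ``b``. A pair is concordant when both
    ends map to the same known contig, strands are convergent (the leftmost
    read on '+'), and — when ``insert_range`` is given — the outer span is
    inside it. Discordant and inter-contig pairs contribute nowhere.
    """
    known = set(contigs.ids)
    for col in ("contig1", "contig2"):
        present = set(pairs[col].dropna().unique())
        unknown = present - known
        if unknown:
            raise ValueError(f"pair contigs absent from ContigSet: {sorted(unknown)[:5]}")
    c1 = pairs["contig1"].to_numpy()
    c2 = pairs["contig2"].to_numpy()
    s1 = pairs["start1"].to_numpy(dtype=np.int64)
    s2 = pairs["start2"].to_numpy(dtype=np.int64)
    e1 = pairs["end1"].to_numpy(dtype=np.int64)
    e2 = pairs["end2"].to_numpy(dtype=np.int64)
    st1 = pairs["strand1"].to_numpy()
    st2 = pairs["strand2"].to_numpy()
    same = (c1 == c2) & (c1 != None)  # noqa: E711
    outer_start = np.minimum(s1, s2)
    outer_end = np.maximum(e1, e2)
    if proper_only:
        left_strand = np.where(s1 <= s2, st1, st2)
        right_strand = np.where(s1 <= s2, st2, st1)
        ok = same & (left_strand == "+") & (right_strand == "-")
        if insert_range is not None:
            span = outer_end - outer_start
            ok &= (span >= insert_range[0]) & (span <= insert_range[1])
    else:
        ok = same
    coverage = {
        contig: np.zeros(contigs.length_of(contig) + 1, dtype=np.int32)
        for contig in contigs.ids
    }
    for contig, os_, oe in zip(c1[ok], outer_start[ok], outer_end[ok]):
        track = coverage[contig]
        track[os_] += 1
        track[min(oe, len(track) - 1)] -= 1
    return PhysicalCoverageTrack(
        coverage={c: np.cumsum(v[:-1]).astype(np.int32) for c, v in coverage.items()},
        end_exclusion=end_exclusion,
    )


def low_coverage_regions(
    track: PhysicalCoverageTrack, min_cov: int = DEFAULT_MIN_COV
) -> list[GenomicInterval]:
    """Maximal unmasked runs with coverage strictly below ``min_cov``."""
    out: list[GenomicInterval] = []
    for contig in sorted(track.coverage):
        cov = track.coverage[contig]
        lo, hi = track.unmasked_bounds(contig)
        if hi <= lo:
            continue
        low = cov[lo:hi] < min_cov
        if not low.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(contig, int(lo + s), int(lo + e)))
    return out


def candidate_regions(
    flagged_windows,
    low_cov: Sequence[GenomicInterval],
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[GenomicInterval]:
    """Merged high-density variant regions covered >= ``min_frac`` by merged
    low-physical-coverage regions — the dual-signal candidate set."""
    if flagged_windows and isinstance(flagged_windows[0], DensityWindow):
        flagged_windows = flagged_intervals(flagged_windows)
    if not flagged_windows:
        return []
    merged_hd = merge_intervals(list(flagged_windows), merge_gap)
    if not low_cov:
        return []
    merged_lc = merge_intervals(list(low_cov), merge_gap)
    return intersect_fraction(merged_hd, merged_lc, min_frac)


def map_conflicts(hits: pd.DataFrame) -> list[tuple[str, GenomicInterval, str]]:
    """Per-map linkage-group conflicts along each contig.

    A contig conflicts on a map when its ordered hits switch linkage group;
    each adjacent switch yields one conflict interval spanning the gap
    between the two nearest hits of different groups.
    """
    out: list[tuple[str, GenomicInterval, str]] = []
    if hits is None or len(hits) == 0:
        return out
    for (map_id, contig), sub in hits.groupby(["map", "contig"], sort=True):
        sub = sub.sort_values("contig_pos", kind="stable")
        lgs = sub["linkage_group"].to_numpy()
        pos = sub["contig_pos"].to_numpy()
        for i in range(1, len(sub)):
            if lgs[i] != lgs[i - 1]:
                s, e = int(pos[i - 1]), int(pos[i])
                if e <= s:
                    e = s + 1
                out.append((contig, GenomicInterval(contig, s, e), map_id))
    return out


def adjudicate(
    candidates: Sequence[GenomicInterval],
    conflicts_rad: Sequence[tuple[str, GenomicInterval, str]],
    conflicts_rh: Sequence[tuple[str, GenomicInterval, str]],
    hits: pd.DataFrame,
) -> list[CandidateMisassembly]:
    """Combine dual-signal candidates with map conflicts.

    Map-conflict regions are always accepted (verdict ``map_only`` until a
    sequence signal also covers them). A dual-signal region overlapping a
    conflict attaches its evidence there. A dual-signal region with no
    markers from either map inside it is accepted on signals alone; one
    spanned by (necessarily same-group) markers is rejected — the maps
    vouch for the assembly across it.
    """
    accepted: list[CandidateMisassembly] = []
    for contig, iv, map_id in list(conflicts_rad) + list(conflicts_rh):
        flag = f"{map_id}_conflict"
        merged = False
        for cand in accepted:
            if cand.interval.overlaps(iv):
                cand.evidence.add(flag)
                # both maps localize the same event: narrow to the overlap
                cand.interval = GenomicInterval(
                    contig,
                    max(cand.interval.start, iv.start),
                    min(cand.interval.end, iv.end),
                )
                merged = True
                break
        if not merged:
            accepted.append(CandidateMisassembly(iv, {flag}, "map_only"))
    out = list(accepted)
    have_hits = hits is not None and len(hits) > 0
    for region in candidates:
        attached = False
        for cand in accepted:
            if cand.interval.overlaps(region):
                cand.evidence.update({"hd_variants", "low_physcov"})
                cand.verdict = "accepted"
                attached = True
                break
        if attached:
            continue
        if have_hits:
            in_span = hits[
                (hits["contig"] == region.contig)
                & (hits["contig_pos"] >= region.start)
                & (hits["contig_pos"] < region.end)
            ]
            n_markers = len(in_span)
        else:
            n_markers = 0
        if n_markers == 0:
            out.append(
                CandidateMisassembly(region, {"hd_variants", "low_physcov"}, "accepted")
            )
        else:
            out.append(
                CandidateMisassembly(
                    region, {"hd_variants", "low_physcov"}, "rejected_by_maps"
                )
            )
    out.sort(key=lambda c: (c.interval.contig, c.interval.start))
    return out


def choose_breakpoint(
    region: GenomicInterval,
    transcript_alignments: Sequence[GenomicInterval] = (),
    repeats: Sequence[GenomicInterval] = (),
    contig_length: int | None = None,
    provenance: str = "",
) -> Breakpoint:
    """Break position nearest the region midpoint that does not fall inside
    a transcript alignment or a single repeat record (leftmost on tie)."""
    blockers = [
        b
        for b in list(transcript_alignments) + list(repeats)
        if b.contig == region.contig and b.overlaps(region)
    ]
    legal = subtract_intervals(region, blockers)
    if contig_length is not None:
        legal = [
            (max(lo, 1), min(hi, contig_length - 1))
            for lo, hi in legal
            if min(hi, contig_length - 1) >= max(lo, 1)
        ]
    if not legal:
        raise NoLegalBreakpointError(region, blockers)
    mid = (region.start + region.end) // 2
    best_pos = None
    best_dist = None
    for lo, hi in legal:
        cand = min(max(mid, lo), hi)
        dist = abs(cand - mid)
        if best_dist is None or dist < best_dist or (dist == best_dist and cand < best_pos):
            best_pos, best_dist = cand, dist
    return Breakpoint(region.contig, int(best_pos), provenance)


def break_contigs(
    contigs: ContigSet, breakpoints: Sequence[Breakpoint]
) -> ContigSet:
    """Split contigs at breakpoints; ``k`` breakpoints add exactly ``k``
    contigs and total sequence is conserved. Pieces of contig ``c`` are
    named ``c.1``, ``c.2``, ... left to right."""
    by_contig: dict[str, list[int]] = defaultdict(list)
    for bp in breakpoints:
        if bp.contig not in contigs:
            raise ValueError(f"breakpoint on unknown contig {bp.contig!r}")
        length = contigs.length_of(bp.contig)
        if not (0 < bp.pos < length):
            raise ValueError(
                f"breakpoint {bp.contig}:{bp.pos} not strictly inside contig "
                f"(length {length})"
            )
        if bp.pos in by_contig[bp.contig]:
            raise ValueError(f"duplicate breakpoint {bp.contig}:{bp.pos}")
        by_contig[bp.contig].append(bp.pos)
    records: list[ContigRecord] = []
    for rec in contigs:
        cuts = sorted(by_contig.get(rec.id, []))
        if not cuts:
            records.append(rec)
            continue
        bounds = [0] + cuts + [rec.length]
        for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
            seq = rec.sequence[lo:hi] if rec.sequence is not None else None
            records.append(ContigRecord(f"{rec.id}.{k}", hi - lo, seq))
    return ContigSet(records)


def remap_positions(
    table: pd.DataFrame, breakpoints: Sequence[tuple[str, int]]
) -> pd.DataFrame:
    """Recoordinate a (contig, pos) table after :func:`break_contigs`,
    using the same ``<id>.<k>`` piece naming."""
    by_contig: dict[str, list[int]] = defaultdict(list)
    for contig, pos in breakpoints:
        by_contig[contig].append(pos)
    contigs_out = []
    pos_out = []
    for contig, pos in zip(table["contig"], table["pos"]):
        cuts = sorted(by_contig.get(contig, []))
        if not cuts:
            contigs_out.append(contig)
            pos_out.append(pos)
            continue
        k = int(np.searchsorted(cuts, pos, side="right"))
        offset = cuts[k - 1] if k else 0
        contigs_out.append(f"{contig}.{k + 1}")
        pos_out.append(pos - offset)
    out = table.copy()
    out["contig"] = contigs_out
    out["pos"] = pos_out
    return out


def scan_misassemblies(
    variants: pd.DataFrame,
    pairs: pd.DataFrame,
    hits: pd.DataFrame,
    contigs: ContigSet,
    window: int = DEFAULT_WINDOW,
    min_qual: float = DEFAULT_MIN_QUAL,
    density_threshold: float = DEFAULT_DENSITY,
    min_cov: int = DEFAULT_MIN_COV,
    end_exclusion: int = DEFAULT_END_EXCLUSION,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_frac: float = DEFAULT_MIN_FRAC,
    insert_range: tuple[int, int] | None = None,
    map_ids: tuple[str, str] = ("rad", "rh"),
) -> list[CandidateMisassembly]:
    """End-to-end scan: density windows x physical coverage, merged and
    intersected, then adjudicated against the two maps in ``hits``."""
    windows = variant_density_windows(
        variants, contigs, window=window, min_qual=min_qual,
        density_threshold=density_threshold,
    )
    track = physical_coverage(
        pairs, contigs, end_exclusion=end_exclusion, insert_range=insert_range
    )
    low = low_coverage_regions(track, min_cov=min_cov)
    dual = candidate_regions(windows, low, merge_gap=merge_gap, min_frac=min_frac)
    conflicts = map_conflicts(hits)
    conflicts_a = [c for c in conflicts if c[2] == map_ids[0]]
    conflicts_b = [c for c in conflicts if c[2] == map_ids[1]]
    return adjudicate(dual, conflicts_a, conflicts_b, hits)
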