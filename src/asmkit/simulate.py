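"""Synthetic genomes with known truth for every stage of the pipeline.

The generators emulate the evidence a long-read assembly project produces
around chimeric-join misassemblies and sex-determination regions:

* chromosomes of random sequence, optionally carrying interspersed repeat
  copies and terminal satellite arrays;
* chimeric contigs that concatenate segments of *different* chromosomes,
  with the junction positions recorded as truth;
* variant calls with a Poisson background and an elevated rate in a halo
  around each junction (the residual-variant signature of a chimeric join
  in raw long-read alignments);
* large-insert mate-pair placements sampled from the *true* chromosomes and
  lifted onto the chimeric contigs, so concordant spanning (physical)
  coverage dips to zero at each junction;
* map markers with monotone map positions per chromosome, lifted onto the
  contigs (a chimeric contig therefore shows hits from two linkage groups);
* pooled allele counts for two sex pools, with sex-patterned structure
  (homogametic pool fixed, heterogametic pool near 0.5) confined to a
  declared sex-determination region;
* BAC-end pairs with truth classes derived from the same lift-over.

Everything is deterministic under the seed passed to each generator.
No read-level simulation is performed: outputs are placement/count tables,
not FASTQ.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import ContigRecord, ContigSet, GenomicInterval
from .repeats import RepeatRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ScenarioConfig:
    """Study conditions for the default synthetic scenario.

    The defaults describe a 10 Mbp genome of five 2 Mbp chromosomes carrying
    ten inter-chromosomal joins, a 40 kbp mate-pair library at ~40x physical
    coverage, markers every ~40 kbp, and two sex pools at 40x read depth
    with sites every 200 bp.
    """

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"chr{i:02d}", 2_000_000) for i in range(1, 6)]
    )
    n_joins: int = 10
    min_segment: int = 500_000
    marker_spacing: int = 40_000
    background_variant_rate: float = 0.05  # per kbp
    junction_variant_rate: float = 3.0  # per kbp
    junction_halo: int = 20_000
    low_qual_fraction: float = 0.1
    insert_mean: int = 40_000
    insert_sd: int = 4_000
    pair_count: int = 10_000
    pool_depth_mean: float = 40.0
    site_spacing: int = 200
    repeat_fraction: float = 0.0
    satellite_bp: int = 0


@dataclass(frozen=True)
class Segment:
    """One forward-strand piece of a true chromosome placed in a contig."""

    contig: str
    contig_start: int
    chrom: str
    chrom_start: int
    chrom_end: int

    @property
    def length(self) -> int:
        return self.chrom_end - self.chrom_start

    @property
    def contig_end(self) -> int:
        return self.contig_start + self.length


class ContigMap:
    """Truth mapping between chromosome and contig coordinates."""

    def __init__(self, segments: Sequence[Segment]):
        self.segments = list(segments)
        self._by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            self._by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in self._by_chrom.values():
            segs.sort(key=lambda s: s.chrom_start)
        self._by_contig: dict[str, list[Segment]] = {}
        for seg in self.segments:
            self._by_contig.setdefault(seg.contig, []).append(seg)
        for segs in self._by_contig.values():
            segs.sort(key=lambda s: s.contig_start)

    @classmethod
    def identity(cls, contigs: ContigSet) -> "ContigMap":
        return cls(
            Segment(rec.id, 0, rec.id, 0, rec.length) for rec in contigs
        )

    def lift(self, chrom: str, pos: int) -> tuple[str, int] | None:
        segs = self._by_chrom.get(chrom)
        if not segs:
            return None
        starts = [s.chrom_start for s in segs]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        seg = segs[i]
        if pos >= seg.chrom_end:
            return None
        return seg.contig, seg.contig_start + (pos - seg.chrom_start)

    def contig_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for seg in self.segments:
            out[seg.contig] = max(out.get(seg.contig, 0), seg.contig_end)
        return out

    def junctions(self) -> list[tuple[str, int]]:
        """Internal segment boundaries where the source chromosome changes."""
        out = []
        for contig, segs in sorted(self._by_contig.items()):
            for a, b in zip(segs, segs[1:]):
                if a.chrom != b.chrom:
                    out.append((contig, a.contig_end))
        return out

    def split_at(self, breakpoints: Sequence[tuple[str, int]]) -> "ContigMap":
        """Truth map after splitting contigs, using the same ``<id>.<k>``
        naming as :func:`asmkit.misassembly.break_contigs`."""
        by_contig: dict[str, list[int]] = {}
        for contig, pos in breakpoints:
            by_contig.setdefault(contig, []).append(pos)
        new_segments: list[Segment] = []
        for contig, segs in self._by_contig.items():
            cuts = sorted(by_contig.get(contig, []))
            if not cuts:
                new_segments.extend(segs)
                continue
            bounds = [0] + cuts + [segs[-1].contig_end]
            for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
                name = f"{contig}.{k}"
                for seg in segs:
                    s = max(seg.contig_start, lo)
                    e = min(seg.contig_end, hi)
                    if s >= e:
                        continue
                    new_segments.append(
                        Segment(
                            name,
                            s - lo,
                            seg.chrom,
                            seg.chrom_start + (s - seg.contig_start),
                            seg.chrom_start + (e - seg.contig_start),
                        )
                    )
        return ContigMap(new_segments)


@dataclass
class TruthTable:
    """Ground truth for a synthetic scenario; serializes losslessly."""

    junctions: list[tuple[str, int]] = field(default_factory=list)
    contig_map: ContigMap | None = None
    sd_region: tuple[str, int, int] | None = None
    repeats: list[RepeatRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "junctions": [list(j) for j in self.junctions],
            "segments": None
            if self.contig_map is None
            else [
                [s.contig, s.contig_start, s.chrom, s.chrom_start, s.chrom_end]
                for s in self.contig_map.segments
            ],
            "sd_region": list(self.sd_region) if self.sd_region else None,
            "repeats": [
                [
                    r.interval.contig,
                    r.interval.start,
                    r.interval.end,
                    r.order,
                    r.family,
                    r.divergence_pct,
                ]
                for r in self.repeats
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTable":
        return cls(
            junctions=[(c, int(p)) for c, p in d["junctions"]],
            contig_map=None
            if d["segments"] is None
            else ContigMap(Segment(c, cs, ch, s, e) for c, cs, ch, s, e in d["segments"]),
            sd_region=None if d["sd_region"] is None else tuple(d["sd_region"]),
            repeats=[
                RepeatRecord(GenomicInterval(c, s, e), order, fam, div)
                for c, s, e, order, fam, div in d["repeats"]
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    out[hits] = _BASES[rng.integers(0, 4, len(hits))]
    return out


def simulate_genome(
    config: ScenarioConfig, seed: int
) -> tuple[ContigSet, TruthTable]:
    """Generate the true chromosomes (and optional repeat annotation).

    With ``repeat_fraction`` > 0 two interspersed families are copied in at
    random non-overlapping positions with per-copy divergence from consensus;
    ``satellite_bp`` > 0 additionally writes tandem monomer arrays at both
    chromosome ends. All repeat placements are recorded in the truth table.
    """
    if len(config.chromosomes) < 2:
        raise ValueError("need >= 2 chromosomes so chimeric joins are possible")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    repeats: list[RepeatRecord] = []
    families = []
    if config.repeat_fraction > 0:
        families = [
            ("DNA", "SimFam1", _random_sequence(rng, 300)),
            ("LTR", "SimFam2", _random_sequence(rng, 600)),
        ]
    monomer = _random_sequence(rng, 171) if config.satellite_bp > 0 else None
    for chrom, length in config.chromosomes:
        if length < 10 * config.insert_mean:
            raise ValueError(
                f"chromosome {chrom}: length {length} < 10 x insert_mean "
                f"({config.insert_mean}); coverage tracks undefined"
            )
        arr = _random_sequence(rng, length)
        if families:
            per_family_bp = config.repeat_fraction * length / len(families)
            for order, fam, consensus in families:
                unit = len(consensus)
                slot = 2 * unit
                n_copies = int(round(per_family_bp / unit))
                n_slots = length // slot - 1
                slots = rng.choice(n_slots, size=n_copies, replace=False)
                for s in np.sort(slots):
                    start = int(s) * slot
                    div = float(rng.uniform(0.0, 25.0))
                    arr[start : start + unit] = _mutate(rng, consensus, div / 100)
                    repeats.append(
                        RepeatRecord(
                            GenomicInterval(chrom, start, start + unit),
                            order,
                            fam,
                            round(div, 1),
                        )
                    )
        if monomer is not None:
            sat = np.tile(monomer, config.satellite_bp // len(monomer) + 1)[
                : config.satellite_bp
            ]
            arr[: len(sat)] = sat
            arr[length - len(sat) :] = sat
            for s, e in [(0, len(sat)), (length - len(sat), length)]:
                repeats.append(
                    RepeatRecord(
                        GenomicInterval(chrom, s, e), "Satellite", "SimSat", 0.0
                    )
                )
        seqs[chrom] = arr.tobytes().decode("ascii")
    genome = ContigSet.from_sequences(seqs)
    return genome, TruthTable(repeats=repeats, contig_map=ContigMap.identity(genome))


def _cut_positions(
    rng: np.random.Generator, length: int, n_segments: int, min_segment: int
) -> list[int]:
    if n_segments == 1:
        return []
    free = length - n_segments * min_segment
    if free < 0:
        raise ValueError(
            f"cannot cut {length} bp into {n_segments} segments of >= {min_segment} bp"
        )
    u = np.sort(rng.uniform(0, free, n_segments - 1))
    return [int(u[i] + min_segment * (i + 1)) for i in range(n_segments - 1)]


def induce_misassemblies(
    genome: ContigSet,
    n_joins: int,
    seed: int,
    min_segment: int = 500_000,
) -> tuple[ContigSet, TruthTable]:
    """Build chimeric contigs joining segments of different chromosomes.

    The chromosomes are cut into ``n_chromosomes + n_joins`` segments and
    re-chained round-robin so every within-contig neighbour pair comes from
    two different chromosomes; total bp is conserved and every junction
    coordinate is recorded. ``n_joins=0`` returns the chromosomes unchanged
    (identity map, no junctions).
    """
    if n_joins < 0:
        raise ValueError("n_joins must be >= 0")
    if n_joins == 0:
        return genome, TruthTable(contig_map=ContigMap.identity(genome))
    rng = np.random.default_rng(seed)
    chroms = genome.ids
    perm = [chroms[i] for i in rng.permutation(len(chroms))]
    n_chrom = len(perm)
    # balanced segment counts, extras to the front of the permutation
    seg_counts = {c: 1 for c in perm}
    for i in range(n_joins):
        seg_counts[perm[i % n_chrom]] += 1
    pieces: dict[str, list[tuple[int, int]]] = {}
    for chrom in perm:
        length = genome.length_of(chrom)
        cuts = _cut_positions(rng, length, seg_counts[chrom], min_segment)
        bounds = [0] + cuts + [length]
        pieces[chrom] = list(zip(bounds, bounds[1:]))
    # round-robin chain: adjacent entries always differ in chromosome
    chain: list[tuple[str, int, int]] = []
    max_rows = max(seg_counts.values())
    for row in range(max_rows):
        for chrom in perm:
            if row < seg_counts[chrom]:
                s, e = pieces[chrom][row]
                chain.append((chrom, s, e))
    # partition the chain into n_chrom contigs with balanced junction counts
    joins_per_contig = [n_joins // n_chrom] * n_chrom
    for i in range(n_joins % n_chrom):
        joins_per_contig[i] += 1
    segments: list[Segment] = []
    junctions: list[tuple[str, int]] = []
    seqs: dict[str, str] = {}
    idx = 0
    for c, k in enumerate(joins_per_contig, start=1):
        name = f"ctg{c:02d}"
        parts = chain[idx : idx + k + 1]
        idx += k + 1
        offset = 0
        chunks = []
        for chrom, s, e in parts:
            segments.append(Segment(name, offset, chrom, s, e))
            offset += e - s
            chunks.append(genome.sequence_of(chrom)[s:e])
        for seg_a, seg_b in zip(segments[-len(parts) : -1], segments[-len(parts) + 1 :]):
            assert seg_a.chrom != seg_b.chrom
            junctions.append((name, seg_a.contig_end))
        seqs[name] = "".join(chunks)
    contigs = ContigSet.from_sequences(seqs)
    assert contigs.total_bp == genome.total_bp
    return contigs, TruthTable(junctions=junctions, contig_map=ContigMap(segments))


def fragment_genome(
    genome: ContigSet, pieces_per_chrom: int, seed: int, min_segment: int = 200_000
) -> tuple[ContigSet, TruthTable]:
    """Cut each chromosome into contigs without introducing any joins
    (junction-free truth, used to exercise anchoring)."""
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    seqs: dict[str, str] = {}
    n = 0
    for chrom in genome.ids:
        length = genome.length_of(chrom)
        cuts = _cut_positions(rng, length, pieces_per_chrom, min_segment)
        bounds = [0] + cuts + [length]
        for s, e in zip(bounds, bounds[1:]):
            n += 1
            name = f"ctg{n:03d}"
            segments.append(Segment(name, 0, chrom, s, e))
            seqs[name] = genome.sequence_of(chrom)[s:e]
    return ContigSet.from_sequences(seqs), TruthTable(contig_map=ContigMap(segments))


def simulate_variant_calls(
    contigs: ContigSet, truth: TruthTable, config: ScenarioConfig, seed: int
) -> pd.DataFrame:
    """Variant sites on the (possibly chimeric) contigs.

    Background sites arrive as a Poisson process at
    ``background_variant_rate`` per kbp; within ``junction_halo`` of each
    truth junction the rate rises to ``junction_variant_rate``. A fraction
    ``low_qual_fraction`` of sites carries QUAL <= 10 and is removed by the
    default quality filter downstream.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int]] = []
    halos_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, pos in truth.junctions:
        length = contigs.length_of(contig)
        halos_by_contig.setdefault(contig, []).append(
            (max(0, pos - config.junction_halo), min(length, pos + config.junction_halo))
        )
    for contig in contigs.ids:
        length = contigs.length_of(contig)
        n_bg = rng.poisson(config.background_variant_rate * length / 1000)
        for p in rng.integers(0, length, n_bg):
            rows.append((contig, int(p)))
        extra_rate = max(config.junction_variant_rate - config.background_variant_rate, 0)
        for lo, hi in halos_by_contig.get(contig, ()):
            n_halo = rng.poisson(extra_rate * (hi - lo) / 1000)
            for p in rng.integers(lo, hi, n_halo):
                rows.append((contig, int(p)))
    df = pd.DataFrame(rows, columns=["contig", "pos"])
    n = len(df)
    low = rng.random(n) < config.low_qual_fraction
    qual = np.where(low, rng.uniform(0, 10, n), rng.uniform(10.5, 60, n))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, n)) % 4]
    df["ref"] = ref
    df["alt"] = alt
    df["qual"] = np.round(qual, 2)
    return df.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)


def _lift_reads(
    cmap: ContigMap, chrom: np.ndarray, start: np.ndarray, read_len: int
) -> tuple[list[str | None], np.ndarray]:
    contigs: list[str | None] = []
    cpos = np.empty(len(chrom), dtype=np.int64)
    for i, (ch, s) in enumerate(zip(chrom, start)):
        hit = cmap.lift(str(ch), int(s))
        if hit is None:
            contigs.append(None)
            cpos[i] = -1
        else:
            contigs.append(hit[0])
            cpos[i] = hit[1]
    return contigs, cpos


def simulate_matepair_placements(
    true_genome: ContigSet,
    contig_map: ContigMap,
    config: ScenarioConfig,
    seed: int,
    read_len: int = 100,
) -> pd.DataFrame:
    """Large-insert pair placements lifted from the true chromosomes.

    Fragments are sampled from the *true* chromosomes (length-proportional),
    then each end is lifted onto the contigs. Ends falling on opposite sides
    of a junction land on different contigs, so no concordant fragment spans
    a junction: spanning coverage dips to zero there by construction.
    """
    rng = np.random.default_rng(seed)
    ids = true_genome.ids
    lengths = np.array([true_genome.length_of(c) for c in ids], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(ids), size=config.pair_count, p=probs)
    inserts = rng.normal(config.insert_mean, config.insert_sd, config.pair_count)
    inserts = np.clip(inserts, 2 * read_len, lengths[chrom_idx] - 1).astype(np.int64)
    start = (rng.random(config.pair_count) * (lengths[chrom_idx] - inserts)).astype(
        np.int64
    )
    chroms = np.array(ids, dtype=object)[chrom_idx]
    e1 = start
    e2 = start + inserts - read_len
    c1, p1 = _lift_reads(contig_map, chroms, e1, read_len)
    c2, p2 = _lift_reads(contig_map, chroms, e2, read_len)
    clens = contig_map.contig_lengths()
    df = pd.DataFrame(
        {
            "pair_id": [f"pair{i}" for i in range(config.pair_count)],
            "contig1": c1,
            "start1": p1,
            "end1": [
                min(p + read_len, clens.get(c, p + read_len)) if c else p + read_len
                for c, p in zip(c1, p1)
            ],
            "strand1": "+",
            "contig2": c2,
            "start2": p2,
            "end2": [
                min(p + read_len, clens.get(c, p + read_len)) if c else p + read_len
                for c, p in zip(c2, p2)
            ],
            "strand2": "-",
            "true_chrom": chroms,
            "true_start": start,
            "true_end": start + inserts,
        }
    )
    return df


def simulate_markers(
    true_genome: ContigSet,
    contig_map: ContigMap,
    spacing: int,
    seed: int,
    map_id: str = "synthetic",
    position_resolution: float | None = None,
    cm_per_bp: float = 5e-5,
) -> pd.DataFrame:
    """Map markers every ~``spacing`` bp with monotone map positions.

    Returns observed hits against the contigs (columns follow
    :data:`asmkit.io.MARKER_COLUMNS`). ``position_resolution`` rounds map
    positions down to a grid, creating tied positions that make contig
    orientation ambiguous — the situation a low-resolution genetic map
    produces.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in true_genome.ids:
        length = true_genome.length_of(chrom)
        n = length // spacing
        for i in range(n):
            jitter = int(rng.integers(-spacing // 5, spacing // 5 + 1))
            pos = min(max(int((i + 0.5) * spacing) + jitter, 0), length - 1)
            map_pos = pos * cm_per_bp
            if position_resolution:
                map_pos = int(map_pos / position_resolution) * position_resolution
            hit = contig_map.lift(chrom, pos)
            if hit is None:
                continue
            contig, cpos = hit
            rows.append(
                (f"{map_id}_{chrom}_{i:04d}", map_id, chrom, map_pos, contig, cpos, "+")
            )
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "map", "linkage_group", "map_position",
            "contig", "contig_pos", "strand",
        ],
    )


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = rng.beta(a, b, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_pool_counts(
    contigs: ContigSet,
    sd_region: tuple[str, int, int] | None,
    config: ScenarioConfig,
    seed: int,
    system: str = "XY",
):
    """Pooled allele counts for two sex pools (pool 0 = female, pool 1 = male).

    Outside the sex-determination region both pools share an allele frequency
    drawn from a truncated Beta(0.5, 0.5) on (0.05, 0.95) — an arbitrary
    neutral-SFS-like background. Inside the region the homogametic pool is
    fixed for the reference allele while the heterogametic pool carries the
    alternate allele at ~Beta(50, 50) around 0.5 (the signature of a
    non-recombining XY or ZW region). Per-pool coverage is Poisson around
    ``pool_depth_mean`` and allele counts are binomial.

    Returns ``(SyncTable, truth)`` where truth is a per-site DataFrame with
    the generating frequencies and region membership.
    """
    from .poolseq import SyncTable

    if system not in ("XY", "ZW"):
        raise ValueError("system must be 'XY' or 'ZW'")
    het_pool = 1 if system == "XY" else 0  # XY: male pool heterogametic
    rng = np.random.default_rng(seed)
    all_contigs: list[str] = []
    all_pos: list[np.ndarray] = []
    for contig in contigs.ids:
        length = contigs.length_of(contig)
        pos = np.arange(config.site_spacing // 2, length, config.site_spacing)
        all_contigs.extend([contig] * len(pos))
        all_pos.append(pos)
    pos_arr = np.concatenate(all_pos)
    n = len(pos_arr)
    contig_arr = np.array(all_contigs, dtype=object)
    in_region = np.zeros(n, dtype=bool)
    if sd_region is not None:
        rc, rs, re = sd_region
        in_region = (contig_arr == rc) & (pos_arr >= rs) & (pos_arr < re)
    freq = np.empty((n, 2))
    shared = _truncated_beta(rng, 0.5, 0.5, 0.05, 0.95, n)
    freq[:, 0] = shared
    freq[:, 1] = shared
    n_reg = int(in_region.sum())
    freq[in_region, 1 - het_pool] = 0.0
    freq[in_region, het_pool] = rng.beta(50, 50, n_reg)
    depth = rng.poisson(config.pool_depth_mean, (n, 2))
    alt = rng.binomial(depth, freq)
    counts = np.zeros((n, 2, 6), dtype=np.int64)
    counts[:, :, 0] = depth - alt  # ref 'A'
    counts[:, :, 1] = alt  # alt 'T'
    table = SyncTable(
        contigs=contig_arr,
        pos=pos_arr.astype(np.int64),
        ref=np.full(n, "A", dtype=object),
        counts=counts,
    )
    truth = pd.DataFrame(
        {
            "contig": contig_arr,
            "pos": pos_arr,
            "freq_pool0": freq[:, 0],
            "freq_pool1": freq[:, 1],
            "in_region": in_region,
        }
    )
    return table, truth


def simulate_bac_ends(
    true_genome: ContigSet,
    contig_map: ContigMap,
    n: int,
    seed: int,
    span_range: tuple[int, int] = (100_000, 200_000),
    read_len: int = 500,
    p_single: float = 0.05,
    p_unaligned: float = 0.02,
    p_wrong_orient: float = 0.03,
) -> pd.DataFrame:
    """BAC-end pairs sampled at ~150 kbp spans with truth classes.

    Truth classes follow the standard end-pair taxonomy: 2 = both ends on
    one contig, convergent, sane span; 3 = orientation (here: a flipped
    end) or span anomaly; 4 = ends on different contigs; 1 = only one end
    aligns confidently; 'unaligned' = neither does.
    """
    rng = np.random.default_rng(seed)
    ids = true_genome.ids
    lengths = np.array([true_genome.length_of(c) for c in ids], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    for i in range(n):
        ci = int(rng.choice(len(ids), p=probs))
        chrom, length = ids[ci], int(lengths[ci])
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        span = min(span, length - 1)
        start = int(rng.integers(0, length - span))
        hit1 = contig_map.lift(chrom, start)
        hit2 = contig_map.lift(chrom, start + span - read_len)
        strand1, strand2 = "+", "-"
        good_e = lambda: float(10.0 ** -rng.uniform(160, 300))
        bad_e = lambda: float(10.0 ** -rng.uniform(10, 100))
        e1, e2 = good_e(), good_e()
        u = rng.random()
        if u < p_unaligned:
            e1, e2 = bad_e(), bad_e()
            truth = "unaligned"
        elif u < p_unaligned + p_single:
            if rng.random() < 0.5:
                e1 = bad_e()
            else:
                e2 = bad_e()
            truth = "1"
        elif hit1 is None or hit2 is None or hit1[0] != hit2[0]:
            truth = "4"
        elif rng.random() < p_wrong_orient:
            strand2 = "+"
            truth = "3"
        else:
            truth = "2"
        rows.append(
            (
                f"clone{i:05d}",
                hit1[0] if hit1 else None,
                hit1[1] if hit1 else -1,
                strand1,
                e1,
                hit2[0] if hit2 else None,
                hit2[1] if hit2 else -1,
                strand2,
                e2,
                truth,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone",
            "contig1", "pos1", "strand1", "evalue1",
            "contig2", "pos2", "strand2", "evalue2",
            "truth_class",
        ],
    )
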