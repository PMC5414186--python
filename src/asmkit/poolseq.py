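"""Pooled two-group comparison: allele frequencies, per-site FST,
sex-patterned variant calling, windowed tracks, and sex-determination
region boundary calling.

Counts come from a Popoolation2-style sync file: one tab-separated row per
site with chromosome, 1-based position, reference base, then one
``A:T:C:G:N:del`` column per pool. Deletions are treated as a fifth allele;
'N' counts are ignored throughout.

The per-site FST is the classical pooled-heterozygosity estimator on the
two most frequent alleles: within each pool k with read depth n_k and
major-allele frequency p_k,

    pi_k = n_k / (n_k - 1) * 2 p_k (1 - p_k)

pi_T is the same quantity on the combined counts, and
FST = (pi_T - (pi_a + pi_b) / 2) / pi_T, defined as 0 when pi_T = 0.

A sex-patterned site is fixed or nearly fixed in the homogametic pool
(minor-allele frequency <= ``fixed_tol``) with that same allele at
intermediate frequency (``inter_lo``..``inter_hi``) in the heterogametic
pool — the expected signature of a non-recombining XY or ZW region. The
three thresholds default to 0.1 / 0.3 / 0.7 and are freely configurable;
the criterion itself, not any particular threshold triple, is the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

ALLELES = ("A", "T", "C", "G", "N", "del")
_N_INDEX = 4
_REAL_ALLELES = np.array([0, 1, 2, 3, 5])  # everything but N

DEFAULT_MIN_DEPTH = 10
DEFAULT_FIXED_TOL = 0.1
DEFAULT_INTER = (0.3, 0.7)


@dataclass(frozen=True)
class SyncSite:
    contig: str
    pos: int  # 0-based
    ref: str
    counts: np.ndarray  # (n_pools, 6) in ALLELES order

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_pools, 6)")
        if self.counts.shape[0] < 2:
            raise ValueError("need >= 2 pools")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    def depth(self, pool: int) -> int:
        return int(self.counts[pool, _REAL_ALLELES].sum())


@dataclass
class SexPatternedSite:
    site: SyncSite
    allele: str | None
    homog_minor_freq: float | None
    het_freq: float | None
    passes: bool


class SyncTable:
    """Column-oriented container for sync-format sites (two or more pools)."""

    def __init__(self, contigs, pos, ref, counts):
        self.contigs = np.asarray(contigs, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_pools, 6)")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def site(self, i: int) -> SyncSite:
        return SyncSite(
            str(self.contigs[i]), int(self.pos[i]), str(self.ref[i]), self.counts[i]
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self.site(i)


def read_sync(path: str | Path) -> SyncTable:
    contigs, pos, ref, counts = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            contigs.append(fields[0])
            pos.append(int(fields[1]) - 1)  # 1-based on disk
            ref.append(fields[2])
            counts.append(
                [[int(x) for x in pool.split(":")] for pool in fields[3:]]
            )
    return SyncTable(contigs, pos, ref, counts)


def write_sync(table: SyncTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(table)):
            pools = "\t".join(
                ":".join(str(int(x)) for x in table.counts[i, k])
                for k in range(table.n_pools)
            )
            fh.write(f"{table.contigs[i]}\t{table.pos[i] + 1}\t{table.ref[i]}\t{pools}\n")


def allele_frequencies(
    site: SyncSite, min_depth: int = DEFAULT_MIN_DEPTH
) -> list[dict[str, float] | None]:
    """Per-pool frequency of each observed allele over A/T/C/G/del
    (N excluded); pools under ``min_depth`` are uncallable (None)."""
    out: list[dict[str, float] | None] = []
    for k in range(site.counts.shape[0]):
        depth = site.depth(k)
        if depth < min_depth:
            out.append(None)
            continue
        freqs = {
            ALLELES[j]: site.counts[k, j] / depth
            for j in _REAL_ALLELES
            if site.counts[k, j] > 0
        }
        out.append(freqs)
    return out


def _top_two_alleles(site: SyncSite, pools: tuple[int, ...]) -> tuple[int, int]:
    combined = site.counts[list(pools)].sum(axis=0).astype(float)
    combined[_N_INDEX] = -1
    order = np.argsort(-combined, kind="stable")
    return int(order[0]), int(order[1])


def _pi(c1: int, c2: int) -> float | None:
    n = c1 + c2
    if n < 2:
        return None
    p = c1 / n
    return (n / (n - 1)) * 2 * p * (1 - p)


def site_fst(
    site: SyncSite,
    pool_a: int = 0,
    pool_b: int = 1,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> float | None:
    """Per-site FST between two pools; None when either pool is uncallable.

    Symmetric in pool order; 0 (not None) for a monomorphic combined site;
    exactly 1 for a fixed difference.
    """
    if site.depth(pool_a) < min_depth or site.depth(pool_b) < min_depth:
        return None
    a1, a2 = _top_two_alleles(site, (pool_a, pool_b))
    ca1, ca2 = int(site.counts[pool_a, a1]), int(site.counts[pool_a, a2])
    cb1, cb2 = int(site.counts[pool_b, a1]), int(site.counts[pool_b, a2])
    pi_a = _pi(ca1, ca2)
    pi_b = _pi(cb1, cb2)
    pi_t = _pi(ca1 + cb1, ca2 + cb2)
    if pi_a is None or pi_b is None or pi_t is None:
        return None
    if pi_t == 0:
        return 0.0
    # the n/(n-1) correction can push the raw estimate slightly negative
    # for undifferentiated pools; clamp to the [0, 1] contract
    return max((pi_t - (pi_a + pi_b) / 2) / pi_t, 0.0)


def sex_patterned(
    site: SyncSite,
    homogametic_pool: int = 0,
    fixed_tol: float = DEFAULT_FIXED_TOL,
    inter_lo: float = DEFAULT_INTER[0],
    inter_hi: float = DEFAULT_INTER[1],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> SexPatternedSite:
    """Call a site sex-patterned: (nearly) fixed in the homogametic pool
    and intermediate in the heterogametic pool. Applies to SNPs and
    deletions alike (the deletion column is a fifth allele)."""
    n_pools = site.counts.shape[0]
    het_pool = 1 - homogametic_pool if n_pools == 2 else next(
        k for k in range(n_pools) if k != homogametic_pool
    )
    if site.depth(homogametic_pool) < min_depth or site.depth(het_pool) < min_depth:
        return SexPatternedSite(site, None, None, None, False)
    a1, a2 = _top_two_alleles(site, (homogametic_pool, het_pool))
    h1 = int(site.counts[homogametic_pool, a1])
    h2 = int(site.counts[homogametic_pool, a2])
    homog_depth = h1 + h2
    if homog_depth == 0:
        return SexPatternedSite(site, None, None, None, False)
    # the allele rare in the homogametic pool
    minor = a2 if h2 <= h1 else a1
    homog_minor_freq = min(h1, h2) / homog_depth
    t1 = int(site.counts[het_pool, a1])
    t2 = int(site.counts[het_pool, a2])
    het_depth = t1 + t2
    if het_depth == 0:
        return SexPatternedSite(site, ALLELES[minor], homog_minor_freq, None, False)
    het_freq = (t1 if minor == a1 else t2) / het_depth
    passes = homog_minor_freq <= fixed_tol and inter_lo <= het_freq <= inter_hi
    return SexPatternedSite(site, ALLELES[minor], homog_minor_freq, het_freq, passes)


def window_tracks(
    table: SyncTable,
    window: int = 10_000,
    homogametic_pool: int = 0,
    pools: tuple[int, int] = (0, 1),
    lengths: dict[str, int] | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    fixed_tol: float = DEFAULT_FIXED_TOL,
    inter_lo: float = DEFAULT_INTER[0],
    inter_hi: float = DEFAULT_INTER[1],
) -> pd.DataFrame:
    """Tiling per-window mean FST and sex-patterned site count.

    One row per window per contig (windows with no sites report zero count
    and NaN mean FST). Window counts sum to the number of passing sites.
    """
    fst = np.full(len(table), np.nan)
    passes = np.zeros(len(table), dtype=bool)
    for i in range(len(table)):
        s = table.site(i)
        f = site_fst(s, *pools, min_depth=min_depth)
        if f is not None:
            fst[i] = f
        passes[i] = sex_patterned(
            s, homogametic_pool, fixed_tol, inter_lo, inter_hi, min_depth
        ).passes
    rows = []
    for contig in sorted(set(table.contigs.tolist())):
        mask = table.contigs == contig
        pos = table.pos[mask]
        length = (
            lengths[contig]
            if lengths is not None
            else (int(pos.max()) + 1 if len(pos) else window)
        )
        n_windows = max((length + window - 1) // window, 1)
        widx = pos // window
        for w in range(n_windows):
            sel = widx == w
            w_fst = fst[mask][sel]
            w_fst = w_fst[~np.isnan(w_fst)]
            rows.append(
                {
                    "contig": contig,
                    "start": w * window,
                    "end": min((w + 1) * window, length),
                    "n_sites": int(sel.sum()),
                    "mean_fst": float(w_fst.mean()) if len(w_fst) else np.nan,
                    "sexpat_count": int(passes[mask][sel].sum()),
                }
            )
    return pd.DataFrame(rows)


def detect_sd_region(
    track: pd.DataFrame,
    min_run_windows: int = 5,
    count_threshold: int = 5,
) -> list[GenomicInterval]:
    """Maximal runs of consecutive windows with sex-patterned count >=
    ``count_threshold``, tolerating single-window dropouts; a run must
    contain at least ``min_run_windows`` qualifying windows. Boundaries are
    the outermost qualifying windows."""
    out: list[GenomicInterval] = []
    for contig, sub in track.groupby("contig", sort=True):
        sub = sub.sort_values("start")
        qual = (sub["sexpat_count"] >= count_threshold).to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        n = len(qual)
        while i < n:
            if not qual[i]:
                i += 1
                continue
            j = i
            last_qual = i
            n_qual = 0
            while j < n:
                if qual[j]:
                    n_qual += 1
                    last_qual = j
                    j += 1
                elif j + 1 < n and qual[j + 1]:  # single-window dropout
                    j += 1
                else:
                    break
            if n_qual >= min_run_windows:
                out.append(
                    GenomicInterval(contig, int(starts[i]), int(ends[last_qual]))
                )
            i = j + 1
    return out


def tally(
    track_or_sites, target_lg: str
) -> tuple[int, int, int]:
    """Partition passing sex-patterned sites into on-target linkage group
    and the rest: returns (on, off, total) with on + off = total."""
    if isinstance(track_or_sites, pd.DataFrame):
        on = int(
            track_or_sites.loc[track_or_sites["contig"] == target_lg, "sexpat_count"].sum()
        )
        total = int(track_or_sites["sexpat_count"].sum())
    else:
        passing = [s for s in track_or_sites if s.passes]
        on = sum(1 for s in passing if s.site.contig == target_lg)
        total = len(passing)
    return on, total - on, total
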