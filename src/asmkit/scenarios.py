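"""Canonical end-to-end synthetic studies with truth-based scoring.

These functions wire the generators to the detectors under the package's
default study conditions — a 10 Mbp genome of five chromosomes with ten
chimeric joins for the misassembly scan, and a 5 Mbp chromosome carrying a
1 Mbp sex-determination region at 40x pool depth for the pool-seq scan —
and score the results against the generator's truth tables. They are the
single source for both the test suite's recovery checks and the
reproduction script.
"""

from __future__ import annotations

import pandas as pd

from .anchoring import (
    anchoring_summary,
    assign_contigs,
    build_chromosomes,
    order_orient,
)
from .intervals import ContigSet
from .misassembly import scan_misassemblies
from .poolseq import detect_sd_region, window_tracks
from .simulate import (
    ScenarioConfig,
    fragment_genome,
    induce_misassemblies,
    simulate_genome,
    simulate_markers,
    simulate_matepair_placements,
    simulate_pool_counts,
    simulate_variant_calls,
)

SEX_SCAN_WINDOW = 10_000
SEX_SCAN_MIN_RUN = 5
SEX_SCAN_COUNT_THRESHOLD = 10


def build_misassembly_scenario(seed: int, config: ScenarioConfig | None = None):
    """Genome + chimeric contigs + all evidence tracks for one seed."""
    cfg = config or ScenarioConfig()
    genome, _ = simulate_genome(cfg, seed)
    contigs, truth = induce_misassemblies(
        genome, cfg.n_joins, seed + 1_000, cfg.min_segment
    )
    variants = simulate_variant_calls(contigs, truth, cfg, seed + 2_000)
    pairs = simulate_matepair_placements(genome, truth.contig_map, cfg, seed + 3_000)
    rad = simulate_markers(genome, truth.contig_map, cfg.marker_spacing, seed + 4_000, "rad")
    rh = simulate_markers(
        genome, truth.contig_map, 2 * cfg.marker_spacing, seed + 5_000, "rh"
    )
    hits = pd.concat([rad, rh], ignore_index=True)
    return {
        "config": cfg,
        "genome": genome,
        "contigs": contigs,
        "truth": truth,
        "variants": variants,
        "pairs": pairs,
        "hits": hits,
    }


def misassembly_recovery(seed: int, config: ScenarioConfig | None = None) -> dict:
    """Run the full scan on one seed; score junction recovery and false
    accepted candidates against truth."""
    sc = build_misassembly_scenario(seed, config)
    cfg = sc["config"]
    cands = scan_misassemblies(
        sc["variants"],
        sc["pairs"],
        sc["hits"],
        sc["contigs"],
        insert_range=(cfg.insert_mean // 2, cfg.insert_mean * 2),
    )
    accepted = [c for c in cands if c.is_accepted]
    junctions = sc["truth"].junctions
    covered = sum(
        any(c.interval.contig == ct and c.interval.contains(p) for c in accepted)
        for ct, p in junctions
    )
    false_accepted = sum(
        not any(
            c.interval.contig == ct and c.interval.contains(p) for ct, p in junctions
        )
        for c in accepted
    )
    return {
        "n_junctions": len(junctions),
        "covered": covered,
        "false_accepted": false_accepted,
        "n_accepted": len(accepted),
        "candidates": cands,
        "scenario": sc,
    }


def sex_region_recovery(seed: int, system: str = "XY") -> dict:
    """Simulate the default sex-pool scenario and score boundary recovery.

    One 5 Mbp chromosome, a 1 Mbp sex-determination region at 2.0-3.0 Mbp,
    sites every 200 bp, 40x mean pool depth; detection on 10 kbp windows.
    Reports the boundary error in windows (worst of start/end), or None if
    the region was not recovered as a single interval.
    """
    cfg = ScenarioConfig()
    contigs = ContigSet.from_lengths({"LG1": 5_000_000})
    sd = ("LG1", 2_000_000, 3_000_000)
    table, _ = simulate_pool_counts(contigs, sd, cfg, seed, system=system)
    homogametic_pool = 0 if system == "XY" else 1
    track = window_tracks(
        table,
        window=SEX_SCAN_WINDOW,
        homogametic_pool=homogametic_pool,
        lengths=contigs.lengths,
    )
    regions = detect_sd_region(track, SEX_SCAN_MIN_RUN, SEX_SCAN_COUNT_THRESHOLD)
    result = {
        "truth": sd,
        "regions": regions,
        "track": track,
        "boundary_error_windows": None,
    }
    if len(regions) == 1:
        r = regions[0]
        err = max(abs(r.start - sd[1]), abs(r.end - sd[2])) / SEX_SCAN_WINDOW
        result["boundary_error_windows"] = err
    return result


def anchoring_recovery(seed: int, pieces_per_chrom: int = 4) -> dict:
    """Fragment a junction-free genome, anchor it back, and score order and
    orientation against truth."""
    cfg = ScenarioConfig()
    genome, _ = simulate_genome(cfg, seed)
    contigs, truth = fragment_genome(genome, pieces_per_chrom, seed + 1_000)
    hits = simulate_markers(genome, truth.contig_map, cfg.marker_spacing, seed + 2_000)
    assignments, unanchored, problem = assign_contigs(hits)
    layouts = order_orient(assignments, hits)
    by_lg = {l.linkage_group: l for l in layouts}
    n_checked = 0
    n_correct = 0
    for chrom in genome.ids:
        true_order = [
            s.contig
            for s in sorted(
                (s for s in truth.contig_map.segments if s.chrom == chrom),
                key=lambda s: s.chrom_start,
            )
            if s.contig in assignments
        ]
        placements = by_lg[chrom].placements if chrom in by_lg else []
        got = [(p.contig, p.orientation) for p in placements]
        for i, contig in enumerate(true_order):
            n_checked += 1
            if i < len(got) and got[i] == (contig, "+"):
                n_correct += 1
    anchored, agp = build_chromosomes(layouts, contigs)
    n_placements, n_gaps, gap_bp = anchoring_summary(layouts)
    return {
        "n_contigs": len(contigs),
        "n_anchored": len(assignments),
        "n_unanchored": len(unanchored),
        "n_problem": len(problem),
        "n_checked": n_checked,
        "n_correct": n_correct,
        "layouts": layouts,
        "anchored": anchored,
        "agp": agp,
        "contigs": contigs,
        "n_gaps": n_gaps,
        "gap_bp": gap_bp,
    }
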