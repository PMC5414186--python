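"""Misassembly detector: window flagging, physical coverage, adjudication,
breakpoint choice, and recovery of engineered junctions."""

import numpy as np
import pandas as pd
import pytest

from asmkit.intervals import ContigSet, GenomicInterval
from asmkit.misassembly import (
    Breakpoint,
    NoLegalBreakpointError,
    adjudicate,
    break_contigs,
    candidate_regions,
    choose_breakpoint,
    flagged_intervals,
    low_coverage_regions,
    map_conflicts,
    physical_coverage,
    remap_positions,
    scan_misassemblies,
    variant_density_windows,
)
from asmkit.simulate import (
    simulate_markers,
    simulate_matepair_placements,
    simulate_variant_calls,
)

from conftest import small_config


def variant_frame(contig, positions, qual=30.0):
    return pd.DataFrame(
        {"contig": contig, "pos": positions, "qual": qual}
    )


def make_pairs(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "contig1", "start1", "end1", "strand1",
            "contig2", "start2", "end2", "strand2",
        ],
    )


class TestDensityWindows:
    def test_eleven_variants_flag_a_window(self):
        contigs = ContigSet.from_lengths({"c1": 10_000})
        wins = variant_density_windows(
            variant_frame("c1", np.arange(11) * 100), contigs
        )
        assert wins[0].flagged and wins[0].variant_count == 11

    def test_ten_variants_do_not(self):
        contigs = ContigSet.from_lengths({"c1": 10_000})
        wins = variant_density_windows(
            variant_frame("c1", np.arange(10) * 100), contigs
        )
        assert not wins[0].flagged

    def test_qual_exactly_ten_excluded(self):
        contigs = ContigSet.from_lengths({"c1": 10_000})
        wins = variant_density_windows(
            variant_frame("c1", np.arange(20) * 100, qual=10.0), contigs
        )
        assert wins[0].variant_count == 0

    def test_partial_last_window_scales_threshold(self):
        contigs = ContigSet.from_lengths({"c1": 12_000})
        # 2 kbp tail window: > 2 variants flags it
        wins = variant_density_windows(
            variant_frame("c1", [10_100, 10_200, 10_300]), contigs
        )
        assert wins[-1].interval == GenomicInterval("c1", 10_000, 12_000)
        assert wins[-1].flagged

    def test_site_beyond_contig_reported(self):
        contigs = ContigSet.from_lengths({"c1": 1_000})
        with pytest.raises(ValueError, match="c1:5000"):
            variant_density_windows(variant_frame("c1", [5_000]), contigs)

    def test_raising_thresholds_never_adds_flags(self, small_scenario):
        contigs = small_scenario["contigs"]
        variants = small_scenario["variants"]
        base = sum(
            w.flagged for w in variant_density_windows(variants, contigs)
        )
        stricter_qual = sum(
            w.flagged
            for w in variant_density_windows(variants, contigs, min_qual=30)
        )
        stricter_density = sum(
            w.flagged
            for w in variant_density_windows(variants, contigs, density_threshold=2.0)
        )
        assert stricter_qual <= base
        assert stricter_density <= base


class TestPhysicalCoverage:
    def test_single_pair_outer_span(self):
        contigs = ContigSet.from_lengths({"c1": 50_000})
        pairs = make_pairs(
            [("p1", "c1", 100, 200, "+", "c1", 40_000, 40_100, "-")]
        )
        track = physical_coverage(pairs, contigs, end_exclusion=0)
        cov = track.coverage["c1"]
        assert cov[100] == 1 and cov[40_099] == 1
        assert cov[99] == 0 and cov[40_100] == 0

    def test_inter_contig_pair_contributes_nowhere(self):
        contigs = ContigSet.from_lengths({"c1": 50_000, "c2": 50_000})
        pairs = make_pairs(
            [("p1", "c1", 100, 200, "+", "c2", 40_000, 40_100, "-")]
        )
        track = physical_coverage(pairs, contigs, end_exclusion=0)
        assert track.coverage["c1"].sum() == 0
        assert track.coverage["c2"].sum() == 0

    def test_unknown_contig_rejected(self):
        contigs = ContigSet.from_lengths({"c1": 50_000})
        pairs = make_pairs(
            [("p1", "cX", 100, 200, "+", "cX", 4_000, 4_100, "-")]
        )
        with pytest.raises(ValueError, match="cX"):
            physical_coverage(pairs, contigs)

    def test_matches_brute_force_stacking(self, rng):
        length = 5_000
        contigs = ContigSet.from_lengths({"c1": length})
        rows = []
        for i in range(200):
            s1 = int(rng.integers(0, length - 200))
            span = int(rng.integers(100, length - s1))
            rows.append(
                (f"p{i}", "c1", s1, s1 + 50, "+", "c1", s1 + span - 50, s1 + span, "-")
            )
        pairs = make_pairs(rows)
        track = physical_coverage(pairs, contigs, end_exclusion=0)
        oracle = np.zeros(length, dtype=int)
        for _, c1, s1, e1, _, c2, s2, e2, _ in rows:
            oracle[min(s1, s2) : max(e1, e2)] += 1
        assert np.array_equal(track.coverage["c1"], oracle)


class TestLowCoverage:
    def _track(self, cov, end_exclusion=0):
        from asmkit.misassembly import PhysicalCoverageTrack

        return PhysicalCoverageTrack({"c1": np.asarray(cov)}, end_exclusion)

    def test_uniform_at_threshold_yields_nothing(self):
        assert low_coverage_regions(self._track(np.full(1000, 20))) == []

    def test_uniform_below_threshold_yields_interior(self):
        got = low_coverage_regions(self._track(np.full(1000, 19), end_exclusion=100))
        assert got == [GenomicInterval("c1", 100, 900)]

    def test_fully_masked_contig_skipped(self):
        assert low_coverage_regions(self._track(np.zeros(100), end_exclusion=60)) == []

    def test_junction_dips_are_flagged(self, small_scenario):
        cfg = small_scenario["config"]
        track = physical_coverage(
            small_scenario["pairs"],
            small_scenario["contigs"],
            end_exclusion=100_000,
            insert_range=(cfg.insert_mean // 2, cfg.insert_mean * 2),
        )
        low = low_coverage_regions(track)
        for contig, pos in small_scenario["truth"].junctions:
            assert any(
                iv.contig == contig and iv.contains(pos) for iv in low
            ), f"junction {contig}:{pos} not inside a low-coverage region"


class TestCandidateRegions:
    def test_disjoint_signals_yield_nothing(self):
        hd = [GenomicInterval("c1", 0, 10_000)]
        lc = [GenomicInterval("c1", 500_000, 520_000)]
        assert candidate_regions(hd, lc) == []

    def test_covered_window_survives(self):
        hd = [GenomicInterval("c1", 100_000, 110_000)]
        lc = [GenomicInterval("c1", 95_000, 130_000)]
        assert candidate_regions(hd, lc) == hd


class TestMapConflicts:
    def _hits(self, rows):
        return pd.DataFrame(
            rows,
            columns=["marker", "map", "linkage_group", "map_position",
                     "contig", "contig_pos", "strand"],
        )

    def test_single_group_no_conflict(self):
        hits = self._hits(
            [("m1", "rad", "lgA", 0.0, "c1", 100, "+"),
             ("m2", "rad", "lgA", 1.0, "c1", 900, "+")]
        )
        assert map_conflicts(hits) == []

    def test_group_switch_yields_gap_interval(self):
        hits = self._hits(
            [("m1", "rad", "lgA", 0.0, "c1", 100, "+"),
             ("m2", "rad", "lgA", 1.0, "c1", 900, "+"),
             ("m3", "rad", "lgB", 5.0, "c1", 2_000, "+")]
        )
        got = map_conflicts(hits)
        assert got == [("c1", GenomicInterval("c1", 900, 2_000), "rad")]

    def test_synthetic_conflict_contains_junction(self, small_scenario):
        conflicts = map_conflicts(small_scenario["hits"])
        for contig, pos in small_scenario["truth"].junctions:
            assert any(
                c == contig and iv.start <= pos <= iv.end
                for c, iv, _ in conflicts
            )

    def test_empty_hits(self):
        assert map_conflicts(pd.DataFrame()) == []


class TestAdjudicate:
    def _hits(self, rows):
        return pd.DataFrame(
            rows,
            columns=["marker", "map", "linkage_group", "map_position",
                     "contig", "contig_pos", "strand"],
        )

    def test_dual_signal_with_concordant_maps_rejected(self):
        region = GenomicInterval("c1", 10_000, 20_000)
        hits = self._hits(
            [("m1", "rad", "lgA", 0.0, "c1", 12_000, "+"),
             ("m2", "rad", "lgA", 1.0, "c1", 18_000, "+"),
             ("m3", "rh", "lgA", 0.0, "c1", 15_000, "+")]
        )
        out = adjudicate([region], [], [], hits)
        assert len(out) == 1
        assert out[0].verdict == "rejected_by_maps"
        assert not out[0].is_accepted

    def test_dual_signal_without_markers_accepted(self):
        region = GenomicInterval("c1", 10_000, 20_000)
        hits = self._hits([("m1", "rad", "lgA", 0.0, "c1", 500_000, "+")])
        out = adjudicate([region], [], [], hits)
        assert out[0].verdict == "accepted"
        assert out[0].evidence == {"hd_variants", "low_physcov"}

    def test_single_map_conflict_accepted(self):
        conflict = [("c1", GenomicInterval("c1", 30_000, 40_000), "rad")]
        out = adjudicate([], conflict, [], self._hits([]))
        assert out[0].is_accepted
        assert out[0].evidence == {"rad_conflict"}
        assert out[0].verdict == "map_only"

    def test_overlapping_conflict_and_signal_merge(self):
        region = GenomicInterval("c1", 32_000, 38_000)
        conflict = [("c1", GenomicInterval("c1", 30_000, 40_000), "rh")]
        out = adjudicate([region], [], conflict, self._hits([]))
        assert len(out) == 1
        assert out[0].evidence == {"rh_conflict", "hd_variants", "low_physcov"}
        assert out[0].verdict == "accepted"


class TestChooseBreakpoint:
    def test_no_annotation_gives_midpoint(self):
        bp = choose_breakpoint(GenomicInterval("c1", 100, 200))
        assert bp.pos == 150

    def test_midpoint_in_repeat_moves_to_nearest_edge(self):
        region = GenomicInterval("c1", 100, 200)
        repeat = [GenomicInterval("c1", 140, 155)]
        bp = choose_breakpoint(region, repeats=repeat)
        # mid = 150; legal candidates 140 and 155; 140 is nearer... both
        # |150-140| = 10 vs |155-150| = 5 -> 155
        assert bp.pos == 155

    def test_leftmost_on_tie(self):
        region = GenomicInterval("c1", 100, 200)
        repeat = [GenomicInterval("c1", 145, 155)]
        bp = choose_breakpoint(region, repeats=repeat)
        assert bp.pos == 145  # 145 and 155 both 5 away; leftmost wins

    def test_fully_blocked_region_raises(self):
        region = GenomicInterval("c1", 100, 200)
        with pytest.raises(NoLegalBreakpointError):
            choose_breakpoint(
                region,
                repeats=[GenomicInterval("c1", 90, 210)],
            )

    def test_matches_exhaustive_scan(self, rng):
        for trial in range(100):
            start = int(rng.integers(0, 100))
            end = start + int(rng.integers(10, 200))
            region = GenomicInterval("c1", start, end)
            blockers = []
            for _ in range(int(rng.integers(0, 6))):
                s = int(rng.integers(max(0, start - 20), end + 20))
                blockers.append(GenomicInterval("c1", s, s + int(rng.integers(1, 40))))
            legal = [
                p
                for p in range(start, end + 1)
                if not any(b.start < p < b.end for b in blockers)
            ]
            mid = (start + end) // 2
            if not legal:
                with pytest.raises(NoLegalBreakpointError):
                    choose_breakpoint(region, repeats=blockers)
                continue
            expect = min(legal, key=lambda p: (abs(p - mid), p))
            got = choose_breakpoint(region, repeats=blockers)
            assert got.pos == expect


class TestBreakContigs:
    def test_no_breakpoints_is_identity(self, small_scenario):
        contigs = small_scenario["contigs"]
        assert break_contigs(contigs, []).ids == contigs.ids

    def test_k_breakpoints_add_k_contigs_and_conserve_bp(self, small_scenario):
        contigs = small_scenario["contigs"]
        bps = [
            Breakpoint(c, p) for c, p in small_scenario["truth"].junctions
        ]
        broken = break_contigs(contigs, bps)
        assert len(broken) == len(contigs) + len(bps)
        assert broken.total_bp == contigs.total_bp

    def test_breakpoint_outside_contig_rejected(self):
        contigs = ContigSet.from_lengths({"c1": 100})
        with pytest.raises(ValueError):
            break_contigs(contigs, [Breakpoint("c1", 0)])
        with pytest.raises(ValueError):
            break_contigs(contigs, [Breakpoint("c1", 100)])

    def test_split_sequences_concatenate_back(self):
        contigs = ContigSet.from_sequences({"c1": "ACGTACGTAC"})
        broken = break_contigs(contigs, [Breakpoint("c1", 4)])
        assert broken.sequence_of("c1.1") + broken.sequence_of("c1.2") == "ACGTACGTAC"


class TestEndToEndRecovery:
    def test_junctions_recovered_with_few_false_positives(self, small_scenario):
        cfg = small_scenario["config"]
        cands = scan_misassemblies(
            small_scenario["variants"],
            small_scenario["pairs"],
            small_scenario["hits"],
            small_scenario["contigs"],
            end_exclusion=100_000,
            insert_range=(cfg.insert_mean // 2, cfg.insert_mean * 2),
        )
        accepted = [c for c in cands if c.is_accepted]
        junctions = small_scenario["truth"].junctions
        covered = sum(
            any(c.interval.contig == ct and c.interval.contains(p) for c in accepted)
            for ct, p in junctions
        )
        false = sum(
            not any(
                c.interval.contig == ct and c.interval.contains(p)
                for ct, p in junctions
            )
            for c in accepted
        )
        assert covered == len(junctions)
        assert false <= 2

    def test_rescan_after_breaking_is_clean(self, small_scenario):
        cfg = small_scenario["config"]
        genome = small_scenario["genome"]
        cands = scan_misassemblies(
            small_scenario["variants"],
            small_scenario["pairs"],
            small_scenario["hits"],
            small_scenario["contigs"],
            end_exclusion=100_000,
            insert_range=(cfg.insert_mean // 2, cfg.insert_mean * 2),
        )
        bps = [
            choose_breakpoint(c.interval, provenance=str(i))
            for i, c in enumerate(cands)
            if c.is_accepted
        ]
        broken = break_contigs(small_scenario["contigs"], bps)
        new_map = small_scenario["truth"].contig_map.split_at(
            [(b.contig, b.pos) for b in bps]
        )
        assert set(new_map.contig_lengths()) == set(broken.ids)
        # the evidence is fixed data, not fresh randomness: lift the same
        # variants onto the broken coordinates and regenerate pairs/markers
        # with the original seeds (identical fragments and marker sequences)
        variants2 = remap_positions(
            small_scenario["variants"], [(b.contig, b.pos) for b in bps]
        )
        pairs2 = simulate_matepair_placements(genome, new_map, cfg, 14)
        rad2 = simulate_markers(genome, new_map, cfg.marker_spacing, 15, "rad")
        rh2 = simulate_markers(genome, new_map, 2 * cfg.marker_spacing, 16, "rh")
        hits2 = pd.concat([rad2, rh2], ignore_index=True)
        cands2 = scan_misassemblies(
            variants2, pairs2, hits2, broken,
            end_exclusion=100_000,
            insert_range=(cfg.insert_mean // 2, cfg.insert_mean * 2),
        )
        accepted2 = [c for c in cands2 if c.is_accepted]
        assert accepted2 == []

    def test_no_output_contig_spans_two_linkage_groups(self, small_scenario):
        cfg = small_scenario["config"]
        genome = small_scenario["genome"]
        cands = scan_misassemblies(
            small_scenario["variants"],
            small_scenario["pairs"],
            small_scenario["hits"],
            small_scenario["contigs"],
            end_exclusion=100_000,
            insert_range=(cfg.insert_mean // 2, cfg.insert_mean * 2),
        )
        bps = [
            choose_breakpoint(c.interval) for c in cands if c.is_accepted
        ]
        new_map = small_scenario["truth"].contig_map.split_at(
            [(b.contig, b.pos) for b in bps]
        )
        # same marker set as the original scan, lifted through the new map
        hits = simulate_markers(genome, new_map, cfg.marker_spacing, 15, "rad")
        for contig, sub in hits.groupby("contig"):
            assert sub["linkage_group"].nunique() == 1
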