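"""Determinism, conservation, and statistical calibration of the generators."""

import numpy as np
import pandas as pd
import pytest

from asmkit.intervals import ContigSet
from asmkit.simulate import (
    ScenarioConfig,
    TruthTable,
    fragment_genome,
    induce_misassemblies,
    simulate_bac_ends,
    simulate_genome,
    simulate_markers,
    simulate_matepair_placements,
    simulate_pool_counts,
    simulate_variant_calls,
)

from conftest import small_config


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        g1, _ = simulate_genome(cfg, 1)
        g2, _ = simulate_genome(cfg, 1)
        assert all(
            g1.sequence_of(c) == g2.sequence_of(c) for c in g1.ids
        )
        g3, _ = simulate_genome(cfg, 2)
        assert any(g1.sequence_of(c) != g3.sequence_of(c) for c in g1.ids)

    def test_total_size_conserved(self):
        cfg = ScenarioConfig()
        g, _ = simulate_genome(cfg, 1)
        assert g.total_bp == 10_000_000

    def test_repeat_fraction_calibrated(self):
        cfg = small_config()
        cfg.repeat_fraction = 0.2
        g, truth = simulate_genome(cfg, 3)
        repeat_bp = sum(r.length for r in truth.repeats)
        frac = repeat_bp / g.total_bp
        assert abs(frac - 0.2) <= 0.02

    def test_too_short_chromosome_rejected(self):
        cfg = small_config()
        cfg.chromosomes = [("chr01", 100_000), ("chr02", 800_000)]
        with pytest.raises(ValueError, match="chr01"):
            simulate_genome(cfg, 1)

    def test_single_chromosome_rejected(self):
        cfg = small_config()
        cfg.chromosomes = [("chr01", 800_000)]
        with pytest.raises(ValueError):
            simulate_genome(cfg, 1)


class TestInduceMisassemblies:
    def test_zero_joins_is_identity(self, small_scenario):
        g = small_scenario["genome"]
        contigs, truth = induce_misassemblies(g, 0, 5)
        assert contigs.ids == g.ids
        assert truth.junctions == []

    def test_bp_conserved_and_junctions_recorded(self, small_scenario):
        contigs = small_scenario["contigs"]
        truth = small_scenario["truth"]
        genome = small_scenario["genome"]
        assert contigs.total_bp == genome.total_bp
        assert len(truth.junctions) == small_scenario["config"].n_joins
        for contig, pos in truth.junctions:
            assert 0 < pos < contigs.length_of(contig)

    def test_junction_joins_two_chromosomes(self, small_scenario):
        cmap = small_scenario["truth"].contig_map
        assert sorted(cmap.junctions()) == sorted(small_scenario["truth"].junctions)

    def test_sequence_matches_source_segments(self, small_scenario):
        genome = small_scenario["genome"]
        contigs = small_scenario["contigs"]
        for seg in small_scenario["truth"].contig_map.segments:
            assert (
                contigs.sequence_of(seg.contig)[seg.contig_start : seg.contig_end]
                == genome.sequence_of(seg.chrom)[seg.chrom_start : seg.chrom_end]
            )

    def test_infeasible_join_count_rejected(self, small_scenario):
        with pytest.raises(ValueError):
            induce_misassemblies(small_scenario["genome"], 100, 1, 200_000)


class TestTruthTable:
    def test_json_round_trip(self, small_scenario, tmp_path):
        truth = small_scenario["truth"]
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthTable.from_json(path)
        assert back.junctions == truth.junctions
        assert back.contig_map.segments == truth.contig_map.segments


class TestVariantCalls:
    def test_all_sites_in_halos_when_background_zero(self, small_scenario):
        cfg = small_config()
        cfg.background_variant_rate = 0.0
        v = simulate_variant_calls(
            small_scenario["contigs"], small_scenario["truth"], cfg, 7
        )
        halo = cfg.junction_halo
        junctions = small_scenario["truth"].junctions
        for row in v.itertuples(index=False):
            assert any(
                row.contig == c and abs(row.pos - p) <= halo for c, p in junctions
            )

    def test_poisson_count_within_3_sigma(self, small_scenario):
        cfg = small_config()
        cfg.junction_variant_rate = cfg.background_variant_rate  # flat rate
        v = simulate_variant_calls(
            small_scenario["contigs"], small_scenario["truth"], cfg, 8
        )
        lam = cfg.background_variant_rate * small_scenario["contigs"].total_bp / 1000
        assert abs(len(v) - lam) <= 3 * np.sqrt(lam)

    def test_quality_mixture_matches_filter_fraction(self, small_scenario):
        v = simulate_variant_calls(
            small_scenario["contigs"], small_scenario["truth"], small_config(), 9
        )
        n = len(v)
        kept = int((v["qual"] > 10).sum())
        p = 1 - small_config().low_qual_fraction
        assert abs(kept - p * n) <= 3 * np.sqrt(n * p * (1 - p))


class TestMatePairs:
    def test_mean_physical_coverage_on_clean_genome(self):
        cfg = small_config()
        genome, truth = simulate_genome(cfg, 21)
        pairs = simulate_matepair_placements(genome, truth.contig_map, cfg, 22)
        expected = cfg.pair_count * cfg.insert_mean / genome.total_bp
        spans = (pairs["true_end"] - pairs["true_start"]).to_numpy()
        observed = spans.sum() / genome.total_bp
        assert abs(observed - expected) / expected < 0.05

    def test_no_concordant_pair_spans_a_junction(self, small_scenario):
        pairs = small_scenario["pairs"]
        same = pairs[pairs["contig1"] == pairs["contig2"]]
        for contig, pos in small_scenario["truth"].junctions:
            spanning = same[
                (same["contig1"] == contig)
                & (same["start1"].clip(lower=0) < pos)
                & (same[["start1", "start2"]].min(axis=1) < pos)
                & (same[["end1", "end2"]].max(axis=1) > pos)
            ]
            assert len(spanning) == 0

    def test_discordant_fraction_matches_junction_capture(self, small_scenario):
        cfg = small_scenario["config"]
        pairs = small_scenario["pairs"]
        discordant = (pairs["contig1"] != pairs["contig2"]).mean()
        # a fragment is discordant iff it straddles one of the chain cut
        # points; expected fraction ~ n_cuts x insert_mean / genome_bp
        n_cuts = len(small_scenario["truth"].contig_map.segments) - len(
            small_scenario["contigs"]
        )
        expected = n_cuts * cfg.insert_mean / small_scenario["genome"].total_bp
        assert abs(discordant - expected) < 3 * np.sqrt(
            expected / cfg.pair_count
        ) + 0.01


class TestMarkers:
    def test_chimeric_contig_shows_two_linkage_groups(self, small_scenario):
        hits = small_scenario["hits"]
        junction_contigs = {c for c, _ in small_scenario["truth"].junctions}
        for contig in junction_contigs:
            lgs = hits.loc[hits["contig"] == contig, "linkage_group"].nunique()
            assert lgs >= 2

    def test_clean_contigs_single_linkage_group(self):
        cfg = small_config()
        genome, truth = simulate_genome(cfg, 31)
        contigs, t2 = fragment_genome(genome, 3, 32)
        hits = simulate_markers(genome, t2.contig_map, cfg.marker_spacing, 33)
        for contig, sub in hits.groupby("contig"):
            assert sub["linkage_group"].nunique() == 1

    def test_sparse_markers_leave_contig_unanchorable(self):
        cfg = small_config()
        genome, truth = simulate_genome(cfg, 34)
        hits = simulate_markers(genome, truth.contig_map, 900_000, 35)
        counts = hits.groupby("contig").size()
        assert (counts <= 1).all()


class TestPoolCounts:
    def test_heterogametic_frequency_near_half_at_high_depth(self):
        cfg = small_config()
        cfg.pool_depth_mean = 4000.0
        contigs = ContigSet.from_lengths({"LG1": 400_000})
        table, truth = simulate_pool_counts(
            contigs, ("LG1", 100_000, 300_000), cfg, 41, system="XY"
        )
        sel = truth["in_region"].to_numpy()
        c = table.counts[sel]
        het_freq = c[:, 1, 1] / (c[:, 1, 0] + c[:, 1, 1])
        assert abs(het_freq.mean() - 0.5) < 0.02
        homog_alt = c[:, 0, 1].sum()
        assert homog_alt == 0

    def test_background_pools_exchangeable(self):
        cfg = small_config()
        contigs = ContigSet.from_lengths({"LG1": 400_000})
        table, truth = simulate_pool_counts(contigs, None, cfg, 42)
        f0 = truth["freq_pool0"]
        f1 = truth["freq_pool1"]
        assert (f0 == f1).all()

    def test_zw_swaps_pool_roles(self):
        cfg = small_config()
        contigs = ContigSet.from_lengths({"LG1": 400_000})
        _, t_xy = simulate_pool_counts(contigs, ("LG1", 0, 400_000), cfg, 43, "XY")
        _, t_zw = simulate_pool_counts(contigs, ("LG1", 0, 400_000), cfg, 43, "ZW")
        assert (t_xy["freq_pool0"] == 0).all()  # female pool fixed under XY
        assert (t_zw["freq_pool1"] == 0).all()  # male pool fixed under ZW


class TestBacEnds:
    def test_truth_classes_follow_liftover(self, small_scenario):
        bacs = simulate_bac_ends(
            small_scenario["genome"], small_scenario["truth"].contig_map, 500, 51
        )
        # oracle: recompute the class from the hit geometry
        for row in bacs.itertuples(index=False):
            if row.truth_class in ("unaligned", "1", "3"):
                continue
            if row.truth_class == "4":
                assert row.contig1 != row.contig2
            else:
                assert row.contig1 == row.contig2
                assert row.strand1 == "+" and row.strand2 == "-"

    def test_classes_partition(self, small_scenario):
        bacs = simulate_bac_ends(
            small_scenario["genome"], small_scenario["truth"].contig_map, 300, 52
        )
        assert bacs["truth_class"].isin(["1", "2", "3", "4", "unaligned"]).all()
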