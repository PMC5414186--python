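"""Shared fixtures: scaled-down synthetic scenarios with known truth.

The "small" scenario (4 x 800 kbp chromosomes, 4 chimeric joins) keeps unit
tests fast; the acceptance tests build the full default scenario themselves.
"""

import numpy as np
import pandas as pd
import pytest

from asmkit.simulate import (
    ScenarioConfig,
    induce_misassemblies,
    simulate_genome,
    simulate_markers,
    simulate_matepair_placements,
    simulate_variant_calls,
)


def small_config() -> ScenarioConfig:
    cfg = ScenarioConfig()
    cfg.chromosomes = [(f"chr{i:02d}", 800_000) for i in range(1, 5)]
    cfg.n_joins = 4
    cfg.min_segment = 200_000
    # keep ~40x physical coverage on the smaller genome
    cfg.pair_count = int(40 * 3_200_000 / cfg.insert_mean)
    return cfg


@pytest.fixture(scope="session")
def small_scenario():
    """Full evidence bundle for a small chimeric genome, seed-fixed."""
    cfg = small_config()
    genome, _ = simulate_genome(cfg, 11)
    contigs, truth = induce_misassemblies(genome, cfg.n_joins, 12, cfg.min_segment)
    variants = simulate_variant_calls(contigs, truth, cfg, 13)
    pairs = simulate_matepair_placements(genome, truth.contig_map, cfg, 14)
    rad = simulate_markers(genome, truth.contig_map, cfg.marker_spacing, 15, "rad")
    rh = simulate_markers(genome, truth.contig_map, 2 * cfg.marker_spacing, 16, "rh")
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


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
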