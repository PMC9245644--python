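import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from repeatscape.io_formats import GeneRecord, GenomeIndex, RepeatHit
from repeatscape.synthetic import PlantedEnrichment, SimulationConfig, plant_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_index():
    return GenomeIndex("toy", {"chr1": 200_000, "chr2": 100_000})


@pytest.fixture
def toy_hits(toy_index):
    return [
        RepeatHit("chr1", 100, 300, "+", "famA", "LINE/BovB", 5.0, 1000.0, "cl0"),
        RepeatHit("chr1", 250, 500, "-", "famA", "LINE/BovB", 8.0, 900.0, "cl0"),
        RepeatHit("chr1", 1000, 1500, "+", "famB", "DNA/TcMar-Tc1", 2.0, 800.0, "cl1"),
        RepeatHit("chr1", 1200, 1400, "+", "famC", "Unknown", 11.0, 700.0, "cl2"),
        RepeatHit("chr2", 0, 400, "-", "famB", "DNA/TcMar-Tc1", 3.5, 600.0, "cl1"),
    ]


@pytest.fixture
def toy_genes():
    return [
        GeneRecord("g1", "chr1", 5_000, 6_000, "+"),
        GeneRecord("g2", "chr1", 20_000, 22_000, "-"),
        GeneRecord("g3", "chr1", 50_000, 51_000, "+"),
        GeneRecord("g4", "chr2", 10_000, 12_000, "+"),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A small planted genome reused by read-only tests."""
    config = SimulationConfig(
        seed=42,
        seq_lengths={"chr1": 2_000_000, "chr2": 1_500_000},
        n_genes=150,
        enrichments=[PlantedEnrichment("fs", 8, "LINE/BovB", 3.0)],
    )
    return plant_genome(config)
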