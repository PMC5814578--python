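import numpy as np
import pandas as pd
import pytest

from poolscan import simulate as sim
from poolscan.snv_matrix import GenotypeMatrix, GroupSpec


@pytest.fixture
def tiny_spec() -> GroupSpec:
    return GroupSpec({"A": ["a1", "a2"], "B": ["b1", "b2"]})


@pytest.fixture
def tiny_matrix(tiny_spec) -> GenotypeMatrix:
    """4 samples x 6 sites over two chromosomes, handmade."""
    sites = pd.DataFrame(
        {
            "chrom": ["c1"] * 4 + ["c2"] * 2,
            "pos": [10, 20, 30, 40, 5, 15],
            "ref": list("AACCGG"),
            "alt": list("TTGGAA"),
        }
    )
    calls = np.array(
        [
            [0, 0, 1, 1, 0, 1],
            [0, 1, 1, 1, 0, 1],
            [1, 1, 0, 0, 1, 0],
            [1, 0, 0, 1, 1, 0],
        ],
        dtype=np.uint8,
    )
    return GenotypeMatrix(samples=tiny_spec.samples, sites=sites, calls=calls)


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    """Scaled-down study design for fast end-to-end tests."""
    return sim.SimConfig(
        chrom_lengths={"1H": 10_000_000, "2H": 10_000_000},
        n_sites={"1H": 5_000, "2H": 5_000},
        group_sizes={"MCB": 9, "QK": 18, "Wb-T": 6, "Wb-NE": 6},
        divergence={"MCB": 0.15, "QK": 0.15, "Wb-T": 0.2, "Wb-NE": 0.3},
        shared_blocks=[
            sim.SharedBlock("1H", 2_000_000, 4_000_000, "QK"),
            sim.SharedBlock("2H", 6_000_000, 8_000_000, "Wb-T"),
        ],
        sweep_blocks=[sim.SweepBlock("1H", 6_000_000, 7_000_000, "QK", "MCB")],
        n_genes=20,
        seq_length=100_000,
        n_islands=2,
        island_length=8_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sim.simulate_frequencies(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    return sim.simulate_genotypes(small_truth)
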