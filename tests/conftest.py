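"""Shared fixtures: small simulated libraries with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from overlapqc import CoverageParams, SimConfig, analyze_records, build_index, simulate_dataset


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_library():
    """~150 reads at 15x over an 80 kb genome, default 10% error."""
    config = SimConfig(genome_length=80_000, depth=15, seed=42)
    records, truth = simulate_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def small_index(small_library):
    _, records, _ = small_library
    return build_index(records)


@pytest.fixture(scope="session")
def small_result(small_library):
    """Full pipeline result on the small library (sample = all reads)."""
    _, records, _ = small_library
    return analyze_records(records, cov=CoverageParams(seed=3))
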