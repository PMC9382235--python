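from __future__ import annotations

import numpy as np
import pytest

from paleodel import mappability, synthetic_data
from paleodel.io_formats import SampleManifest


@pytest.fixture(scope="session")
def small_config() -> synthetic_data.SimulationConfig:
    return synthetic_data.SimulationConfig(
        seed=11,
        chrom_lengths={"chr1": 300_000},
        genes_per_chrom=6,
        n_indels=3_000,
        n_deletions=3,
        repeats_per_chrom=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_config) -> synthetic_data.Simulation:
    return synthetic_data.simulate(small_config)


@pytest.fixture(scope="session")
def small_mask(small_sim) -> mappability.MappabilityMask:
    return mappability.build_mappability_mask(small_sim.reference)


@pytest.fixture(scope="session")
def small_vcf(small_sim, tmp_path_factory):
    path = tmp_path_factory.mktemp("vcf") / "indels.vcf"
    synthetic_data.write_vcf(small_sim, path)
    return path


@pytest.fixture
def tiny_manifest() -> SampleManifest:
    """Five in-group genomes at 11.8X and two outgroup groups."""
    samples = [f"mam{i}" for i in range(1, 6)] + ["afr1", "afr2", "asi1"]
    groups = {s: "ingroup" for s in samples[:5]}
    groups.update({"afr1": "african", "afr2": "african", "asi1": "asian"})
    covs = {s: 11.8 for s in samples[:5]}
    covs.update({"afr1": 30.0, "afr2": 30.0, "asi1": 25.0})
    return SampleManifest(tuple(samples), groups, covs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
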