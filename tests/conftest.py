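"""Shared fixtures: small simulated experiments reused across test modules."""

import pytest

from epilineage import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def lossless_run():
    """Error-free, full-capture run: ideal conditions for round-trip checks."""
    config = SimConfig(
        n_founders=4,
        episomes_per_founder=30,
        replication_prob=0.2,
        capture_efficiency=1.0,
        sequencing_error_rate=0.0,
        reads_per_cell=150,
        seed=11,
    )
    lineage, observations, sampled_generation, batch = simulate_experiment(config, 3)
    return config, lineage, observations, sampled_generation, batch


@pytest.fixture(scope="session")
def reference_tracing_run():
    """Reference ancestry simulation: 8 founders, 50 single-copy episomes,
    no replication, 4 generations, 80% capture."""
    config = SimConfig(
        n_founders=8,
        episomes_per_founder=50,
        replication_prob=0.0,
        capture_efficiency=0.8,
        sequencing_error_rate=0.0,
        reads_per_cell=1,
        seed=3,
    )
    lineage, observations, sampled_generation, _batch = simulate_experiment(
        config, 4, [0, 4]
    )
    return config, lineage, observations, sampled_generation
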