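import pytest
from hypothesis import HealthCheck, settings

import circbench as cb

# Deterministic, example-light hypothesis profile: the suite must behave the
# same on every run and machine.
settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> cb.SimConfig:
    """Desk-scale study conditions for fast unit tests (not the defaults)."""
    return cb.SimConfig(
        n_circ=12,
        n_linear=40,
        genome_length=200_000,
        depth=8_000,
        n_decoys=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Transcriptome + total/rnaser libraries for the small config."""
    tx = cb.simulate_transcriptome(small_config)
    m1, m2, truth_total = cb.simulate_reads(tx, small_config, "total")
    r1, r2, truth_rnaser = cb.simulate_reads(tx, small_config, "rnaser")
    return {
        "config": small_config,
        "tx": tx,
        "total": (m1, m2),
        "rnaser": (r1, r2),
        "truth_total": truth_total,
        "truth_rnaser": truth_rnaser,
    }


@pytest.fixture(scope="session")
def default_benchmark():
    """The full default-scale benchmark run (shared by the heavier tests).

    This is the study's stated condition set: 50 planted circles, 200k read
    pairs per library, 5% linear survival under RNase R, seed 42.
    """
    config = cb.RunConfig(seed=42)
    return cb.run_benchmark(config)
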