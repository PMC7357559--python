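from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from mirseed import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


def small_config(**overrides) -> sim.SimulationConfig:
    """A scaled-down study: 13 loci over 2 x 120 kb contigs."""
    kwargs = dict(
        contig_length=120_000,
        n_intergenic=3, n_intronic=3, n_exonic=1, n_utr=1, n_splice=1,
        clusters=((2, "homo"),), n_mirror_pairs=1,
        age_counts={"vertebrate": 4, "mammal": 3, "primate": 3, "cercopithecidae": 3},
        rng_seed=11,
    )
    kwargs.update(overrides)
    return sim.SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_truth() -> sim.TruthSet:
    return sim.generate_truth_set(small_config())


@pytest.fixture(scope="session")
def small_libraries(small_truth) -> sim.SimulatedLibraries:
    specs = sim.default_library_specs(n_samples=4, n_reads=20_000)
    return sim.simulate_libraries(small_truth, specs)


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES
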