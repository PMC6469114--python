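import pytest

from hgtscan import SimulationConfig, analyze, simulate_study


def small_config(seed: int, **overrides) -> SimulationConfig:
    """A scaled-down study: fast enough for per-module tests while keeping
    the depth strata and layout of the full conditions."""
    base = dict(
        seed=seed,
        host_length=120_000,
        symbiont_length=60_000,
        n_host_scaffolds=2,
        n_symbiont_scaffolds=2,
        n_insertions=1,
        insertion_length_range=(1_000, 5_000),
        chimera_count=1,
        chimera_host_len=6_000,
        chimera_symbiont_len=5_000,
        alt_mean_fragment=20_000,
        edge_margin=2_500,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(small_config(seed=11))


@pytest.fixture(scope="session")
def small_result(small_bundle):
    b = small_bundle
    return analyze(
        b.scaffolds, b.tracks, b.host_ref, b.symbiont_ref,
        b.alt_assemblies, b.features, b.fpkm,
    )
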