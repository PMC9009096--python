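import pytest


@pytest.fixture(scope="session")
def npt_benchmark():
    """120 ps NPT TIP3P-FB benchmark (shared across acceptance tests)."""
    from npbcmd.benchmarks import npt_pressure_benchmark
    return npt_pressure_benchmark(seed=1)


@pytest.fixture(scope="session")
def hwhm_vacuum():
    """220 ps SPC NVT benchmark with a vacuum boundary."""
    from npbcmd.benchmarks import boundary_hwhm_benchmark
    return boundary_hwhm_benchmark(seed=1, reaction_field=False)


@pytest.fixture(scope="session")
def hwhm_ddcosmo():
    """220 ps SPC NVT benchmark with the conductor reaction field."""
    from npbcmd.benchmarks import boundary_hwhm_benchmark
    return boundary_hwhm_benchmark(seed=1, reaction_field=True)
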