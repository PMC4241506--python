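"""Shared fixtures: a small simulated study generated once per session."""
import pytest

from erlnc.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def sim_data(default_config):
    """Full default synthetic study (seed 7), shared read-only by tests."""
    return simulate_all(default_config, seed=7)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, default_config):
    """The same study written to disk for file-based stages."""
    outdir = tmp_path_factory.mktemp("sim") / "inputs"
    simulate_all(default_config, seed=7, outdir=outdir)
    return outdir
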