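import logging

import pytest

from dronbuild import FixtureConfig, generate_fixture, run_pipeline

logging.getLogger("dronbuild").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default-condition fixture with its pipeline result, shared read-only."""
    out = tmp_path_factory.mktemp("fixture")
    fx = generate_fixture(FixtureConfig(seed=7), out)
    result = run_pipeline(fx.release_dirs, chebi_path=fx.chebi_path)
    return fx, result
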