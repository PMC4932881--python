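import numpy as np
import pytest

from chronoclim import fixtures, pipeline


@pytest.fixture()
def rng():
    # fresh, fixed-seed stream per test so results don't depend on test order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_archive():
    """Shared synthetic archive (seed 0, monthly paleo stacks)."""
    return fixtures.generate(fixtures.FixtureScenario(seed=0))


@pytest.fixture(scope="session")
def downscaled(fixture_archive):
    """Downscaled primary variables for the shared archive."""
    return pipeline.downscale_paleo(fixture_archive)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full end-to-end run, reused across integration tests."""
    out = tmp_path_factory.mktemp("artifact")
    return pipeline.run_pipeline({"scenario": {"seed": 1}, "output": str(out)})
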