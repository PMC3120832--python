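import pytest

from dpnseq.config import SimConfig
from dpnseq.report import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def full_run():
    """The packaged simulation: toy genome, default planted events, 2 x 20,000
    reads, fixed seed — shared by the truth-recovery tests."""
    return run_pipeline(RunConfig(seed=1))


@pytest.fixture(scope="session")
def small_run():
    """A cheaper end-to-end run for structural checks."""
    return run_pipeline(RunConfig(seed=3, sim=SimConfig(n_reads=1500)))
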