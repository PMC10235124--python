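import numpy as np
import pytest

from dinoeve.pipeline import scan_assembly
from dinoeve.synthio import (
    SimConfig,
    default_cellular_panel,
    default_viral_panel,
    make_benchmark,
)

BENCH_SEED = 1


@pytest.fixture(scope="session")
def viral_panel():
    return default_viral_panel()


@pytest.fixture(scope="session")
def cellular_panel():
    return default_cellular_panel()


@pytest.fixture(scope="session")
def bench():
    """The default planted-truth benchmark (seeded, generated once)."""
    return make_benchmark(SimConfig(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def scan_result(bench, viral_panel, cellular_panel):
    """Full pipeline run over the default benchmark (computed once)."""
    return scan_assembly(
        bench.scaffolds, viral_panel, cellular_panel, depth=bench.depth
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
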