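import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from circtdmd import RunConfig
from circtdmd.synthetic_data import SimulationModel, generate_dataset


@pytest.fixture(scope="session")
def config():
    return RunConfig()


def small_model(seed: int = 11, **kw) -> SimulationModel:
    """A scaled-down cohort that keeps every structural feature."""
    defaults = dict(
        n_mirnas=24,
        n_circrnas=16,
        n_mrnas=10,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationModel(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_model())


@pytest.fixture(scope="session")
def emitted_tree(tmp_path_factory):
    from circtdmd.synthetic_data import emit_dataset

    outdir = tmp_path_factory.mktemp("fixture")
    ds = emit_dataset(small_model(seed=7), outdir)
    return outdir, ds
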