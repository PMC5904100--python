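import pytest

from amoatax.pipeline import run_pipeline
from amoatax.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic corpus at the default study conditions (seed fixed)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at default conditions, exports written."""
    outdir = tmp_path_factory.mktemp("exports")
    return run_pipeline(SimConfig(seed=1), outdir=outdir), outdir


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=5, n_clades=2, otus_per_clade=4, seqs_per_otu=6, chimera_fraction=0.0)
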