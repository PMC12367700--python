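import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from panfam.synth import SyntheticConfig, generate_pangenome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact 5-accession synthetic pan-genome shared across tests."""
    config = SyntheticConfig(
        n_accessions=5,
        n_core=12,
        n_softcore=0,  # soft-core occupancy range is empty at n=5
        n_shell=8,
        n_cloud=6,
        n_background_genes=80,
        seed=20240915,
    )
    return generate_pangenome(config)


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    small_bundle.write(out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
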