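import pytest

from mirscoppi import PipelineConfig, generate_dataset
from mirscoppi.pipeline import sponge_step


@pytest.fixture(scope="session")
def small_bundle():
    """A compact seeded bundle: 5 planted pairs, 30+30 samples."""
    return generate_dataset(
        n_mirna=40, n_lncrna=12, n_mrna=40, n_tumor=30, n_normal=30,
        n_pairs=5, shared_per_pair=3, n_decoy_disease=8,
        n_extra_proteins=10, n_background_ppi=12,
        n_diff_modules=1, diff_module_size=5, seed=7,
    )


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_inference(small_bundle, default_config):
    bundle, _ = small_bundle
    return sponge_step(bundle, default_config)
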