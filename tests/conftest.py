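import numpy as np
import pytest

from gextemplates import SimConfig, build_templates, generate_compendium
from gextemplates.synthetic_data import truth_templates


@pytest.fixture(scope="session")
def small_compendium():
    """Three small datasets, 8 tissues, 20 planted signature genes."""
    cfg = SimConfig(
        n_tissues=8,
        n_genes=400,
        n_signature=20,
        n_datasets=3,
        samples_per_tissue_per_dataset=2,
        tissue_effect_sd=2.0,
        batch_sd=0.5,
        noise_sd=0.5,
        seed=101,
    )
    return generate_compendium(cfg)


@pytest.fixture(scope="session")
def small_truth_templates(small_compendium):
    _, _, truth = small_compendium
    return truth_templates(truth)


@pytest.fixture(scope="session")
def small_built_templates(small_compendium):
    matrices, metas, truth = small_compendium
    from gextemplates import Signature

    sig = Signature(tuple(truth["signature_genes"]))
    return build_templates(matrices, metas, sig)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
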