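import numpy as np
import pytest

from contextmpnn.featurization import FeatureConfig
from contextmpnn.fixtures import FixtureSpec, LigandSpec, make_backbone, make_context
from contextmpnn.nn.model import ModelConfig, SequenceDesignModel
from contextmpnn.structures_io import Category


@pytest.fixture(scope="session")
def helix_spec():
    return FixtureSpec(
        chain_length=20,
        ligands=(LigandSpec(n_atoms=1, elements=(30,), placement_radius=2.2,
                            anchor_residue=10, category=int(Category.METAL)),),
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def helix_structure(helix_spec):
    return make_backbone(helix_spec)


@pytest.fixture(scope="session")
def helix_context(helix_spec, helix_structure):
    return make_context(helix_spec, helix_structure)


@pytest.fixture(scope="session")
def small_feature_config():
    return FeatureConfig(K=8, M=5, m=16)


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(m=16)


@pytest.fixture(scope="session")
def small_model(small_model_config, small_feature_config):
    model = SequenceDesignModel(small_model_config, small_feature_config,
                                variant="full", seed=0)
    return model.eval()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rotation(rng):
    """Uniform random rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
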