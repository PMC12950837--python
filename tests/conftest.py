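import numpy as np
import pytest

from edgeflow import AnomalyFlowModel, PhantomSpec, RunConfig, generate_dataset


@pytest.fixture(scope="session")
def phantom_root(tmp_path_factory):
    """Default phantom dataset (40/10/20 at 64x64), generated once."""
    root = tmp_path_factory.mktemp("phantoms")
    return generate_dataset(PhantomSpec(seed=0), root)


@pytest.fixture(scope="session")
def tiny_config():
    return RunConfig.tiny_test(seed=1)


@pytest.fixture(scope="session")
def trained_results(phantom_root, tiny_config):
    """The tiny model fitted on the phantom train split (5 epochs)."""
    model = AnomalyFlowModel.from_folder(phantom_root, tiny_config)
    return model.fit()


@pytest.fixture(scope="session")
def phantom_test_set(phantom_root, tiny_config):
    from edgeflow.data import FolderDataset

    ds = FolderDataset(phantom_root, tiny_config.resolution)
    images, labels, masks, samples = ds.load_test()
    return images, labels, masks, samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
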