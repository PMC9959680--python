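import numpy as np
import pytest

from radqsar import apply_split, make_reference_fixture, split_dataset


@pytest.fixture(scope="session")
def ref_ds():
    """The canonical 15-compound x 33-descriptor synthetic dataset."""
    return make_reference_fixture(seed=0)


@pytest.fixture(scope="session")
def ref_split(ref_ds):
    """Kennard-Stone 12/3 train/test split of the reference dataset."""
    split = split_dataset(ref_ds, fraction=0.8)
    train, test = apply_split(ref_ds, split)
    return split, train, test


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
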