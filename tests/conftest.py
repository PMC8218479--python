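import numpy as np
import pytest

from abequant import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small but geometrically valid phantom configuration."""
    return PhantomConfig(n_pos=5, n_neg=4, n_slices=5, slice_shape=(96, 96), seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    records, stacks = generate_cohort(small_config)
    return records, stacks


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_config, small_cohort):
    from abequant import write_dataset

    records, stacks = small_cohort
    out = tmp_path_factory.mktemp("phantom_ds")
    write_dataset(stacks, records, out, small_config)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
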