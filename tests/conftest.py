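import numpy as np
import pytest

from mindist import FamilySpec, HairpinRecord, encode_batch, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_record():
    return HairpinRecord("h1", "GGGAAACCC", "(((...)))")


@pytest.fixture(scope="session")
def small_dataset():
    """Two 10-member families plus 20 unrelated hairpins, half of family 0 known."""
    spec = FamilySpec(n_families=2, members_per_family=10, seed=7)
    return generate_dataset(spec, n_background=20)


@pytest.fixture(scope="session")
def small_coords(small_dataset):
    from mindist import fit_feature_space

    table, diagnostics = encode_batch(small_dataset.records)
    assert not diagnostics
    return fit_feature_space(table).transform(table)
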