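import pytest

from tdnas.space import default_space, enumerate_configs, encode_all
from tdnas.synthetic import SyntheticDatasetSpec, generate_dataset, split_dataset
from tdnas.training import BackboneSpec, extract_features


@pytest.fixture(scope="session")
def space_noext():
    """The default grid with the external level pinned (1,641 configs)."""
    return default_space(num_classes=8, search_external=False)


@pytest.fixture(scope="session")
def configs_noext(space_noext):
    return enumerate_configs(space_noext)


@pytest.fixture(scope="session")
def encoded_noext(space_noext, configs_noext):
    return encode_all(configs_noext, space_noext)


@pytest.fixture(scope="session")
def tiny_backbone():
    return BackboneSpec.from_variant("tiny")


@pytest.fixture(scope="session")
def small_dataset():
    """8-class, 50 images/class synthetic dataset at moderate noise."""
    return generate_dataset(SyntheticDatasetSpec(
        num_classes=8, per_class=50, image_size=32, noise_sd=0.3, seed=7))


@pytest.fixture(scope="session")
def small_features(small_dataset, tiny_backbone):
    """Frozen-backbone features for the small dataset's 7:2:1 split."""
    tr, va, te = split_dataset(small_dataset, (7, 2, 1), seed=7)
    Xtr = extract_features(tr.images, tiny_backbone, seed=7)
    Xva = extract_features(va.images, tiny_backbone, seed=7)
    return (Xtr, tr.labels), (Xva, va.labels)
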