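import numpy as np
import pytest
from hypothesis import settings

from ofml import (
    OFMLModel,
    SyntheticSpec,
    generate_synthetic_dataset,
    tiny_config,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """The frozen desk-scale study data: 4 classes x 25 images at 32 px."""
    return generate_synthetic_dataset(SyntheticSpec(n_classes=4, per_class=25, image_size=32, seed=0, keep_masks=True))


@pytest.fixture(scope="session")
def overfit_study(tiny_dataset):
    """Train the full model on the frozen tiny dataset once per session.

    Several behavioural checks (overfit capacity, prediction contracts,
    Grad-CAM localization, loss trajectories) share this fit.
    """
    model = OFMLModel(tiny_dataset, tiny_config(seed=1))
    results = model.fit()
    return {"results": results, "data": tiny_dataset}


@pytest.fixture()
def small_images(rng):
    """A handful of random 32-px images with labels, for plumbing tests."""
    from ofml import LabeledImageSet

    images = [rng.random((32, 32, 3)).astype(np.float32) for _ in range(12)]
    labels = np.array([0, 1, 2, 3] * 3)
    return LabeledImageSet(images, labels, [f"c{k}" for k in range(4)])
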