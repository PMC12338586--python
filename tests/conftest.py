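import numpy as np
import pytest

import ftuscope as ft


@pytest.fixture(scope="session")
def prostate():
    return ft.default_prostate_vocabulary()


@pytest.fixture(scope="session")
def breast():
    return ft.default_breast_vocabulary()


@pytest.fixture(scope="session")
def scene(prostate):
    """One seeded synthetic scene shared by read-only tests."""
    spec = ft.SyntheticSpec(seed=11)
    image, mask, aset = ft.generate(spec, prostate)
    return {"spec": spec, "image": image, "mask": mask, "aset": aset}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_label_mask(rng, shape=(40, 40), n_classes=3, p=0.4):
    """Blobby random multi-class mask for property tests."""
    from scipy import ndimage

    base = rng.random(shape) < p
    base = ndimage.binary_closing(base, structure=np.ones((3, 3)))
    lab, n = ndimage.label(base, structure=np.ones((3, 3)))
    mask = np.zeros(shape, dtype=np.uint16)
    for i in range(1, n + 1):
        mask[lab == i] = int(rng.integers(1, n_classes + 1))
    return mask
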