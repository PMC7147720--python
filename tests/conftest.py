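import numpy as np
import pytest

from lesionfuse import synthfixtures as sf
from lesionfuse.preprocess import DermoscopyImage

#: Small frame used by image-level unit tests (fast to render).
SMALL = (280, 384)


@pytest.fixture(scope="session")
def small_melanoma():
    """One rendered melanoma fixture with its ground-truth lesion mask."""
    rng = np.random.default_rng(7)
    spec = sf.random_spec("melanoma", SMALL, rng)
    img, mask, label = sf.generate_lesion_image(spec, SMALL, seed=7)
    return img, mask, label


@pytest.fixture(scope="session")
def small_nevus():
    rng = np.random.default_rng(8)
    spec = sf.random_spec("common_nevus", SMALL, rng)
    img, mask, label = sf.generate_lesion_image(spec, SMALL, seed=8)
    return img, mask, label


@pytest.fixture
def flat_image():
    """Uniform mid-gray RGB image."""
    return DermoscopyImage(pixels=np.full((40, 56, 3), 128, dtype=np.uint8))


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """The seed-17 ph2-profile dataset run end to end through the pipeline.

    Shared session-wide: generated once, consumed by the end-to-end
    behaviour tests.
    """
    from lesionfuse.config import load_config
    from lesionfuse.pipeline import run_pipeline

    root = tmp_path_factory.mktemp("ph2_seed17")
    manifest = sf.generate_dataset("ph2", root, seed=17)
    report = run_pipeline(manifest, load_config(), seed=17)
    return manifest, report
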