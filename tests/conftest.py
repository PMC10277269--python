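import numpy as np
import pytest
from hypothesis import settings

from usimgen import phantom, preprocess, ussim

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def heart_volume():
    return phantom.make_heart_like_volume(seed=7)


@pytest.fixture(scope="session")
def lesion_volume():
    return phantom.make_lesion_volume(seed=7)


@pytest.fixture(scope="session")
def fast_probe():
    return ussim.ProbeSpec.fast_profile()


@pytest.fixture()
def uniform_template():
    """Flat 20 x 20 mm template at intensity 0.5, 0.2 mm pixels."""
    px = np.full((100, 100), 0.5)
    return preprocess.TemplateImage(px, spacing=(0.2, 0.2))


@pytest.fixture(scope="session")
def cropped_heart_templates(heart_volume):
    slices = preprocess.extract_salient_slices(heart_volume, "target", 8)
    return [
        preprocess.crop_to_fov(preprocess.resample_template(s, 4), 73.0, 45.0)
        for s in slices
    ]
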