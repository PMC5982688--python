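import numpy as np
import pytest

from weightsense.segmentation import SegmentationConfig
from weightsense.synthetic import SceneSpec, SyntheticSubject, render_reference, render_scene


@pytest.fixture(scope="session")
def subject():
    """One mid-sized humanoid used by many geometry tests."""
    return SyntheticSubject(height_m=1.76, girth=1.05, gender="male", person_id=1)


@pytest.fixture(scope="session")
def lying_frame(subject):
    spec = SceneSpec(mode="lying")
    cloud, labels = render_scene(subject, spec, seed=11)
    return spec, cloud, labels


@pytest.fixture(scope="session")
def standing_frame(subject):
    spec = SceneSpec(mode="standing", thermal=False)
    cloud, labels = render_scene(subject, spec, seed=12)
    reference = render_reference(spec, seed=13)
    return spec, cloud, labels, reference


@pytest.fixture()
def seg_cfg():
    return SegmentationConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
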