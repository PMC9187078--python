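import numpy as np
import pytest

from ccemap.classify import make_oracle_classifier
from ccemap.pipeline import process_stills
from ccemap.synthfix import generate_study


@pytest.fixture(scope="session")
def oracle():
    return make_oracle_classifier()


@pytest.fixture(scope="session")
def study_bundle():
    """A full synthetic dual-camera study (4 segments x 5 stills x 2 cameras)."""
    return generate_study(seed=7)


@pytest.fixture(scope="session")
def study_map(study_bundle, oracle):
    """The study processed end-to-end with the oracle classifier."""
    return process_stills(
        study_bundle.stills, oracle, study_id=study_bundle.study_id
    )


@pytest.fixture()
def mid_gray_still():
    """Uniform mid-gray 576x576 still: nothing triggers exclusion."""
    from ccemap.ingest import Camera, Segment, StillPicture

    px = np.full((576, 576, 3), 128, dtype=np.uint8)
    return StillPicture("t", Camera.FORWARD, Segment.TRANSVERSE, 0, px)
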