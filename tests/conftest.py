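import numpy as np
import pytest

from cogniphys.gaze import ROI, ROILayout


@pytest.fixture()
def rois() -> ROILayout:
    return ROILayout(
        [
            ROI("pfd", 0.0, 10.0, 0.0, 10.0),
            ROI("nav", 10.0, 20.0, 0.0, 10.0),
            ROI("radio", 0.0, 10.0, 10.0, 20.0),
        ]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
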