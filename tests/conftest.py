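import numpy as np
import pytest

from leukotrace.detection import Detection
from leukotrace.segmentation import SCHEME, SegmentationMap


def make_detection(frame=0, det_id=0, x=10.0, y=10.0, area=900,
                   fracs=(1.0, 0.0, 0.0), single_multi="unset", est_count=1):
    """Detection stub for tests that do not need a real pixel set."""
    d = Detection(
        frame=frame, det_id=det_id, pixels=np.empty((0, 2), dtype=int),
        area_px=area, centroid=(x, y), radius_px=float(np.sqrt(area / np.pi)),
        class_fractions=fracs, single_multi=single_multi, est_count=est_count,
    )
    d.state = "abluminal" if fracs[2] > 0.5 else "luminal"
    return d


def one_hot_map(labels: np.ndarray, frame: int = 0) -> SegmentationMap:
    """Segmentation map with one-hot probabilities from a label raster."""
    proba = np.zeros((SCHEME.n_classes,) + labels.shape)
    for c in range(SCHEME.n_classes):
        proba[c] = labels == c
    return SegmentationMap(labels=labels.astype(np.uint8), probabilities=proba, frame=frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
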