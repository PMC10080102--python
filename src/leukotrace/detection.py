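"""Per-frame PMN object detection from segmentation maps.

PMN-class pixels (luminal static, luminal probing, transmigrated) are
morphologically linked into 8-connected components; components of 600
pixels or fewer are discarded as noise. Each surviving component becomes a
:class:`Detection` carrying its centroid, area, equivalent disk radius and
the pixel-share of each PMN class, from which the luminal/abluminal state
is decided by the strict >50% transmigrated-pixel rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .segmentation import SCHEME, ClassScheme, SegmentationMap

DEFAULT_MIN_AREA = 600


@dataclass
class Detection:
    """One connected PMN object (cell or cluster) in one frame.

    Coordinates are 0-based with x = column, y = row and pixel centers at
    integer positions; the centroid is the unweighted mean of pixel centers.
    ``class_fractions`` are pixel shares of the three PMN classes (static,
    probing, transmigrated) and sum to 1.
    """

    frame: int
    det_id: int
    pixels: np.ndarray            # (n, 2) array of (row, col)
    area_px: int
    centroid: tuple[float, float]  # (x, y)
    radius_px: float
    class_fractions: tuple[float, float, float]
    state: str = "luminal"         # {"luminal", "abluminal"}
    single_multi: str = "unset"    # {"single", "multiple", "unset"}
    est_count: int = 1

    @property
    def frac_transmigrated(self) -> float:
        return self.class_fractions[2]

    @property
    def luminal_px(self) -> float:
        return self.area_px * (self.class_fractions[0] + self.class_fractions[1])

    @property
    def transmigrated_px(self) -> float:
        return self.area_px * self.class_fractions[2]


def extract_detections(
    seg: SegmentationMap,
    min_area: int = DEFAULT_MIN_AREA,
    scheme: ClassScheme = SCHEME,
) -> list[Detection]:
    """Extract PMN detections from one segmentation map.

    Connected components are computed over the union of the three PMN
    classes with 8-connectivity; components with area strictly greater
    than ``min_area`` are kept (the threshold is a noise floor, so equality
    is discarded). States are assigned immediately from class fractions.
    """
    pmn_mask = np.isin(seg.labels, scheme.pmn_classes)
    labeled, n = measure.label(pmn_mask, connectivity=2, return_num=True)
    detections: list[Detection] = []
    det_id = 0
    for region in measure.regionprops(labeled):
        if region.area <= min_area:
            continue
        coords = region.coords                     # (n, 2) rows, cols
        r_mean, c_mean = region.centroid
        classes = seg.labels[coords[:, 0], coords[:, 1]]
        fracs = tuple(
            float((classes == c).sum()) / region.area
            for c in (scheme.LUMINAL_STATIC, scheme.LUMINAL_PROBING, scheme.TRANSMIGRATED)
        )
        det = Detection(
            frame=seg.frame,
            det_id=det_id,
            pixels=coords,
            area_px=int(region.area),
            centroid=(float(c_mean), float(r_mean)),
            radius_px=math.sqrt(region.area / math.pi),
            class_fractions=fracs,
        )
        detections.append(assign_state(det))
        det_id += 1
    return detections


def assign_state(d: Detection, threshold: float = 0.5) -> Detection:
    """Set a detection's state from its transmigrated-pixel fraction.

    The detection is abluminal iff strictly more than ``threshold`` of its
    pixels carry the transmigrated class; a fraction of exactly 50% stays
    luminal.
    """
    d.state = "abluminal" if d.frac_transmigrated > threshold else "luminal"
    return d


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Tabulate detections; carries both 0-based and 1-based frame indices."""
    rows = [
        {
            "frame": d.frame,
            "frame_1based": d.frame + 1,
            "det_id": d.det_id,
            "area_px": d.area_px,
            "centroid_x": d.centroid[0],
            "centroid_y": d.centroid[1],
            "radius_px": d.radius_px,
            "frac_static": d.class_fractions[0],
            "frac_probing": d.class_fractions[1],
            "frac_transmigrated": d.class_fractions[2],
            "state": d.state,
            "single_multi": d.single_multi,
            "est_count": d.est_count,
        }
        for d in detections
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "frame_1based", "det_id", "area_px", "centroid_x", "centroid_y",
            "radius_px", "frac_static", "frac_probing", "frac_transmigrated",
            "state", "single_multi", "est_count",
        ],
    )
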