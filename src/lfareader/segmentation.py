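"""Strip-label segmentation inside the rectified strip region.

Each strip carries a printed colored label at its top.  The labels are the
only large saturated blobs in the upper half of the strip region, which
makes them reliable anchors: per-channel Otsu thresholding finds colored
(non-white) pixels, a morphological closing and a column-occupancy filter
clean the mask, and contour filters (position, then relative area) reject
line dips, alcohol pads and specks.  Survivors are ordered left-to-right
and matched one-to-one to the declared panel; any mismatch means the
capture cannot be interpreted.

The histogram-extraction window for each strip hangs below the label's
bottom-middle point, scaled from the label size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing

from .config import SegmentationParams, WindowGeometry
from .errors import SegmentationError


@dataclass
class LabeledRegion:
    """One detected strip-label blob and its derived histogram window."""

    strip_id: str
    bbox: tuple[int, int, int, int]        # x, y, w, h (ROI frame)
    centroid: tuple[float, float]          # x, y
    area: float
    bottom_middle: tuple[float, float]     # midpoint of the bbox bottom edge
    histogram_window: tuple[int, int, int, int] | None = None


def _otsu_foreground(channel: np.ndarray) -> np.ndarray:
    """Darker-or-equal-to-threshold pixels; empty for a constant channel.

    ``threshold_otsu`` labels values strictly above the threshold as the
    bright class, so the dark (colored) class includes the threshold value.
    """
    if channel.min() == channel.max():
        return np.zeros(channel.shape, dtype=bool)
    return channel <= threshold_otsu(channel)


def threshold_strips(roi_image: np.ndarray, alcohol_present: bool,
                     params: SegmentationParams | None = None) -> np.ndarray:
    """Binary mask of colored (label) pixels in the rectified ROI.

    Channels are Otsu-binarized independently with foreground = the darker
    class.  Alcohol panels combine the conjunctions (G and B) and (G and R);
    line-only panels take the union of the R and B masks.  A morphological
    closing fills small gaps.
    """
    params = params or SegmentationParams()
    roi = np.asarray(roi_image)
    if roi.ndim != 3 or roi.shape[2] != 3:
        raise SegmentationError("threshold_strips expects an RGB ROI")
    r = _otsu_foreground(roi[:, :, 0])
    g = _otsu_foreground(roi[:, :, 1])
    b = _otsu_foreground(roi[:, :, 2])
    if alcohol_present:
        gb, gr = g & b, g & r
        if params.alcohol_combination == "intersection":
            mask = gb & gr
        else:
            mask = gb | gr
    else:
        mask = r | b
    footprint = np.ones((params.closing_size, params.closing_size), dtype=bool)
    return closing(mask, footprint)


def column_filter(mask: np.ndarray, min_fraction: float = 0.10) -> np.ndarray:
    """Zero out columns whose foreground occupancy is below ``min_fraction``."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    fraction = mask.sum(axis=0) / mask.shape[0]
    out[:, fraction < min_fraction] = False
    return out


def histogram_window(bbox: tuple[int, int, int, int],
                     roi_size: tuple[int, int],
                     geometry: WindowGeometry | None = None):
    """Histogram-extraction rectangle derived from a label bounding box.

    Centered on the label's bottom-middle x, ``width_factor`` of the label
    width (narrower, to dodge strip-edge shadows), spanning from
    ``gap_factor`` label heights below the label down another
    ``length_factor`` label heights; clipped to the ROI.
    """
    geom = geometry or WindowGeometry()
    roi_w, roi_h = roi_size
    x, y, w, h = bbox
    win_w = int(round(geom.width_factor * w))
    cx = x + w / 2.0
    wx = int(round(cx - win_w / 2.0))
    wy = int(round(y + h + geom.gap_factor * h))
    wy2 = int(round(y + h + (geom.gap_factor + geom.length_factor) * h))
    wx0, wx1 = max(wx, 0), min(wx + win_w, roi_w)
    wy0, wy1 = max(wy, 0), min(wy2, roi_h)
    if wx1 - wx0 <= 0 or wy1 - wy0 < 3:
        raise SegmentationError("histogram window degenerate after clipping")
    return (wx0, wy0, wx1 - wx0, wy1 - wy0)


def extract_label_regions(mask: np.ndarray, panel: tuple[str, ...],
                          params: SegmentationParams | None = None,
                          ) -> list[LabeledRegion]:
    """Contour filtering and panel assignment.

    Connected components of the mask are filtered by position (centroid in
    the lower half of the ROI is rejected) and then by relative area
    (``A_i < 0.5 * A_max`` over the remaining contours is rejected).  The
    survivors, ordered left to right, must match the panel one-to-one.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    roi_h, roi_w = mask.shape
    props = regionprops(cc_label(mask, connectivity=2))

    upper = [p for p in props if p.centroid[0] < roi_h / 2.0]
    if not upper:
        raise SegmentationError(
            f"found 0 candidate regions, expected {len(panel)}")
    max_area = max(p.area for p in upper)
    survivors = [p for p in upper if p.area >= 0.5 * max_area]
    survivors.sort(key=lambda p: p.centroid[1])

    if len(survivors) != len(panel):
        raise SegmentationError(
            f"found {len(survivors)} strip labels, expected {len(panel)}")

    regions = []
    for strip_id, p in zip(panel, survivors):
        minr, minc, maxr, maxc = p.bbox
        bbox = (minc, minr, maxc - minc, maxr - minr)
        bottom_middle = (minc + (maxc - minc) / 2.0, float(maxr))
        window = histogram_window(bbox, (roi_w, roi_h), params.window)
        regions.append(LabeledRegion(
            strip_id=strip_id, bbox=bbox,
            centroid=(p.centroid[1], p.centroid[0]),
            area=float(p.area), bottom_middle=bottom_middle,
            histogram_window=window))
    return regions


def segment_roi(roi_image: np.ndarray, panel: tuple[str, ...],
                alcohol_present: bool | None = None,
                params: SegmentationParams | None = None) -> list[LabeledRegion]:
    """Full segmentation chain: threshold -> column filter -> contour filters."""
    from .synthetic import ALCOHOL_STRIP_ID  # shared strip-id convention

    params = params or SegmentationParams()
    if alcohol_present is None:
        alcohol_present = ALCOHOL_STRIP_ID in panel
    mask = threshold_strips(roi_image, alcohol_present, params)
    mask = column_filter(mask, params.column_min_fraction)
    return extract_label_regions(mask, panel, params)
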