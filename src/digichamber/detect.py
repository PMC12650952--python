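"""Microchamber localization in the reference fluorescence channel.

Chambers appear as bright disks of ~10 px diameter on a regular grid.
Detection is a band-pass filter (difference of Gaussians tuned to the
expected disk diameter) followed by local-maximum picking with a minimum
separation, which merges near-duplicates onto the brighter response.
Chambers whose measurement crop would cross the image border are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

#: fraction of the peak band-pass response required to accept a maximum
PEAK_THRESHOLD_FRACTION = 0.3


@dataclass(frozen=True)
class ChamberROI:
    """One detected chamber: center position and measurement geometry.

    Positions are 0-based pixel indices with the pixel-center convention
    (the center of pixel (0, 0) is position (0.0, 0.0)).  The circular
    measurement ROI has ``roi_diameter_px`` (default 10 px) and the square
    crop used for the radius-of-gyration is ``crop_size_px`` on a side
    (default 16 px).
    """

    roi_id: int
    center_x_px: float
    center_y_px: float
    roi_diameter_px: float = 10.0
    crop_size_px: int = 16

    def __post_init__(self) -> None:
        if self.roi_diameter_px > self.crop_size_px:
            raise ValueError("roi_diameter_px must not exceed crop_size_px")


def crop_start(center: float, crop_size: int) -> int:
    """Start index of an axis-aligned crop: nearest pixel minus half the size.

    For a 16-px crop around center 50.0 this gives start 42, i.e. columns
    42..57 inclusive; the nominal center maps to local index 8, within half
    a pixel of the geometric crop center (7.5).
    """
    return int(math.floor(center + 0.5)) - crop_size // 2


def crop_in_bounds(roi: ChamberROI, shape: tuple[int, int]) -> bool:
    n = roi.crop_size_px
    x0 = crop_start(roi.center_x_px, n)
    y0 = crop_start(roi.center_y_px, n)
    return x0 >= 0 and y0 >= 0 and x0 + n <= shape[1] and y0 + n <= shape[0]


def detect_chambers(reference_image: np.ndarray,
                    expected_diameter_px: float = 10.0,
                    min_separation_px: float = 12.0,
                    roi_diameter_px: float = 10.0,
                    crop_size_px: int = 16) -> list[ChamberROI]:
    """Locate chamber-like bright blobs in the reference channel.

    Returns one :class:`ChamberROI` per detected chamber, sorted row-major
    (by y, then x).  Maxima closer than ``min_separation_px`` collapse onto
    the stronger response.  Chambers whose ``crop_size_px`` square crop
    would cross the image border are excluded.  An empty or constant image
    yields an empty list.
    """
    reference_image = np.asarray(reference_image, dtype=float)
    if reference_image.ndim != 2:
        raise ValueError("reference image must be 2D")
    if np.any(reference_image < 0):
        raise ValueError("reference image must be nonnegative")
    if expected_diameter_px < 3:
        raise ValueError("expected_diameter_px must be >= 3")
    if min_separation_px <= expected_diameter_px / 2.0:
        raise ValueError("min_separation_px must exceed expected_diameter_px / 2")

    if reference_image.max() == reference_image.min():
        return []

    # band-pass at the chamber scale: keep structure between ~d/6 and ~d/2
    low_sigma = expected_diameter_px / 6.0
    high_sigma = expected_diameter_px / 2.0
    bandpassed = difference_of_gaussians(reference_image, low_sigma, high_sigma)
    peak = bandpassed.max()
    if peak <= 0:
        return []

    coords = peak_local_max(bandpassed,
                            min_distance=max(1, int(round(min_separation_px))),
                            threshold_abs=PEAK_THRESHOLD_FRACTION * peak,
                            exclude_border=False)
    if coords.size == 0:
        return []

    ys = coords[:, 0].astype(float)
    xs = coords[:, 1].astype(float)
    order = np.lexsort((xs, ys))
    rois = []
    for y, x in zip(ys[order], xs[order]):
        roi = ChamberROI(roi_id=len(rois), center_x_px=float(x), center_y_px=float(y),
                         roi_diameter_px=roi_diameter_px, crop_size_px=crop_size_px)
        if crop_in_bounds(roi, reference_image.shape):
            rois.append(roi)
    return rois


def crop_region(image: np.ndarray, roi: ChamberROI) -> np.ndarray:
    """Axis-aligned square crop around the ROI center; values copied unmodified."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    n = roi.crop_size_px
    x0 = crop_start(roi.center_x_px, n)
    y0 = crop_start(roi.center_y_px, n)
    if x0 < 0 or y0 < 0 or x0 + n > image.shape[1] or y0 + n > image.shape[0]:
        raise ValueError("crop crosses the image border; ROI should have been filtered")
    return image[y0:y0 + n, x0:x0 + n].copy()


def rois_to_frame(rois: list[ChamberROI]) -> pd.DataFrame:
    """ROI list as a DataFrame (roi_id, center_x_px, center_y_px) for CSV export."""
    return pd.DataFrame({
        "roi_id": [r.roi_id for r in rois],
        "center_x_px": [r.center_x_px for r in rois],
        "center_y_px": [r.center_y_px for r in rois],
    })


def match_to_truth(rois: list[ChamberROI], truth_x: np.ndarray, truth_y: np.ndarray,
                   max_dist_px: float = 2.0) -> tuple[int, int, int]:
    """Greedy nearest-neighbor matching of detections to true chamber centers.

    Returns (n_matched, n_spurious_detections, n_missed_truth); a detection
    matches at most one truth center within ``max_dist_px``.
    """
    from scipy.spatial import cKDTree

    if not rois:
        return 0, 0, len(truth_x)
    det = np.array([[r.center_x_px, r.center_y_px] for r in rois])
    tree = cKDTree(np.column_stack([truth_x, truth_y]))
    dist, idx = tree.query(det, distance_upper_bound=max_dist_px)
    taken: set[int] = set()
    matched = 0
    for d, i in sorted(zip(dist, idx)):
        if np.isinf(d) or i in taken:
            continue
        taken.add(i)
        matched += 1
    return matched, len(rois) - matched, len(truth_x) - matched
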