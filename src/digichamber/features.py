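"""Per-chamber features and two-stage positive/negative classification.

Each chamber yields two features from the signal channel: the mean
intensity over a 10-px circular ROI, and the radius of gyration (ROG) of a
16 x 16 px crop — the intensity-weighted RMS distance of the crop's signal
from the crop center.  A genuine amplification-positive chamber is a
bright chamber-sized spot, so its ROG is small; a negative chamber or a
crop dominated by a large diffuse autofluorescent object has near-uniform
intensity and an ROG near the uniform-image value (sqrt(42.5) ~ 6.52 for
16 x 16).

Classification is a two-gate logic tree: a chamber whose ROG exceeds the
ROG threshold is negative (diffuse/uniform); otherwise it is positive iff
its mean intensity exceeds the intensity threshold fitted from a negative
control (Gaussian fit to the intensity histogram, threshold = mean +
k_sd * SD with k_sd = 15 by default).  Ties go negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .detect import ChamberROI, crop_region

logger = logging.getLogger(__name__)

DEFAULT_K_SD = 15.0
DEFAULT_ROG_THRESHOLD_PX = 5.5

POSITIVE = "positive"
NEGATIVE = "negative"


class UndefinedROGError(ValueError):
    """Raised when the ROG is undefined (all-zero crop, m00 = 0)."""


def radius_of_gyration(crop: np.ndarray, subtract_min: bool = False) -> float:
    """ROG of an M x N crop: sqrt((m20 + m02) / m00) in pixels.

    m20 and m02 are the second central moments about the geometric crop
    center ((N-1)/2, (M-1)/2) weighted by raw pixel intensity g(x, y), and
    m00 is the total intensity.  No background subtraction is applied.
    The result is the g-weighted root-mean-square pixel radius: a uniform
    16 x 16 crop gives sqrt(42.5) ~ 6.5192, a centered chamber-sized spot
    gives ~3.5-4, and only intensity concentrated toward the crop's
    corners can exceed the uniform value.

    ``subtract_min`` removes the crop minimum first (optional background
    suppression, off by default to match the raw-moment definition).
    """
    crop = np.asarray(crop, dtype=float)
    if crop.ndim != 2:
        raise ValueError("crop must be 2D")
    if np.any(crop < 0):
        raise ValueError("crop must be nonnegative")
    if subtract_min:
        crop = crop - crop.min()
    m00 = crop.sum()
    if m00 == 0:
        raise UndefinedROGError("all-zero crop: ROG undefined")
    m, n = crop.shape
    x = np.arange(n, dtype=float) - (n - 1) / 2.0
    y = np.arange(m, dtype=float) - (m - 1) / 2.0
    m20 = (crop * (x * x)[None, :]).sum()
    m02 = (crop * (y * y)[:, None]).sum()
    return float(np.sqrt((m20 + m02) / m00))


def uniform_rog(crop_size: int = 16) -> float:
    """ROG of a uniform square crop — what a blank or artifact-filled crop gives."""
    x = np.arange(crop_size, dtype=float) - (crop_size - 1) / 2.0
    return float(np.sqrt(2.0 * np.mean(x * x)))


def mean_roi_intensity(image: np.ndarray, roi: ChamberROI) -> float:
    """Arithmetic mean over pixels whose centers lie within the circular ROI."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    r = roi.roi_diameter_px / 2.0
    cx, cy = roi.center_x_px, roi.center_y_px
    x0 = int(np.floor(cx - r))
    x1 = int(np.ceil(cx + r)) + 1
    y0 = int(np.floor(cy - r))
    y1 = int(np.ceil(cy + r)) + 1
    if x0 < 0 or y0 < 0 or x1 > image.shape[1] or y1 > image.shape[0]:
        raise ValueError("ROI extends outside the image")
    yy = np.arange(y0, y1, dtype=float)[:, None] - cy
    xx = np.arange(x0, x1, dtype=float)[None, :] - cx
    mask = yy * yy + xx * xx <= r * r
    return float(image[y0:y1, x0:x1][mask].mean())


# ---------------------------------------------------------------------------
# threshold fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Classification thresholds and the negative-control fit behind them."""

    intensity_mu: float
    intensity_sigma: float
    k_sd: float = DEFAULT_K_SD
    rog_threshold: float = DEFAULT_ROG_THRESHOLD_PX
    fit_method: str = "manual"
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity_sigma <= 0:
            raise ValueError("intensity_sigma must be positive")

    @property
    def intensity_threshold(self) -> float:
        return self.intensity_mu + self.k_sd * self.intensity_sigma

    def to_dict(self) -> dict:
        return {
            "mu": self.intensity_mu,
            "sigma": self.intensity_sigma,
            "k_sd": self.k_sd,
            "intensity_threshold": self.intensity_threshold,
            "rog_threshold": self.rog_threshold,
            "fit_method": self.fit_method,
            "fit_diagnostics": self.fit_diagnostics,
        }


def rog_threshold_from_negatives(negative_rogs, percentile: float = 0.5) -> float:
    """Data-driven ROG threshold: a low percentile of the negative control's
    ROG distribution, so at most ~percentile% of genuine negatives fall
    below the gate.  Alternative to the fixed 5.5-px default."""
    negative_rogs = np.asarray(negative_rogs, dtype=float)
    negative_rogs = negative_rogs[np.isfinite(negative_rogs)]
    if negative_rogs.size < 100:
        raise ValueError("need >= 100 finite negative-control ROG values")
    return float(np.percentile(negative_rogs, percentile))


def _gaussian(x, amplitude, mu, sigma):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_intensity_threshold(negative_intensities,
                            k_sd: float = DEFAULT_K_SD,
                            rog_threshold: float = DEFAULT_ROG_THRESHOLD_PX
                            ) -> ThresholdSet:
    """Fit mean and SD of the negative-control intensity distribution.

    The values are histogrammed (Freedman-Diaconis bin width) and a
    Gaussian (amplitude, mu, sigma) is least-squares fitted to the bin
    counts; the intensity threshold is mu + k_sd * sigma.  The histogram
    fit locks onto the dominant mode, so a small bright contaminant
    fraction barely moves mu — unlike the plain sample mean.  If the fit
    fails, falls back to median and 1.4826 * MAD with a logged warning;
    a degenerate (zero-spread) sample is an error.
    """
    values = np.asarray(negative_intensities, dtype=float)
    if values.size < 100:
        raise ValueError("need >= 100 negative-control values for a reliable fit")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")

    median = float(np.median(values))
    mad_sigma = 1.4826 * float(np.median(np.abs(values - median)))

    fitted = None
    if values.max() > values.min():
        edges = np.histogram_bin_edges(values, bins="fd")
        if len(edges) >= 4:
            counts, edges = np.histogram(values, bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            p0 = (counts.max(), median, mad_sigma if mad_sigma > 0 else values.std() or 1.0)
            try:
                popt, pcov = curve_fit(_gaussian, centers, counts.astype(float), p0=p0,
                                       maxfev=10000)
                sigma = abs(float(popt[2]))
                if np.isfinite(popt).all() and sigma > 0:
                    fitted = ThresholdSet(
                        intensity_mu=float(popt[1]), intensity_sigma=sigma,
                        k_sd=k_sd, rog_threshold=rog_threshold,
                        fit_method="gaussian_fit",
                        fit_diagnostics={
                            "n": int(values.size),
                            "n_bins": int(len(centers)),
                            "amplitude": float(popt[0]),
                            "perr": [float(e) for e in np.sqrt(np.diag(pcov))],
                        })
            except (RuntimeError, ValueError):
                fitted = None
    if fitted is not None:
        return fitted

    logger.warning("Gaussian histogram fit failed; falling back to median/MAD")
    if mad_sigma <= 0:
        raise ValueError("degenerate negative-control distribution: zero spread")
    return ThresholdSet(intensity_mu=median, intensity_sigma=mad_sigma,
                        k_sd=k_sd, rog_threshold=rog_threshold,
                        fit_method="mad_fallback",
                        fit_diagnostics={"n": int(values.size)})


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberMeasurement:
    """Features of one chamber; ``rog`` is NaN when undefined (all-zero crop)."""

    roi_id: int
    mean_intensity: float
    rog: float
    label: str | None = None
    excluded: bool = False


def classify(measurement: ChamberMeasurement, thresholds: ThresholdSet) -> str:
    """Two-gate logic tree; a pure function of (measurement, thresholds).

    ROG gate first: ROG above the threshold (or undefined) is negative —
    the signal is diffuse, not a chamber-sized spot — regardless of how
    bright it is.  Surviving chambers are positive iff mean intensity is
    strictly above the intensity threshold.  Excluded chambers are always
    negative.
    """
    if measurement.excluded:
        return NEGATIVE
    if not np.isfinite(measurement.rog):
        return NEGATIVE
    if measurement.rog > thresholds.rog_threshold:
        return NEGATIVE
    if measurement.mean_intensity > thresholds.intensity_threshold:
        return POSITIVE
    return NEGATIVE


def measure_chambers(signal_image: np.ndarray,
                     rois: list[ChamberROI]) -> list[ChamberMeasurement]:
    """Mean ROI intensity and crop ROG for every chamber in the signal channel."""
    out = []
    for roi in rois:
        crop = crop_region(signal_image, roi)
        try:
            rog = radius_of_gyration(crop)
        except UndefinedROGError:
            rog = float("nan")
        out.append(ChamberMeasurement(roi_id=roi.roi_id,
                                      mean_intensity=mean_roi_intensity(signal_image, roi),
                                      rog=rog))
    return out


def classify_chambers(measurements: list[ChamberMeasurement],
                      thresholds: ThresholdSet) -> list[ChamberMeasurement]:
    return [replace(m, label=classify(m, thresholds)) for m in measurements]


def apply_exclusions(measurements: list[ChamberMeasurement],
                     exclusion_ids) -> list[ChamberMeasurement]:
    """Flag chambers by roi_id as manually excluded (and relabel them negative).

    Exclusion lists exist for reproducible removal of by-eye false
    positives (bubbles, aggregates); totals downstream report both raw and
    post-exclusion counts.
    """
    ids = set(exclusion_ids)
    known = {m.roi_id for m in measurements}
    unknown = ids - known
    if unknown:
        raise ValueError(f"unknown roi_id(s) in exclusion list: {sorted(unknown)}")
    return [replace(m, excluded=True, label=NEGATIVE) if m.roi_id in ids else m
            for m in measurements]


def measurements_to_frame(measurements: list[ChamberMeasurement],
                          rois: list[ChamberROI] | None = None) -> pd.DataFrame:
    """Per-chamber results table for CSV export."""
    frame = pd.DataFrame({
        "roi_id": [m.roi_id for m in measurements],
        "mean_intensity": [m.mean_intensity for m in measurements],
        "rog": [m.rog for m in measurements],
        "label": [m.label for m in measurements],
        "excluded": [m.excluded for m in measurements],
    })
    if rois is not None:
        pos = pd.DataFrame({
            "roi_id": [r.roi_id for r in rois],
            "center_x_px": [r.center_x_px for r in rois],
            "center_y_px": [r.center_y_px for r in rois],
        })
        frame = pos.merge(frame, on="roi_id")
        frame = frame[["roi_id", "center_x_px", "center_y_px",
                       "mean_intensity", "rog", "label", "excluded"]]
    return frame
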