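"""End-to-end pipelines tying simulation, detection, features and quantification.

The three entry points mirror the assay workflows:

* :func:`run_simulation` — generate a chip (truth + rendered frames).
* :func:`analyze_image` — endpoint analysis of one two-channel image:
  detect chambers in the reference channel, measure intensity and ROG in
  the signal channel, classify against thresholds fitted from a negative
  control, and estimate concentration.
* :func:`analyze_timeseries` — time-lapse analysis: thresholds from the
  first frame of the same series, per-frame positive counts, detection
  and quantification times, endpoint concentration from the last frame.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .detect import ChamberROI, detect_chambers
from .features import (ThresholdSet, apply_exclusions, classify_chambers,
                       fit_intensity_threshold, measure_chambers,
                       measurements_to_frame, POSITIVE)
from .quantify import (InitialStateWarning, QuantResult, TimeCourse,
                       detection_time, quantification_time, summarize_counts)
from .synthetic import AssayTruth, render_timeseries, simulate_loading


@dataclass
class AnalysisResult:
    """Everything one analysis run produces, ready for CSV/JSON export."""

    rois: list[ChamberROI]
    measurements: pd.DataFrame
    thresholds: ThresholdSet
    quant: QuantResult
    timecourse: TimeCourse | None = None
    provenance: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out = self.quant.to_dict()
        out["thresholds"] = self.thresholds.to_dict()
        out["provenance"] = self.provenance
        return out

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def provenance_block(config: RunConfig) -> dict:
    cfg_yaml = config.to_yaml()
    return {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "digichamber_version": __version__,
        "numpy_version": np.__version__,
    }


def run_simulation(config: RunConfig) -> tuple[AssayTruth, np.ndarray, np.ndarray]:
    """Simulate loading and render frames per the config; returns (truth, frames, times)."""
    sim = config.simulation
    truth = simulate_loading(sim.concentration_M, config.geometry,
                             sim.amplification_efficiency, config.kinetics,
                             seed=config.seed)
    if sim.times_min is not None:
        times = np.asarray(sim.times_min, dtype=float)
    else:
        times = np.asarray([sim.endpoint_time_min])
    frames = render_timeseries(truth, config.geometry, times, config.kinetics,
                               config.noise, seed=config.seed)
    return truth, frames, times


def _detect(reference: np.ndarray, config: RunConfig) -> list[ChamberROI]:
    return detect_chambers(reference,
                           expected_diameter_px=config.geometry.diameter_px,
                           min_separation_px=config.min_separation_px,
                           roi_diameter_px=config.analysis.roi_diameter_px,
                           crop_size_px=config.analysis.crop_size_px)


def negative_control_intensities(image: np.ndarray, config: RunConfig) -> np.ndarray:
    """Per-chamber mean signal intensities of a negative-control chip image."""
    ref, sig = _as_two_channel(image)
    rois = _detect(ref, config)
    return np.array([m.mean_intensity for m in measure_chambers(sig, rois)])


def _as_two_channel(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(image)
    if image.ndim == 4:  # (T, 2, H, W): endpoint analysis takes the last frame
        image = image[-1]
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a two-channel image of shape (2, H, W)")
    return image[0], image[1]


def analyze_image(image: np.ndarray, config: RunConfig,
                  thresholds: ThresholdSet | None = None,
                  negative_control_image: np.ndarray | None = None,
                  exclusion_ids=None) -> AnalysisResult:
    """Endpoint analysis of a two-channel chip image.

    Thresholds must come from somewhere: pass a fitted :class:`ThresholdSet`
    directly, or a matched negative-control image to fit mean + k_sd * SD
    from.  ``exclusion_ids`` optionally flags chambers (by roi_id) to drop
    from the positive count, mirroring documented manual exclusion of
    artifact false positives.
    """
    ref, sig = _as_two_channel(image)
    rois = _detect(ref, config)
    measurements = measure_chambers(sig, rois)

    if thresholds is None:
        if negative_control_image is None:
            raise ValueError("provide thresholds or a negative-control image")
        neg = negative_control_intensities(negative_control_image, config)
        thresholds = fit_intensity_threshold(neg, k_sd=config.thresholds.k_sd,
                                             rog_threshold=config.thresholds.rog_threshold)

    measurements = classify_chambers(measurements, thresholds)
    if exclusion_ids:
        measurements = apply_exclusions(measurements, exclusion_ids)

    n_total = len(measurements)
    n_excluded = sum(m.excluded for m in measurements)
    n_positive = sum(m.label == POSITIVE for m in measurements)
    quant = summarize_counts(n_total, n_positive, n_excluded,
                             config.geometry.chamber_volume_L)
    return AnalysisResult(rois=rois,
                          measurements=measurements_to_frame(measurements, rois),
                          thresholds=thresholds, quant=quant,
                          provenance=provenance_block(config))


def analyze_timeseries(frames: np.ndarray, times, config: RunConfig,
                       thresholds: ThresholdSet | None = None) -> AnalysisResult:
    """Time-lapse analysis of a (T, 2, H, W) series.

    Chamber positions come from the first frame's reference channel (the
    chip does not move).  Unless supplied, classification thresholds are
    fitted from the first frame's own signal intensities — at t = 0 no
    chamber has turned on, so the first frame is its own negative control.
    """
    frames = np.asarray(frames)
    times = np.asarray(times, dtype=float)
    if frames.ndim != 4 or frames.shape[0] != times.size:
        raise ValueError("frames must be (T, 2, H, W) matching the time vector")
    if frames.shape[0] < 2:
        raise ValueError("time-lapse analysis needs at least two frames")

    rois = _detect(frames[0, 0], config)
    if thresholds is None:
        first = [m.mean_intensity for m in measure_chambers(frames[0, 1], rois)]
        thresholds = fit_intensity_threshold(np.asarray(first),
                                             k_sd=config.thresholds.k_sd,
                                             rog_threshold=config.thresholds.rog_threshold)

    counts = []
    last_measurements = None
    for t in range(frames.shape[0]):
        measurements = classify_chambers(measure_chambers(frames[t, 1], rois),
                                         thresholds)
        counts.append(sum(m.label == POSITIVE for m in measurements))
        last_measurements = measurements

    tc = TimeCourse(times_min=times, positive_counts=np.asarray(counts),
                    n_total=len(rois),
                    frame_interval_min=config.analysis.frame_interval_min)

    warn_msgs: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", InitialStateWarning)
        det_t = detection_time(tc, initial_max=config.analysis.detection_initial_max,
                               trigger=config.analysis.detection_trigger)
        warn_msgs.extend(str(w.message) for w in caught)
    quant_t = (quantification_time(tc, det_t,
                                   rel_change=config.analysis.quantification_rel_change)
               if det_t is not None else None)

    n_total = len(rois)
    quant = summarize_counts(n_total, counts[-1], 0, config.geometry.chamber_volume_L)
    quant.detection_time_min = det_t
    quant.quantification_time_min = quant_t
    quant.warnings = warn_msgs
    return AnalysisResult(rois=rois,
                          measurements=measurements_to_frame(last_measurements, rois),
                          thresholds=thresholds, quant=quant, timecourse=tc,
                          provenance=provenance_block(config))
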