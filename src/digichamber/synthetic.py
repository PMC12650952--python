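"""Synthetic microchamber-chip image generator with known ground truth.

Emulates the data produced by a femtoliter-well digital nucleic-acid
amplification assay: a regular grid of cylindrical microchambers imaged in
two fluorescence channels.  The *reference* channel contains a passive dye
that marks every chamber; the *signal* channel reports amplification, so
only chambers that received at least one template molecule (and amplified
successfully) light up, with a sigmoidal onset in time.

The generator is the forward model of the analysis pipeline: template
molecules are Poisson-distributed over chambers with mean occupancy
``lambda = c * V * N_A`` (concentration times chamber volume times
Avogadro's number), which is exactly the loading law the concentration
estimators invert.  Ground truth (per-chamber template count, positivity,
onset time) is returned alongside the images so detection and
classification can be scored.

All randomness flows from one integer seed through named sub-streams
(loading, onset, artifacts, per-frame noise), so identical seeds give
bit-identical truth tables and images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc, expit

AVOGADRO = 6.02214076e23  # mol^-1 (exact, SI)
UM3_TO_L = 1e-15

#: margin of blank pixels around the chamber grid in rendered images
GRID_MARGIN_PX = 12

#: amplitude of the reference-channel chamber disks above background (a.u.)
REF_AMPLITUDE = 500.0

#: 1-sigma width of the soft disk edge, emulating optical blur (px)
EDGE_SIGMA_PX = 1.0


# ---------------------------------------------------------------------------
# geometry and model parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipGeometry:
    """Physical layout of the microchamber array and the imaging scale.

    Defaults describe a chip with cylindrical chambers of 4.2 um diameter
    (midpoint of the fabricated 4.0-4.4 um range) and 3.15 um depth
    (midpoint of 3.0-3.3 um) on a 9 um pitch, imaged at 0.42 um/px so a
    chamber appears as a disk of ~10 px diameter.  The default field of
    view holds 100 x 100 = 10,000 chambers.
    """

    chamber_diameter_um: float = 4.2
    chamber_depth_um: float = 3.15
    pitch_um: float = 9.0
    n_rows: int = 100
    n_cols: int = 100
    pixel_size_um: float = 0.42

    def __post_init__(self) -> None:
        for name in ("chamber_diameter_um", "chamber_depth_um", "pitch_um",
                     "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.chamber_diameter_um >= self.pitch_um:
            raise ValueError("chamber diameter must be smaller than pitch")

    @property
    def diameter_px(self) -> float:
        return self.chamber_diameter_um / self.pixel_size_um

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_size_um

    @property
    def n_chambers(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def chamber_volume_L(self) -> float:
        """Cylinder volume pi*(d/2)^2*h converted from um^3 to liters."""
        r = self.chamber_diameter_um / 2.0
        return math.pi * r * r * self.chamber_depth_um * UM3_TO_L

    def image_shape(self, margin_px: int = GRID_MARGIN_PX) -> tuple[int, int]:
        """(height, width) of an image covering the grid plus a margin."""
        h = 2 * (margin_px + self.pitch_px / 2.0) + (self.n_rows - 1) * self.pitch_px
        w = 2 * (margin_px + self.pitch_px / 2.0) + (self.n_cols - 1) * self.pitch_px
        return int(math.ceil(h)), int(math.ceil(w))

    def chamber_centers(self, margin_px: int = GRID_MARGIN_PX
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Grid indices and pixel centers (row, col, x, y), row-major order."""
        rows, cols = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols),
                                 indexing="ij")
        rows = rows.ravel()
        cols = cols.ravel()
        origin = margin_px + self.pitch_px / 2.0
        x = origin + cols * self.pitch_px
        y = origin + rows * self.pitch_px
        return rows, cols, x, y


@dataclass(frozen=True)
class KineticsModel:
    """Sigmoidal fluorescence-onset kinetics of an amplification-positive chamber.

    Per-chamber signal amplitude at time t is
    ``baseline + (plateau - baseline) * sigmoid((t - onset) / rise_tau)``
    where the onset time is drawn per chamber from
    Normal(onset_mean_min, onset_sd_min), truncated at zero.  Defaults
    (onset 10 +/- 3 min, rise 2 min) give time courses in which the
    positive count rises detectably within ~8 min and saturates well
    before 30 min.
    """

    baseline: float = 0.0
    plateau: float = 600.0
    onset_mean_min: float = 10.0
    onset_sd_min: float = 3.0
    rise_tau_min: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be nonnegative")
        if self.plateau <= self.baseline:
            raise ValueError("plateau must exceed baseline")
        if self.onset_sd_min < 0:
            raise ValueError("onset_sd_min must be nonnegative")
        if self.rise_tau_min <= 0:
            raise ValueError("rise_tau_min must be positive")

    def amplitude(self, time_min, onset_min):
        """Disk amplitude of a positive chamber at ``time_min``."""
        z = (np.asarray(time_min, dtype=float) - np.asarray(onset_min, dtype=float))
        return self.baseline + (self.plateau - self.baseline) * expit(z / self.rise_tau_min)


@dataclass(frozen=True)
class NoiseModel:
    """Camera/background noise and diffuse autofluorescent artifacts.

    ``artifact_rate`` is the expected number of large bright blobs per
    image, emulating autofluorescence from air bubbles or aggregates;
    artifact diameters always exceed the chamber diameter so they fill a
    chamber crop nearly uniformly.  Shot noise applies a Poisson draw to
    the noise-free intensity (photon counting); read noise is additive
    Gaussian.
    """

    read_noise_sd: float = 2.0
    background_level: float = 100.0
    shot_noise_enabled: bool = True
    artifact_rate: float = 0.0
    artifact_diameter_px_range: tuple[float, float] = (20.0, 60.0)
    artifact_intensity_range: tuple[float, float] = (50.0, 200.0)

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be nonnegative")
        lo, hi = self.artifact_diameter_px_range
        if not (0 < lo <= hi):
            raise ValueError("invalid artifact diameter range")
        lo, hi = self.artifact_intensity_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid artifact intensity range")


NOISELESS = NoiseModel(read_noise_sd=0.0, background_level=0.0,
                       shot_noise_enabled=False, artifact_rate=0.0)

TRUTH_COLUMNS = ["row", "col", "center_x_px", "center_y_px", "n_templates",
                 "is_positive", "onset_time_min", "covered_by_artifact"]


@dataclass
class AssayTruth:
    """Per-chamber ground truth of a simulated chip loading.

    ``table`` has one row per chamber with columns row, col, center_x_px,
    center_y_px, n_templates, is_positive, onset_time_min (NaN for
    negatives) and covered_by_artifact.  ``lam`` is the expected
    per-chamber occupancy c*V*N_A, so the occupied fraction converges to
    1 - exp(-lam) as the chamber count grows.
    """

    table: pd.DataFrame
    concentration_M: float
    lam: float

    @property
    def n_chambers(self) -> int:
        return len(self.table)

    @property
    def n_positive(self) -> int:
        return int(self.table["is_positive"].sum())

    @property
    def occupied_fraction(self) -> float:
        return float((self.table["n_templates"] >= 1).mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def read_csv(path, concentration_M: float = float("nan"),
                 lam: float = float("nan")) -> "AssayTruth":
        table = pd.read_csv(path)
        missing = set(TRUTH_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        return AssayTruth(table=table, concentration_M=concentration_M, lam=lam)


# ---------------------------------------------------------------------------
# seeding helpers: named sub-streams off one base seed
# ---------------------------------------------------------------------------

_STREAM_LOADING = 0
_STREAM_ONSET = 1
_STREAM_ARTIFACTS = 2
_STREAM_FRAME_NOISE = 3


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream, *map(int, extra)])


# ---------------------------------------------------------------------------
# Poisson loading
# ---------------------------------------------------------------------------

def simulate_loading(concentration: float,
                     geometry: ChipGeometry | None = None,
                     amplification_efficiency: float = 1.0,
                     kinetics: KineticsModel | None = None,
                     seed: int = 0) -> AssayTruth:
    """Poisson-load template molecules into chambers and assign onset times.

    Parameters
    ----------
    concentration : float
        Template concentration in mol/L.  Expected occupancy per chamber is
        ``lambda = concentration * chamber_volume_L * AVOGADRO``.
    amplification_efficiency : float
        Probability that a chamber holding >= 1 template actually turns
        fluorescence-positive.  1.0 models ideal amplification.
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if not 0.0 <= amplification_efficiency <= 1.0:
        raise ValueError("amplification_efficiency must lie in [0, 1]")
    geometry = geometry or ChipGeometry()
    kinetics = kinetics or KineticsModel()

    rows, cols, x, y = geometry.chamber_centers()
    n = geometry.n_chambers
    lam = concentration * geometry.chamber_volume_L * AVOGADRO

    n_templates = _rng(seed, _STREAM_LOADING).poisson(lam, size=n)
    success = _rng(seed, _STREAM_LOADING, 1).random(n) < amplification_efficiency
    is_positive = (n_templates >= 1) & success

    onset = np.full(n, np.nan)
    draws = _rng(seed, _STREAM_ONSET).normal(kinetics.onset_mean_min,
                                             kinetics.onset_sd_min, size=n)
    onset[is_positive] = np.clip(draws[is_positive], 0.0, None)

    table = pd.DataFrame({
        "row": rows, "col": cols,
        "center_x_px": x, "center_y_px": y,
        "n_templates": n_templates,
        "is_positive": is_positive,
        "onset_time_min": onset,
        "covered_by_artifact": np.zeros(n, dtype=bool),
    })
    return AssayTruth(table=table, concentration_M=concentration, lam=lam)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_soft_disk(img: np.ndarray, cx: float, cy: float, radius: float,
                   amplitude: float, edge_sigma: float = EDGE_SIGMA_PX) -> None:
    """Add a disk with a Gaussian-softened edge (erfc profile) in place."""
    if amplitude == 0.0:
        return
    h, w = img.shape
    pad = int(math.ceil(radius + 4 * edge_sigma))
    x0 = max(int(math.floor(cx)) - pad, 0)
    x1 = min(int(math.ceil(cx)) + pad + 1, w)
    y0 = max(int(math.floor(cy)) - pad, 0)
    y1 = min(int(math.ceil(cy)) + pad + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy = np.arange(y0, y1, dtype=float)[:, None] - cy
    xx = np.arange(x0, x1, dtype=float)[None, :] - cx
    r = np.sqrt(yy * yy + xx * xx)
    img[y0:y1, x0:x1] += amplitude * 0.5 * erfc((r - radius) / (math.sqrt(2) * edge_sigma))


def _add_gaussian_blob(img: np.ndarray, cx: float, cy: float, diameter: float,
                       amplitude: float) -> None:
    """Add a diffuse Gaussian blob (sigma = diameter/4) in place."""
    sigma = diameter / 4.0
    h, w = img.shape
    pad = int(math.ceil(3 * sigma))
    x0 = max(int(math.floor(cx)) - pad, 0)
    x1 = min(int(math.ceil(cx)) + pad + 1, w)
    y0 = max(int(math.floor(cy)) - pad, 0)
    y1 = min(int(math.ceil(cy)) + pad + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy = np.arange(y0, y1, dtype=float)[:, None] - cy
    xx = np.arange(x0, x1, dtype=float)[None, :] - cx
    img[y0:y1, x0:x1] += amplitude * np.exp(-(yy * yy + xx * xx) / (2 * sigma * sigma))


def _draw_artifacts(noise: NoiseModel, shape: tuple[int, int],
                    rng: np.random.Generator) -> pd.DataFrame:
    n_art = rng.poisson(noise.artifact_rate)
    h, w = shape
    return pd.DataFrame({
        "center_x_px": rng.uniform(0, w, size=n_art),
        "center_y_px": rng.uniform(0, h, size=n_art),
        "diameter_px": rng.uniform(*noise.artifact_diameter_px_range, size=n_art),
        "intensity": rng.uniform(*noise.artifact_intensity_range, size=n_art),
    })


def render_frame(truth: AssayTruth,
                 geometry: ChipGeometry | None = None,
                 time_min: float = 30.0,
                 kinetics: KineticsModel | None = None,
                 noise: NoiseModel | None = None,
                 seed: int = 0,
                 frame_index: int = 0,
                 ref_amplitude: float = REF_AMPLITUDE) -> np.ndarray:
    """Render a two-channel (reference, signal) image of the chip at ``time_min``.

    Returns a float array of shape (2, H, W).  Channel 0 (reference) shows
    every chamber as a uniform soft-edged disk above background; channel 1
    (signal) shows positives at their kinetic amplitude and negatives at
    the kinetic baseline.  Artifacts are drawn from a sub-stream that
    depends only on the base seed, so all frames of a time series share
    one static artifact field; per-frame noise uses ``frame_index`` and is
    independent between frames.  Chambers lying under an artifact are
    flagged in ``truth.table['covered_by_artifact']`` as a side effect.
    """
    if time_min < 0:
        raise ValueError("time_min must be nonnegative")
    geometry = geometry or ChipGeometry()
    kinetics = kinetics or KineticsModel()
    noise = noise or NoiseModel()
    shape = geometry.image_shape()
    if min(shape) < 2 * GRID_MARGIN_PX:
        raise ValueError("geometry too small to place the chamber grid")

    tbl = truth.table
    ref = np.zeros(shape)
    sig = np.zeros(shape)
    radius = geometry.diameter_px / 2.0

    pos = tbl["is_positive"].to_numpy()
    amp = np.full(len(tbl), kinetics.baseline, dtype=float)
    amp[pos] = kinetics.amplitude(time_min, tbl.loc[pos, "onset_time_min"].to_numpy())

    xs = tbl["center_x_px"].to_numpy()
    ys = tbl["center_y_px"].to_numpy()
    for cx, cy, a in zip(xs, ys, amp):
        _add_soft_disk(ref, cx, cy, radius, ref_amplitude)
        if a > 0.0:
            _add_soft_disk(sig, cx, cy, radius, a)

    artifacts = _draw_artifacts(noise, shape, _rng(seed, _STREAM_ARTIFACTS))
    if len(artifacts):
        covered = np.zeros(len(tbl), dtype=bool)
        for art in artifacts.itertuples():
            _add_gaussian_blob(ref, art.center_x_px, art.center_y_px,
                               art.diameter_px, art.intensity)
            _add_gaussian_blob(sig, art.center_x_px, art.center_y_px,
                               art.diameter_px, art.intensity)
            d2 = (xs - art.center_x_px) ** 2 + (ys - art.center_y_px) ** 2
            covered |= d2 <= (art.diameter_px / 2.0) ** 2
        tbl["covered_by_artifact"] = tbl["covered_by_artifact"].to_numpy() | covered

    img = np.stack([ref, sig]) + noise.background_level
    rng = _rng(seed, _STREAM_FRAME_NOISE, frame_index)
    if noise.shot_noise_enabled:
        img = rng.poisson(img).astype(float)
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_timeseries(truth: AssayTruth,
                      geometry: ChipGeometry | None = None,
                      times: "list[float] | np.ndarray" = (),
                      kinetics: KineticsModel | None = None,
                      noise: NoiseModel | None = None,
                      seed: int = 0,
                      ref_amplitude: float = REF_AMPLITUDE) -> np.ndarray:
    """Render one two-channel frame per time point; shape (T, 2, H, W).

    Chamber positions, onset times and the artifact field are identical
    across frames; only the camera noise is redrawn per frame.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be a nonempty list")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    frames = [render_frame(truth, geometry, t, kinetics, noise,
                           seed=seed, frame_index=i, ref_amplitude=ref_amplitude)
              for i, t in enumerate(times)]
    return np.stack(frames)


# ---------------------------------------------------------------------------
# TIFF output
# ---------------------------------------------------------------------------

def write_tiff(path, frames: np.ndarray) -> None:
    """Write frames as multi-page 16-bit TIFF, pages ordered (t0 ref, t0 sig, t1 ref, ...)."""
    import tifffile

    frames = np.asarray(frames)
    if frames.ndim == 3:  # single time point (2, H, W)
        frames = frames[None]
    if frames.ndim != 4 or frames.shape[1] != 2:
        raise ValueError("expected frames of shape (T, 2, H, W) or (2, H, W)")
    t, c, h, w = frames.shape
    pages = np.clip(np.round(frames), 0, 65535).astype(np.uint16).reshape(t * c, h, w)
    tifffile.imwrite(path, pages)


def read_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF written by :func:`write_tiff`; returns (T, 2, H, W) float."""
    import tifffile

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise ValueError("expected an interleaved two-channel stack, got a single page")
    if pages.shape[0] % 2 != 0:
        raise ValueError("page count must be even (reference, signal per time point)")
    t = pages.shape[0] // 2
    return pages.reshape(t, 2, *pages.shape[1:]).astype(float)
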