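"""Pupil and corneal-reflection detection in grayscale ocular images.

A video eye tracker locates two landmarks in each camera frame: the dark pupil
and the bright first-surface corneal reflection of the IR illuminator (the
Purkinje image). Their displacement (U, V) = purkinje − pupil, in camera
pixels, is approximately invariant to small head translations and varies with
eye rotation, which makes it the regressor of the gaze calibration model.

Detection is deliberately simple: double thresholding, connected components,
and an intensity-weighted sub-pixel centroid with an area gate on the pupil.
No ellipse fitting is attempted.

Coordinates: sub-pixel centers are (x, y) with x the column and y the row,
origin at the top-left pixel center, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "ImagingConfig",
    "RenderConfig",
    "EyeFeatures",
    "detect_pupil",
    "detect_purkinje",
    "extract_features",
    "render_eye_image",
    "load_image",
    "save_image",
]


@dataclass
class ImagingConfig:
    """Detection thresholds and gates.

    dark_threshold / bright_threshold are 8-bit intensity levels; a pupil
    candidate's pixel count must fall within pupil_area_range; the Purkinje
    search is restricted to glint_roi_radius pixels around the pupil center.
    """

    dark_threshold: float = 80.0
    bright_threshold: float = 200.0
    pupil_area_range: tuple[int, int] = (100, 20000)
    glint_roi_radius: float = 60.0


@dataclass(frozen=True)
class EyeFeatures:
    """Per-frame detection result; (U, V) = purkinje_center − pupil_center."""

    pupil_center: Optional[tuple[float, float]]
    purkinje_center: Optional[tuple[float, float]]
    U: float
    V: float
    ok: bool


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("ocular image must be a 2-D grayscale array")
    return img.astype(float)


def _weighted_centroid(weights: np.ndarray) -> tuple[float, float]:
    """(x, y) centroid of a nonnegative weight map."""
    total = weights.sum()
    rows, cols = np.nonzero(weights)
    w = weights[rows, cols]
    return (float((cols * w).sum() / total), float((rows * w).sum() / total))


def detect_pupil(
    img: np.ndarray,
    dark_threshold: float,
    area_range: tuple[int, int] = (100, 20000),
) -> Optional[tuple[float, float]]:
    """Locate the pupil center, or return None on failure.

    Pixels strictly darker than ``dark_threshold`` are grouped into connected
    components (8-connectivity); of the components whose pixel count lies in
    ``area_range`` the largest is taken, and its sub-pixel center is the
    centroid weighted by darkness (threshold − intensity), which uses the
    anti-aliased pupil edge for sub-pixel accuracy. The corneal glint often
    lies over the pupil and punches a bright hole in the dark component; holes
    are filled at full interior weight so the occlusion does not bias the
    centroid.
    """
    img = _check_image(img)
    mask = img < dark_threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    lo, hi = area_range
    candidates = [i + 1 for i, a in enumerate(areas) if lo <= a <= hi]
    if not candidates:
        return None
    best = max(candidates, key=lambda lab: areas[lab - 1])
    comp = labels == best
    weights = np.where(comp, np.clip(dark_threshold - img, 0.0, None), 0.0)
    holes = ndimage.binary_fill_holes(comp) & ~comp
    if np.any(holes):
        weights[holes] = weights.max()
    return _weighted_centroid(weights)


def detect_purkinje(
    img: np.ndarray,
    bright_threshold: float,
    roi_center: tuple[float, float],
    roi_radius: float,
) -> Optional[tuple[float, float]]:
    """Locate the corneal glint inside a circular ROI, or None on failure.

    Among connected components of pixels strictly brighter than
    ``bright_threshold`` within the ROI, the one with the highest peak
    intensity wins (ties broken by integrated brightness); its center is the
    centroid weighted by (intensity − threshold).
    """
    img = _check_image(img)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    roi = (xx - roi_center[0]) ** 2 + (yy - roi_center[1]) ** 2 <= roi_radius**2
    mask = (img > bright_threshold) & roi
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    peaks = ndimage.maximum(img, labels, index=np.arange(1, n + 1))
    sums = ndimage.sum_labels(img, labels, index=np.arange(1, n + 1))
    best = max(range(1, n + 1), key=lambda lab: (peaks[lab - 1], sums[lab - 1]))
    weights = np.where(labels == best, img - bright_threshold, 0.0)
    return _weighted_centroid(weights)


def extract_features(img: np.ndarray, cfg: ImagingConfig) -> EyeFeatures:
    """Run both detectors on one frame and form (U, V).

    Failure of either detector yields ``ok=False`` with NaN features; the
    glint search ROI is centered on the detected pupil, mirroring the physical
    arrangement (the reflection sits on the cornea over the pupil).
    """
    pupil = detect_pupil(img, cfg.dark_threshold, cfg.pupil_area_range)
    if pupil is None:
        return EyeFeatures(None, None, float("nan"), float("nan"), False)
    glint = detect_purkinje(img, cfg.bright_threshold, pupil, cfg.glint_roi_radius)
    if glint is None:
        return EyeFeatures(pupil, None, float("nan"), float("nan"), False)
    return EyeFeatures(pupil, glint, glint[0] - pupil[0], glint[1] - pupil[1], True)


# ---------------------------------------------------------------------------
# Synthetic ocular-image rendering (test fixture generator)


@dataclass
class RenderConfig:
    """Parameters of the synthetic eye image.

    Intensities are 8-bit levels: a mid-gray iris background, a dark pupil
    disk with an analytically anti-aliased edge, and a Gaussian glint added on
    top. ``noise_sd`` adds i.i.d. Gaussian pixel noise (seeded).
    """

    width: int = 320
    height: int = 240
    background: float = 128.0
    pupil_intensity: float = 20.0
    pupil_radius: float = 30.0
    glint_amplitude: float = 235.0
    glint_sigma: float = 2.0
    noise_sd: float = 0.0
    seed: Optional[int] = None
    render_glint: bool = True


def render_eye_image(
    pupil: tuple[float, float],
    glint: tuple[float, float],
    cfg: RenderConfig,
) -> np.ndarray:
    """Render a synthetic ocular frame as a uint8 array.

    ``pupil`` and ``glint`` are sub-pixel (x, y) centers and must lie inside
    the frame. With ``noise_sd=0`` the image is deterministic; with a seed the
    noisy image is reproducible.
    """
    for name, (cx, cy) in (("pupil", pupil), ("glint", glint)):
        if not (0 <= cx < cfg.width and 0 <= cy < cfg.height):
            raise ValueError(f"{name} center {cx, cy} outside the frame")
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width].astype(float)

    d_pupil = np.hypot(xx - pupil[0], yy - pupil[1])
    coverage = np.clip(cfg.pupil_radius + 0.5 - d_pupil, 0.0, 1.0)
    img = cfg.background + coverage * (cfg.pupil_intensity - cfg.background)

    if cfg.render_glint:
        d2 = (xx - glint[0]) ** 2 + (yy - glint[1]) ** 2
        img = img + cfg.glint_amplitude * np.exp(-d2 / (2.0 * cfg.glint_sigma**2))

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def save_image(img: np.ndarray, path) -> None:
    """Write an 8-bit grayscale PNG fixture."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG fixture."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.uint8)
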