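"""Trap-site image quantitation.

Two image operations support the acoustic-trapping workflow:

* **Yellow-pixel aggregate scoring** — the size of the fluorescent-bead
  aggregate at the trap site is scored as the number of pixels whose
  hue/saturation/brightness fall in a yellow window; the drive frequency
  whose frame scores highest is the visually-optimal trapping frequency.
* **CIELAB contrast boost + hue rotation** — a chroma manipulation that
  pulls the shadow of a trapped cell aggregate out of a low-contrast
  brightfield frame: in L*a*b* space the (a, b) chroma vectors are scaled
  about the image-mean chroma, then rotated about the origin, leaving L*
  untouched. Mean-centred scaling keeps neutral scenes neutral.

Frames are 8-bit RGB arrays (row-major, origin top-left), interpreted as
sRGB with the D65 white point; scikit-image provides the fixed conversion
constants, so conversions are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor
from skimage.draw import ellipse as _ellipse

__all__ = [
    "ColorAdjustSpec",
    "rgb_to_lab",
    "lab_to_rgb",
    "color_adjust",
    "yellow_pixel_count",
    "best_frequency_by_image",
    "synth_trap_frame",
]


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3 or frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"expected a non-empty HxWx3 RGB raster, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError(f"expected an 8-bit (uint8) frame, got dtype {frame.dtype}")
    return frame


def rgb_to_lab(frame: np.ndarray) -> np.ndarray:
    """8-bit sRGB frame -> CIELAB (float, D65 white point)."""
    return _skcolor.rgb2lab(_check_frame(frame) / 255.0)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """CIELAB image -> 8-bit sRGB frame; out-of-gamut values are clipped."""
    import warnings

    with warnings.catch_warnings():
        # gamut clipping after a large chroma boost is expected behaviour
        warnings.filterwarnings("ignore", message="Conversion from CIE-LAB")
        rgb = _skcolor.lab2rgb(np.asarray(lab, dtype=float))
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ColorAdjustSpec:
    """Chroma contrast factor and hue rotation (degrees, CCW positive)."""

    contrast: float = 14.09
    rotation_deg: float = -90.0

    def __post_init__(self) -> None:
        if not self.contrast > 0:
            raise ValueError(f"contrast must be positive, got {self.contrast!r}")


def color_adjust(frame: np.ndarray, spec: ColorAdjustSpec) -> np.ndarray:
    """Boost chroma contrast and rotate hue in CIELAB; L* is unchanged.

    The (a, b) vector of each pixel is scaled by ``spec.contrast`` about the
    image-mean (a, b), then rotated by ``spec.rotation_deg`` about the
    origin. Results outside the sRGB gamut are clipped on conversion back.
    """
    lab = rgb_to_lab(frame)
    a, b = lab[..., 1], lab[..., 2]
    mean_a, mean_b = float(a.mean()), float(b.mean())
    a_scaled = mean_a + spec.contrast * (a - mean_a)
    b_scaled = mean_b + spec.contrast * (b - mean_b)
    theta = math.radians(spec.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    lab_out = lab.copy()
    lab_out[..., 1] = cos_t * a_scaled - sin_t * b_scaled
    lab_out[..., 2] = sin_t * a_scaled + cos_t * b_scaled
    return lab_to_rgb(lab_out)


def yellow_pixel_count(
    frame: np.ndarray,
    hue_window: tuple[float, float] = (40.0, 70.0),
    min_saturation: float = 0.3,
    min_brightness: float = 0.3,
) -> int:
    """Number of yellow pixels: HSB hue in ``hue_window`` (degrees), S and B floors.

    The saturation/brightness floors reject the grey channel background and
    dim noise so the count tracks the fluorescent-bead aggregate.
    """
    hsv = _skcolor.rgb2hsv(_check_frame(frame) / 255.0)
    hue_deg = hsv[..., 0] * 360.0
    lo, hi = hue_window
    mask = (
        (hue_deg >= lo)
        & (hue_deg <= hi)
        & (hsv[..., 1] >= min_saturation)
        & (hsv[..., 2] >= min_brightness)
    )
    return int(mask.sum())


def best_frequency_by_image(frames: dict, **count_kwargs) -> float:
    """Frequency whose frame has the largest yellow-pixel count.

    ``frames`` maps drive frequency -> RGB frame. Ties resolve toward the
    lower frequency, consistent with the voltage-scan controller.
    """
    if not frames:
        raise ValueError("need at least one frame")
    best_f = None
    best_count = -1
    for frequency in sorted(frames):
        count = yellow_pixel_count(frames[frequency], **count_kwargs)
        if count > best_count:
            best_f, best_count = frequency, count
    return best_f


def synth_trap_frame(
    area_px: float,
    shape: tuple[int, int] = (200, 200),
    seed: int | None = None,
    noise_sigma: float = 5.0,
    background: int = 60,
    aspect: float = 2.0,
) -> np.ndarray:
    """Synthetic trap-site still: grey background + centred yellow aggregate.

    An elliptical "aggregate" of roughly ``area_px`` pixels (aspect ratio
    ``aspect``, long axis along the channel) is drawn in fluorescent-bead
    yellow on a grey channel background, and seeded Gaussian pixel noise is
    added. :func:`yellow_pixel_count` recovers ``area_px`` to within a few
    percent (ellipse rasterisation error plus noise at the rim).
    """
    if area_px < 0:
        raise ValueError(f"area must be non-negative, got {area_px!r}")
    rows, cols = shape
    frame = np.full((rows, cols, 3), float(background))
    if area_px > 0:
        semi_minor = math.sqrt(area_px / (math.pi * aspect))
        semi_major = aspect * semi_minor
        if 2 * semi_major > min(rows, cols):
            raise ValueError(
                f"aggregate of {area_px} px does not fit a {rows}x{cols} frame"
            )
        rr, cc = _ellipse(rows / 2.0, cols / 2.0, semi_minor, semi_major, shape=(rows, cols))
        frame[rr, cc] = (230.0, 220.0, 30.0)
    rng = np.random.default_rng(seed)
    frame += rng.normal(0.0, noise_sigma, size=frame.shape)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)
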