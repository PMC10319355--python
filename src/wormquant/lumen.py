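"""Intestinal luminal width in the posterior gut.

The intestinal lumen appears as a darker band along the body axis. Luminal
width is reported as the average of width measurements at two transects in
the posterior intestine (defaults: normalized arc positions 0.70 and 0.85).
A manual mode (:func:`average_lumen_width`) accepts externally measured
widths, mirroring hand measurement in an image viewer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import LumenBandError
from .morphometry import CalibratedImage, Midline

__all__ = ["LumenMeasurement", "LumenConfig", "average_lumen_width", "measure_lumen"]

DEFAULT_POSITIONS = (0.70, 0.85)


@dataclass(frozen=True)
class LumenMeasurement:
    point_widths_um: tuple[float, ...]
    mean_width_um: float
    positions: tuple[float, ...]


@dataclass(frozen=True)
class LumenConfig:
    """positions: normalized arc positions of the transects, all in the
    posterior half (0.5, 1.0); min_contrast_fraction: smallest luminal
    intensity dip, as a fraction of the body-over-background contrast, that
    counts as a band; orient: "darker-posterior" flips the midline so the
    darker half sits at s → 1 (the lumen-bearing posterior), "as-is" trusts
    the given orientation."""

    positions: tuple[float, ...] = DEFAULT_POSITIONS
    min_contrast_fraction: float = 0.15
    orient: str = "darker-posterior"
    step_px: float = 0.25


DEFAULT_CONFIG = LumenConfig()


def average_lumen_width(widths_um) -> float:
    """Arithmetic mean of >= 2 point width measurements (µm)."""
    w = np.asarray(widths_um, dtype=float)
    if w.size < 2:
        raise ValueError("need at least 2 point widths")
    if np.any(w < 0):
        raise ValueError("widths must be non-negative")
    return float(np.mean(w))


def _intensity_at(px: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(px, pts.T, order=1, mode="nearest")


def _oriented(image: CalibratedImage, midline: Midline, config: LumenConfig) -> Midline:
    if config.orient == "as-is":
        return midline
    if config.orient != "darker-posterior":
        raise ValueError(f"unknown orientation policy {config.orient!r}")
    px = np.asarray(image.pixels, dtype=float)
    s = np.linspace(0.05, 0.95, 61)
    pts = np.array([midline.point_at(v) for v in s])
    vals = _intensity_at(px, pts)
    # the lumen-bearing (posterior) half reads darker along the midline
    if vals[s < 0.5].mean() < vals[s > 0.5].mean():
        return midline.reversed()
    return midline


def measure_lumen(
    image: CalibratedImage,
    midline: Midline,
    config: LumenConfig = DEFAULT_CONFIG,
) -> LumenMeasurement:
    """Measure luminal width on perpendicular transects of the midline.

    At each configured posterior arc position a transect is cast
    perpendicular to the midline tangent; the luminal width is the extent
    of the contiguous sub-threshold (dark) intensity run crossing the
    midline, with sub-pixel edges by linear interpolation, converted to µm
    by the calibration factor. The dark-band threshold is the midpoint
    between the local body intensity and the lumen-floor intensity of that
    transect.
    """
    for s in config.positions:
        if not 0.5 < s < 1.0:
            raise ValueError(f"lumen position s={s} outside the posterior range (0.5, 1.0)")
    midline = _oriented(image, midline, config)
    px = np.asarray(image.pixels, dtype=float)
    body_thr = threshold_otsu(px)
    background = float(np.median(px[px <= body_thr]))
    widths = []
    for s in config.positions:
        widths.append(
            _transect_lumen_width(px, midline, s, body_thr, background, config)
            / image.pixels_per_um
        )
    return LumenMeasurement(
        point_widths_um=tuple(widths),
        mean_width_um=average_lumen_width(widths),
        positions=tuple(config.positions),
    )


def _transect_lumen_width(
    px: np.ndarray,
    midline: Midline,
    s: float,
    body_thr: float,
    background: float,
    config: LumenConfig,
) -> float:
    p = midline.point_at(s)
    t = midline.tangent_at(s)
    normal = np.array([-t[1], t[0]])
    reach = float(min(px.shape)) / 2.0
    d = np.arange(-reach, reach + config.step_px, config.step_px)
    pts = p[None, :] + d[:, None] * normal[None, :]
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= px.shape[0] - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= px.shape[1] - 1)
    )
    d, pts = d[inside], pts[inside]
    prof = _intensity_at(px, pts)
    center = int(np.argmin(np.abs(d)))
    # contiguous body run around the midline point
    above = prof > body_thr
    # the lumen itself may dip below the global threshold: treat a dark gap
    # bounded by body on both sides as part of the body run
    lo = center
    while lo > 0 and (above[lo - 1] or _gap_is_lumen(above, lo - 1, direction=-1)):
        lo -= 1
    hi = center
    while hi < len(d) - 1 and (above[hi + 1] or _gap_is_lumen(above, hi + 1, direction=+1)):
        hi += 1
    body = prof[lo : hi + 1]
    if body.size < 3:
        raise LumenBandError(f"no body cross-section at s={s:.2f}")
    body_level = float(np.max(body))
    lumen_level = float(np.min(body))
    if body_level - lumen_level < config.min_contrast_fraction * (body_level - background):
        raise LumenBandError(f"no dark band detected on the transect at s={s:.2f}")
    thr = 0.5 * (body_level + lumen_level)
    below = prof < thr
    # dark run containing (or adjacent to) the midline point
    i0 = center
    if not below[i0]:
        # allow the run center to sit within 2 px of the midline point
        near = np.where(below & (np.abs(d - d[center]) <= 2.0))[0]
        if near.size == 0:
            raise LumenBandError(f"dark band does not cross the midline at s={s:.2f}")
        i0 = int(near[np.argmin(np.abs(d[near]))])
    a = i0
    while a > lo and below[a - 1]:
        a -= 1
    b = i0
    while b < hi and below[b + 1]:
        b += 1
    left = _subpixel_cross(d, prof, a, a - 1, thr)
    right = _subpixel_cross(d, prof, b, b + 1, thr)
    return right - left


def _gap_is_lumen(above: np.ndarray, i: int, direction: int, max_gap: int = 400) -> bool:
    """True if the sub-threshold run starting at i re-enters body tissue."""
    j = i
    n = 0
    while 0 <= j < len(above) and not above[j] and n < max_gap:
        j += direction
        n += 1
    return 0 <= j < len(above) and bool(above[j])


def _subpixel_cross(d: np.ndarray, prof: np.ndarray, i_in: int, i_out: int, thr: float) -> float:
    """Linear interpolation of the threshold crossing between two samples."""
    if i_out < 0 or i_out >= len(d):
        return float(d[i_in])
    v_in, v_out = prof[i_in], prof[i_out]
    if v_in == v_out:
        return float(0.5 * (d[i_in] + d[i_out]))
    frac = (thr - v_in) / (v_out - v_in)
    frac = min(max(frac, 0.0), 1.0)
    return float(d[i_in] + frac * (d[i_out] - d[i_in]))
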