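"""File I/O: calibrated images with sidecar calibration, tidy CSV tables.

Images are 16-bit grayscale TIFF (or PNG); the calibration factor travels
in a sidecar JSON next to the image (``<stem>.json`` with key
``pixels_per_um``), since neither format carries physical units reliably.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .morphometry import CalibratedImage

__all__ = [
    "write_calibrated_tiff",
    "read_calibrated_image",
    "write_ground_truth_json",
    "wells_to_frame",
    "write_overlay_png",
]


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def write_calibrated_tiff(image: CalibratedImage, path) -> Path:
    """Write a 16-bit TIFF plus its calibration sidecar; returns the sidecar path."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image.pixels, dtype=np.uint16))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"pixels_per_um": image.pixels_per_um}))
    return sidecar


def read_calibrated_image(path, pixels_per_um: float | None = None) -> CalibratedImage:
    """Read a grayscale TIFF/PNG; calibration from the argument or the sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    if px.ndim == 3:  # collapse an RGB(A) image to luminance
        px = px[..., :3].mean(axis=-1)
    if pixels_per_um is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no calibration given and no sidecar {sidecar.name} next to {path.name}"
            )
        pixels_per_um = float(json.loads(sidecar.read_text())["pixels_per_um"])
    return CalibratedImage(pixels=px, pixels_per_um=pixels_per_um, source=path.name)


def write_ground_truth_json(truth, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2))


def wells_to_frame(wells) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(w) for w in wells])


def write_overlay_png(image: CalibratedImage, mask: np.ndarray, midline, path) -> None:
    """QC overlay: grayscale image with the mask outline and midline painted."""
    px = np.asarray(image.pixels, dtype=float)
    lo, hi = np.percentile(px, [1, 99])
    base = np.clip((px - lo) / max(hi - lo, 1e-9), 0, 1)
    rgb = np.stack([base] * 3, axis=-1)
    from scipy import ndimage as ndi

    outline = mask ^ ndi.binary_erosion(mask)
    rgb[outline] = (0.0, 0.9, 0.2)
    pts = np.round(midline.points).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, px.shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, px.shape[1] - 1)
    rgb[pts[:, 0], pts[:, 1]] = (0.95, 0.3, 0.1)
    iio.imwrite(Path(path), (rgb * 255).astype(np.uint8))
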