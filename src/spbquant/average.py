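"""Class averaging of realigned images and display scaling.

Averaged panels are the voxelwise arithmetic mean over all realigned SPB
images of one (stage x genotype) class, with the contributing count and a
per-voxel variance map retained.  Display versions are laterally upscaled
4x4 by bilinear interpolation and optionally converted to 8-bit with a
consistent brightness/contrast window across a figure set; the float
averages are always kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .realign import RealignedImage

__all__ = ["ClassAverage", "average_class", "upscale_display", "to_8bit"]


@dataclass
class ClassAverage:
    mean_image: np.ndarray  # (C, Z, Y, X)
    n: int
    class_key: tuple
    variance_map: np.ndarray
    channels: list[str]
    voxel_xy: float
    voxel_z: float


def average_class(images: Sequence[RealignedImage],
                  class_key: tuple = ()) -> ClassAverage:
    """Voxelwise mean (and unbiased variance, n > 1) of realigned images."""
    if len(images) == 0:
        raise ValueError("cannot average an empty image list")
    first = images[0]
    for img in images[1:]:
        if img.pixels.shape != first.pixels.shape:
            raise ValueError("all images must share grid dimensions")
        if img.channels != first.channels:
            raise ValueError("all images must share channel names")
    data = np.stack([img.pixels for img in images])
    mean = data.mean(axis=0)
    var = (data.var(axis=0, ddof=1) if len(images) > 1
           else np.zeros_like(mean))
    return ClassAverage(mean_image=mean, n=len(images), class_key=class_key,
                        variance_map=var, channels=list(first.channels),
                        voxel_xy=first.voxel_xy, voxel_z=first.voxel_z)


def upscale_display(image: np.ndarray, factor: int = 4) -> np.ndarray:
    """Upscale the two lateral (Y, X) axes by ``factor`` with bilinear
    interpolation; leading axes (channel, z) untouched.

    Corner-aligned sampling is used, so affine intensity ramps are
    reproduced exactly.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return np.asarray(image, dtype=float).copy()
    arr = np.asarray(image, dtype=float)
    ny, nx = arr.shape[-2:]
    ys = np.linspace(0.0, ny - 1.0, ny * factor)
    xs = np.linspace(0.0, nx - 1.0, nx * factor)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()])

    lead = arr.shape[:-2]
    flat = arr.reshape(-1, ny, nx)
    out = np.empty((flat.shape[0], ny * factor, nx * factor))
    for i in range(flat.shape[0]):
        out[i] = ndimage.map_coordinates(flat[i], coords, order=1,
                                         mode="nearest"
                                         ).reshape(ny * factor, nx * factor)
    return out.reshape(*lead, ny * factor, nx * factor)


def to_8bit(image: np.ndarray, vmin: Optional[float] = None,
            vmax: Optional[float] = None) -> np.ndarray:
    """Scale to 8-bit depth; pass a shared (vmin, vmax) window for consistent
    brightness/contrast across a figure set."""
    arr = np.asarray(image, dtype=float)
    lo = float(arr.min()) if vmin is None else vmin
    hi = float(arr.max()) if vmax is None else vmax
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    return np.round(scaled * 255).astype(np.uint8)
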