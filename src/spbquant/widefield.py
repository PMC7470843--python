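"""Wide-field quantitation: projection, windowed integrated intensities,
reference normalisation and the reference-normalised asymmetry index.

This reproduces the lower-resolution workflow used for cells coexpressing a
query label (Spc72-like) and a reference label (Spc42-like): five-plane
z-stacks are max-projected, integrated intensities are measured in a 7 x 7
pixel window around each SPB with per-channel cell background subtracted,
and the per-SPB relative value query/reference feeds the asymmetry index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .image_io import ImageStack
from .metrics import AsymmetryRecord, asymmetry_index

__all__ = ["WindowMeasurement", "project_stack", "window_intensity",
           "annulus_background", "locate_spb", "relative_label",
           "widefield_asymmetry"]


@dataclass
class WindowMeasurement:
    """Integrated intensity in an odd-sided square window, background
    corrected: corrected = raw_sum - side^2 * background_per_px."""

    center_px: tuple[int, int]  # (x, y)
    window_side: int
    raw_sum: float
    background_per_px: float
    corrected: float


def project_stack(stack: ImageStack) -> np.ndarray:
    """Per-channel maximum-intensity 2D projection, shape (C, Y, X)."""
    if stack.pixels.shape[1] < 1:
        raise ValueError("stack has no z planes")
    return stack.pixels.max(axis=1)


def _window_bounds(image2d: np.ndarray, center_px: tuple[int, int],
                   side: int) -> tuple[int, int, int, int]:
    if side % 2 != 1 or side < 1:
        raise ValueError("window side must be odd and positive")
    cx, cy = int(center_px[0]), int(center_px[1])
    h = side // 2
    ny, nx = image2d.shape
    if cx - h < 0 or cy - h < 0 or cx + h >= nx or cy + h >= ny:
        raise ValueError("window clipped by image border")
    return cx - h, cx + h + 1, cy - h, cy + h + 1


def annulus_background(image2d: np.ndarray, center_px: tuple[int, int],
                       side: int = 7, annulus_width: int = 15) -> float:
    """Fallback background: median of an annulus beyond the window."""
    cx, cy = int(center_px[0]), int(center_px[1])
    ny, nx = image2d.shape
    inner = side // 2 + 1
    outer = inner + annulus_width
    yy, xx = np.ogrid[:ny, :nx]
    cheb = np.maximum(np.abs(xx - cx), np.abs(yy - cy))
    mask = (cheb > inner) & (cheb <= outer)
    if not mask.any():
        raise ValueError("annulus empty (window too close to border)")
    return float(np.median(image2d[mask]))


def window_intensity(image2d: np.ndarray, center_px: tuple[int, int],
                     side: int = 7,
                     background_per_px: Optional[float] = None
                     ) -> WindowMeasurement:
    """Integrated intensity in an odd ``side`` x ``side`` window with
    background subtraction.  ``background_per_px`` defaults to the median of
    a surrounding annulus (a cytoplasmic-ROI median can be passed instead).
    """
    arr = np.asarray(image2d, dtype=float)
    x0, x1, y0, y1 = _window_bounds(arr, center_px, side)
    raw = float(arr[y0:y1, x0:x1].sum())
    if background_per_px is None:
        background_per_px = annulus_background(arr, center_px, side)
    corrected = raw - side * side * background_per_px
    return WindowMeasurement(center_px=(int(center_px[0]), int(center_px[1])),
                             window_side=side, raw_sum=raw,
                             background_per_px=float(background_per_px),
                             corrected=corrected)


def locate_spb(image2d: np.ndarray, seed_px: tuple[int, int],
               radius: int = 4) -> tuple[int, int]:
    """Refine an SPB centre to the reference-channel maximum near a seed."""
    arr = np.asarray(image2d)
    ny, nx = arr.shape
    cx, cy = int(seed_px[0]), int(seed_px[1])
    x0, x1 = max(0, cx - radius), min(nx, cx + radius + 1)
    y0, y1 = max(0, cy - radius), min(ny, cy + radius + 1)
    sub = arr[y0:y1, x0:x1]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    return (x0 + int(ix), y0 + int(iy))


def relative_label(query: WindowMeasurement,
                   reference: WindowMeasurement) -> float:
    """Reference-normalised label level at one SPB (query / reference),
    cancelling illumination and focus differences between cells."""
    if reference.corrected <= 0:
        raise ValueError("non-positive reference intensity")
    return query.corrected / reference.corrected


def widefield_asymmetry(rel_spb1: float, rel_spb2: float) -> AsymmetryRecord:
    """Asymmetry index over the two reference-normalised SPB values."""
    idx = asymmetry_index(max(rel_spb1, 0.0), max(rel_spb2, 0.0))
    return AsymmetryRecord(index=idx, mode=None,
                           basis="widefield_ref_normalized")
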