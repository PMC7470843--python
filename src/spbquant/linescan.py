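"""Linescan intensity profiles along the spindle or bridge axis.

Profiles are sampled on a 2D image (by default the z max-projection of a
realigned stack) along a segment, averaging over 1, 3 or 5 parallel
pixel-width lines perpendicular to the axis, at one-pixel sampling pitch
with bilinear in-plane interpolation.  Normalisation is either internal
(min -> 0, max -> 1 per channel within the image) or relative to the
maximum of a reference profile, matching the two conventions used in the
figure panels.

Peak detection assigns local maxima above a robust noise floor
(median + 3*MAD of the profile) to plaque roles by their order along the
axis: a realigned spindle reads outer_old, inner_old, inner_new, outer_new
from left to right (old SPB on the left); a side-by-side profile has the
bridge at the centre.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

__all__ = ["LineProfile", "PeakSet", "profile", "normalize_profile",
           "find_plaque_peaks", "mad_floor", "DegenerateProfileError",
           "LAYOUT_ROLES"]

LAYOUT_ROLES = {
    "single_spb": ("inner_old", "outer_old"),
    "spindle": ("outer_old", "inner_old", "inner_new", "outer_new"),
    "side_by_side_bridge": ("outer_old", "bridge", "outer_new"),
}


class DegenerateProfileError(ValueError):
    """Raised when a flat profile cannot be normalised internally."""


@dataclass
class LineProfile:
    """Intensity profile: ``values`` has shape (C, n); positions in nm."""

    positions: np.ndarray
    values: np.ndarray
    channels: list[str]
    width_px: int
    pixel_nm: float
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def channel_values(self, channel: int | str) -> np.ndarray:
        if isinstance(channel, str):
            channel = self.channels.index(channel)
        return self.values[channel]


def profile(image2d: np.ndarray, start_nm: np.ndarray, end_nm: np.ndarray,
            width_px: int, pixel_nm: float,
            channels: Optional[list[str]] = None) -> LineProfile:
    """Sample a linescan on a 2D image or (C, Y, X) channel set.

    ``start_nm``/``end_nm`` are (x, y) positions in the image frame (pixel
    (0, 0) centred at (pixel_nm/2, pixel_nm/2)).  Each sample is the mean
    over ``width_px`` parallel lines perpendicular to the axis.
    """
    if width_px not in (1, 3, 5):
        raise ValueError("width_px must be 1, 3 or 5")
    arr = np.asarray(image2d, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    ny, nx = arr.shape[-2:]
    start = np.asarray(start_nm, dtype=float)
    end = np.asarray(end_nm, dtype=float)
    length = float(np.linalg.norm(end - start))
    if length <= 0:
        raise ValueError("degenerate segment")
    for p in (start, end):
        if not (0 <= p[0] <= nx * pixel_nm and 0 <= p[1] <= ny * pixel_nm):
            raise ValueError("segment endpoint outside image bounds")

    u = (end - start) / length
    perp = np.array([-u[1], u[0]])
    n = int(np.floor(length / pixel_nm)) + 1
    t = np.arange(n) * pixel_nm
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * pixel_nm

    vals = np.zeros((arr.shape[0], n))
    for off in offsets:
        pts = start[None, :] + t[:, None] * u[None, :] + off * perp[None, :]
        coords = np.stack([pts[:, 1] / pixel_nm - 0.5,
                           pts[:, 0] / pixel_nm - 0.5])
        for c in range(arr.shape[0]):
            vals[c] += ndimage.map_coordinates(arr[c], coords, order=1,
                                               mode="nearest")
    vals /= width_px
    names = channels if channels is not None else [f"ch{i}" for i in
                                                   range(arr.shape[0])]
    return LineProfile(positions=t, values=vals, channels=list(names),
                       width_px=width_px, pixel_nm=pixel_nm)


def normalize_profile(prof: LineProfile, mode: str,
                      reference: Optional[LineProfile] = None) -> LineProfile:
    """Normalise per channel: ``internal`` maps min->0, max->1 within the
    profile; ``reference`` divides by the reference profile's maximum."""
    if mode == "internal":
        out = np.empty_like(prof.values)
        for c in range(prof.values.shape[0]):
            v = prof.values[c]
            lo, hi = float(v.min()), float(v.max())
            if hi == lo:
                raise DegenerateProfileError(
                    "flat profile cannot be internally normalised")
            out[c] = (v - lo) / (hi - lo)
    elif mode == "reference":
        if reference is None:
            raise ValueError("reference profile required for mode='reference'")
        out = np.empty_like(prof.values)
        for c in range(prof.values.shape[0]):
            ref_max = float(reference.values[min(c, reference.values.shape[0]
                                                 - 1)].max())
            if ref_max <= 0:
                raise ValueError("non-positive reference maximum")
            out[c] = prof.values[c] / ref_max
    else:
        raise ValueError("mode must be 'internal' or 'reference'")
    new = dataclasses.replace(prof, values=out, normalization=mode)
    return new


def mad_floor(values: np.ndarray, k: float = 3.0) -> float:
    """Robust detection floor: median + k * median-absolute-deviation."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return med + k * mad


@dataclass
class PeakSet:
    """Detected profile peaks annotated with plaque roles per channel."""

    peaks: dict  # role -> (position nm, height)
    missing: tuple[str, ...] = ()
    floor: float = 0.0
    channel: int = 0

    def height(self, role: str) -> Optional[float]:
        if role in self.peaks:
            return self.peaks[role][1]
        return None


def _assign_spindle(pos: np.ndarray, hts: np.ndarray, center: float) -> dict:
    out: dict = {}
    left = [(p, h) for p, h in zip(pos, hts) if p < center]
    right = [(p, h) for p, h in zip(pos, hts) if p >= center]
    for side, (outer_role, inner_role) in (
            (left, ("outer_old", "inner_old")),
            (right, ("outer_new", "inner_new"))):
        side = sorted(side, key=lambda t: abs(t[0] - center))
        if len(side) >= 2:
            out[inner_role] = side[0]
            out[outer_role] = max(side[1:], key=lambda t: abs(t[0] - center))
        elif len(side) == 1:
            # single peak on this side: the inner plaque is always present
            out[inner_role] = side[0]
    return out


def find_plaque_peaks(prof: LineProfile, expected_layout: str,
                      channel: int | str = 0,
                      floor: Optional[float] = None,
                      mad_k: float = 3.0) -> PeakSet:
    """Detect peaks above the noise floor and assign plaque roles.

    Fewer peaks than the layout expects yields a partial
    :class:`PeakSet` with the missing roles flagged.
    """
    if expected_layout not in LAYOUT_ROLES:
        raise ValueError(f"unknown layout {expected_layout!r}")
    if isinstance(channel, str):
        channel = prof.channels.index(channel)
    v = prof.values[channel]
    if floor is None:
        floor = mad_floor(v, mad_k)
    idx, _ = signal.find_peaks(v, height=floor)
    # boundary samples can be maxima too (plaque at profile end)
    for edge in (0, len(v) - 1):
        neighbour = 1 if edge == 0 else len(v) - 2
        if len(v) > 1 and v[edge] > floor and v[edge] > v[neighbour]:
            idx = np.sort(np.append(idx, edge))
    pos = prof.positions[idx]
    hts = v[idx]

    roles = LAYOUT_ROLES[expected_layout]
    center = 0.5 * (prof.positions[0] + prof.positions[-1])
    assigned: dict = {}
    if expected_layout == "spindle":
        assigned = _assign_spindle(pos, hts, center)
    elif expected_layout == "single_spb":
        order = np.argsort(pos)
        if len(order) >= 2:
            assigned["inner_old"] = (pos[order[0]], hts[order[0]])
            assigned["outer_old"] = (pos[order[-1]], hts[order[-1]])
        elif len(order) == 1:
            assigned["inner_old"] = (pos[order[0]], hts[order[0]])
    else:  # side_by_side_bridge
        if len(pos) > 0:
            i_mid = int(np.argmin(np.abs(pos - center)))
            assigned["bridge"] = (pos[i_mid], hts[i_mid])
            lefts = [(p, h) for j, (p, h) in enumerate(zip(pos, hts))
                     if j != i_mid and p < pos[i_mid]]
            rights = [(p, h) for j, (p, h) in enumerate(zip(pos, hts))
                      if j != i_mid and p > pos[i_mid]]
            if lefts:
                assigned["outer_old"] = max(lefts, key=lambda t: t[1])
            if rights:
                assigned["outer_new"] = max(rights, key=lambda t: t[1])
    missing = tuple(r for r in roles if r not in assigned)
    return PeakSet(peaks={r: (float(p), float(h))
                          for r, (p, h) in assigned.items()},
                   missing=missing, floor=float(floor), channel=channel)
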