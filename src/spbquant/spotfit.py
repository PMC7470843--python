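"""3D Gaussian spot fitting of SPB foci.

The fitted model is the same voxel-integrated anisotropic Gaussian used by
the forward model in :mod:`.synth` (laterally isotropic, sigma_x = sigma_y;
independent axial width), so the ``amplitude`` parameter is the integrated
flux of the focus.  Single spots are fitted with their own background;
double fits share one background over the ROI.  Optimisation is bounded
nonlinear least squares (scipy ``least_squares``, trf).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, special
from skimage.feature import peak_local_max

from .image_io import ImageStack

__all__ = [
    "SpotFit", "SPBPair", "Roi", "roi_around", "fit_single", "fit_double",
    "edge_slice_exclusion", "find_seeds", "DegenerateRoiError",
]

_SQRT2 = np.sqrt(2.0)


class DegenerateRoiError(ValueError):
    """Raised when a fit ROI carries no structure (constant intensities)."""


@dataclass
class SpotFit:
    """One fitted 3D Gaussian focus.

    ``center`` is (x, y, z) in stack-frame nm; ``amplitude`` is the
    integrated flux; ``rss`` the residual sum of squares over the ROI.
    """

    center: np.ndarray
    sigma_xy: float
    sigma_z: float
    amplitude: float
    background: float
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    def distance_to(self, other: "SpotFit") -> float:
        return float(np.linalg.norm(self.center - other.center))


@dataclass
class SPBPair:
    """Two reference-channel fits with inter-distance and exclusion state.

    ``fit_old`` is the brighter (old) SPB after assignment.
    """

    fit_old: SpotFit
    fit_new: SpotFit
    inter_distance: float = field(init=False)
    excluded: bool = False
    reason: str = ""
    tie: bool = False

    def __post_init__(self) -> None:
        self.inter_distance = self.fit_old.distance_to(self.fit_new)

    def exclude(self, reason: str) -> "SPBPair":
        out = dataclasses.replace(self, excluded=True, reason=reason)
        out.inter_distance = self.inter_distance
        return out


@dataclass(frozen=True)
class Roi:
    """An axis-aligned voxel box: half-open index ranges (z, y, x)."""

    z: tuple[int, int]
    y: tuple[int, int]
    x: tuple[int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.z), slice(*self.y), slice(*self.x))

    def shape(self) -> tuple[int, int, int]:
        return (self.z[1] - self.z[0], self.y[1] - self.y[0],
                self.x[1] - self.x[0])

    def contains_nm(self, pos: np.ndarray, vxy: float, vz: float) -> bool:
        x, y, z = pos
        return (self.x[0] * vxy <= x <= self.x[1] * vxy
                and self.y[0] * vxy <= y <= self.y[1] * vxy
                and self.z[0] * vz <= z <= self.z[1] * vz)


def roi_around(stack: ImageStack, centers_nm: Sequence[np.ndarray],
               half_xy_nm: float, half_z_nm: float) -> Roi:
    """Axis-aligned box around one or more centres, clipped to the stack."""
    centers = np.atleast_2d(np.asarray(centers_nm, dtype=float))
    lo = centers.min(axis=0)
    hi = centers.max(axis=0)
    nz, ny, nx = stack.shape_zyx
    x0 = max(0, int((lo[0] - half_xy_nm) // stack.voxel_xy))
    x1 = min(nx, int(np.ceil((hi[0] + half_xy_nm) / stack.voxel_xy)))
    y0 = max(0, int((lo[1] - half_xy_nm) // stack.voxel_xy))
    y1 = min(ny, int(np.ceil((hi[1] + half_xy_nm) / stack.voxel_xy)))
    z0 = max(0, int((lo[2] - half_z_nm) // stack.voxel_z))
    z1 = min(nz, int(np.ceil((hi[2] + half_z_nm) / stack.voxel_z)))
    if x1 <= x0 or y1 <= y0 or z1 <= z0:
        raise ValueError("ROI is empty (centres outside stack?)")
    return Roi(z=(z0, z1), y=(y0, y1), x=(x0, x1))


def default_roi(stack: ImageStack, centers_nm: Sequence[np.ndarray],
                sigma_xy: float, sigma_z: float) -> Roi:
    """Cube of half-width max(4*sigma_xy, d/2 + 3*sigma_xy) around the seeds."""
    centers = np.atleast_2d(np.asarray(centers_nm, dtype=float))
    d = 0.0
    if len(centers) == 2:
        d = float(np.linalg.norm(centers[1] - centers[0]))
    half_xy = max(4.0 * sigma_xy, d / 2.0 + 3.0 * sigma_xy)
    half_z = max(3.0 * sigma_z, d / 2.0 + 2.0 * sigma_z)
    return roi_around(stack, [centers.mean(axis=0)], half_xy, half_z)


def _axis_frac(i0: int, n: int, pitch: float, mu: float, sigma: float
               ) -> np.ndarray:
    edges = (i0 + np.arange(n + 1)) * pitch
    cdf = 0.5 * (1.0 + special.erf((edges - mu) / (sigma * _SQRT2)))
    return np.diff(cdf)


def _spot_image(roi: Roi, vxy: float, vz: float, x: float, y: float,
                z: float, sxy: float, sz: float, flux: float) -> np.ndarray:
    nz, ny, nx = roi.shape()
    gx = _axis_frac(roi.x[0], nx, vxy, x, sxy)
    gy = _axis_frac(roi.y[0], ny, vxy, y, sxy)
    gz = _axis_frac(roi.z[0], nz, vz, z, sz)
    return flux * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def _check_roi(stack: ImageStack, roi: Roi) -> np.ndarray:
    nz, ny, nx = stack.shape_zyx
    if not (0 <= roi.z[0] < roi.z[1] <= nz and 0 <= roi.y[0] < roi.y[1] <= ny
            and 0 <= roi.x[0] < roi.x[1] <= nx):
        raise ValueError("ROI not fully inside stack")


def _flux_guess(data: np.ndarray, background: float) -> float:
    return float(max(data.sum() - background * data.size, 1.0))


def fit_single(stack: ImageStack, channel: int | str, roi: Roi,
               init_center_nm: np.ndarray,
               init_sigma_xy: float = 60.0, init_sigma_z: float = 160.0,
               max_nfev: int = 500,
               sigma_bounds: tuple[float, float] = (0.25, 4.0),
               center_halfwidth_nm: Optional[float] = None) -> SpotFit:
    """Least-squares fit of one integrated Gaussian plus background to a ROI.

    ``sigma_bounds`` are multiplicative bounds on the widths relative to
    their initial values; tighten them (e.g. (0.7, 1.4)) when the PSF is
    known and neighbouring structure must not be absorbed.
    ``center_halfwidth_nm`` optionally confines the centre to a box around
    its initial value (useful when the spot position is known from another
    channel and nearby structure must not capture the fit).
    """
    _check_roi(stack, roi)
    vxy, vz = stack.voxel_xy, stack.voxel_z
    c0 = np.asarray(init_center_nm, dtype=float)
    if not roi.contains_nm(c0, vxy, vz):
        raise ValueError("init centre outside ROI")
    data = stack.channel_pixels(channel)[roi.slices()].astype(float)
    if np.ptp(data) == 0:
        raise DegenerateRoiError("constant-intensity ROI cannot be fitted")

    bg0 = float(np.median(data))
    f0 = _flux_guess(data, bg0)
    s_lo, s_hi = sigma_bounds
    p0 = np.array([c0[0], c0[1], c0[2], init_sigma_xy, init_sigma_z, f0, bg0])
    lo = np.array([roi.x[0] * vxy, roi.y[0] * vxy, roi.z[0] * vz,
                   s_lo * init_sigma_xy, s_lo * init_sigma_z, 0.0, 0.0])
    hi = np.array([roi.x[1] * vxy, roi.y[1] * vxy, roi.z[1] * vz,
                   s_hi * init_sigma_xy, s_hi * init_sigma_z,
                   max(10.0 * f0, 1.0), max(float(data.max()), bg0 + 1.0)])
    if center_halfwidth_nm is not None:
        lo[:3] = np.maximum(lo[:3], c0 - center_halfwidth_nm)
        hi[:3] = np.minimum(hi[:3], c0 + center_halfwidth_nm)
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        model = _spot_image(roi, vxy, vz, *p[:6]) + p[6]
        return (model - data).ravel()

    res = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                 xtol=1e-8, ftol=1e-8, gtol=1e-8,
                                 max_nfev=max_nfev)
    p = res.x
    return SpotFit(center=p[:3].copy(), sigma_xy=float(p[3]),
                   sigma_z=float(p[4]), amplitude=float(p[5]),
                   background=float(p[6]), rss=float(np.sum(res.fun ** 2)),
                   converged=bool(res.status > 0))


def fit_double(stack: ImageStack, channel: int | str, roi: Roi,
               init_a_nm: np.ndarray, init_b_nm: np.ndarray,
               init_sigma_xy: float = 60.0, init_sigma_z: float = 160.0,
               max_nfev: int = 500,
               sigma_bounds: tuple[float, float] = (0.25, 4.0),
               center_halfwidth_nm: Optional[float] = None
               ) -> tuple[SpotFit, SpotFit]:
    """Joint fit of two integrated Gaussians with a shared background.

    Spots are returned in input order (old/new assignment happens later).
    Fits whose centres collapse closer than 0.25 * sigma_xy are flagged
    ``unresolved``.
    """
    _check_roi(stack, roi)
    a0 = np.asarray(init_a_nm, dtype=float)
    b0 = np.asarray(init_b_nm, dtype=float)
    if np.allclose(a0, b0):
        raise ValueError("init centres must be distinct")
    vxy, vz = stack.voxel_xy, stack.voxel_z
    for c in (a0, b0):
        if not roi.contains_nm(c, vxy, vz):
            raise ValueError("init centre outside ROI")
    data = stack.channel_pixels(channel)[roi.slices()].astype(float)
    if np.ptp(data) == 0:
        raise DegenerateRoiError("constant-intensity ROI cannot be fitted")

    bg0 = float(np.median(data))
    f0 = _flux_guess(data, bg0) / 2.0
    p0 = np.array([
        a0[0], a0[1], a0[2], init_sigma_xy, init_sigma_z, f0,
        b0[0], b0[1], b0[2], init_sigma_xy, init_sigma_z, f0,
        bg0,
    ])
    s_lo, s_hi = sigma_bounds
    lo_spot = [roi.x[0] * vxy, roi.y[0] * vxy, roi.z[0] * vz,
               s_lo * init_sigma_xy, s_lo * init_sigma_z, 0.0]
    hi_spot = [roi.x[1] * vxy, roi.y[1] * vxy, roi.z[1] * vz,
               s_hi * init_sigma_xy, s_hi * init_sigma_z,
               max(20.0 * f0, 1.0)]
    lo = np.array(lo_spot * 2 + [0.0])
    hi = np.array(hi_spot * 2 + [max(float(data.max()), bg0 + 1.0)])
    if center_halfwidth_nm is not None:
        for base, c in ((0, a0), (6, b0)):
            lo[base:base + 3] = np.maximum(lo[base:base + 3],
                                           c - center_halfwidth_nm)
            hi[base:base + 3] = np.minimum(hi[base:base + 3],
                                           c + center_halfwidth_nm)
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        model = (_spot_image(roi, vxy, vz, *p[0:6])
                 + _spot_image(roi, vxy, vz, *p[6:12]) + p[12])
        return (model - data).ravel()

    res = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                 xtol=1e-8, ftol=1e-8, gtol=1e-8,
                                 max_nfev=max_nfev)
    p = res.x
    rss = float(np.sum(res.fun ** 2))
    conv = bool(res.status > 0)

    flags: tuple[str, ...] = ()
    dist = float(np.linalg.norm(p[0:3] - p[6:9]))
    mean_sxy = 0.5 * (p[3] + p[9])
    if dist < 0.25 * mean_sxy:
        flags = ("unresolved",)

    def spot(q):
        return SpotFit(center=q[:3].copy(), sigma_xy=float(q[3]),
                       sigma_z=float(q[4]), amplitude=float(q[5]),
                       background=float(p[12]), rss=rss, converged=conv,
                       flags=flags)

    return spot(p[0:6]), spot(p[6:12])


def edge_slice_exclusion(stack: ImageStack, channels: Sequence[int | str],
                         pair: SPBPair,
                         half_xy_sigmas: float = 3.0,
                         half_z_sigmas: float = 3.0) -> SPBPair:
    """Exclude the pair when, for either SPB in any listed channel, the
    local intensity maximum over the SPB's ROI lies in the first or last
    z-slice of the stack."""
    nz = stack.shape_zyx[0]
    for fit in (pair.fit_old, pair.fit_new):
        roi = roi_around(stack, [fit.center],
                         half_xy_sigmas * fit.sigma_xy,
                         half_z_sigmas * fit.sigma_z)
        for ch in channels:
            sub = stack.channel_pixels(ch)[roi.slices()]
            zmax = roi.z[0] + int(np.unravel_index(np.argmax(sub),
                                                   sub.shape)[0])
            if zmax == 0 or zmax == nz - 1:
                return pair.exclude("edge_slice")
    return pair


def find_seeds(stack: ImageStack, channel: int | str,
               smooth_sigma_nm: float = 50.0,
               min_distance_nm: float = 120.0,
               threshold_rel: float = 0.2,
               max_peaks: int = 2) -> list[np.ndarray]:
    """Auto-seed candidate foci from local maxima of a smoothed channel.

    Stands in for the manual spot identification used on real data.
    Returns stack-frame (x, y, z) nm positions, brightest first.
    """
    vol = stack.channel_pixels(channel).astype(float)
    sig = (smooth_sigma_nm / stack.voxel_z,
           smooth_sigma_nm / stack.voxel_xy,
           smooth_sigma_nm / stack.voxel_xy)
    sm = ndimage.gaussian_filter(vol, sig)
    min_dist = max(1, int(min_distance_nm / stack.voxel_xy))
    peaks = peak_local_max(sm, min_distance=min_dist,
                           threshold_rel=threshold_rel,
                           num_peaks=max_peaks, exclude_border=False)
    out = []
    for z, y, x in peaks:
        out.append(np.array([(x + 0.5) * stack.voxel_xy,
                             (y + 0.5) * stack.voxel_xy,
                             (z + 0.5) * stack.voxel_z]))
    return out
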