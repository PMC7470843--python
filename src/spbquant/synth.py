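"""Ground-truthed synthetic SPB image generation.

Scenes emulate SIM-reconstruction-like two-channel 3D stacks of budding
yeast spindle pole bodies across the duplication / spindle cycle.  Each SPB
carries a reference-channel focus at its core and query-channel point
sources at the inner and outer plaque, separated along the plaque axis; a
bridge source can sit at the midpoint between side-by-side SPBs.  The
forward model convolves the point sources with an anisotropic Gaussian PSF
(voxel-integrated, so fluxes are conserved up to boundary truncation), adds
a uniform background, then optional Poisson shot noise and Gaussian read
noise.

The generator is deterministic: identical (config, seed) gives bit-identical
ground truth and pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .config import (
    STAGE_DISTANCE_NM, STAGES, AsymmetryConfig, GeometryConfig, NoiseConfig,
    OpticsConfig,
)
from .image_io import ImageStack

__all__ = [
    "Emitter", "OpticsModel", "GroundTruth", "build_scene", "render",
    "sample_population", "noiseless_image",
]

ROLES = ("inner_plaque", "outer_plaque", "bridge", "satellite")

#: Channel indices of the two labels.
REF_CHANNEL, QUERY_CHANNEL = 0, 1


@dataclass(frozen=True)
class Emitter:
    """A point source: position (x, y, z) nm, integrated flux, channel, role."""

    position: np.ndarray
    amplitude: float
    channel: int
    role: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))
        if self.amplitude < 0:
            raise ValueError("emitter amplitude must be >= 0")
        if self.role not in ROLES:
            raise ValueError(f"unknown emitter role {self.role!r}")

    def to_dict(self) -> dict:
        return {"position": list(map(float, self.position)),
                "amplitude": self.amplitude, "channel": self.channel,
                "role": self.role}


# The optics model coincides with OpticsConfig; keep the domain-facing alias.
OpticsModel = OpticsConfig


@dataclass
class GroundTruth:
    """Emitter set and generating parameters of one synthetic scene."""

    emitters: list[Emitter]
    spb_axis: np.ndarray  # unit vector old -> new (plaque axis if single SPB)
    inter_distance: float  # nm, 0 for a single SPB
    old_new_fold: float
    stage_label: str
    ploidy: int
    seed: int
    plaque_axis: np.ndarray = field(default_factory=lambda: np.array([1., 0., 0.]))
    top_view: bool = False
    old_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    new_position: Optional[np.ndarray] = None
    ip_op_ratio: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.inter_distance < 0:
            raise ValueError("inter_distance must be >= 0")
        if not self.old_new_fold >= 1.0:
            raise ValueError("old_new_fold must be >= 1")
        self.spb_axis = np.asarray(self.spb_axis, dtype=float)
        self.plaque_axis = np.asarray(self.plaque_axis, dtype=float)

    def emitters_of(self, channel: int, role: Optional[str] = None
                    ) -> list[Emitter]:
        return [e for e in self.emitters
                if e.channel == channel and (role is None or e.role == role)]

    def to_dict(self) -> dict:
        return {
            "emitters": [e.to_dict() for e in self.emitters],
            "spb_axis": list(map(float, self.spb_axis)),
            "plaque_axis": list(map(float, self.plaque_axis)),
            "inter_distance": self.inter_distance,
            "old_new_fold": (None if math.isinf(self.old_new_fold)
                             else self.old_new_fold),
            "stage_label": self.stage_label,
            "ploidy": self.ploidy,
            "seed": self.seed,
            "top_view": self.top_view,
            "old_position": list(map(float, self.old_position)),
            "new_position": (None if self.new_position is None
                             else list(map(float, self.new_position))),
            "ip_op_ratio": self.ip_op_ratio,
            "source_id": self.source_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            emitters=[Emitter(np.array(e["position"]), e["amplitude"],
                              e["channel"], e["role"]) for e in d["emitters"]],
            spb_axis=np.array(d["spb_axis"]),
            inter_distance=d["inter_distance"],
            old_new_fold=(math.inf if d["old_new_fold"] is None
                          else d["old_new_fold"]),
            stage_label=d["stage_label"], ploidy=d["ploidy"], seed=d["seed"],
            plaque_axis=np.array(d["plaque_axis"]),
            top_view=d["top_view"],
            old_position=np.array(d["old_position"]),
            new_position=(None if d["new_position"] is None
                          else np.array(d["new_position"])),
            ip_op_ratio=d.get("ip_op_ratio", 1.0),
            source_id=d.get("source_id", ""),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _in_plane_axis(rng: np.random.Generator, max_tilt_deg: float) -> np.ndarray:
    """Random unit vector tilted at most ``max_tilt_deg`` out of the xy-plane."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    tilt = np.deg2rad(rng.uniform(-max_tilt_deg, max_tilt_deg))
    return np.array([np.cos(tilt) * np.cos(phi),
                     np.cos(tilt) * np.sin(phi),
                     np.sin(tilt)])


def _near_z_axis(rng: np.random.Generator, jitter_deg: float) -> np.ndarray:
    """Unit vector within ``jitter_deg`` of the optical (z) axis."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    theta = np.deg2rad(rng.uniform(0.0, jitter_deg))
    return np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


def build_scene(stage_label: str,
                asymmetry: Optional[AsymmetryConfig] = None,
                geometry: Optional[GeometryConfig] = None,
                seed: int = 0,
                ploidy: int = 1,
                top_view: bool = False) -> GroundTruth:
    """Build the ground-truth emitter set for one scene.

    The old SPB sits at ``-d/2`` and the new at ``+d/2`` along a randomly
    oriented inter-SPB axis (``d`` drawn from the stage's distance interval).
    Query-channel inner plaques sit at the SPB cores; outer plaques are
    displaced ``ip_op_separation`` along the plaque axis, which is the
    spindle axis (pointing outward) for separated spindles and a direction
    perpendicular to the bridge axis for unseparated SPBs.  The new outer
    plaque flux is the old one divided by ``old_new_fold`` (``inf`` -> 0,
    the incompletely assembled new outer plaque).
    """
    if stage_label not in STAGES:
        raise ValueError(f"unknown stage label {stage_label!r}")
    asymmetry = asymmetry or AsymmetryConfig()
    geometry = geometry or GeometryConfig()
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    rng = np.random.default_rng(seed)

    lo, hi = STAGE_DISTANCE_NM[stage_label]
    d = float(rng.uniform(lo, hi)) if hi > lo else lo
    if d < 0:
        raise ValueError("geometry produced a negative inter-distance")

    fold = asymmetry.old_new_fold
    sep = geometry.ip_op_separation
    amp = asymmetry.amplitude * ploidy
    ip_amp_old = asymmetry.amplitude * asymmetry.ip_op_ratio * ploidy
    ip_amp_new = ip_amp_old / asymmetry.ip_old_new_fold
    op_amp_new = 0.0 if math.isinf(fold) else amp / fold
    ref_amp_old = asymmetry.ref_amplitude * ploidy
    ref_amp_new = ref_amp_old / asymmetry.ref_old_new_fold

    single = stage_label == "unduplicated"
    separated = stage_label in ("short_spindle_lt1", "spindle_1_2p5",
                                "elongated")

    if single:
        plaque_axis = (_near_z_axis(rng, geometry.top_view_jitter_deg)
                       if top_view
                       else _in_plane_axis(rng, geometry.max_tilt_deg))
        axis = plaque_axis
        old_pos = np.zeros(3)
        new_pos = None
    else:
        axis = _in_plane_axis(rng, geometry.max_tilt_deg)
        old_pos = -0.5 * d * axis
        new_pos = 0.5 * d * axis
        if separated:
            # outer plaques face outward along the spindle axis
            plaque_axis = axis if not top_view else _near_z_axis(
                rng, geometry.top_view_jitter_deg)
            if top_view:
                axis = plaque_axis  # spindle itself near-vertical
                old_pos = -0.5 * d * axis
                new_pos = 0.5 * d * axis
        else:
            # side-by-side: plaque axis perpendicular to the bridge axis
            if top_view:
                plaque_axis = _near_z_axis(rng, geometry.top_view_jitter_deg)
                plaque_axis = _unit(plaque_axis
                                    - plaque_axis.dot(axis) * axis)
            else:
                perp = np.cross(axis, np.array([0.0, 0.0, 1.0]))
                if np.linalg.norm(perp) < 1e-9:
                    perp = np.array([1.0, 0.0, 0.0])
                plaque_axis = _unit(perp) * rng.choice([-1.0, 1.0])

    emitters: list[Emitter] = []

    def add(pos, flux, channel, role):
        emitters.append(Emitter(np.asarray(pos, dtype=float), float(flux),
                                channel, role))

    if single:
        add(old_pos, ref_amp_old, REF_CHANNEL, "inner_plaque")
        add(old_pos, ip_amp_old, QUERY_CHANNEL, "inner_plaque")
        add(old_pos + sep * plaque_axis, amp, QUERY_CHANNEL, "outer_plaque")
    elif separated:
        u = axis  # old -> new
        add(old_pos, ref_amp_old, REF_CHANNEL, "inner_plaque")
        add(new_pos, ref_amp_new, REF_CHANNEL, "inner_plaque")
        add(old_pos, ip_amp_old, QUERY_CHANNEL, "inner_plaque")
        add(new_pos, ip_amp_new, QUERY_CHANNEL, "inner_plaque")
        add(old_pos - sep * u, amp, QUERY_CHANNEL, "outer_plaque")
        if op_amp_new > 0:
            add(new_pos + sep * u, op_amp_new, QUERY_CHANNEL, "outer_plaque")
    else:  # side_by_side
        add(old_pos, ref_amp_old, REF_CHANNEL, "inner_plaque")
        add(new_pos, ref_amp_new, REF_CHANNEL, "inner_plaque")
        add(old_pos, ip_amp_old, QUERY_CHANNEL, "inner_plaque")
        add(new_pos, ip_amp_new, QUERY_CHANNEL, "inner_plaque")
        add(old_pos + sep * plaque_axis, amp, QUERY_CHANNEL, "outer_plaque")
        if op_amp_new > 0:
            add(new_pos + sep * plaque_axis, op_amp_new, QUERY_CHANNEL,
                "outer_plaque")
        if geometry.bridge and asymmetry.bridge_fraction > 0:
            # the bridge pool sits between the unseparated SPB signals
            mid = 0.5 * (old_pos + new_pos)
            add(mid, asymmetry.bridge_fraction * amp, QUERY_CHANNEL, "bridge")

    return GroundTruth(
        emitters=emitters, spb_axis=axis, inter_distance=d,
        old_new_fold=fold, stage_label=stage_label, ploidy=ploidy,
        seed=int(seed), plaque_axis=plaque_axis, top_view=top_view,
        old_position=old_pos, new_position=new_pos,
        ip_op_ratio=asymmetry.ip_op_ratio,
    )


def _axis_integral(n: int, pitch: float, mu: float, sigma: float
                   ) -> np.ndarray:
    """Fraction of a unit Gaussian falling in each of n voxels along one axis."""
    edges = np.arange(n + 1) * pitch
    cdf = 0.5 * (1.0 + special.erf((edges - mu) / (sigma * np.sqrt(2.0))))
    return np.diff(cdf)


def noiseless_image(truth: GroundTruth, optics: OpticsModel,
                    shape_zyx: tuple[int, int, int],
                    origin_nm: np.ndarray,
                    n_channels: int = 2) -> np.ndarray:
    """Expected (pre-noise) image: integrated-Gaussian emitters + background."""
    nz, ny, nx = shape_zyx
    img = np.full((n_channels, nz, ny, nx), float(optics.background))
    for e in truth.emitters:
        if e.amplitude == 0:
            continue
        x, y, z = e.position - origin_nm
        gx = _axis_integral(nx, optics.voxel_xy, x, optics.psf_sigma_xy)
        gy = _axis_integral(ny, optics.voxel_xy, y, optics.psf_sigma_xy)
        gz = _axis_integral(nz, optics.voxel_z, z, optics.psf_sigma_z)
        img[e.channel] += e.amplitude * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :])
    return img


def _auto_grid(truth: GroundTruth, optics: OpticsModel,
               margin_sigmas: float = 3.5
               ) -> tuple[tuple[int, int, int], np.ndarray]:
    pos = np.array([e.position for e in truth.emitters])
    mxy = margin_sigmas * optics.psf_sigma_xy + optics.voxel_xy
    mz = margin_sigmas * optics.psf_sigma_z + optics.voxel_z
    lo = pos.min(axis=0) - np.array([mxy, mxy, mz])
    hi = pos.max(axis=0) + np.array([mxy, mxy, mz])
    span = hi - lo
    nx = max(8, int(np.ceil(span[0] / optics.voxel_xy)))
    ny = max(8, int(np.ceil(span[1] / optics.voxel_xy)))
    nz = max(6, int(np.ceil(span[2] / optics.voxel_z)))
    return (nz, ny, nx), lo


def render(truth: GroundTruth, optics: OpticsModel,
           noise: Optional[NoiseConfig] = None, seed: int = 0,
           shape_zyx: Optional[tuple[int, int, int]] = None,
           origin_nm: Optional[np.ndarray] = None,
           channels: Sequence[str] = ("Spc42", "Tub4"),
           margin_sigmas: float = 3.5) -> ImageStack:
    """Render a scene to an :class:`ImageStack`.

    With ``shape_zyx``/``origin_nm`` unset, the grid is sized to contain all
    emitters with a ``margin_sigmas``-sigma margin.  ``noise=None`` renders
    the noiseless expectation.
    """
    if shape_zyx is None or origin_nm is None:
        auto_shape, auto_origin = _auto_grid(truth, optics, margin_sigmas)
        shape_zyx = shape_zyx or auto_shape
        origin_nm = auto_origin if origin_nm is None else np.asarray(origin_nm)
    origin_nm = np.asarray(origin_nm, dtype=float)
    extent = np.array([shape_zyx[2] * optics.voxel_xy,
                       shape_zyx[1] * optics.voxel_xy,
                       shape_zyx[0] * optics.voxel_z])
    for e in truth.emitters:
        rel = e.position - origin_nm
        if np.any(rel < 0) or np.any(rel > extent):
            raise ValueError(
                f"emitter at {e.position} outside renderable volume")

    n_channels = max(len(channels), 1 + max(e.channel for e in truth.emitters))
    img = noiseless_image(truth, optics, shape_zyx, origin_nm, n_channels)
    if noise is not None:
        rng = np.random.default_rng(seed)
        if noise.poisson:
            img = rng.poisson(img).astype(float)
        if noise.read_sigma > 0:
            img = img + rng.normal(0.0, noise.read_sigma, size=img.shape)
    return ImageStack(pixels=img, channels=list(channels),
                      voxel_xy=optics.voxel_xy, voxel_z=optics.voxel_z,
                      source_id=truth.source_id or f"scene{truth.seed}",
                      origin_nm=origin_nm)


def sample_population(stage_mix: dict[str, float], n: int, seed: int = 0,
                      asymmetry: Optional[AsymmetryConfig] = None,
                      geometry: Optional[GeometryConfig] = None,
                      optics: Optional[OpticsModel] = None,
                      noise: Optional[NoiseConfig] = NoiseConfig(),
                      ploidy: int = 1,
                      channels: Sequence[str] = ("Spc42", "Tub4"),
                      ) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate ``n`` scenes with stages drawn from ``stage_mix``.

    One global seed fans out to per-scene substreams by scene counter, so
    populations are reproducible and individual scenes re-renderable.
    """
    if not stage_mix:
        raise ValueError("stage_mix must not be empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(stage_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("stage_mix proportions must sum to 1")
    geometry = geometry or GeometryConfig()
    optics = optics or OpticsModel()

    labels = list(stage_mix)
    probs = np.array([stage_mix[k] for k in labels])
    master = np.random.default_rng([seed, 0])
    out: list[tuple[ImageStack, GroundTruth]] = []
    for i in range(n):
        stage = labels[int(master.choice(len(labels), p=probs))]
        top = bool(master.random() < geometry.top_view_fraction)
        scene_seed = int((1_000_003 * seed + 7919 * i + 1) % (2 ** 31))
        truth = build_scene(stage, asymmetry=asymmetry, geometry=geometry,
                            seed=scene_seed, ploidy=ploidy, top_view=top)
        truth.source_id = f"scene{i:04d}"
        stack = render(truth, optics, noise=noise, seed=scene_seed + 1,
                       channels=channels)
        out.append((stack, truth))
    return out
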