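"""Validated configuration models for the simulation and analysis pipeline.

All physical lengths are in nanometres unless a field name says otherwise.
Two optics presets are provided: a SIM-reconstruction-like regime (the
super-resolution data that resolves the ~150 nm inner/outer plaque
separation) and a conventional wide-field regime (five-plane z-stacks with
2x2 camera binning, which resolves only whole SPBs).
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Synthesis stage labels, ordered along the SPB duplication / spindle pathway.
STAGES = (
    "unduplicated",
    "side_by_side",
    "short_spindle_lt1",
    "spindle_1_2p5",
    "elongated",
)

#: Inter-SPB distance interval (nm) sampled for each stage.  Each interval is
#: consistent with the distance-based staging boundaries in :mod:`.metrics`
#: (0.35 / 1 / 2.5 um).
STAGE_DISTANCE_NM = {
    "unduplicated": (0.0, 0.0),
    "side_by_side": (150.0, 340.0),
    "short_spindle_lt1": (400.0, 990.0),
    "spindle_1_2p5": (1000.0, 2400.0),
    "elongated": (2600.0, 4000.0),
}


class OpticsConfig(BaseModel):
    """Point-spread-function and sampling parameters of the forward model."""

    psf_sigma_xy: float = 50.0
    psf_sigma_z: float = 140.0
    voxel_xy: float = 40.0
    voxel_z: float = 125.0
    background: float = 2.0  # expected counts per voxel

    @field_validator("psf_sigma_xy", "psf_sigma_z", "voxel_xy", "voxel_z")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("optics parameters must be strictly positive")
        return v

    @field_validator("background")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("background must be >= 0")
        return v

    @model_validator(mode="after")
    def _anisotropic(self) -> "OpticsConfig":
        if self.psf_sigma_z < self.psf_sigma_xy:
            raise ValueError("psf_sigma_z must be >= psf_sigma_xy (axial blur)")
        return self


def sim_optics() -> OpticsConfig:
    """SIM-reconstruction-like preset (lateral sigma 50 nm, axial 140 nm)."""
    return OpticsConfig()


def widefield_optics() -> OpticsConfig:
    """Wide-field preset: 2x2-binned camera, 0.8 um z step."""
    return OpticsConfig(
        psf_sigma_xy=110.0, psf_sigma_z=300.0, voxel_xy=129.0, voxel_z=800.0,
        background=10.0,
    )


class NoiseConfig(BaseModel):
    """Camera noise model: Poisson shot noise plus Gaussian read noise."""

    poisson: bool = True
    read_sigma: float = 1.0

    @field_validator("read_sigma")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("read_sigma must be >= 0")
        return v


class GeometryConfig(BaseModel):
    """Scene geometry of the simulated SPBs."""

    ip_op_separation: float = 150.0  # nm along the plaque axis
    max_tilt_deg: float = 30.0  # axis tilt out of the focal plane, non-top-view
    top_view_fraction: float = Field(0.12, ge=0.0, le=1.0)
    top_view_jitter_deg: float = 5.0
    bridge: bool = True

    @field_validator("ip_op_separation")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("ip_op_separation must be > 0")
        return v


class AsymmetryConfig(BaseModel):
    """Label amplitudes and fold-ratios of the simulated structures.

    ``old_new_fold`` is the old:new outer-plaque intensity fold of the query
    label (>= 1; ``inf`` means no label at the new outer plaque).
    ``ip_op_ratio`` is the inner:outer plaque ratio of the query label
    (default 2.5, inside the ~2-3 range measured for gamma-tubulin-complex
    components).  ``ref_old_new_fold`` is the modest brightness advantage of
    the old SPB in the reference channel used for old/new assignment.
    """

    amplitude: float = 10000.0  # query-label outer-plaque flux, old SPB
    ref_amplitude: float = 10000.0
    old_new_fold: float = 1.0
    ip_old_new_fold: float = 1.0
    ip_op_ratio: float = 2.5
    ref_old_new_fold: float = 1.5
    bridge_fraction: float = 0.5  # bridge flux as a fraction of the old OP

    @field_validator("old_new_fold", "ip_old_new_fold", "ref_old_new_fold")
    @classmethod
    def _fold(cls, v: float) -> float:
        if not v >= 1.0:
            raise ValueError("fold-ratios must be >= 1")
        return v

    @field_validator("amplitude", "ref_amplitude", "ip_op_ratio",
                     "bridge_fraction")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("amplitudes and ratios must be >= 0")
        return v


class ThresholdConfig(BaseModel):
    """Classification and exclusion thresholds."""

    strong_fold: float = 8.0  # >= -> strongly asymmetric
    sym_fold: float = 1.3  # < -> symmetric
    stage_boundaries_um: tuple[float, float, float] = (0.35, 1.0, 2.5)
    overlap_sigma_factor: float = 2.0  # top-view lateral overlap, x sigma_xy
    mad_factor: float = 3.0  # detection floor = median + mad_factor * MAD


class RunConfig(BaseModel):
    """Full configuration of an end-to-end synthetic pipeline run."""

    seed: int = 0
    n: int = 50
    stage_mix: dict[str, float] = {"short_spindle_lt1": 1.0}
    ploidy: int = Field(1, ge=1, le=2)
    genotype: str = "WT"
    channels: tuple[str, str] = ("Spc42", "Tub4")
    optics: OpticsConfig = Field(default_factory=sim_optics)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    asymmetry: AsymmetryConfig = Field(default_factory=AsymmetryConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    linescan_width_px: int = 3
    out_dir: Optional[str] = None

    @field_validator("stage_mix")
    @classmethod
    def _mix(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("stage_mix must not be empty")
        unknown = set(v) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage labels: {sorted(unknown)}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage_mix proportions must sum to 1 (got {total})")
        return v

    @field_validator("linescan_width_px")
    @classmethod
    def _width(cls, v: int) -> int:
        if v not in (1, 3, 5):
            raise ValueError("linescan width must be 1, 3 or 5 px")
        return v


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
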