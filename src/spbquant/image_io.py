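"""Image-stack and table input/output.

Stacks are stored as plain multi-page TIFF with page ordering Z,C,Y,X and a
JSON sidecar (``<stem>.json``) recording channel names, voxel sizes and the
source identifier.  OME-style ``ImageDescription`` metadata, when present,
is used as a fallback for voxel sizes.  Pixel round-trips are lossless and
dtype-preserving.

Seed tables (the stand-in for the manual spot identification step) and
result tables are CSV; result tables are accompanied by a JSON schema header
file so they can be re-read with stable dtypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack", "SeedGroup", "read_stack", "write_stack", "read_seeds",
    "write_seeds", "write_result_table", "read_result_table",
    "MissingMetadataError", "SeedTableError",
]


class MissingMetadataError(ValueError):
    """Raised when voxel sizes are neither stored with the image nor supplied."""


class SeedTableError(ValueError):
    """Raised for malformed seed tables; the message names offending lines."""


@dataclass
class ImageStack:
    """A multi-channel 3D intensity grid with physical voxel sizes.

    ``pixels`` has axes (channel, z, y, x).  Continuous positions are in nm
    with voxel index (0, 0, 0) centred at (voxel_xy/2, voxel_xy/2,
    voxel_z/2); ``origin_nm`` records the offset of the stack frame inside a
    larger scene frame (zero for acquired data).
    """

    pixels: np.ndarray
    channels: list[str]
    voxel_xy: float
    voxel_z: float
    source_id: str = ""
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 3:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 4:
            raise ValueError("pixels must have axes (channel, z, y, x)")
        if len(self.channels) != self.pixels.shape[0]:
            raise ValueError("channel names must match pixel channel axis")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        self.origin_nm = np.asarray(self.origin_nm, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.pixels.shape[1:]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channels.index(channel)
        return int(channel)

    def channel_pixels(self, channel: int | str) -> np.ndarray:
        return self.pixels[self.channel_index(channel)]

    def to_stack_coords(self, position_nm: np.ndarray) -> np.ndarray:
        """Scene-frame (x, y, z) nm -> stack-frame (x, y, z) nm."""
        return np.asarray(position_nm, dtype=float) - self.origin_nm

    def voxel_of(self, position_nm: np.ndarray) -> tuple[int, int, int]:
        """Stack-frame position (x, y, z) nm -> containing voxel (z, y, x)."""
        x, y, z = np.asarray(position_nm, dtype=float)
        return (int(z // self.voxel_z), int(y // self.voxel_xy),
                int(x // self.voxel_xy))

    def physical_extent(self) -> np.ndarray:
        nz, ny, nx = self.shape_zyx
        return np.array([nx * self.voxel_xy, ny * self.voxel_xy,
                         nz * self.voxel_z])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF (Z,C,Y,X) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.moveaxis(stack.pixels, 0, 1)  # (Z, C, Y, X)
    tifffile.imwrite(path, arr, metadata={"axes": "ZCYX"})
    meta = {
        "axes": "ZCYX",
        "channels": list(stack.channels),
        "voxel_xy_nm": stack.voxel_xy,
        "voxel_z_nm": stack.voxel_z,
        "source_id": stack.source_id,
        "origin_nm": list(map(float, stack.origin_nm)),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path, voxel_xy: Optional[float] = None,
               voxel_z: Optional[float] = None,
               channels: Optional[Sequence[str]] = None) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack` (or compatible).

    Voxel sizes come from the JSON sidecar when present; otherwise they must
    be supplied explicitly, else :class:`MissingMetadataError` is raised.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]  # (Z, Y, X) -> single channel
    if arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {arr.shape}")
    pixels = np.moveaxis(arr, 1, 0)  # (C, Z, Y, X)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    vxy = voxel_xy if voxel_xy is not None else meta.get("voxel_xy_nm")
    vz = voxel_z if voxel_z is not None else meta.get("voxel_z_nm")
    if vxy is None or vz is None:
        raise MissingMetadataError(
            f"{path}: no voxel-size metadata found; pass voxel_xy/voxel_z")
    names = list(channels) if channels is not None else meta.get("channels")
    if names is None:
        names = [f"ch{i}" for i in range(pixels.shape[0])]
    return ImageStack(
        pixels=pixels, channels=names, voxel_xy=float(vxy), voxel_z=float(vz),
        source_id=meta.get("source_id", path.stem),
        origin_nm=np.asarray(meta.get("origin_nm", [0.0, 0.0, 0.0])),
    )


@dataclass
class SeedGroup:
    """Seed coordinates for one candidate SPB (pair), in scene nm."""

    source_id: str
    pair_id: str
    points: list[np.ndarray]


SEED_COLUMNS = ("source_id", "pair_id", "x_nm", "y_nm", "z_nm")


def read_seeds(path) -> list[SeedGroup]:
    """Read a seed table; rows sharing (source_id, pair_id) form one group."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"source_id": str, "pair_id": str})
    if df.empty:
        return []
    missing = set(SEED_COLUMNS) - set(df.columns)
    if missing:
        raise SeedTableError(f"{path}: missing columns {sorted(missing)}")
    bad: list[str] = []
    for col in ("x_nm", "y_nm", "z_nm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna()]:
            bad.append(f"line {idx + 2}: non-numeric {col}={df.loc[idx, col]!r}")
        df[col] = vals
    if bad:
        raise SeedTableError(f"{path}: malformed rows:\n" + "\n".join(bad))
    groups: list[SeedGroup] = []
    for (src, pid), sub in df.groupby(["source_id", "pair_id"], sort=False):
        pts = [np.array([r.x_nm, r.y_nm, r.z_nm]) for r in sub.itertuples()]
        groups.append(SeedGroup(source_id=src, pair_id=pid, points=pts))
    return groups


def write_seeds(groups: list[SeedGroup], path) -> Path:
    path = Path(path)
    rows = []
    for g in groups:
        for p in g.points:
            rows.append({"source_id": g.source_id, "pair_id": g.pair_id,
                         "x_nm": p[0], "y_nm": p[1], "z_nm": p[2]})
    pd.DataFrame(rows, columns=list(SEED_COLUMNS)).to_csv(path, index=False)
    return path


def write_result_table(df: pd.DataFrame, path) -> Path:
    """Write a result table as CSV plus a JSON schema header file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = df.reset_index(drop=True)
    df.to_csv(path, index=False)
    schema = {"columns": [{"name": c, "dtype": str(df[c].dtype)}
                          for c in df.columns]}
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))
    return path


def read_result_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    schema_path = path.with_suffix(".schema.json")
    if schema_path.exists():
        schema = json.loads(schema_path.read_text())
        for col in schema["columns"]:
            name, dtype = col["name"], col["dtype"]
            if name in df.columns and dtype == "object":
                df[name] = df[name].astype(object)
    return df
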