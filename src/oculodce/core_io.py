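"""Shared domain types, NIfTI reading/writing, configuration and run manifests.

Conventions used throughout the package:

* voxel indexing is 0-based; ``values[i, j, k]`` with axis order (x, y, z);
* world coordinates are millimetres in a right-handed patient frame;
* the orientation matrix maps index steps to world directions, so the affine
  is ``orientation @ diag(spacing)`` with the origin as translation;
* the time axis is seconds internally; Ktrans is reported in 1/min only at
  the reporting boundary.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "VolumeImage",
    "DynamicSeries",
    "FlipAngleSeries",
    "B1Map",
    "Mask",
    "AcquisitionParams",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_dynamic",
    "write_dynamic",
    "load_config",
    "RunManifest",
]


def _check_orientation(orientation: np.ndarray) -> np.ndarray:
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (3, 3):
        raise ValueError(f"orientation must be 3x3, got {orientation.shape}")
    if not np.allclose(orientation @ orientation.T, np.eye(3), atol=1e-5):
        raise ValueError("orientation matrix is not orthonormal")
    return orientation


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar grid with world geometry (spacing/origin in mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {values.ndim}D data")
        if min(values.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 per axis")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive numbers, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "orientation", _check_orientation(self.orientation))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 index -> world affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ (self.orientation @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.orientation @ np.diag(self.spacing))
        return (pts - np.asarray(self.origin)) @ inv.T

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        """A new volume sharing this geometry."""
        return VolumeImage(values, self.spacing, self.origin, self.orientation)

    def same_geometry(self, other: "VolumeImage", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.orientation, other.orientation, atol=atol)
        )

    def world_center(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.shape, dtype=float) - 1) / 2.0)[0]


@dataclass
class DynamicSeries:
    """An ordered 4D enhancement movie: frames on one grid plus timestamps (s)."""

    frames: list[VolumeImage]
    times: np.ndarray
    interval: float = 2.0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a dynamic series needs at least 2 frames")
        ref = self.frames[0]
        for i, f in enumerate(self.frames[1:], start=1):
            if not ref.same_geometry(f):
                raise ValueError(f"frame {i} geometry differs from frame 0")
        times = np.asarray(self.times, dtype=float)
        if times.shape != (len(self.frames),):
            raise ValueError(
                f"got {len(self.frames)} frames but {times.size} timestamps"
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.times = times

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def grid(self) -> VolumeImage:
        return self.frames[0]

    def stack(self) -> np.ndarray:
        """(nx, ny, nz, nt) array view of the series."""
        return np.stack([f.values for f in self.frames], axis=-1)

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        grid: VolumeImage,
        times: np.ndarray | None = None,
        interval: float = 2.0,
    ) -> "DynamicSeries":
        data = np.asarray(data)
        if data.ndim != 4:
            raise ValueError(f"expected 4D data, got {data.ndim}D")
        if times is None:
            times = np.arange(data.shape[-1]) * float(interval)
        frames = [grid.with_values(data[..., t]) for t in range(data.shape[-1])]
        return cls(frames, np.asarray(times, dtype=float), interval)


@dataclass
class FlipAngleSeries:
    """Multi-flip-angle SPGR volumes for variable-flip-angle T1 mapping."""

    volumes: list[VolumeImage]
    nominal_flip_angles_deg: np.ndarray
    tr_ms: float

    def __post_init__(self) -> None:
        angles = np.asarray(self.nominal_flip_angles_deg, dtype=float)
        if len(self.volumes) != angles.size:
            raise ValueError("one flip angle required per volume")
        if angles.size < 2:
            raise ValueError("need at least 2 flip angles")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("flip angles must be strictly increasing")
        if np.any(angles <= 0) or np.any(angles >= 90):
            raise ValueError("flip angles must lie in (0, 90) degrees")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        self.nominal_flip_angles_deg = angles

    def stack(self) -> np.ndarray:
        """(n_angles, nx, ny, nz)."""
        return np.stack([v.values for v in self.volumes], axis=0)

    @property
    def grid(self) -> VolumeImage:
        return self.volumes[0]


@dataclass
class B1Map:
    """Relative achieved transmit field: effective/nominal flip-angle fraction."""

    fraction: VolumeImage

    def __post_init__(self) -> None:
        vals = self.fraction.values
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("B1+ fractions must be finite and > 0")

    def as_fraction(self) -> np.ndarray:
        """Values as fractions; percent-style maps (median > 2) are rescaled."""
        vals = np.asarray(self.fraction.values, dtype=float)
        if np.median(vals) > 2.0:
            return vals / 100.0
        return vals


@dataclass
class Mask:
    """A binary region on a reference geometry."""

    image: VolumeImage
    label: str = "other"

    def __post_init__(self) -> None:
        vals = np.asarray(self.image.values)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        if self.label not in ("eye", "lesion", "other"):
            raise ValueError(f"unknown mask label {self.label!r}")
        object.__setattr__(self, "image", self.image.with_values(vals.astype(np.uint8)))

    @property
    def values(self) -> np.ndarray:
        return self.image.values

    def as_bool(self) -> np.ndarray:
        return self.image.values.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.image.values.sum())


@dataclass
class AcquisitionParams:
    """Sequence parameters needed for signal modelling and conversion.

    relaxivity_r1 is the gadolinium longitudinal relaxivity in L/(mmol*s);
    injection_delay_s is the time between scan start and bolus injection.
    """

    tr_dce_ms: float = 4.53
    flip_angle_dce_deg: float = 13.0
    tr_vfa_ms: float = 7.0
    relaxivity_r1: float = 3.4
    injection_delay_s: float = 6.0

    def __post_init__(self) -> None:
        for name in ("tr_dce_ms", "flip_angle_dce_deg", "tr_vfa_ms", "relaxivity_r1", "injection_delay_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class RigidTransform:
    """A rigid map y = R (x - c) + c + t in world (mm) coordinates.

    Stored as a rotation matrix plus translation so that composition and
    inversion are exact; Euler angles are derived on demand (intrinsic
    x-y-z convention, degrees).
    """

    def __init__(
        self,
        translation_mm: Sequence[float] = (0.0, 0.0, 0.0),
        rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
        center_mm: Sequence[float] = (0.0, 0.0, 0.0),
        matrix: np.ndarray | None = None,
    ) -> None:
        self.translation_mm = np.asarray(translation_mm, dtype=float)
        self.center_mm = np.asarray(center_mm, dtype=float)
        if matrix is not None:
            self.matrix = _check_orientation(matrix)
        else:
            self.matrix = Rotation.from_euler("xyz", rotation_deg, degrees=True).as_matrix()

    @property
    def rotation_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.matrix).as_euler("xyz", degrees=True)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.center_mm) @ self.matrix.T + self.center_mm + self.translation_mm

    def _as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, b) with y = A x + b."""
        b = self.center_mm + self.translation_mm - self.matrix @ self.center_mm
        return self.matrix, b

    @classmethod
    def _from_affine(cls, A: np.ndarray, b: np.ndarray, center: Sequence[float]) -> "RigidTransform":
        center = np.asarray(center, dtype=float)
        t = A @ center + b - center
        return cls(translation_mm=t, center_mm=center, matrix=A)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other))(x) == self(other(x))."""
        A1, b1 = self._as_affine()
        A2, b2 = other._as_affine()
        return RigidTransform._from_affine(A1 @ A2, A1 @ b2 + b1, self.center_mm)

    def inverse(self) -> "RigidTransform":
        A, b = self._as_affine()
        Ai = A.T
        return RigidTransform._from_affine(Ai, -Ai @ b, self.center_mm)

    def with_center(self, center_mm: Sequence[float]) -> "RigidTransform":
        A, b = self._as_affine()
        return RigidTransform._from_affine(A, b, center_mm)

    def is_identity(self, trans_tol_mm: float = 1e-9, rot_tol_deg: float = 1e-9) -> bool:
        return (
            np.all(np.abs(self.translation_mm) <= trans_tol_mm)
            and np.all(np.abs(self.rotation_deg) <= rot_tol_deg)
        )

    @classmethod
    def identity(cls, center_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center_mm=center_mm)

    def to_dict(self) -> dict:
        return {
            "translation_mm": self.translation_mm.tolist(),
            "rotation_deg": self.rotation_deg.tolist(),
            "center_mm": self.center_mm.tolist(),
        }

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        t = np.round(self.translation_mm, 4)
        r = np.round(self.rotation_deg, 4)
        return f"RigidTransform(t={t.tolist()} mm, r={r.tolist()} deg)"


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path) -> VolumeImage:
    """Read a 3D NIfTI-1 volume into a :class:`VolumeImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} holds {data.ndim}D data; expected a 3D volume")
    return _volume_from_affine(data, img.affine)


def _volume_from_affine(data: np.ndarray, affine: np.ndarray) -> VolumeImage:
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine: zero-length axis")
    orientation = lin / spacing
    return VolumeImage(data, tuple(spacing), tuple(affine[:3, 3]), orientation)


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_dynamic(
    path: str | Path,
    interval: float = 2.0,
    times: Sequence[float] | None = None,
) -> DynamicSeries:
    """Read a 4D NIfTI dynamic series.

    Timestamps default to ``i * interval`` seconds; an explicit list (one per
    frame) overrides that.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} holds {data.ndim}D data; expected a 4D series")
    if data.shape[-1] < 2:
        raise ValueError("dynamic series must have at least 2 frames")
    grid = _volume_from_affine(data[..., 0], img.affine)
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.size != data.shape[-1]:
            raise ValueError(
                f"{data.shape[-1]} frames but {times.size} timestamps supplied"
            )
    return DynamicSeries.from_array(data, grid, times=times, interval=interval)


def write_dynamic(series: DynamicSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.stack(), series.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Configuration and run manifest


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


@dataclass
class RunManifest:
    """A record of one pipeline run: config echo, stage parameters, outputs."""

    config: dict = field(default_factory=dict)
    version: str = "0.1.0"
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def record_stage(self, name: str, status: str, **params) -> None:
        self.stages[name] = {"status": status, **_jsonable(params)}

    def write(self, path: str | Path) -> None:
        payload = {
            "config": _jsonable(self.config),
            "version": self.version,
            "stages": self.stages,
            "outputs": _jsonable(self.outputs),
            "seeds": _jsonable(self.seeds),
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        tmp = Path(str(path) + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        tmp.replace(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, RigidTransform):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
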