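"""Core image-space types: 3-D intensity volumes and rigid transforms.

Conventions used throughout the package:

* arrays are indexed ``(axis0, axis1, axis2)`` with the scan (axial) axis
  first by default;
* physical coordinates are ``index * spacing`` in millimetres — phantom
  volumes carry no origin offset;
* a :class:`RigidTransform` maps *moving* (follow-up) physical coordinates
  into *fixed* (baseline) physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["Volume3D", "RigidTransform", "DEFAULT_VOXEL_MM"]

#: XtremeCT nominal isotropic voxel size in millimetres.
DEFAULT_VOXEL_MM = 0.082


@dataclass
class Volume3D:
    """A 3-D scalar intensity grid with isotropic-by-default voxel spacing.

    Parameters
    ----------
    data:
        3-D float array of intensities (arbitrary units).
    spacing_mm:
        Per-axis voxel spacing in millimetres.
    axial_axis:
        Which array axis is the scan (slice-stacking) axis.
    frame:
        Free-text frame label: ``"baseline"``, ``"followup"`` or
        ``"baseline-registered"``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (
        DEFAULT_VOXEL_MM,
        DEFAULT_VOXEL_MM,
        DEFAULT_VOXEL_MM,
    )
    axial_axis: int = 0
    frame: str = "baseline"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if np.isscalar(self.spacing_mm):
            self.spacing_mm = (float(self.spacing_mm),) * 3
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.axial_axis]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def axial_extent_mm(self) -> float:
        """Physical length of the scanned stack along the axial axis."""
        return self.n_slices * self.spacing_mm[self.axial_axis]

    def with_data(self, data: np.ndarray, frame: str | None = None) -> "Volume3D":
        return replace(self, data=data, frame=self.frame if frame is None else frame)

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices ``(..., 3)`` to physical mm coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing_mm)

    def mm_to_index(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Physical mm coordinates ``(..., 3)`` to (fractional) voxel indices."""
        return np.asarray(xyz_mm, dtype=float) / np.asarray(self.spacing_mm)

    def center_mm(self) -> np.ndarray:
        """Physical coordinate of the grid centre."""
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing_mm)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rotation + translation between physical coordinate frames.

    ``apply(x) = R @ x + t`` maps follow-up (moving) physical coordinates
    into baseline (fixed) physical coordinates; ``convention`` records this
    direction in serialized files.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    convention: str = "moving-to-fixed"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(
        cls,
        angles_rad: tuple[float, float, float],
        translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
        center_mm: tuple[float, float, float] | None = None,
    ) -> "RigidTransform":
        """Build from rotations about array axes 0, 1, 2 (axis 0 = axial).

        When ``center_mm`` is given the rotation pivots about that point and
        ``translation_mm`` is applied on top:
        ``x' = R (x - c) + c + t``.
        """
        R = Rotation.from_euler("xyz", angles_rad).as_matrix()
        t = np.asarray(translation_mm, dtype=float)
        if center_mm is not None:
            c = np.asarray(center_mm, dtype=float)
            t = c - R @ c + t
        return cls(rotation=R, translation_mm=t)

    def euler_angles(self, center_mm: tuple[float, float, float] | None = None):
        """Return (angles_rad, translation_mm) in the ``from_euler`` sense."""
        angles = Rotation.from_matrix(self.rotation).as_euler("xyz")
        t = self.translation_mm.copy()
        if center_mm is not None:
            c = np.asarray(center_mm, dtype=float)
            t = t - (c - self.rotation @ c)
        return angles, t

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return pts @ self.rotation.T + self.translation_mm

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation_mm=self.rotation @ other.translation_mm + self.translation_mm,
            convention=self.convention,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            rotation=Rinv,
            translation_mm=-Rinv @ self.translation_mm,
            convention=self.convention,
        )

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation_mm
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, convention: str = "moving-to-fixed"):
        M = np.asarray(M, dtype=float)
        return cls(rotation=M[:3, :3], translation_mm=M[:3, 3], convention=convention)
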