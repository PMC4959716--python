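"""9-DoF affine transforms: translation, rotation and anisotropic scale.

The transform maps world points of the primary (fixed) frame to world
points of the secondary (moving) frame:

    q = c + t + R S (p - c)

with rotation centre ``c`` (mm), translation ``t`` (mm), rotations in
degrees composed ``Rz @ Ry @ Rx`` and per-axis scales ``S``.  All world
coordinates are mm in a right-handed patient frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["AffineTransform9"]


@dataclass
class AffineTransform9:
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        self.scale = np.asarray(self.scale, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if np.any(self.scale <= 0):
            raise ValueError(f"scales must be positive, got {self.scale}")

    # -- parameter vector view (order fixed: t mm, r deg, s unitless) -----
    def to_params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation_deg, self.scale])

    @classmethod
    def from_params(cls, params: np.ndarray, center: np.ndarray) -> "AffineTransform9":
        params = np.asarray(params, dtype=float).reshape(9)
        return cls(
            translation=params[0:3],
            rotation_deg=params[3:6],
            scale=params[6:9],
            center=np.asarray(center, dtype=float),
        )

    @property
    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        Rx = Rotation.from_euler("x", rx).as_matrix()
        Ry = Rotation.from_euler("y", ry).as_matrix()
        Rz = Rotation.from_euler("z", rz).as_matrix()
        return Rz @ Ry @ Rx

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-to-world matrix of q = c + t + R S (p - c)."""
        A = self.rotation_matrix * self.scale[np.newaxis, :]
        M = np.eye(4)
        M[:3, :3] = A
        M[:3, 3] = self.center + self.translation - A @ self.center
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to (..., 3) world points."""
        points = np.asarray(points, dtype=float)
        M = self.as_matrix()
        return points @ M[:3, :3].T + M[:3, 3]

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.as_matrix())

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "translation_mm": self.translation.tolist(),
            "rotation_deg": self.rotation_deg.tolist(),
            "scale": self.scale.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform9":
        return cls(
            translation=d["translation_mm"],
            rotation_deg=d["rotation_deg"],
            scale=d["scale"],
            center=d["center_mm"],
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform9":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def identity(cls, center: np.ndarray | tuple = (0.0, 0.0, 0.0)) -> "AffineTransform9":
        return cls(center=np.asarray(center, dtype=float))
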