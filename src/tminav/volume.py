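"""Axis-aligned scalar voxel volumes with world-coordinate lookups."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class VoxelVolume:
    """Scalar voxel grid with isotropic-per-axis spacing.

    ``data[i, j, k]`` is the sample at world point
    ``origin + (i, j, k) * spacing`` (mm); world axes align with array axes.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float).reshape(3))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (mm)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def contains(self, point: np.ndarray) -> bool:
        idx = self.world_to_voxel(point)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.shape) - 1))

    def save(self, basepath: str | Path) -> None:
        """Write raw float32 voxels plus a JSON header next to it."""
        base = Path(basepath)
        self.data.astype(np.float32).tofile(base.with_suffix(".raw"))
        header = {
            "shape": list(self.shape),
            "spacing": self.spacing.tolist(),
            "origin": self.origin.tolist(),
            "dtype": "float32",
            "order": "C",
        }
        base.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, basepath: str | Path) -> "VoxelVolume":
        base = Path(basepath)
        header = json.loads(base.with_suffix(".json").read_text())
        data = np.fromfile(base.with_suffix(".raw"), dtype=np.float32).reshape(header["shape"])
        return cls(data=data, spacing=np.array(header["spacing"]), origin=np.array(header["origin"]))
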