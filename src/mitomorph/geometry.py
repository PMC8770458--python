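"""Anisotropic voxel geometry shared by all 3-D operations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Serial block-face SEM stacks are strongly anisotropic: the in-plane pixel
# pitch is set by the SEM raster while the z pitch is the block-face cutting
# increment.  Defaults correspond to a 13.5 x 13.5 x 50 nm acquisition.
DEFAULT_XY_NM = 13.5
DEFAULT_Z_NM = 50.0


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel size in nanometres.

    Arrays in this package are indexed ``(z, y, x)``; ``spacing`` returns the
    per-axis pitch in that order so it can be passed directly to scipy/skimage
    ``sampling``/``spacing`` arguments.
    """

    size_x_nm: float = DEFAULT_XY_NM
    size_y_nm: float = DEFAULT_XY_NM
    size_z_nm: float = DEFAULT_Z_NM

    def __post_init__(self) -> None:
        for name in ("size_x_nm", "size_y_nm", "size_z_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel pitch (z, y, x) in nm."""
        return (self.size_z_nm, self.size_y_nm, self.size_x_nm)

    @property
    def voxel_volume_nm3(self) -> float:
        return self.size_x_nm * self.size_y_nm * self.size_z_nm

    def scaled(self, k: float) -> "VoxelGeometry":
        """Geometry with every pitch multiplied by ``k`` (for equivariance checks)."""
        return VoxelGeometry(self.size_x_nm * k, self.size_y_nm * k, self.size_z_nm * k)

    def to_dict(self) -> dict:
        return {
            "size_x_nm": self.size_x_nm,
            "size_y_nm": self.size_y_nm,
            "size_z_nm": self.size_z_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        try:
            return cls(
                size_x_nm=float(d["size_x_nm"]),
                size_y_nm=float(d["size_y_nm"]),
                size_z_nm=float(d["size_z_nm"]),
            )
        except KeyError as exc:  # pragma: no cover - exercised via read_fixture
            raise ValueError(f"voxel geometry missing field {exc.args[0]!r}") from exc


def physical_coords(indices: np.ndarray, geom: VoxelGeometry) -> np.ndarray:
    """Map (n, 3) voxel indices (z, y, x) to nm coordinates."""
    return np.asarray(indices, dtype=float) * np.asarray(geom.spacing)
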