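"""Label-volume container and lossless fixture I/O.

A :class:`LabelVolume` is the unit of all 3-D analysis: a ``(z, y, x)``
unsigned-integer raster of mitochondrion labels, binary nucleus and
sarcolemma masks, a cardiomyocyte (cell) mask, and the anisotropic voxel
geometry.  Fixtures are written as plain multi-page TIFFs plus a JSON
sidecar holding the geometry and any ground truth, so a written volume
reads back bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from mitomorph.geometry import VoxelGeometry
from mitomorph.truth import CristaeImageTruth, GroundTruth

__all__ = ["LabelVolume", "GreyImage", "write_fixture", "read_fixture"]


@dataclass
class LabelVolume:
    """3-D mitochondrion label raster with context masks.

    ``labels``: 0 = background, >0 = one mitochondrion.  ``nucleus_mask`` and
    ``sarcolemma_mask`` mark the nuclear envelope region and the sarcolemma
    band; ``cell_mask`` marks the cardiomyocyte (the stereological reference
    space).  All arrays share one shape.
    """

    labels: np.ndarray
    nucleus_mask: np.ndarray | None
    sarcolemma_mask: np.ndarray | None
    geom: VoxelGeometry
    cell_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D (z, y, x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        for name in ("nucleus_mask", "sarcolemma_mask", "cell_mask"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m).astype(bool)
            if m.shape != self.labels.shape:
                raise ValueError(f"{name} shape {m.shape} != labels shape {self.labels.shape}")
            setattr(self, name, m)
        fg = self.labels > 0
        for name in ("nucleus_mask", "sarcolemma_mask"):
            m = getattr(self, name)
            if m is not None and np.any(fg & m):
                raise ValueError(f"{name} must be disjoint from mitochondrion voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def cardiomyocyte_mask(self) -> np.ndarray:
        """Reference space for volume fractions: the cell interior."""
        if self.cell_mask is not None:
            return self.cell_mask
        if self.sarcolemma_mask is not None:
            return ~self.sarcolemma_mask
        return np.ones(self.labels.shape, dtype=bool)

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mito_voxel_fraction(self) -> float:
        """Exact voxel-count fraction of the cardiomyocyte occupied by mitochondria."""
        cm = self.cardiomyocyte_mask
        denom = int(cm.sum())
        if denom == 0:
            raise ValueError("empty cardiomyocyte mask")
        return int(((self.labels > 0) & cm).sum()) / denom


@dataclass
class GreyImage:
    """2-D greyscale image with physical pixel size (TEM-style, dark membranes)."""

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _masks_path(path: Path) -> Path:
    return path.with_name(path.stem + ".masks.tif")


def write_fixture(obj, path, ground_truth=None) -> Path:
    """Write a LabelVolume or GreyImage plus its JSON sidecar.

    ``path`` names the primary TIFF; masks go into ``<stem>.masks.tif`` and
    geometry/ground truth into ``<stem>.json``.  Returns the primary path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta: dict = {"format": None}
    if isinstance(obj, LabelVolume):
        tifffile.imwrite(path, np.ascontiguousarray(obj.labels.astype(np.uint16)))
        zeros = np.zeros(obj.labels.shape, dtype=np.uint8)
        masks = np.stack(
            [
                zeros if obj.nucleus_mask is None else obj.nucleus_mask.astype(np.uint8),
                zeros if obj.sarcolemma_mask is None else obj.sarcolemma_mask.astype(np.uint8),
                obj.cardiomyocyte_mask.astype(np.uint8),
            ]
        )
        tifffile.imwrite(_masks_path(path), masks)
        meta["format"] = "label_volume"
        meta["geometry"] = obj.geom.to_dict()
        if ground_truth is not None:
            meta["ground_truth"] = ground_truth.to_dict()
    elif isinstance(obj, GreyImage):
        tifffile.imwrite(path, np.ascontiguousarray(obj.pixels))
        meta["format"] = "grey_image"
        meta["pixel_size_nm"] = obj.pixel_size_nm
        if ground_truth is not None:
            meta["ground_truth"] = ground_truth.to_dict()
    else:
        raise TypeError(f"cannot write fixture for {type(obj).__name__}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_fixture(path):
    """Read a fixture written by :func:`write_fixture`.

    Returns ``(object, ground_truth_or_None)``.  Malformed sidecars raise
    ``ValueError`` naming the offending field.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    fmt = meta.get("format")
    if fmt == "label_volume":
        labels = tifffile.imread(path)
        masks = tifffile.imread(_masks_path(path)).astype(bool)
        if "geometry" not in meta:
            raise ValueError("sidecar missing field 'geometry'")
        geom = VoxelGeometry.from_dict(meta["geometry"])
        vol = LabelVolume(
            labels=labels,
            nucleus_mask=masks[0],
            sarcolemma_mask=masks[1],
            geom=geom,
            cell_mask=masks[2],
        )
        truth = GroundTruth.from_dict(meta["ground_truth"]) if "ground_truth" in meta else None
        return vol, truth
    if fmt == "grey_image":
        if "pixel_size_nm" not in meta:
            raise ValueError("sidecar missing field 'pixel_size_nm'")
        img = GreyImage(tifffile.imread(path), float(meta["pixel_size_nm"]))
        truth = (
            CristaeImageTruth.from_dict(meta["ground_truth"]) if "ground_truth" in meta else None
        )
        return img, truth
    raise ValueError(f"sidecar field 'format' unrecognised: {fmt!r}")
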