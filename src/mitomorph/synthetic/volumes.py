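"""Synthetic 3-D cardiomyocyte label volumes.

The phantom emulates the geometry a block-face SEM segmentation of
myocardium yields: a cell bounded by sarcolemma bands, a central nucleus,
SSM packed against the sarcolemma, IFM in strand-like rows separated by
unlabeled myofibril slabs, and PNM ringing the nuclear envelope.  Bodies are
randomly oriented ellipsoids; "irregular" bodies add a low-order
spherical-harmonic radial perturbation; tubular projections are capsules
appended to a body; a nanotunnel is two bodies joined by a capsule.  These
primitives make length and surface ground truth analytic.

All placements are strictly disjoint (rejection sampling, bounded retries)
and keep one voxel clear of the raster boundary, which also keeps the
stereological counting frame free of genuinely clipped objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from mitomorph.geometry import VoxelGeometry
from mitomorph.truth import GroundTruth, NanotunnelTruth, ObjectTruth, ProjectionTruth
from mitomorph.volume import LabelVolume

SUBTYPES = ("SSM", "IFM", "PNM")

# Mean body volumes (nm^3) per subpopulation for a wild-type-like heart;
# PNM run markedly smaller than SSM/IFM.
_WT_BODY_VOLUME = {"SSM": 7.23e8, "IFM": 7.29e8, "PNM": 3.70e8}
# Tubular-projection length / tip-width distributions (um, mean and sd).
_WT_PROJ_LENGTH = {"SSM": (0.574, 0.415), "IFM": (0.432, 0.242), "PNM": (0.488, 0.316)}
_WT_PROJ_WIDTH = {"SSM": (0.220, 0.068), "IFM": (0.253, 0.106), "PNM": (0.215, 0.075)}

_FULL_STRUCT = np.ones((3, 3, 3), dtype=bool)


class CapacityError(RuntimeError):
    """Raised when the requested objects cannot be placed without overlap."""


def _normalized(mix: dict[str, float], what: str) -> dict[str, float]:
    vals = np.array([mix[s] for s in SUBTYPES], dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"{what} proportions must lie in [0, 1]")
    total = vals.sum()
    if not np.isclose(total, 1.0, atol=0.02):
        raise ValueError(f"{what} proportions must sum to 1, got {total:.3f}")
    vals = vals / total
    return dict(zip(SUBTYPES, vals))


@dataclass
class VolumeParams:
    """Study conditions for one synthetic cardiomyocyte volume.

    Defaults reproduce a wild-type-like myocardium: mitochondria occupy
    30.2% of the cell, split 15.3 / 80.1 / 4.7% between SSM / IFM / PNM by
    voxel volume; the IFM oval:irregular mix is 69:31.
    """

    shape_zyx: tuple[int, int, int] = (48, 512, 512)
    target_mito_fraction: float = 0.302
    subtype_mix: dict[str, float] = field(
        default_factory=lambda: {"SSM": 0.153, "IFM": 0.801, "PNM": 0.047}
    )
    oval_fraction: dict[str, float] = field(
        default_factory=lambda: {"SSM": 0.45, "IFM": 0.69, "PNM": 0.45}
    )
    projection_prob: dict[str, float] = field(
        default_factory=lambda: {"SSM": 0.20, "IFM": 0.12, "PNM": 0.28}
    )
    projection_length_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_WT_PROJ_LENGTH)
    )
    projection_tip_width_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_WT_PROJ_WIDTH)
    )
    mean_body_volume_nm3: dict[str, float] = field(
        default_factory=lambda: dict(_WT_BODY_VOLUME)
    )
    body_volume_cv: float = 0.25
    oval_amplitude: float = 0.05
    irregular_amplitude: float = 0.30
    n_nanotunnels: int = 0
    nanotunnel_length_range_um: tuple[float, float] = (1.1, 1.91)
    nanotunnel_diameter_range_um: tuple[float, float] = (0.28, 0.33)
    include_nucleus: bool = True
    myofibril_width_nm: float = 800.0
    max_retries: int = 100
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.target_mito_fraction <= 1.0:
            raise ValueError("target_mito_fraction must lie in [0, 1]")
        _normalized(self.subtype_mix, "subtype_mix")
        for s in SUBTYPES:
            if not 0.0 <= self.oval_fraction[s] <= 1.0:
                raise ValueError("oval_fraction must lie in [0, 1]")
            if not 0.0 <= self.projection_prob[s] <= 1.0:
                raise ValueError("projection_prob must lie in [0, 1]")
            for name in ("projection_length_um", "projection_tip_width_um"):
                if getattr(self, name)[s][1] < 0:
                    raise ValueError(f"{name} sd must be >= 0")
        if self.n_nanotunnels < 0:
            raise ValueError("n_nanotunnels must be >= 0")
        if not 0.0 <= self.oval_amplitude < self.irregular_amplitude <= 0.6:
            raise ValueError("need 0 <= oval_amplitude < irregular_amplitude <= 0.6")
        if len(self.shape_zyx) != 3 or any(int(d) < 1 for d in self.shape_zyx):
            raise ValueError("shape_zyx must have three dims >= 1")


# --------------------------------------------------------------------------
# Low-order spherical-harmonic radial perturbation.
#
# Real surface harmonics of degree 2 and 3 written as Cartesian polynomials
# on the unit sphere; normalisation constants are absorbed into the random
# coefficients, and the drawn field is rescaled so the amplitude parameter
# equals the maximum fractional radial perturbation.
# --------------------------------------------------------------------------

def _harmonic_basis(ux, uy, uz):
    return [
        ux * uy,
        uy * uz,
        ux * uz,
        ux * ux - uy * uy,
        3.0 * uz * uz - 1.0,
        uz * (5.0 * uz * uz - 3.0),
        ux * (5.0 * uz * uz - 1.0),
        uy * (5.0 * uz * uz - 1.0),
        uz * (ux * ux - uy * uy),
        ux * uy * uz,
        ux * (ux * ux - 3.0 * uy * uy),
        uy * (3.0 * ux * ux - uy * uy),
    ]


_N_HARMONICS = 12


def _fibonacci_dirs(n: int = 400) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z])


_PROBE_DIRS = _fibonacci_dirs()


def _draw_field(rng: np.random.Generator) -> np.ndarray:
    """Random harmonic coefficients scaled so max |field| == 1 on the sphere."""
    coeffs = rng.normal(size=_N_HARMONICS)
    vals = _eval_field(_PROBE_DIRS[0], _PROBE_DIRS[1], _PROBE_DIRS[2], coeffs, 1.0)
    scale = np.abs(vals).max()
    return coeffs / max(scale, 1e-9)


def _eval_field(ux, uy, uz, coeffs: np.ndarray, scale: float = 1.0):
    basis = _harmonic_basis(ux, uy, uz)
    out = coeffs[0] * basis[0]
    for c, b in zip(coeffs[1:], basis[1:]):
        out = out + c * b
    return out * scale


def _random_rotation(rng: np.random.Generator, tilt_sd: float = 0.15) -> np.ndarray:
    """Rotation with free in-plane yaw and modest out-of-plane tilt.

    Axis order is (z, y, x) to match array indexing.
    """
    yaw = rng.uniform(0.0, 2.0 * np.pi)
    pitch = rng.normal(0.0, tilt_sd)
    roll = rng.normal(0.0, tilt_sd)
    cz, sz = math.cos(yaw), math.sin(yaw)
    cy, sy = math.cos(pitch), math.sin(pitch)
    cx, sx = math.cos(roll), math.sin(roll)
    # rotations about the z (yaw, in the x-y plane), y and x axes
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _thomsen_area(semi: np.ndarray) -> float:
    """Knud Thomsen approximation to the ellipsoid surface area (<1.1% error)."""
    a, b, c = semi
    p = 1.6075
    return 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def _volume_factor(p: float) -> float:
    """Volume of the unit superellipsoid |x|^p + |y|^p + |z|^p <= 1."""
    from scipy.special import gamma

    return 8.0 * gamma(1.0 + 1.0 / p) ** 3 / gamma(1.0 + 3.0 / p)


# body aspect ranges (fraction of the long semi-axis): rod-like bodies,
# elongated along the fibre (x) axis and flattest along the cutting (z) axis,
# as cardiac interfibrillar mitochondria in block-face stacks are
_ASPECT_Z = (0.35, 0.50)
_ASPECT_Y = (0.50, 0.70)


def _semis_for_volume(rng: np.random.Generator, volume_nm3: float, p: float) -> np.ndarray:
    """Semi-axes (z, y, x order in the local frame) with a random rod aspect."""
    aspect = np.array([rng.uniform(*_ASPECT_Z), rng.uniform(*_ASPECT_Y), 1.0])
    s = (volume_nm3 / (_volume_factor(p) * np.prod(aspect))) ** (1.0 / 3.0)
    return s * aspect


def _typical_extents_vox(volume_nm3: float, geom: VoxelGeometry) -> np.ndarray:
    """Expected body extents (z, y, x) in voxels for layout planning."""
    aspect = np.array([np.mean(_ASPECT_Z), np.mean(_ASPECT_Y), 1.0])
    s = (volume_nm3 / (_volume_factor(2.5) * np.prod(aspect))) ** (1.0 / 3.0)
    return 2.0 * s * aspect / np.array(geom.spacing)


def _surface_area_truth(
    semi: np.ndarray, amp: float, coeffs: np.ndarray, p: float, n_theta: int = 180
) -> float:
    """Surface area of the (possibly perturbed) superellipsoid body.

    Numerical integration over a parametric (theta, phi) mesh of the radial
    surface r(dir) = t(dir) * dir with t = (1 + amp*f) / rho_p(dir); serves
    as the analytic oracle for mesh-based surface measurements.
    """
    n_phi = 2 * n_theta
    theta = np.linspace(0.0, math.pi, n_theta + 1)
    phi = np.linspace(0.0, 2.0 * math.pi, n_phi + 1)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    # local-frame direction components in (z, y, x) order
    dz = np.cos(tt)
    dy = np.sin(tt) * np.sin(pp)
    dx = np.sin(tt) * np.cos(pp)
    rho = (
        np.abs(dz / semi[0]) ** p + np.abs(dy / semi[1]) ** p + np.abs(dx / semi[2]) ** p
    ) ** (1.0 / p)
    scale = 1.0
    if amp > 0:
        scale = 1.0 + amp * _eval_field(dx, dy, dz, coeffs)
    t = scale / np.maximum(rho, 1e-12)
    verts = np.stack([t * dz, t * dy, t * dx], axis=-1)
    a = verts[:-1, :-1]
    b = verts[1:, :-1]
    c = verts[:-1, 1:]
    d = verts[1:, 1:]
    area1 = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
    area2 = 0.5 * np.linalg.norm(np.cross(d - b, d - c), axis=-1)
    return float(area1.sum() + area2.sum())


def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def _inplane_direction(rng: np.random.Generator, z_sd: float = 0.12) -> np.ndarray:
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return _unit(np.array([rng.normal(0.0, z_sd), math.sin(phi), math.cos(phi)]))


@dataclass
class _BuiltObject:
    mask: np.ndarray  # local boolean raster
    center_idx: tuple[int, int, int]  # index of the body centre inside ``mask``
    shape_class: str
    surface_area_nm2: float | None
    projections: list[ProjectionTruth]
    nanotunnel: NanotunnelTruth | None
    extent_x: int  # occupied x-extent in voxels (strand cursor advance)


def _boundary_distance(u_world: np.ndarray, rot: np.ndarray, semi: np.ndarray,
                       amp: float, coeffs: np.ndarray, p: float = 2.0) -> float:
    """Distance from body centre to the perturbed surface along ``u_world``."""
    local = rot.T @ u_world
    rho = float(np.sum(np.abs(local / semi) ** p)) ** (1.0 / p)
    f = float(_eval_field(local[2], local[1], local[0], coeffs))
    return (1.0 + amp * f) / max(rho, 1e-12)


def _build_object(
    rng: np.random.Generator,
    geom: VoxelGeometry,
    volume_nm3: float,
    shape_class: str,
    amp: float,
    proj_dims_nm: Sequence[tuple[float, float]] = (),
    tunnel: tuple[float, float, float] | None = None,
) -> _BuiltObject:
    """Rasterize one mitochondrion (body + optional capsules) in a local box.

    ``proj_dims_nm``: per projection (length, tip_radius) in nm.
    ``tunnel``: (tube_length_nm, tube_radius_nm, partner_volume_nm3) builds a
    dumbbell: two bodies joined by a capsule, emitted as one label.
    """
    spacing = np.array(geom.spacing)
    # superellipsoid exponent: 2 = ellipsoid, towards 3 = rounded brick
    p_exp = float(rng.uniform(2.0, 3.0))
    semi = _semis_for_volume(rng, volume_nm3, p_exp)
    rot = _random_rotation(rng)
    coeffs = _draw_field(rng)

    # capsule segments [(a, b, radius)], coordinates in nm relative to centre
    capsules: list[tuple[np.ndarray, np.ndarray, float]] = []
    projections: list[ProjectionTruth] = []
    for length_nm, tip_r_nm in proj_dims_nm:
        u = _inplane_direction(rng)
        t_surf = _boundary_distance(u, rot, semi, amp, coeffs, p_exp)
        p0 = t_surf * u
        tip = p0 + length_nm * u
        a = p0 - min(2.0 * tip_r_nm, 0.5 * t_surf) * u
        b = tip - tip_r_nm * u
        capsules.append((a, b, tip_r_nm))
        projections.append(ProjectionTruth(length_um=length_nm / 1e3,
                                           tip_width_um=2.0 * tip_r_nm / 1e3))

    nanotunnel = None
    body2: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None  # centre, semi, rot
    if tunnel is not None:
        tube_len, tube_r, vol2 = tunnel
        u = _inplane_direction(rng, z_sd=0.05)
        semi2 = _semis_for_volume(rng, vol2, p_exp)
        rot2 = _random_rotation(rng)
        t1 = _boundary_distance(u, rot, semi, amp, coeffs, p_exp)
        t2 = _boundary_distance(-u, rot2, semi2, amp, coeffs, p_exp)
        c2 = (t1 + tube_len + t2) * u
        embed = 2.0 * tube_r
        a = (t1 - embed) * u
        b = c2 - (t2 - embed) * u
        capsules.append((a, b, tube_r))
        body2 = (c2, semi2, rot2)
        nanotunnel = NanotunnelTruth(tube_length_um=tube_len / 1e3,
                                     tube_diameter_um=2.0 * tube_r / 1e3)

    # local grid extents (nm): tight per-axis support of the rotated body
    # (dual-norm support function of the superellipsoid), plus appendages
    q_exp = p_exp / (p_exp - 1.0)

    def support(rot_b, semi_b):
        ax = np.abs(semi_b[None, :] * rot_b)  # row i: |semi * (R^T e_i)|
        return ((ax**q_exp).sum(axis=1)) ** (1.0 / q_exp) * (1.0 + amp)

    reach = support(rot, semi)
    lo = -reach
    hi = reach.copy()
    for a, b, r in capsules:
        lo = np.minimum(lo, np.minimum(a, b) - r)
        hi = np.maximum(hi, np.maximum(a, b) + r)
    if body2 is not None:
        c2, semi2, rot2_ = body2
        r2 = support(rot2_, semi2)
        lo = np.minimum(lo, c2 - r2)
        hi = np.maximum(hi, c2 + r2)
    lo -= spacing
    hi += spacing
    n_lo = np.ceil(-lo / spacing).astype(int)
    n_hi = np.ceil(hi / spacing).astype(int)

    axes = [
        (np.arange(-n_lo[i], n_hi[i] + 1) * spacing[i]).astype(np.float32)
        for i in range(3)
    ]
    pz = axes[0][:, None, None]
    py = axes[1][None, :, None]
    px = axes[2][None, None, :]

    def body_mask(center, semi_b, rot_b):
        dz = pz - center[0]
        dy = py - center[1]
        dx = px - center[2]
        lz = rot_b[0, 0] * dz + rot_b[1, 0] * dy + rot_b[2, 0] * dx
        ly = rot_b[0, 1] * dz + rot_b[1, 1] * dy + rot_b[2, 1] * dx
        lx = rot_b[0, 2] * dz + rot_b[1, 2] * dy + rot_b[2, 2] * dx
        rho = (
            np.abs(lz / semi_b[0]) ** p_exp
            + np.abs(ly / semi_b[1]) ** p_exp
            + np.abs(lx / semi_b[2]) ** p_exp
        ) ** (1.0 / p_exp)
        if amp > 0:
            norm = np.sqrt(lz * lz + ly * ly + lx * lx)
            norm = np.maximum(norm, 1e-6)
            f = _eval_field(lx / norm, ly / norm, lz / norm, coeffs)
            return rho <= 1.0 + amp * f
        return rho <= 1.0

    mask = body_mask(np.zeros(3), semi, rot)
    if body2 is not None:
        c2, semi2, rot2 = body2
        mask |= body_mask(c2, semi2, rot2)
    for a, b, r in capsules:
        d = b - a
        dd = float(d @ d)
        qz = pz - a[0]
        qy = py - a[1]
        qx = px - a[2]
        t = (qz * d[0] + qy * d[1] + qx * d[2]) / max(dd, 1e-12)
        t = np.clip(t, 0.0, 1.0)
        dist2 = (qz - t * d[0]) ** 2 + (qy - t * d[1]) ** 2 + (qx - t * d[2]) ** 2
        mask |= dist2 <= r * r

    sa = None
    if not capsules and body2 is None:
        sa = _surface_area_truth(semi, amp, coeffs, p_exp)

    occ = np.argwhere(mask)
    extent_x = int(occ[:, 2].max() - occ[:, 2].min()) + 1 if len(occ) else 0
    return _BuiltObject(
        mask=mask,
        center_idx=(int(n_lo[0]), int(n_lo[1]), int(n_lo[2])),
        shape_class=shape_class,
        surface_area_nm2=sa,
        projections=projections,
        nanotunnel=nanotunnel,
        extent_x=extent_x,
    )


# --------------------------------------------------------------------------
# Placement canvas
# --------------------------------------------------------------------------

class _Canvas:
    def __init__(self, shape: tuple[int, int, int], geom: VoxelGeometry):
        self.shape = shape
        self.geom = geom
        self.labels = np.zeros(shape, dtype=np.uint16)
        self.nucleus = np.zeros(shape, dtype=bool)
        self.sarcolemma = np.zeros(shape, dtype=bool)
        self.cell = np.ones(shape, dtype=bool)

    def _window(self, built: _BuiltObject, center: tuple[int, int, int]):
        """Global slice window for ``built.mask`` centred at ``center``.

        Returns (slices, cropped_mask) or None if occupied voxels would fall
        outside the 1-voxel interior margin.
        """
        cz, cy, cx = built.center_idx
        lo = np.array([center[0] - cz, center[1] - cy, center[2] - cx])
        hi = lo + np.array(built.mask.shape)
        clip_lo = np.maximum(lo, 1)
        clip_hi = np.minimum(hi, np.array(self.shape) - 1)
        if np.any(clip_lo >= clip_hi):
            return None
        mask = built.mask[
            clip_lo[0] - lo[0] : built.mask.shape[0] - (hi[0] - clip_hi[0]),
            clip_lo[1] - lo[1] : built.mask.shape[1] - (hi[1] - clip_hi[1]),
            clip_lo[2] - lo[2] : built.mask.shape[2] - (hi[2] - clip_hi[2]),
        ]
        if mask.sum() != built.mask.sum():
            return None  # clipped at the raster boundary
        sl = tuple(slice(int(a), int(b)) for a, b in zip(clip_lo, clip_hi))
        return sl, mask

    def _dilated(self, mask: np.ndarray, it: int) -> np.ndarray:
        return ndimage.binary_dilation(mask, structure=_FULL_STRUCT, iterations=it)

    def check(self, built, center, forbid_near=(), require_near=None, gap: int = 2):
        """Validate a placement; returns (slices, mask) or None.

        ``forbid_near``: masks that must stay more than ``gap`` voxels away
        (so downstream contact classification stays unambiguous).
        ``require_near``: a mask the object must touch within one voxel.
        """
        win = self._window(built, center)
        if win is None:
            return None
        sl, mask = win
        if self.labels[sl][mask].any():
            return None
        if self.nucleus[sl][mask].any() or self.sarcolemma[sl][mask].any():
            return None
        if not self.cell[sl][mask].all():
            return None
        if forbid_near or require_near is not None:
            # dilate in a window padded by ``gap`` so contact just outside the
            # object's bounding box is still seen
            pad_lo = [min(gap, s.start) for s in sl]
            pad_hi = [min(gap, self.shape[i] - sl[i].stop) for i in range(3)]
            sl_ext = tuple(
                slice(sl[i].start - pad_lo[i], sl[i].stop + pad_hi[i]) for i in range(3)
            )
            padded = np.pad(mask, list(zip(pad_lo, pad_hi)))
            grown = self._dilated(padded, gap)
            for m in forbid_near:
                if m[sl_ext][grown].any():
                    return None
            if require_near is not None and not require_near[sl_ext][grown].any():
                return None
        return sl, mask

    def paint(self, sl, mask, label: int) -> int:
        self.labels[sl][mask] = label
        return int(mask.sum())


# --------------------------------------------------------------------------
# Generator
# --------------------------------------------------------------------------

def _ellipsoid_mask(shape, center_vox, semi_nm, geom) -> np.ndarray:
    spacing = np.array(geom.spacing)
    zz = (np.arange(shape[0]) - center_vox[0]) * spacing[0]
    yy = (np.arange(shape[1]) - center_vox[1]) * spacing[1]
    xx = (np.arange(shape[2]) - center_vox[2]) * spacing[2]
    e = (
        (zz[:, None, None] / semi_nm[0]) ** 2
        + (yy[None, :, None] / semi_nm[1]) ** 2
        + (xx[None, None, :] / semi_nm[2]) ** 2
    )
    return e <= 1.0


class _QuotaSampler:
    """Online largest-remainder class assignment tracking a target fraction."""

    def __init__(self, fraction: float):
        self.fraction = fraction
        self.n = 0
        self.k = 0

    def draw(self) -> bool:
        take = self.k < round(self.fraction * (self.n + 1))
        self.n += 1
        self.k += int(take)
        return take


def _draw_projection_dims(rng, params: VolumeParams, subtype: str) -> tuple[float, float]:
    mu_l, sd_l = params.projection_length_um[subtype]
    mu_w, sd_w = params.projection_tip_width_um[subtype]
    # floor just above the morphometric detection threshold so every true
    # projection is recoverable; widths clipped to a physical range
    length = max(0.26, rng.normal(mu_l, sd_l))
    width = float(np.clip(rng.normal(mu_w, sd_w), 0.12, 0.40))
    return length * 1e3, width * 1e3 / 2.0  # (length_nm, tip_radius_nm)


def generate_cardiomyocyte_volume(
    params: VolumeParams | None = None,
    geom: VoxelGeometry | None = None,
) -> tuple[LabelVolume, GroundTruth]:
    """Generate a seeded cardiomyocyte label volume plus exhaustive truth.

    The realized mitochondrial voxel fraction lands within one percentage
    point of ``params.target_mito_fraction`` (the final object of each
    subtype is resized to close the budget).  Identical parameters and seed
    give identical output.
    """
    params = params or VolumeParams()
    geom = geom or VoxelGeometry()
    params.validate()
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = (int(d) for d in params.shape_zyx)
    canvas = _Canvas((nz, ny, nx), geom)

    # --- context: extracellular margins, sarcolemma bands, nucleus ---------
    ex, band = 2, 2
    if ny >= 6 * (ex + band):
        canvas.cell[:, : ex + band, :] = False
        canvas.cell[:, ny - ex - band :, :] = False
        canvas.sarcolemma[:, ex : ex + band, :] = True
        canvas.sarcolemma[:, ny - ex - band : ny - ex, :] = True
    y_lo, y_hi = ex + band, ny - ex - band  # cell interior rows

    spacing = np.array(geom.spacing)
    nuc_centers: list[np.ndarray] = []
    nuc_semi = None
    if params.include_nucleus:
        # elongated along the fibre (x) axis, as cardiomyocyte nuclei are;
        # large volumes carry several nuclei so the perinuclear niche scales
        # with the perinuclear voxel budget
        mix_pre = _normalized(params.subtype_mix, "subtype_mix")
        r_pnm = (3.0 * params.mean_body_volume_nm3["PNM"] / (4.0 * math.pi)) ** (
            1.0 / 3.0
        )
        nuc_semi = np.array(
            [
                min(0.38 * nz * spacing[0], 1500.0),
                min(0.12 * ny * spacing[1], 1500.0),
                min(0.16 * nx * spacing[2], 5000.0),
            ]
        )
        cell_est = nz * max(ny - 2 * (ex + band), 1) * nx
        pnm_objs = (
            params.target_mito_fraction * mix_pre["PNM"] * cell_est
            * geom.voxel_volume_nm3 / params.mean_body_volume_nm3["PNM"]
        )
        # roughly half the nuclear envelope is usable for body footprints
        per_nucleus = max(
            0.45 * _thomsen_area(nuc_semi) / (2.2 * r_pnm) ** 2, 1.0
        )
        if pnm_objs <= 1.15 * per_nucleus:  # one envelope can take mild crowding
            n_nuclei = 1
        else:
            n_nuclei = int(np.clip(math.ceil(pnm_objs / per_nucleus), 1, 4))
        # nuclei themselves must not merge
        while n_nuclei > 1 and nx * spacing[2] / n_nuclei < 2.0 * nuc_semi[2]:
            n_nuclei -= 1
        for i in range(n_nuclei):
            cx_i = int((i + 0.5) / n_nuclei * nx)
            center = (nz // 2, ny // 2, cx_i)
            nuc = _ellipsoid_mask((nz, ny, nx), center, nuc_semi, geom)
            canvas.nucleus |= nuc & canvas.cell
            nuc_centers.append(np.array(center, dtype=float))

    cell_voxels = int(canvas.cell.sum())
    budget_total = params.target_mito_fraction * cell_voxels
    mix = _normalized(params.subtype_mix, "subtype_mix")
    voxvol = geom.voxel_volume_nm3

    truth = GroundTruth()
    next_label = 1
    painted = {s: 0 for s in SUBTYPES}

    # strand cursors for SSM (two sarcolemma faces) and IFM rows ------------
    ext = {s: _typical_extents_vox(params.mean_body_volume_nm3[s], geom)
           for s in SUBTYPES}
    ssm_zone = int(ext["SSM"][1]) + 8
    # z layers spaced to the typical body thickness
    z_pitch = max(int(ext["IFM"][0]) + 2, 6)
    n_layers = max(1, round((nz - 2) / z_pitch))
    z_layers = [int(round(z)) for z in
                np.linspace(1 + z_pitch // 2, nz - 1 - z_pitch // 2, n_layers)]
    # IFM row stride: body height plus a myofibril slab.  The slab takes the
    # requested width but narrows (down to 150 nm) when the requested
    # mitochondrial budget needs more rows; the myofibril/mitochondria
    # partition is a free parameter of the phantom.
    row_core = int(ext["IFM"][1]) + 6
    min_gap = max(int(150.0 / spacing[1]), 4)
    y_first = y_lo + ssm_zone + int(ext["IFM"][1] / 2) + 2
    y_last = y_hi - ssm_zone
    mean_obj_vox = params.mean_body_volume_nm3["IFM"] / voxvol
    per_lane = max(1, int((nx - 8) / (ext["IFM"][2] + 4)))
    ifm_budget_vox = params.target_mito_fraction * mix["IFM"] * cell_voxels
    # 1.8x headroom absorbs nucleus blockage and packing losses
    need_lanes = math.ceil(1.8 * ifm_budget_vox / max(per_lane * mean_obj_vox, 1.0))
    n_rows_needed = max(1, math.ceil(need_lanes / len(z_layers)))
    avail = max(y_last - y_first, 1)
    stride = int(
        np.clip(
            avail / n_rows_needed,
            row_core + min_gap,
            row_core + params.myofibril_width_nm / spacing[1],
        )
    )
    row_y = list(range(y_first, y_last + stride // 2, stride))

    def subtype_forbid(subtype):
        if subtype == "SSM":
            return (canvas.nucleus,)
        if subtype == "PNM":
            return (canvas.sarcolemma,)
        return (canvas.nucleus, canvas.sarcolemma)

    def make_built(subtype, vol_nm3, shape_class, tunnel=None):
        amp = params.oval_amplitude if shape_class == "oval" else params.irregular_amplitude
        projs = []
        if tunnel is None and rng.random() < params.projection_prob[subtype]:
            projs.append(_draw_projection_dims(rng, params, subtype))
        return _build_object(rng, geom, vol_nm3, shape_class, amp, projs, tunnel)

    def register(built, sl, mask, subtype):
        nonlocal next_label
        label = next_label
        next_label += 1
        n_vox = canvas.paint(sl, mask, label)
        painted[subtype] += n_vox
        truth.objects[label] = ObjectTruth(
            label=label,
            subtype=subtype,
            shape_class=built.shape_class,
            voxel_volume_nm3=n_vox * voxvol,
            surface_area_nm2=built.surface_area_nm2,
            projections=built.projections,
            nanotunnel=built.nanotunnel,
        )

    def draw_volume(subtype, remaining):
        mean = params.mean_body_volume_nm3[subtype]
        sd = params.body_volume_cv * mean
        sigma = math.sqrt(math.log(1.0 + (sd / mean) ** 2))
        mu = math.log(mean) - 0.5 * sigma**2
        v = float(rng.lognormal(mu, sigma))
        if v > remaining:
            v = max(remaining, 0.15 * mean)
        return v

    # --- PNM: walk a cursor around each nuclear envelope -------------------
    pnm_states = [
        {"angle": rng.uniform(0.0, 2.0 * np.pi), "center": c, "turn": i}
        for i, c in enumerate(nuc_centers)
    ]

    def place_pnm(built):
        r_body = (3.0 * built.mask.sum() * voxvol / (4.0 * math.pi)) ** (1.0 / 3.0)
        # conservative start outside any possible body orientation, then nudge in
        r_outer = 0.5 * max(s * sp for s, sp in zip(built.mask.shape, spacing))
        for attempt in range(params.max_retries):
            pnm_state = pnm_states[attempt % len(pnm_states)]
            nuc_center = pnm_state["center"]
            phi = pnm_state["angle"]
            lat = rng.uniform(-0.7, 0.7)  # use the envelope beyond the equator
            u = _unit(
                np.array(
                    [
                        math.sin(lat),
                        math.cos(lat) * math.sin(phi),
                        math.cos(lat) * math.cos(phi),
                    ]
                )
            )
            t_nuc = 1.0 / max(np.linalg.norm(u / nuc_semi), 1e-9)
            dist0 = t_nuc + r_outer + spacing[2]
            ring_r = max(t_nuc + r_body, spacing[2])
            placed = None
            for step in range(80):
                center_nm = nuc_center * spacing + (dist0 - step * spacing[2]) * u
                center = tuple(int(round(c)) for c in (center_nm / spacing))
                res = canvas.check(
                    built, center, forbid_near=subtype_forbid("PNM"),
                    require_near=canvas.nucleus, gap=2,
                )
                if res is not None:
                    placed = res
                    break
                # if the body already collides, pulling it closer cannot help
                win = canvas._window(built, center)
                if win is not None:
                    sl, mask = win
                    if canvas.nucleus[sl][mask].any() or canvas.labels[sl][mask].any():
                        break
            if placed is not None:
                # advance by the arc this body subtends plus a small gap
                pnm_state["angle"] = phi + (2.2 * r_body + 80.0) / ring_r
                return placed
            pnm_state["angle"] = phi + max(0.6 * r_body / ring_r, 0.05)
        return None

    # --- SSM / IFM: strand lanes with deterministic cursors ----------------
    ssm_lanes = [
        {"face": f, "z": z, "x": 4, "laps": 0}
        for f in ("lo", "hi")
        for z in z_layers
    ]
    ifm_lanes = [
        {"y": y, "z": z, "x": 4, "laps": 0} for y in row_y for z in z_layers
    ]

    def _strand_place(built, lanes, subtype, y_for_lane, require=None):
        occ = np.argwhere(built.mask)
        occ_x_min = int(occ[:, 2].min())
        cz, cy, cx = built.center_idx
        for _ in range(3 * params.max_retries):
            live = [l for l in lanes if l["laps"] < 2]
            if not live:
                return None
            lane = min(live, key=lambda l: (l["laps"], l["x"]))
            x = lane["x"] + (cx - occ_x_min) + int(rng.integers(0, 4))
            y = y_for_lane(lane, occ, cy)
            z = lane["z"] + int(rng.integers(-1, 2))
            res = canvas.check(
                built, (z, y, x), forbid_near=subtype_forbid(subtype),
                require_near=require, gap=2,
            )
            if res is not None:
                lane["x"] = x - (cx - occ_x_min) + built.extent_x + 3
                return res
            lane["x"] += max(8, built.extent_x // 3)
            if lane["x"] + built.extent_x >= nx - 4:
                lane["x"] = 4
                lane["laps"] += 1
        return None

    def place_ssm(built):
        def y_for_lane(lane, occ, cy):
            if lane["face"] == "lo":
                return y_lo + (cy - int(occ[:, 1].min()))  # abuts the band
            return (y_hi - 1) - (int(occ[:, 1].max()) - cy)

        res = _strand_place(built, ssm_lanes, "SSM", y_for_lane,
                            require=canvas.sarcolemma)
        for lane in ssm_lanes:
            lane["laps"] = 0  # later, smaller bodies may still fit
        return res

    def place_ifm(built, tunnel=False):
        def y_for_lane(lane, occ, cy):
            return lane["y"] + int(rng.integers(-3, 4))

        res = _strand_place(built, ifm_lanes, "IFM", y_for_lane)
        for lane in ifm_lanes:
            lane["laps"] = 0
        return res

    # --- fill each subtype to its voxel budget -----------------------------
    order = [s for s in ("PNM", "SSM", "IFM") if mix[s] > 0]
    placers = {"PNM": place_pnm, "SSM": place_ssm, "IFM": place_ifm}
    if budget_total > 0:
        for subtype in order:
            if not params.include_nucleus and subtype == "PNM":
                raise CapacityError("cannot place PNM without a nucleus")
            shape_q = _QuotaSampler(params.oval_fraction[subtype])
            budget = mix[subtype] * budget_total
            mean = params.mean_body_volume_nm3[subtype]
            while budget - painted[subtype] > 0.15 * mean / voxvol:
                remaining_nm3 = (budget - painted[subtype]) * voxvol
                vol = draw_volume(subtype, remaining_nm3)
                shape_class = "oval" if shape_q.draw() else "irregular"
                # a drawn body that finds no home is redrawn smaller a few
                # times: the tail of the size distribution fills residual gaps
                res = built = None
                while vol >= 0.14 * mean:
                    built = make_built(subtype, vol, shape_class)
                    res = placers[subtype](built)
                    if res is not None:
                        break
                    vol *= 0.7
                if res is None:
                    # a bounded shortfall keeps the realized fraction within
                    # its +-1 point contract; only a real deficit is an error
                    shortfall = budget - painted[subtype]
                    if shortfall <= 0.006 * cell_voxels:
                        break
                    raise CapacityError(
                        f"could not place {subtype} object after "
                        f"{params.max_retries} retries "
                        f"(placed {painted[subtype]} of {budget:.0f} voxels)"
                    )
                register(built, res[0], res[1], subtype)

    # --- nanotunnels: dumbbells dropped into spare row space --------------
    for _ in range(params.n_nanotunnels):
        tube_len = rng.uniform(*params.nanotunnel_length_range_um) * 1e3
        tube_diam = rng.uniform(*params.nanotunnel_diameter_range_um) * 1e3
        vol1 = draw_volume("PNM", math.inf)
        vol2 = draw_volume("PNM", math.inf)
        built = _build_object(
            rng, geom, vol1, "oval", params.oval_amplitude,
            tunnel=(tube_len, tube_diam / 2.0, vol2),
        )
        res = place_ifm(built, tunnel=True)
        if res is None:
            raise CapacityError("could not place nanotunnel dumbbell")
        register(built, res[0], res[1], "PNM")

    total_mito = int((canvas.labels > 0).sum())
    truth.true_fraction = total_mito / cell_voxels
    truth.subtype_shares = {
        s: (painted[s] / total_mito if total_mito else 0.0) for s in SUBTYPES
    }
    volume = LabelVolume(
        labels=canvas.labels,
        nucleus_mask=canvas.nucleus,
        sarcolemma_mask=canvas.sarcolemma,
        geom=geom,
        cell_mask=canvas.cell,
    )
    return volume, truth


def generate_shape_population(
    n: int,
    oval_fraction: float,
    seed: int = 0,
    geom: VoxelGeometry | None = None,
    subtype: str = "IFM",
    mean_body_volume_nm3: float | None = None,
    body_volume_cv: float = 0.25,
    oval_amplitude: float = 0.05,
    irregular_amplitude: float = 0.30,
    projection_prob: float = 0.0,
) -> tuple[LabelVolume, GroundTruth]:
    """Grid-packed population of single bodies for classifier validation.

    Exactly ``round(oval_fraction * n)`` objects are oval (largest-remainder
    allocation), the rest irregular; order is shuffled by the seed.
    """
    if not 0.0 <= oval_fraction <= 1.0:
        raise ValueError("oval_fraction must lie in [0, 1]")
    geom = geom or VoxelGeometry()
    rng = np.random.default_rng(seed)
    mean_vol = mean_body_volume_nm3 or _WT_BODY_VOLUME[subtype]
    sigma = math.sqrt(math.log(1.0 + body_volume_cv**2))
    mu = math.log(mean_vol) - 0.5 * sigma**2

    n_oval = round(oval_fraction * n)
    classes = np.array(["oval"] * n_oval + ["irregular"] * (n - n_oval))
    rng.shuffle(classes)

    built_objs = []
    for shape_class in classes:
        amp = oval_amplitude if shape_class == "oval" else irregular_amplitude
        projs = []
        if rng.random() < projection_prob:
            projs.append(
                _draw_projection_dims(
                    rng,
                    VolumeParams(),
                    subtype,
                )
            )
        vol = float(rng.lognormal(mu, sigma))
        built_objs.append(_build_object(rng, geom, vol, shape_class, amp, projs))

    if not built_objs:
        empty = np.zeros((4, 4, 4), dtype=np.uint16)
        lv = LabelVolume(empty, np.zeros_like(empty, bool), np.zeros_like(empty, bool), geom)
        return lv, GroundTruth()

    cell = np.array([max(b.mask.shape[i] for b in built_objs) + 2 for i in range(3)])
    # near-cubic canvas in voxel units despite anisotropic cells
    gy = max(1, round((n * cell[0] / cell[1]) ** (1.0 / 3.0)))
    gx = gy
    gz = math.ceil(n / (gy * gx))
    shape = (gz * cell[0] + 2, gy * cell[1] + 2, gx * cell[2] + 2)
    canvas = _Canvas(shape, geom)
    truth = GroundTruth()
    for idx, built in enumerate(built_objs):
        iz, rem = divmod(idx, gy * gx)
        iy, ix = divmod(rem, gx)
        # centre the bounding box (not the body) so capsules stay in-cell
        center = tuple(
            1 + g * cell[i] + (cell[i] - built.mask.shape[i]) // 2 + built.center_idx[i]
            for i, g in enumerate((iz, iy, ix))
        )
        res = canvas.check(built, center)
        if res is None:
            raise CapacityError("grid cell too small for object")
        label = idx + 1
        n_vox = canvas.paint(res[0], res[1], label)
        truth.objects[label] = ObjectTruth(
            label=label,
            subtype=subtype,
            shape_class=built.shape_class,
            voxel_volume_nm3=n_vox * geom.voxel_volume_nm3,
            surface_area_nm2=built.surface_area_nm2,
            projections=built.projections,
        )
    total = int((canvas.labels > 0).sum())
    truth.true_fraction = total / canvas.labels.size
    truth.subtype_shares = {s: (1.0 if s == subtype else 0.0) for s in SUBTYPES}
    volume = LabelVolume(
        labels=canvas.labels,
        nucleus_mask=canvas.nucleus,
        sarcolemma_mask=canvas.sarcolemma,
        geom=geom,
        cell_mask=canvas.cell,
    )
    return volume, truth


def generate_dumbbell_volume(
    tube_length_um: float = 1.5,
    tube_diameter_um: float = 0.30,
    body_volume_nm3: float = 7.0e8,
    seed: int = 0,
    geom: VoxelGeometry | None = None,
) -> tuple[LabelVolume, GroundTruth]:
    """Two ellipsoid bodies joined by a capsule, emitted as a single label."""
    geom = geom or VoxelGeometry()
    rng = np.random.default_rng(seed)
    built = _build_object(
        rng,
        geom,
        body_volume_nm3,
        "oval",
        0.05,
        tunnel=(tube_length_um * 1e3, tube_diameter_um * 1e3 / 2.0, body_volume_nm3),
    )
    pad = 2
    shape = tuple(int(s) + 2 * pad for s in built.mask.shape)
    canvas = _Canvas(shape, geom)
    center = tuple(built.center_idx[i] + pad for i in range(3))
    res = canvas.check(built, center)
    if res is None:  # pragma: no cover - shape is padded to fit by construction
        raise CapacityError("dumbbell does not fit its own padded box")
    n_vox = canvas.paint(res[0], res[1], 1)
    truth = GroundTruth(
        objects={
            1: ObjectTruth(
                label=1,
                subtype="PNM",
                shape_class="oval",
                voxel_volume_nm3=n_vox * geom.voxel_volume_nm3,
                nanotunnel=built.nanotunnel,
            )
        },
        true_fraction=n_vox / canvas.labels.size,
        subtype_shares={"SSM": 0.0, "IFM": 0.0, "PNM": 1.0},
    )
    volume = LabelVolume(
        labels=canvas.labels,
        nucleus_mask=canvas.nucleus,
        sarcolemma_mask=canvas.sarcolemma,
        geom=geom,
        cell_mask=canvas.cell,
    )
    return volume, truth
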