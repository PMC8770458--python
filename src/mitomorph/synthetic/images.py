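"""Synthetic TEM-style cristae images.

A mitochondrion profile (ellipse, dark boundary) filled with parallel
membrane doublets on a light matrix, following the TEM convention of dark
membranes.  Each crista is a pair of uniform membrane lines: outer edges
``W_O`` apart, lumen (inner edge to inner edge) ``W_I`` wide, so each
membrane leaflet is ``(W_O - W_I)/2`` thick; consecutive doublets are
separated by an edge-to-edge gap ``S``.  The rendered pre-noise membrane
mask reproduces the requested widths to within a pixel, which is what makes
the line-profile pipeline testable against truth.

Quality classes are realised by the fraction of the mitochondrion area the
ordered lamellae cover: class 1 fills it, class 3 covers about half, class 5
carries no discernible cristae.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from mitomorph.truth import CristaTruth, CristaeImageTruth
from mitomorph.volume import GreyImage

_DEFAULT_COVERAGE = {1: 1.0, 3: 0.5, 5: 0.0}

# Wild-type-average cristae dimensions (nm): outer width ~36, lumen ~16.
_DEFAULT_W_O = (36.0, 2.0)
_DEFAULT_W_I = (16.0, 1.0)
_DEFAULT_S = (28.0, 3.0)


@dataclass
class CristaeImageParams:
    """Study conditions for one synthetic cristae image."""

    pixel_size_nm: float = 2.0
    shape: tuple[int, int] = (600, 600)
    w_o_nm: tuple[float, float] = _DEFAULT_W_O  # (mean, sd) outer width
    w_i_nm: tuple[float, float] = _DEFAULT_W_I  # (mean, sd) lumen width
    s_nm: tuple[float, float] = _DEFAULT_S  # (mean, sd) doublet gap
    n_cristae: int | None = None  # None = fill the covered band
    quality_class: int = 1
    ordered_coverage: float | None = None  # override the class default
    mito_radii_nm: tuple[float, float] = (520.0, 430.0)  # (x, y) semi-axes
    boundary_half_width_nm: float = 5.0
    interior_margin_nm: float = 20.0
    noise_sd: float = 8.0  # grey levels
    blur_sigma_px: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.w_i_nm[0] >= self.w_o_nm[0]:
            raise ValueError("lumen width W_I must be smaller than outer width W_O")
        if self.s_nm[0] <= 0:
            raise ValueError("cristae spacing S must be > 0")
        if self.quality_class not in (1, 3, 5):
            raise ValueError("quality_class must be one of 1, 3, 5")
        if self.n_cristae is not None and self.n_cristae < 0:
            raise ValueError("n_cristae must be >= 0")
        if min(self.w_o_nm[1], self.w_i_nm[1], self.s_nm[1]) < 0:
            raise ValueError("distribution sds must be >= 0")


@dataclass
class CristaeScene:
    """Image plus every truth raster the tests need."""

    image: GreyImage
    truth: CristaeImageTruth
    membrane_mask: np.ndarray  # cristae membranes only (pre-noise)
    ring_mask: np.ndarray  # mitochondrion boundary membrane
    mito_mask: np.ndarray  # whole mitochondrion profile
    interior_mask: np.ndarray  # matrix region inside the boundary
    band_mask: np.ndarray  # ordered-lamellae band (coverage region)
    center_px: tuple[float, float]

    def default_profile_line(self, margin_nm: float = 30.0):
        """Endpoints (row, col) of a line normal to the lamellae through the
        mitochondrion centre, spanning every rendered crista."""
        t = self.truth
        if t.cristae:
            span = max(abs(c.center_nm) + c.w_o_nm / 2 for c in t.cristae) + margin_nm
        else:
            span = margin_nm
        alpha = math.radians(t.lamella_angle_deg)
        dy, dx = math.sin(alpha), math.cos(alpha)
        cy, cx = self.center_px
        s = span / t.pixel_size_nm
        return (cy - s * dy, cx - s * dx), (cy + s * dy, cx + s * dx)


def _chord_length(a: float, b: float, alpha: float, u: float) -> float:
    """Chord length of the axis-aligned ellipse (semi-axes a=x, b=y) cut by a
    line with unit normal (cos alpha, sin alpha) at signed offset ``u``."""
    h = math.sqrt((a * math.cos(alpha)) ** 2 + (b * math.sin(alpha)) ** 2)
    if abs(u) >= h:
        return 0.0
    return 2.0 * a * b / h * math.sqrt(1.0 - (u / h) ** 2)


def generate_cristae_scene(params: CristaeImageParams | None = None) -> CristaeScene:
    params = params or CristaeImageParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    px = params.pixel_size_nm
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a_nm, b_nm = params.mito_radii_nm  # x, y semi-axes

    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) * px
    dy = (yy - cy) * px
    e = np.sqrt((dx / a_nm) ** 2 + (dy / b_nm) ** 2)
    mito_mask = e <= 1.0
    # signed approximate distance to the ellipse boundary (nm)
    bdist = (1.0 - e) * min(a_nm, b_nm)
    ring_frac = np.clip(
        (params.boundary_half_width_nm - np.abs(bdist)) / px + 0.5, 0.0, 1.0
    )
    interior_mask = bdist > params.interior_margin_nm

    alpha = rng.uniform(0.0, math.pi)
    u = dx * math.cos(alpha) + dy * math.sin(alpha)

    coverage = (
        params.ordered_coverage
        if params.ordered_coverage is not None
        else _DEFAULT_COVERAGE[params.quality_class]
    )
    coverage = float(np.clip(coverage, 0.0, 1.0))
    if coverage > 0 and interior_mask.any():
        u_int = np.abs(u[interior_mask])
        u_star = float(np.quantile(u_int, coverage)) if coverage < 1.0 else float(
            u_int.max() + 1.0
        )
    else:
        u_star = 0.0
    band_mask = interior_mask & (np.abs(u) <= u_star)

    # --- lay out the membrane doublets along the lamella normal -----------
    cristae: list[CristaTruth] = []
    spacing_s: list[float] = []
    membrane_frac = np.zeros((h, w), dtype=np.float32)
    a_in, b_in = a_nm - params.interior_margin_nm, b_nm - params.interior_margin_nm
    membrane_length = 0.0

    def draw_dims():
        w_o = max(rng.normal(*params.w_o_nm), 8.0)
        w_i = float(np.clip(rng.normal(*params.w_i_nm), 4.0, w_o - 4.0))
        return w_o, w_i

    placed: list[tuple[float, float, float]] = []  # (center, w_o, w_i)
    if u_star > 0 and (params.n_cristae is None or params.n_cristae > 0):
        dims: list[tuple[float, float]] = []
        gaps: list[float] = []
        if params.n_cristae is not None:
            dims = [draw_dims() for _ in range(params.n_cristae)]
            gaps = [max(rng.normal(*params.s_nm), 6.0) for _ in range(len(dims) - 1)]
            span = sum(d[0] for d in dims) + sum(gaps)
            c = -span / 2.0 + dims[0][0] / 2.0
            for k, (w_o, w_i) in enumerate(dims):
                placed.append((c, w_o, w_i))
                if k + 1 < len(dims):
                    c += w_o / 2.0 + gaps[k] + dims[k + 1][0] / 2.0
        else:
            w_o, w_i = draw_dims()
            c = -u_star + w_o / 2.0 + 2.0
            while c + w_o / 2.0 <= u_star:
                placed.append((c, w_o, w_i))
                gap = max(rng.normal(*params.s_nm), 6.0)
                w_o2, w_i2 = draw_dims()
                c = c + w_o / 2.0 + gap + w_o2 / 2.0
                w_o, w_i = w_o2, w_i2

    for k, (c, w_o, w_i) in enumerate(placed):
        t_m = (w_o - w_i) / 2.0  # leaflet thickness
        for side in (-1.0, 1.0):
            lc = c + side * (w_o - t_m) / 2.0
            frac = np.clip((t_m / 2.0 - np.abs(u - lc)) / px + 0.5, 0.0, 1.0)
            np.maximum(membrane_frac, frac.astype(np.float32), out=membrane_frac)
            membrane_length += _chord_length(a_in, b_in, alpha, lc)
        cristae.append(CristaTruth(w_o_nm=w_o, w_i_nm=w_i, center_nm=c))
        if k + 1 < len(placed):
            nc, nw_o, _ = placed[k + 1]
            spacing_s.append((nc - nw_o / 2.0) - (c + w_o / 2.0))

    membrane_frac *= band_mask.astype(np.float32)
    membrane_mask = membrane_frac > 0.5
    ring_frac *= mito_mask | (e <= 1.0 + params.boundary_half_width_nm / min(a_nm, b_nm))
    ring_mask = ring_frac > 0.5

    # --- compose the greyscale image ---------------------------------------
    img = np.full((h, w), 150.0, dtype=np.float32)
    img[mito_mask] = 205.0
    dark = np.maximum(membrane_frac, ring_frac.astype(np.float32))
    img -= 160.0 * dark
    if params.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma_px)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0).astype(np.uint8)

    interior_area = float(interior_mask.sum()) * px * px
    truth = CristaeImageTruth(
        pixel_size_nm=px,
        quality_class=params.quality_class,
        ordered_coverage=coverage,
        cristae=cristae,
        spacing_s_nm=spacing_s,
        membrane_length_nm=membrane_length,
        mito_area_nm2=interior_area,
        lamella_angle_deg=math.degrees(alpha),
    )
    return CristaeScene(
        image=GreyImage(img, px),
        truth=truth,
        membrane_mask=membrane_mask,
        ring_mask=ring_mask,
        mito_mask=mito_mask,
        interior_mask=interior_mask,
        band_mask=band_mask,
        center_px=(cy, cx),
    )


def generate_cristae_image(
    params: CristaeImageParams | None = None,
) -> tuple[GreyImage, CristaeImageTruth]:
    """Generate a seeded TEM-style cristae image plus ground truth."""
    scene = generate_cristae_scene(params)
    return scene.image, scene.truth
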