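"""2-D TEM cristae analysis.

The measurement chain mirrors the classical interactive workflow: threshold
the micrograph so membranes are dark/binary, draw a line across a stack of
cristae, read the grey-level profile, detect the membrane doublet of each
crista, and measure the outer width W_O (outer half-prominence edges), the
lumen width W_I (inner half-prominence edges) and the spacing S between the
facing outer edges of consecutive doublets.  A separate 1/3/5 quality score
rates cristae order from the area fraction covered by ordered lamellae.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage import filters, measure

from mitomorph.volume import GreyImage

__all__ = [
    "CristaeConfig",
    "CristaeProfile",
    "Doublet",
    "CristaeDims",
    "QualityScore",
    "threshold_membranes",
    "line_profile",
    "detect_doublets",
    "measure_dims",
    "score_quality",
    "measure_image_dims",
]


class DegenerateImageError(ValueError):
    """Thresholding a (near-)constant image is meaningless."""


class RegionTooSmallError(ValueError):
    """Region below the minimum area for quality scoring."""


@dataclass(frozen=True)
class CristaeConfig:
    threshold_method: str = "otsu"
    profile_step_px: float = 0.5
    peak_prominence_frac: float = 0.25  # of the profile dynamic range
    max_pair_separation_nm: float = 30.0  # membrane peaks closer than this pair up
    min_lamella_elongation: float = 4.0  # major/minor axis ratio for "ordered"
    min_lamella_length_nm: float = 60.0
    lamella_reach_nm: float = 40.0  # how far one lamella "organises" the matrix
    quality_hi_coverage: float = 0.70  # >= hi -> score 1
    quality_lo_coverage: float = 0.20  # <= lo -> score 5
    min_region_px: int = 400


@dataclass
class CristaeProfile:
    """Grey values sampled along a line, positions in nm."""

    positions_nm: np.ndarray
    values: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions_nm) <= 0):
            raise ValueError("profile positions must be strictly increasing")

    @property
    def step_nm(self) -> float:
        return float(self.positions_nm[1] - self.positions_nm[0])


@dataclass
class Doublet:
    """One crista's membrane pair on a profile (all positions in nm)."""

    peak_left_nm: float
    peak_right_nm: float
    outer_left_nm: float
    outer_right_nm: float
    inner_left_nm: float
    inner_right_nm: float

    def __post_init__(self) -> None:
        if not (
            self.outer_left_nm
            <= self.inner_left_nm
            <= self.inner_right_nm
            <= self.outer_right_nm
        ):
            raise ValueError("doublet inner pair must nest within its outer pair")


@dataclass
class CristaeDims:
    w_o_nm: float
    w_i_nm: float
    s_gap_nm: float | None = None  # to the next doublet, edge to edge
    s_center_nm: float | None = None  # to the next doublet, centre to centre

    def __post_init__(self) -> None:
        if not 0 < self.w_i_nm < self.w_o_nm:
            raise ValueError("need 0 < W_I < W_O")


@dataclass
class QualityScore:
    score: int
    ordered_coverage: float


def threshold_membranes(image: GreyImage, config: CristaeConfig | None = None) -> np.ndarray:
    """Binary membrane mask: automatic global threshold, membranes dark."""
    config = config or CristaeConfig()
    px = np.asarray(image.pixels, dtype=float)
    if np.ptp(px) < 1e-9:
        raise DegenerateImageError("constant image has no threshold")
    if config.threshold_method == "otsu":
        t = filters.threshold_otsu(px)
    elif config.threshold_method == "isodata":
        t = filters.threshold_isodata(px)
    else:
        raise ValueError(f"unknown threshold method {config.threshold_method!r}")
    return px < t


def line_profile(
    image: GreyImage,
    src: tuple[float, float],
    dst: tuple[float, float],
    config: CristaeConfig | None = None,
) -> CristaeProfile:
    """Grey values interpolated along the line ``src``->``dst`` (row, col px).

    Positions are physical (nm) with sub-pixel sampling.
    """
    config = config or CristaeConfig()
    h, w = image.pixels.shape
    for p in (src, dst):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise IndexError(f"profile endpoint {p} outside image of shape {(h, w)}")
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    length_px = float(np.hypot(*(dst - src)))
    n = max(int(math.ceil(length_px / config.profile_step_px)), 1) + 1
    ts = np.linspace(0.0, 1.0, n)
    coords = src[:, None] + (dst - src)[:, None] * ts[None, :]
    vals = ndimage.map_coordinates(
        np.asarray(image.pixels, dtype=float), coords, order=1, mode="nearest"
    )
    positions = ts * length_px * image.pixel_size_nm
    return CristaeProfile(positions, vals, image.pixel_size_nm)


def _refine_peak(y: np.ndarray, i: int) -> float:
    """Sub-sample parabolic refinement of a discrete peak index."""
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if abs(denom) > 1e-12:
            return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i)


def detect_doublets(
    profile: CristaeProfile, config: CristaeConfig | None = None
) -> list[Doublet]:
    """Pair adjacent membrane peaks into per-crista doublets.

    Membranes are dark, so peaks are detected on the inverted profile; outer
    and inner edges are the half-prominence crossings on the outward and
    inward flanks.  An odd unpaired peak is dropped.
    """
    config = config or CristaeConfig()
    v = np.asarray(profile.values, dtype=float)
    if len(v) < 5:
        return []
    inv = v.max() - v
    rng = float(np.ptp(v))
    if rng < 1e-9:
        return []
    peaks, props = signal.find_peaks(inv, prominence=config.peak_prominence_frac * rng)
    if len(peaks) < 2:
        return []
    widths = signal.peak_widths(inv, peaks, rel_height=0.5)
    left_ips, right_ips = widths[2], widths[3]
    step = profile.step_nm
    pos = profile.positions_nm

    def nm(sample_idx: float) -> float:
        return float(pos[0] + sample_idx * step)

    doublets: list[Doublet] = []
    i = 0
    while i < len(peaks) - 1:
        gap_nm = (peaks[i + 1] - peaks[i]) * step
        if gap_nm <= config.max_pair_separation_nm:
            pl = nm(_refine_peak(inv, peaks[i]))
            pr = nm(_refine_peak(inv, peaks[i + 1]))
            try:
                doublets.append(
                    Doublet(
                        peak_left_nm=pl,
                        peak_right_nm=pr,
                        outer_left_nm=nm(left_ips[i]),
                        outer_right_nm=nm(right_ips[i + 1]),
                        inner_left_nm=nm(right_ips[i]),
                        inner_right_nm=nm(left_ips[i + 1]),
                    )
                )
            except ValueError:
                pass  # malformed crossing order: skip this pair
            i += 2
        else:
            i += 1  # unpaired peak: flagged by omission
    return doublets


def measure_dims(doublets: list[Doublet]) -> list[CristaeDims]:
    """W_O, W_I per doublet and S to the next doublet (gap and centre-to-centre).

    W_O is the outer-edge-to-outer-edge distance, W_I the lumen width between
    the inner membrane edges, S the gap between the facing outer edges of
    consecutive doublets.  S is None for the last (or a single) doublet.
    """
    dims: list[CristaeDims] = []
    for k, d in enumerate(doublets):
        w_o = d.outer_right_nm - d.outer_left_nm
        w_i = d.inner_right_nm - d.inner_left_nm
        s_gap = s_center = None
        if k + 1 < len(doublets):
            nxt = doublets[k + 1]
            s_gap = nxt.outer_left_nm - d.outer_right_nm
            s_center = (
                (nxt.outer_left_nm + nxt.outer_right_nm) / 2.0
                - (d.outer_left_nm + d.outer_right_nm) / 2.0
            )
        dims.append(CristaeDims(w_o_nm=w_o, w_i_nm=w_i, s_gap_nm=s_gap, s_center_nm=s_center))
    return dims


def score_quality(
    image: GreyImage,
    region_mask: np.ndarray,
    config: CristaeConfig | None = None,
) -> QualityScore:
    """Ordinal 1/3/5 cristae-order score for one mitochondrion region.

    The membrane mask is filtered for elongated lamellar fragments; the
    fraction of the region within ``lamella_reach_nm`` of such a fragment is
    the ordered coverage.  Coverage >= ``quality_hi_coverage`` scores 1
    (ordered), <= ``quality_lo_coverage`` scores 5 (no discernible cristae),
    otherwise 3 (partially ordered).
    """
    config = config or CristaeConfig()
    region_mask = np.asarray(region_mask).astype(bool)
    if int(region_mask.sum()) < config.min_region_px:
        raise RegionTooSmallError(
            f"region has {int(region_mask.sum())} px "
            f"(minimum {config.min_region_px})"
        )
    try:
        membranes = threshold_membranes(image, config)
    except DegenerateImageError:
        return QualityScore(score=5, ordered_coverage=0.0)
    membranes = membranes & region_mask
    px = image.pixel_size_nm
    lab = measure.label(membranes, connectivity=2)
    ordered = np.zeros_like(membranes)
    for rp in measure.regionprops(lab):
        minor = max(rp.axis_minor_length, 1.0)
        if (
            rp.axis_major_length / minor >= config.min_lamella_elongation
            and rp.axis_major_length * px >= config.min_lamella_length_nm
        ):
            ordered[lab == rp.label] = True
    if ordered.any():
        dist = ndimage.distance_transform_edt(~ordered, sampling=px)
        coverage = float((region_mask & (dist <= config.lamella_reach_nm)).sum()
                         / region_mask.sum())
    else:
        coverage = 0.0
    if coverage >= config.quality_hi_coverage:
        score = 1
    elif coverage <= config.quality_lo_coverage:
        score = 5
    else:
        score = 3
    return QualityScore(score=score, ordered_coverage=coverage)


def measure_image_dims(
    image: GreyImage,
    src: tuple[float, float],
    dst: tuple[float, float],
    config: CristaeConfig | None = None,
) -> list[CristaeDims]:
    """Convenience chain: profile -> doublets -> dimensions for one line."""
    prof = line_profile(image, src, dst, config)
    return measure_dims(detect_doublets(prof, config))
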