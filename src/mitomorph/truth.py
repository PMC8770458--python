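"""Generator-side ground-truth records.

Every synthetic object carries its true class and dimensions so recovery by
the measurement modules can be scored against a known answer.  Records are
plain dataclasses with a lossless JSON round trip (the fixture sidecar).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class ProjectionTruth:
    """True dimensions of one tubular projection (body surface to tip)."""

    length_um: float
    tip_width_um: float


@dataclass
class NanotunnelTruth:
    """True dimensions of a tubular connection between two bodies."""

    tube_length_um: float
    tube_diameter_um: float


@dataclass
class ObjectTruth:
    label: int
    subtype: str  # "SSM" | "IFM" | "PNM"
    shape_class: str  # "oval" | "irregular"
    voxel_volume_nm3: float
    surface_area_nm2: float | None = None  # analytic, bodies without appendages only
    projections: list[ProjectionTruth] = field(default_factory=list)
    nanotunnel: NanotunnelTruth | None = None


@dataclass
class GroundTruth:
    """Exhaustive truth for one synthetic cardiomyocyte volume."""

    objects: dict[int, ObjectTruth] = field(default_factory=dict)
    true_fraction: float = 0.0  # mito voxels / cardiomyocyte voxels
    subtype_shares: dict[str, float] = field(default_factory=dict)  # of mito voxels

    def labels(self) -> list[int]:
        return sorted(self.objects)

    def to_dict(self) -> dict:
        d = asdict(self)
        # JSON object keys must be strings
        d["objects"] = {str(k): v for k, v in d["objects"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        try:
            objects = {}
            for key, od in d["objects"].items():
                projections = [ProjectionTruth(**p) for p in od.pop("projections", [])]
                nt = od.pop("nanotunnel", None)
                objects[int(key)] = ObjectTruth(
                    **od,
                    projections=projections,
                    nanotunnel=NanotunnelTruth(**nt) if nt else None,
                )
            return cls(
                objects=objects,
                true_fraction=float(d["true_fraction"]),
                subtype_shares={k: float(v) for k, v in d["subtype_shares"].items()},
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed ground-truth sidecar: {exc}") from exc


@dataclass
class CristaTruth:
    """One rendered crista: the membrane-doublet landmark positions.

    ``w_o_nm`` is the outer-edge-to-outer-edge width of the doublet,
    ``w_i_nm`` the distance between the two membrane centre lines (the
    lumen landmark used throughout this package), and ``center_nm`` the
    doublet midline position along the lamella normal.
    """

    w_o_nm: float
    w_i_nm: float
    center_nm: float


@dataclass
class CristaeImageTruth:
    """Truth for one synthetic TEM-style cristae image."""

    pixel_size_nm: float
    quality_class: int  # 1 | 3 | 5
    ordered_coverage: float  # fraction of the mito area carrying lamellae
    cristae: list[CristaTruth] = field(default_factory=list)
    spacing_s_nm: list[float] = field(default_factory=list)  # gaps between doublets
    membrane_length_nm: float = 0.0  # total membrane centre-line length
    mito_area_nm2: float = 0.0
    lamella_angle_deg: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CristaeImageTruth":
        try:
            cristae = [CristaTruth(**c) for c in d.pop("cristae", [])]
            return cls(**d, cristae=cristae)
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed cristae ground-truth sidecar: {exc}") from exc
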