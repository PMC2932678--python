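"""Fixed 2-D callus geometry and its cell-centered finite-volume grid.

The solution domain is a planar longitudinal quarter-section of an
osteotomized long bone: the fracture plane (``x = 0``) and the marrow
axis (``y = 0``) are symmetry edges, the cortical wall is an excluded
rectangle, and the regenerating tissue consists of three regions:

* periosteal callus  — above the cortex,
* intercortical gap  — between the cut bone ends (half of the 1 mm gap),
* endosteal callus   — the marrow canal below the cortex.

The atrophic non-union variant extends the domain distally (away from
the fracture) over the distance that the periosteum was stripped and
the marrow canal reamed: a thin periosteal flank on top of the cortex
and the continued marrow canal below it.  The distal end faces of the
extension meet undisturbed tissue and therefore carry the intact cell
sources in non-union scenarios.

Geometry is rectilinear; cells are assigned to regions by cell-center
containment (staircase boundaries).  All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GeometryConfig",
    "CallusDomain",
    "Grid",
    "build_callus_domain",
    "discretize",
    "build_rectangle_grid",
    "REGION_CODES",
]

#: integer codes stored in :attr:`Grid.region`
REGION_CODES = {
    "outside": 0,
    "periosteal": 1,
    "gap": 2,
    "endosteal": 3,
    "cortex": 4,
}

# canonical boundary-segment names (healing variant uses the first six)
SEG_FRACTURE = "fracture_plane"
SEG_MARROW_AXIS = "marrow_axis"
SEG_PERIOSTEAL = "periosteal_surface"
SEG_ENDOSTEAL = "endosteal_surface"
SEG_CORTEX = "cortex_interface"
SEG_SOFT = "outer_soft_tissue"
SEG_MARROW_DISTAL = "marrow_distal"
SEG_PERIOSTEAL_DISTAL = "periosteal_distal"

ALL_SEGMENTS = (
    SEG_FRACTURE,
    SEG_MARROW_AXIS,
    SEG_PERIOSTEAL,
    SEG_ENDOSTEAL,
    SEG_CORTEX,
    SEG_SOFT,
    SEG_MARROW_DISTAL,
    SEG_PERIOSTEAL_DISTAL,
)


@dataclass(frozen=True)
class GeometryConfig:
    """Dimensions of the callus cross-section, in mm.

    Only the interfragmentary gap width (1 mm) is fixed by the animal
    model; the remaining outline dimensions are reconstructed defaults
    for a rat tibia and are free parameters.
    """

    gap_mm: float = 1.0  # full interfragmentary gap (model holds half)
    callus_length_mm: float = 3.0  # axial extent of the callus
    callus_height_mm: float = 1.5  # periosteal callus thickness
    marrow_mm: float = 1.0  # endosteal half-canal height
    cortex_mm: float = 0.5  # cortical wall thickness
    extension_mm: float = 4.0  # distal stripping/reaming distance (1 tibial diameter)
    flank_mm: float = 0.75  # periosteal tissue layer thickness along the stripped cortex

    def validate(self, variant: str) -> None:
        for key in (
            "gap_mm",
            "callus_length_mm",
            "callus_height_mm",
            "marrow_mm",
            "cortex_mm",
            "flank_mm",
        ):
            if getattr(self, key) <= 0.0:
                raise ConfigurationError(f"geometry key {key!r} must be > 0, got {getattr(self, key)}")
        if self.extension_mm < 0.0:
            raise ConfigurationError(f"geometry key 'extension_mm' must be >= 0, got {self.extension_mm}")
        if variant == "nonunion" and self.extension_mm <= 0.0:
            raise ConfigurationError(
                "geometry key 'extension_mm' must be > 0 for the non-union variant "
                "(the domain is extended over the stripped/reamed distance)"
            )
        if self.gap_mm / 2.0 >= self.callus_length_mm:
            raise ConfigurationError("geometry key 'callus_length_mm' must exceed half the gap width")
        if self.flank_mm > self.callus_height_mm:
            raise ConfigurationError("geometry key 'flank_mm' cannot exceed 'callus_height_mm'")


@dataclass(frozen=True)
class CallusDomain:
    """Labeled rectilinear callus geometry (regions as axis-aligned boxes).

    ``regions`` maps region name -> tuple of (x0, x1, y0, y1) boxes; the
    cortical wall is stored separately and is excluded from the solution
    domain.
    """

    config: GeometryConfig
    variant: str  # "healing" | "nonunion"
    regions: Dict[str, Tuple[Tuple[float, float, float, float], ...]]
    cortex_boxes: Tuple[Tuple[float, float, float, float], ...]
    x_max: float
    y_max: float

    @property
    def gap_half(self) -> float:
        return self.config.gap_mm / 2.0

    def region_area(self, name: str) -> float:
        return sum((x1 - x0) * (y1 - y0) for x0, x1, y0, y1 in self.regions[name])

    @property
    def total_area(self) -> float:
        return sum(self.region_area(name) for name in self.regions)


def build_callus_domain(config: GeometryConfig | None = None, variant: str = "healing") -> CallusDomain:
    """Construct the healing or distally extended non-union geometry.

    The non-union domain is a strict superset of the healing domain,
    extended only distally: the marrow canal continues under the cortex
    and a thin periosteal flank runs on top of it over ``extension_mm``.
    """
    config = config or GeometryConfig()
    if variant not in ("healing", "nonunion"):
        raise ConfigurationError(f"unknown domain variant {variant!r}")
    config.validate(variant)

    g = config.gap_mm / 2.0
    L = config.callus_length_mm
    hm = config.marrow_mm
    hc = config.cortex_mm
    hp = config.callus_height_mm
    y_cortex0, y_cortex1 = hm, hm + hc
    y_top = hm + hc + hp

    regions: Dict[str, Tuple[Tuple[float, float, float, float], ...]] = {
        "periosteal": ((0.0, L, y_cortex1, y_top),),
        "gap": ((0.0, g, y_cortex0, y_cortex1),),
        "endosteal": ((0.0, L, 0.0, y_cortex0),),
    }
    cortex = [(g, L, y_cortex0, y_cortex1)]
    x_max = L

    if variant == "nonunion":
        E = config.extension_mm
        regions["periosteal"] = regions["periosteal"] + ((L, L + E, y_cortex1, y_cortex1 + config.flank_mm),)
        regions["endosteal"] = regions["endosteal"] + ((L, L + E, 0.0, y_cortex0),)
        cortex.append((L, L + E, y_cortex0, y_cortex1))
        x_max = L + E

    return CallusDomain(
        config=config,
        variant=variant,
        regions=regions,
        cortex_boxes=tuple(cortex),
        x_max=x_max,
        y_max=y_top,
    )


@dataclass
class Grid:
    """Cell-centered rectangular grid with domain masks and face segments.

    ``seg_x[j, i]`` labels the x-normal face between cells ``(j, i-1)``
    and ``(j, i)`` (shape ``(ny, nx+1)``); ``seg_y[j, i]`` the y-normal
    face between ``(j-1, i)`` and ``(j, i)`` (shape ``(ny+1, nx)``).
    Interior and outside faces carry ``-1``; every boundary face of the
    discretized domain carries exactly one segment code (index into
    ``segment_names``).
    """

    dx: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    in_domain: np.ndarray  # bool (ny, nx)
    region: np.ndarray  # int  (ny, nx)
    roi: np.ndarray  # bool (ny, nx)
    seg_x: np.ndarray  # int  (ny, nx+1)
    seg_y: np.ndarray  # int  (ny+1, nx)
    segment_names: Tuple[str, ...]
    variant: str = "healing"
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.in_domain.shape

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx

    @property
    def n_cells(self) -> int:
        return int(self.in_domain.sum())

    def segment_code(self, name: str) -> int:
        try:
            return self.segment_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown boundary segment {name!r}") from None

    def boundary_face_counts(self) -> Dict[str, int]:
        counts = {}
        for code, name in enumerate(self.segment_names):
            counts[name] = int((self.seg_x == code).sum() + (self.seg_y == code).sum())
        return counts

    def n_boundary_faces(self) -> int:
        """Total boundary faces: in-domain cell on exactly one side."""
        ind = np.pad(self.in_domain, 1, constant_values=False)
        nx_faces = int((ind[1:-1, :-1] ^ ind[1:-1, 1:]).sum())
        ny_faces = int((ind[:-1, 1:-1] ^ ind[1:, 1:-1]).sum())
        return nx_faces + ny_faces


def _boxes_mask(boxes, xc, yc):
    """Cell-center containment for a union of half-open boxes [x0,x1)x[y0,y1)."""
    X, Y = np.meshgrid(xc, yc)
    mask = np.zeros(X.shape, dtype=bool)
    for x0, x1, y0, y1 in boxes:
        mask |= (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)
    return mask


def discretize(domain: CallusDomain, dx: float, roi_extent_mm: float | None = None) -> Grid:
    """Rasterize the domain onto a uniform cell-centered grid.

    The ROI (interfragmentary analysis region) is the central column of
    in-domain cells with ``x <= roi_extent_mm`` (default: the half gap
    width), spanning all three regions; it excludes the parts of the
    domain stretching distally along the cortex and is therefore
    identical for the healing and non-union variants.
    """
    cfg = domain.config
    narrowest = min(cfg.gap_mm / 2.0, cfg.marrow_mm, cfg.callus_height_mm, cfg.cortex_mm)
    if domain.variant == "nonunion":
        narrowest = min(narrowest, cfg.flank_mm)
    if dx <= 0.0:
        raise ConfigurationError(f"grid key 'dx_mm' must be > 0, got {dx}")
    if dx >= narrowest:
        raise ConfigurationError(
            f"grid key 'dx_mm' = {dx} is too coarse: it must resolve the narrowest "
            f"region dimension ({narrowest} mm)"
        )

    nx = int(np.ceil(domain.x_max / dx - 1e-12))
    ny = int(np.ceil(domain.y_max / dx - 1e-12))
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx

    region = np.zeros((ny, nx), dtype=np.int8)
    for name, code in (("periosteal", 1), ("gap", 2), ("endosteal", 3)):
        region[_boxes_mask(domain.regions[name], xc, yc)] = code
    cortex = _boxes_mask(domain.cortex_boxes, xc, yc)
    region[cortex] = REGION_CODES["cortex"]
    in_domain = (region > 0) & ~cortex

    if roi_extent_mm is None:
        roi_extent_mm = domain.gap_half
    roi = in_domain & (xc[None, :] <= roi_extent_mm + 1e-12)

    seg_x = np.full((ny, nx + 1), -1, dtype=np.int8)
    seg_y = np.full((ny + 1, nx), -1, dtype=np.int8)
    _assign_segments(domain, dx, xc, yc, in_domain, cortex, seg_x, seg_y)

    return Grid(
        dx=dx,
        x_centers=xc,
        y_centers=yc,
        in_domain=in_domain,
        region=region,
        roi=roi,
        seg_x=seg_x,
        seg_y=seg_y,
        segment_names=ALL_SEGMENTS,
        variant=domain.variant,
        meta={"geometry": cfg, "roi_extent_mm": roi_extent_mm},
    )


def _assign_segments(domain, dx, xc, yc, in_domain, cortex, seg_x, seg_y):
    """Classify every boundary face into exactly one named segment."""
    cfg = domain.config
    ny, nx = in_domain.shape
    code = {name: i for i, name in enumerate(ALL_SEGMENTS)}
    y_cortex1 = cfg.marrow_mm + cfg.cortex_mm
    tol = 0.25 * dx

    def classify(j, i, orient, outward):
        # face coordinates
        if orient == "x":
            fx = (i if outward < 0 else i + 1) * dx
            fx = min(fx, domain.x_max)
        else:
            fy = (j if outward < 0 else j + 1) * dx
            fy = min(fy, domain.y_max)
        cy = yc[j]
        # neighbor cell (may be off-array)
        jn, in_ = (j, i + outward) if orient == "x" else (j + outward, i)
        nb_cortex = 0 <= jn < ny and 0 <= in_ < nx and cortex[jn, in_]
        if nb_cortex:
            if orient == "y" and outward > 0:
                return code[SEG_ENDOSTEAL]  # endosteal lining under the cortex
            return code[SEG_CORTEX]  # cortex top or cut bone end
        if orient == "x" and outward < 0 and i == 0:
            return code[SEG_FRACTURE]
        if orient == "y" and outward < 0 and j == 0:
            return code[SEG_MARROW_AXIS]
        if orient == "y" and outward > 0:
            return code[SEG_PERIOSTEAL]  # any upward-facing tissue surface
        if orient == "x" and outward > 0:
            at_distal_end = abs(fx - domain.x_max) <= tol
            if cy < y_cortex1:  # endosteal band
                return code[SEG_MARROW_DISTAL]
            if domain.variant == "nonunion" and at_distal_end:
                return code[SEG_PERIOSTEAL_DISTAL]
            return code[SEG_SOFT]  # distal callus surface (step face or end face)
        if orient == "y" and outward < 0:
            # downward-facing tissue surface (only at geometry steps); treat as
            # part of the distal soft-tissue envelope
            return code[SEG_SOFT]
        raise ConfigurationError(
            f"orphan boundary face at cell ({j}, {i}), orientation {orient}{outward:+d}"
        )

    for j in range(ny):
        for i in range(nx):
            if not in_domain[j, i]:
                continue
            if i == 0 or not in_domain[j, i - 1]:
                seg_x[j, i] = classify(j, i, "x", -1)
            if i == nx - 1 or not in_domain[j, i + 1]:
                seg_x[j, i + 1] = classify(j, i, "x", +1)
            if j == 0 or not in_domain[j - 1, i]:
                seg_y[j, i] = classify(j, i, "y", -1)
            if j == ny - 1 or not in_domain[j + 1, i]:
                seg_y[j + 1, i] = classify(j, i, "y", +1)


def build_rectangle_grid(
    nx: int,
    ny: int,
    dx: float,
    segment_names: Tuple[str, str, str, str] = ("west", "east", "south", "north"),
) -> Grid:
    """All-in-domain rectangular grid for verification problems and fixtures.

    Boundary faces are labeled by side with ``segment_names`` given in
    (west, east, south, north) order; the ROI is the whole rectangle.
    """
    if nx <= 0 or ny <= 0 or dx <= 0:
        raise ConfigurationError("rectangle grid requires nx, ny, dx > 0")
    in_domain = np.ones((ny, nx), dtype=bool)
    seg_x = np.full((ny, nx + 1), -1, dtype=np.int8)
    seg_y = np.full((ny + 1, nx), -1, dtype=np.int8)
    seg_x[:, 0] = 0
    seg_x[:, -1] = 1
    seg_y[0, :] = 2
    seg_y[-1, :] = 3
    return Grid(
        dx=dx,
        x_centers=(np.arange(nx) + 0.5) * dx,
        y_centers=(np.arange(ny) + 0.5) * dx,
        in_domain=in_domain,
        region=np.ones((ny, nx), dtype=np.int8),
        roi=in_domain.copy(),
        seg_x=seg_x,
        seg_y=seg_y,
        segment_names=tuple(segment_names),
        variant="rectangle",
    )
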