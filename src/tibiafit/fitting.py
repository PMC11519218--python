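"""Tibial-component footprint library and constrained planar placement.

The footprint family mirrors the anatomy's base shape: a rounded,
posteriorly tapered oval with a straight ventral shield, scaled isotropically
to the five nominal tray areas.  Placement follows the clinical criteria in
lexicographic order: the shield is aligned parallel to the anterior cortical
flat (hard constraint), the footprint must not intrude medial of the marked
malleolus border and may overhang the cortex by at most a fixed area
tolerance (feasibility), and among feasible placements cortical contact is
maximized, then overhang minimized.  The search is a deterministic
coarse-to-fine translation grid in the shield-aligned frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .config import FitParams
from .contour import anterior_tangent, fit_closed_spline, spline_area
from .errors import CalibrationError
from .resection import CrossSection
from .shapes import base_outline

__all__ = [
    "ImplantFootprint",
    "Placement",
    "FitResult",
    "footprint_library",
    "place_implant",
    "select_size",
    "export_footprints",
]

_N_OUTLINE = 128


@dataclass
class ImplantFootprint:
    size_id: int  # 1..5
    nominal_area: float  # mm^2, spline-integrated outline area
    outline: np.ndarray  # (n, 2) CCW, shield along +v
    shield_edge: tuple[int, int]  # inclusive index range of the straight shield

    def shield_points(self) -> np.ndarray:
        i0, i1 = self.shield_edge
        return self.outline[i0 : i1 + 1]


@dataclass
class Placement:
    translation: np.ndarray  # (du, dv) mm applied after rotation
    rotation: float  # degrees CCW about the footprint centroid


@dataclass
class FitResult:
    size_id: int | None
    placement: Placement | None
    overhang_area: float  # mm^2 of footprint outside the bony contour
    contact_score: float  # fraction of perimeter in cortical contact
    malleolus_intrusion_area: float  # mm^2 covered medial of the border
    feasible: bool


def footprint_library(params: FitParams) -> list[ImplantFootprint]:
    """Five nested footprints whose spline areas equal the nominal areas."""
    params.validate()
    base = base_outline(
        _N_OUTLINE, params.aspect_ratio, params.taper, params.anterior_flat_fraction
    )
    base_area = spline_area(fit_closed_spline(base)).area
    if base_area <= 0:
        raise CalibrationError("degenerate footprint base outline")
    b = 1.0 / np.sqrt(np.pi * params.aspect_ratio)
    v_cut = b * np.sqrt(max(1.0 - params.anterior_flat_fraction**2, 0.0))
    on_flat = base[:, 1] >= v_cut - 1e-12
    idx = np.flatnonzero(on_flat)
    shield = (int(idx[0]), int(idx[-1]))

    library = []
    for i, nominal in enumerate(params.nominal_areas, start=1):
        s = np.sqrt(nominal / base_area)
        library.append(
            ImplantFootprint(
                size_id=i,
                nominal_area=float(nominal),
                outline=base * s,
                shield_edge=shield,
            )
        )
    return library


def placed_outline(fp: ImplantFootprint, placement: Placement) -> np.ndarray:
    """Footprint outline under a placement (rotation about centroid, then shift)."""
    c = fp.outline.mean(axis=0)
    phi = np.deg2rad(placement.rotation)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return (fp.outline - c) @ rot.T + c + placement.translation


class _SectionContext:
    """Cached shapely geometry for one cross-section."""

    def __init__(self, section: CrossSection):
        self.section = section
        self.polygon = Polygon(section.contour)
        self.boundary = LineString(
            np.vstack([section.contour, section.contour[:1]])
        )
        half = section.forbidden_halfplane()
        if half is None:
            self.allowed = self.polygon
            self.forbidden = None
        else:
            q0, m = half
            d = np.array([-m[1], m[0]])
            big = 10.0 * np.sqrt(max(self.polygon.area, 1.0))
            rect = Polygon(
                [
                    q0 + big * d,
                    q0 + big * d + big * m,
                    q0 - big * d + big * m,
                    q0 - big * d,
                ]
            )
            self.forbidden = rect
            self.allowed = self.polygon.difference(rect)
        self.usable_area = self.allowed.area
        tangent = anterior_tangent(section)
        # rotation aligning the footprint shield (medial->lateral = (-1, 0))
        self.shield_angle = float(
            np.degrees(np.arctan2(-tangent[1], -tangent[0]))
        )
        phi = np.deg2rad(self.shield_angle)
        self.frame = np.array(
            [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
        )
        self.anchor = np.asarray(self.allowed.centroid.coords[0])


def _evaluate_batch(
    ctx: _SectionContext,
    outline_rot: np.ndarray,
    fp_area: float,
    offsets: np.ndarray,
    contact_distance: float,
    overhang_tol: float,
):
    """(feasible, contact, overhang, intrusion) arrays over candidate offsets.

    Overlap areas come from vectorized polygon clipping; cortical contact
    (fraction of outline vertices within the contact band of the cortical
    contour) is only evaluated for feasible candidates.
    """
    n_cand = len(offsets)
    n_pts = len(outline_rot)
    coords = (outline_rot[None, :, :] + offsets[:, None, :]).reshape(-1, 2)
    rings = shapely.linearrings(coords, indices=np.repeat(np.arange(n_cand), n_pts))
    polys = shapely.polygons(rings)
    in_bone = shapely.area(shapely.intersection(polys, ctx.polygon))
    overhang = fp_area - in_bone
    if ctx.forbidden is not None:
        on_allowed = shapely.area(shapely.intersection(polys, ctx.allowed))
        intrusion = np.maximum(in_bone - on_allowed, 0.0)
    else:
        intrusion = np.zeros(n_cand)
    feasible = (overhang <= overhang_tol) & (intrusion <= 1e-6)
    contact = np.full(n_cand, -1.0)
    if feasible.any():
        which = np.flatnonzero(feasible)
        sub = (outline_rot[None, :, :] + offsets[which, None, :]).reshape(-1, 2)
        sample = shapely.points(sub)
        near = shapely.distance(sample, ctx.boundary) <= contact_distance
        contact[which] = near.reshape(len(which), n_pts).mean(axis=1)
    return feasible, contact, overhang, intrusion


def _grid(step: float, halfspan: float) -> np.ndarray:
    k = int(round(halfspan / step))
    axis = step * np.arange(-k, k + 1)
    gu, gv = np.meshgrid(axis, axis)
    return np.column_stack([gu.ravel(), gv.ravel()])


def place_implant(
    fp: ImplantFootprint,
    section: CrossSection,
    params: FitParams | None = None,
    _ctx: _SectionContext | None = None,
) -> FitResult:
    """Best shield-aligned placement of one footprint on a cross-section.

    Deterministic coarse (1 mm) then refined (0.1 mm) translation search in
    the shield-aligned frame; lexicographic objective (feasibility, maximal
    cortical contact, minimal overhang).  Infeasibility is reported as a
    result, not an error.
    """
    params = params or FitParams()
    if len(section.contour) < 3:
        raise ValueError("empty or degenerate cross-section")
    ctx = _ctx or _SectionContext(section)

    centroid = fp.outline.mean(axis=0)
    outline_rot = (fp.outline - centroid) @ ctx.frame.T + centroid
    fp_area = fp.nominal_area
    base_offset = ctx.anchor - centroid

    # certainly-infeasible shortcut: not even the usable area can host it
    if fp_area - ctx.usable_area > params.overhang_tol_mm2:
        feas, contact, over, intr = (
            arr[0]
            for arr in _evaluate_batch(
                ctx, outline_rot, fp_area, base_offset[None, :],
                params.contact_distance, params.overhang_tol_mm2,
            )
        )
        return FitResult(
            size_id=fp.size_id,
            placement=Placement(translation=base_offset, rotation=ctx.shield_angle),
            overhang_area=float(over),
            contact_score=float(max(contact, 0.0)),
            malleolus_intrusion_area=float(intr),
            feasible=False,
        )

    def search(grid: np.ndarray):
        offsets = base_offset + grid @ ctx.frame.T
        feas, contact, over, intr = _evaluate_batch(
            ctx, outline_rot, fp_area, offsets,
            params.contact_distance, params.overhang_tol_mm2,
        )
        # lexicographic: feasibility, then contact, then least overhang
        keys = np.lexsort((over + intr, -contact, ~feas))
        i = keys[0]
        return grid[i], bool(feas[i]), float(contact[i]), float(over[i]), float(intr[i])

    g0, *_ = search(_grid(params.coarse_step, params.coarse_halfspan))
    g, feas, contact, over, intr = search(g0 + _grid(params.fine_step, params.fine_halfspan))

    return FitResult(
        size_id=fp.size_id,
        placement=Placement(
            translation=base_offset + ctx.frame @ g, rotation=ctx.shield_angle
        ),
        overhang_area=float(over),
        contact_score=float(max(contact, 0.0)),
        malleolus_intrusion_area=float(intr),
        feasible=bool(feas),
    )


def select_size(
    section: CrossSection,
    library: list[ImplantFootprint],
    params: FitParams | None = None,
) -> FitResult:
    """Best-fitting size for a cross-section.

    All sizes are placed; among feasible fits the highest cortical contact
    wins, with ties (contact within ``contact_tie_tol``) resolved toward the
    larger size and then the smaller overhang.  With no feasible size the
    result carries ``size_id=None`` and the least-overhang attempt's scores.
    """
    params = params or FitParams()
    ctx = _SectionContext(section)
    results = [place_implant(fp, section, params, _ctx=ctx) for fp in library]

    feasible = [r for r in results if r.feasible]
    if not feasible:
        best = min(results, key=lambda r: r.overhang_area + r.malleolus_intrusion_area)
        return FitResult(
            size_id=None,
            placement=best.placement,
            overhang_area=best.overhang_area,
            contact_score=best.contact_score,
            malleolus_intrusion_area=best.malleolus_intrusion_area,
            feasible=False,
        )
    top = max(r.contact_score for r in feasible)
    near = [r for r in feasible if r.contact_score >= top - params.contact_tie_tol]
    near.sort(key=lambda r: (-r.size_id, r.overhang_area))
    return near[0]


def export_footprints(library: list[ImplantFootprint], path: str | Path) -> None:
    """JSON export of the outline polygons (mm) for plotting/verification."""
    payload = [
        {
            "size_id": fp.size_id,
            "nominal_area_mm2": fp.nominal_area,
            "outline": fp.outline.tolist(),
            "shield_edge": list(fp.shield_edge),
        }
        for fp in library
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
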