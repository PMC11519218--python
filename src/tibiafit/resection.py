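"""Resection-plane construction and cross-section extraction.

The osteotomy plane is anchored at the articular dome apex, displaced a few
mm proximally along the shaft axis and tilted about the medial axis so its
posterior extent lies more distal (the posterior slope).  Slicing the
surface with this plane yields one closed contour; the contour is projected
into the in-plane frame (u medial, v anterior), oriented counter-clockwise,
resampled uniformly in arc length, and annotated with the anterior cortical
flat and the medial-malleolus border.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .anatomy import TibiaModel
from .config import ResectionParams
from .errors import AmbiguousTopologyError, EmptySliceError, LandmarkError
from .shapes import ensure_ccw, polygon_area, resample_closed

__all__ = [
    "ResectionPlane",
    "CrossSection",
    "build_resection_plane",
    "slice_surface",
    "mark_malleolus",
    "section_to_json",
    "section_from_json",
]

_CHAIN_TOL = 1e-6  # mm, segment endpoint matching
_N_CONTOUR = 256  # resampled contour points
_FLAT_CURVATURE = 0.02  # 1/mm, anterior-flat curvature threshold
_FLAT_MIN_RUN = 10  # minimum points in the anterior arc


@dataclass
class ResectionPlane:
    origin: np.ndarray  # (3,)
    normal: np.ndarray  # (3,) unit
    u_dir: np.ndarray  # (3,) in-plane, medial
    v_dir: np.ndarray  # (3,) in-plane, anterior

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project 3D points along the normal into (u, v) plane coordinates."""
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ self.u_dir, rel @ self.v_dir])


@dataclass
class CrossSection:
    """Ordered CCW planar resection contour with annotations."""

    contour: np.ndarray  # (n, 2), closed implicitly, CCW
    anterior_arc: tuple[int, int] | None  # inclusive index range, may wrap
    plane: ResectionPlane
    source_id: str = ""
    malleolus_border: np.ndarray | None = None  # (2, 2) segment in (u, v)

    def anterior_points(self) -> np.ndarray:
        if self.anterior_arc is None:
            raise ValueError("cross-section has no detected anterior flat")
        i0, i1 = self.anterior_arc
        n = len(self.contour)
        if i0 <= i1:
            return self.contour[i0 : i1 + 1]
        return np.vstack([self.contour[i0:], self.contour[: i1 + 1]])

    def polygon(self) -> Polygon:
        return Polygon(self.contour)

    def forbidden_halfplane(self) -> tuple[np.ndarray, np.ndarray] | None:
        """(point, medial-pointing unit normal) of the malleolus border line.

        Points x with (x - point) . normal > 0 lie medial of the border and
        are forbidden for implant coverage; None if no border is marked.
        """
        if self.malleolus_border is None:
            return None
        q0, q1 = self.malleolus_border
        d = q1 - q0
        d = d / np.linalg.norm(d)
        m = np.array([d[1], -d[0]])
        if m[0] < 0:
            m = -m
        return q0, m


def build_resection_plane(model: TibiaModel, params: ResectionParams) -> ResectionPlane:
    """Plane ``proximal_offset`` mm above the apex, tilted posteriorly.

    The normal is the shaft axis rotated by ``posterior_inclination`` about
    the medial axis, signed so that plane points posterior of the origin lie
    more distal.
    """
    params.validate()
    axis = np.asarray(model.shaft_axis, dtype=float)
    anterior = np.asarray(model.anterior_dir, dtype=float)
    if np.linalg.norm(axis) < 1e-12 or np.linalg.norm(anterior) < 1e-12:
        raise LandmarkError("degenerate shaft axis or anterior direction")
    axis = axis / np.linalg.norm(axis)
    anterior = anterior / np.linalg.norm(anterior)
    if abs(axis @ anterior) > 1e-6:
        raise LandmarkError("shaft_axis and anterior_dir must be orthogonal")
    medial = np.cross(anterior, axis)
    medial /= np.linalg.norm(medial)

    origin = np.asarray(model.apex, dtype=float) + params.proximal_offset * axis
    phi = np.deg2rad(params.posterior_inclination)
    # Rodrigues rotation of the shaft axis about the medial axis; the +phi
    # sense drops the posterior side of the plane distally
    normal = (
        axis * np.cos(phi)
        + np.cross(medial, axis) * np.sin(phi)
        + medial * (medial @ axis) * (1.0 - np.cos(phi))
    )
    normal /= np.linalg.norm(normal)
    u_dir = medial - (medial @ normal) * normal
    u_dir /= np.linalg.norm(u_dir)
    v_dir = np.cross(normal, u_dir)
    return ResectionPlane(origin=origin, normal=normal, u_dir=u_dir, v_dir=v_dir)


def _chain_segments(segments: np.ndarray) -> list[np.ndarray]:
    """Chain unordered 3D segments into closed loops (endpoint tol 1e-6 mm).

    Coincident endpoints are merged by radius search (robust against
    floating-point jitter across the triangles sharing an edge).
    """
    from scipy.spatial import cKDTree

    n = len(segments)
    endpoints = segments.reshape(-1, 3)
    tree = cKDTree(endpoints)
    # union-find over endpoint clusters
    parent = np.arange(2 * n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(_CHAIN_TOL):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    labels = np.array([find(i) for i in range(2 * n)])

    endpoint_map: dict[int, list[tuple[int, int]]] = {}
    for i in range(n):
        for e in (0, 1):
            endpoint_map.setdefault(labels[2 * i + e], []).append((i, e))

    used = np.zeros(n, dtype=bool)
    loops: list[np.ndarray] = []
    for start in range(n):
        if used[start]:
            continue
        loop_pts = [segments[start, 0]]
        used[start] = True
        start_label = labels[2 * start]
        cur_label = labels[2 * start + 1]
        cur_pt = segments[start, 1]
        while cur_label != start_label:
            loop_pts.append(cur_pt)
            nxt = [(i, e) for i, e in endpoint_map.get(cur_label, []) if not used[i]]
            if not nxt:
                raise AmbiguousTopologyError("open slice chain: surface not closed")
            i, e = nxt[0]
            used[i] = True
            cur_pt = segments[i, 1 - e]
            cur_label = labels[2 * i + (1 - e)]
        loops.append(np.asarray(loop_pts))
    return loops


def slice_surface(model: TibiaModel, plane: ResectionPlane) -> CrossSection:
    """Intersect the surface with the plane and extract the CCW contour.

    Raises EmptySliceError when the plane misses the surface and
    AmbiguousTopologyError when the cut produces more than one closed loop
    (a valid paraxial tibial cut yields exactly one).
    """
    segments = trimesh.intersections.mesh_plane(
        model.mesh, plane_normal=plane.normal, plane_origin=plane.origin
    )
    if len(segments) == 0:
        raise EmptySliceError("resection plane does not intersect the surface")
    lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    segments = segments[lengths > _CHAIN_TOL]
    loops = _chain_segments(segments)
    loops = [lp for lp in loops if len(lp) >= 3]
    if len(loops) == 0:
        raise EmptySliceError("resection plane only grazes the surface")
    if len(loops) > 1:
        raise AmbiguousTopologyError(
            f"resection plane cuts the surface in {len(loops)} loops"
        )

    contour = ensure_ccw(plane.project(loops[0]))
    contour = resample_closed(contour, _N_CONTOUR)
    arc = _detect_anterior_arc(contour)
    return CrossSection(
        contour=contour, anterior_arc=arc, plane=plane, source_id=model.subject_id
    )


def _detect_anterior_arc(contour: np.ndarray) -> tuple[int, int] | None:
    """Longest anterior-facing low-curvature run of contour points.

    Discrete curvature = turning angle over mean incident segment length;
    a point qualifies when its curvature is below 0.02 / mm and its outward
    normal has a positive anterior (v) component.  Ties between equally long
    runs go to the lower mean curvature.  Returns None when the contour has
    no anterior flat (e.g. an analytic test cylinder); downstream implant
    alignment then refuses to run, but area measurement is unaffected.
    """
    n = len(contour)
    prev_seg = contour - np.roll(contour, 1, axis=0)
    next_seg = np.roll(contour, -1, axis=0) - contour
    ang_prev = np.arctan2(prev_seg[:, 1], prev_seg[:, 0])
    ang_next = np.arctan2(next_seg[:, 1], next_seg[:, 0])
    turn = np.mod(ang_next - ang_prev + np.pi, 2.0 * np.pi) - np.pi
    ds = 0.5 * (np.linalg.norm(prev_seg, axis=1) + np.linalg.norm(next_seg, axis=1))
    curvature = np.abs(turn) / ds
    # outward normal of a CCW contour: tangent rotated by -90 degrees
    tangent = next_seg / np.linalg.norm(next_seg, axis=1, keepdims=True)
    outward_v = -tangent[:, 0]
    ok = (curvature < _FLAT_CURVATURE) & (outward_v > 0.0)

    if not ok.any():
        return None
    # maximal circular runs of qualifying points
    best: tuple[int, float, int] | None = None  # (length, -mean curvature, start)
    i = 0
    visited = np.zeros(n, dtype=bool)
    order = np.flatnonzero(ok)
    for i in order:
        if visited[i]:
            continue
        if ok[(i - 1) % n]:
            continue  # not a run start
        j, run = i, []
        while ok[j % n] and len(run) < n:
            visited[j % n] = True
            run.append(j % n)
            j += 1
        cand = (len(run), -float(np.mean(curvature[run])), i)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:  # every point qualifies (e.g. giant circle): take all
        return 0, n - 1
    length, _, start = best
    if length < _FLAT_MIN_RUN:
        return None
    return int(start), int((start + length - 1) % n)


def mark_malleolus(section: CrossSection, model: TibiaModel) -> CrossSection:
    """Project the three malleolus margin points and mark the border line.

    The best-fit (total-least-squares) line through the projected points,
    oriented anterior-posterior, becomes the malleolus border; the contour
    itself is unchanged, but the half-plane medial of the border is flagged
    forbidden for implant coverage.
    """
    pts3 = np.asarray(model.malleolus_margin_points, dtype=float)
    if pts3.shape != (3, 3):
        raise LandmarkError("exactly 3 malleolus margin points are required")
    proj = section.plane.project(pts3)
    distinct = np.unique(np.round(proj / 1e-9).astype(np.int64), axis=0)
    if len(distinct) < 2:
        raise LandmarkError("malleolus margin projections are degenerate")
    center = proj.mean(axis=0)
    _, _, vt = np.linalg.svd(proj - center)
    d = vt[0]
    d = d / np.linalg.norm(d)
    if d[1] < 0:  # orient anterior -> posterior consistently
        d = -d
    # segment representation spanning the section's v extent
    v_lo = float(section.contour[:, 1].min()) - 1.0
    v_hi = float(section.contour[:, 1].max()) + 1.0
    if abs(d[1]) > 1e-9:
        t_lo = (v_lo - center[1]) / d[1]
        t_hi = (v_hi - center[1]) / d[1]
    else:  # border parallel to u axis: degenerate for a medial border but legal
        t_lo, t_hi = -50.0, 50.0
    border = np.vstack([center + t_lo * d, center + t_hi * d])
    return replace(section, malleolus_border=border)


def section_to_json(section: CrossSection) -> str:
    payload = {
        "contour": section.contour.tolist(),
        "anterior_arc": None if section.anterior_arc is None else list(section.anterior_arc),
        "malleolus_border": None
        if section.malleolus_border is None
        else section.malleolus_border.tolist(),
        "plane": {
            "origin": section.plane.origin.tolist(),
            "normal": section.plane.normal.tolist(),
            "u_dir": section.plane.u_dir.tolist(),
            "v_dir": section.plane.v_dir.tolist(),
        },
        "source_id": section.source_id,
        "units": "mm",
    }
    return json.dumps(payload, indent=1)


def section_from_json(text: str) -> CrossSection:
    raw = json.loads(text)
    plane = ResectionPlane(
        origin=np.asarray(raw["plane"]["origin"], dtype=float),
        normal=np.asarray(raw["plane"]["normal"], dtype=float),
        u_dir=np.asarray(raw["plane"]["u_dir"], dtype=float),
        v_dir=np.asarray(raw["plane"]["v_dir"], dtype=float),
    )
    border = raw.get("malleolus_border")
    arc = raw.get("anterior_arc")
    return CrossSection(
        contour=np.asarray(raw["contour"], dtype=float),
        anterior_arc=None if arc is None else (int(arc[0]), int(arc[1])),
        plane=plane,
        source_id=raw.get("source_id", ""),
        malleolus_border=None if border is None else np.asarray(border, dtype=float),
    )


def save_section(section: CrossSection, path: str | Path) -> None:
    Path(path).write_text(section_to_json(section))


def load_section(path: str | Path) -> CrossSection:
    return section_from_json(Path(path).read_text())


def section_contour_csv(section: CrossSection, path: str | Path) -> None:
    """Plain CSV of the contour for plotting."""
    header = "u_mm,v_mm"
    np.savetxt(path, section.contour, delimiter=",", header=header, comments="")


# re-export for callers that only need the area of a polygonal contour
contour_polygon_area = polygon_area
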