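"""Parametric synthetic distal-tibia surface models.

The generator is contour-first: the resection-level cross-section is built
as a tapered oval with an anterior cortical flat, a medial-malleolus bump
and low-order Fourier perturbations, rescaled so its dense-polygon area
equals the requested target area exactly.  The 3D surface is a stack of
z-scaled copies of this contour — cylindrical in a band around the
resection level, narrowing quadratically up the shaft — capped distally by
a concave articular dome whose apex is a recorded landmark and proximally
by a flat cap.

Frame convention (right leg): +z proximal along the shaft axis, +y
anterior, +x medial; all coordinates in mm.  The dome rim sits at z = 0 and
the apex at z = ``dome_depth``, so the default osteotomy (2 mm proximal to
the apex) runs through the cylindrical band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .config import AnatomyParams
from .cohort import SubjectProfile
from .errors import GenerationError
from .shapes import base_outline, polygon_area

__all__ = ["TibiaModel", "generate_tibia", "export_model", "load_model"]

_N_DENSE = 2048  # dense contour samples for area normalization


@dataclass
class TibiaModel:
    """Closed distal-tibia surface with landmarks and construction truth."""

    mesh: trimesh.Trimesh
    apex: np.ndarray  # (3,) most proximal point of the articular concavity
    shaft_axis: np.ndarray  # (3,) unit, +z proximal
    anterior_dir: np.ndarray  # (3,) unit, +y anterior
    malleolus_margin_points: np.ndarray  # (3, 3) lateral border of the malleolus
    true_area: float | None  # mm^2 ground-truth resection-level area
    subject_id: str = ""

    @property
    def medial_dir(self) -> np.ndarray:
        return np.cross(self.anterior_dir, self.shaft_axis)


def _dense_contour(
    target_area: float, params: AnatomyParams, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Resection-level contour on a dense theta grid, plus the medial tangent.

    Returns (points (N,2), u_border) where u_border is the medial extent of
    the bump-free contour — the lateral border of the malleolus bump.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, _N_DENSE, endpoint=False)
    pts = base_outline(_N_DENSE, params.aspect_ratio, params.taper, flat_fraction=0.0)

    # low-order Fourier irregularity, radial, harmonics 2..6
    if params.contour_irregularity > 0:
        factor = np.ones(_N_DENSE)
        for k in range(2, 7):
            c_k = params.contour_irregularity * rng.uniform(0.5, 1.5) / k
            phi_k = rng.uniform(0.0, 2.0 * np.pi)
            factor += c_k * np.cos(k * theta + phi_k)
        if factor.min() <= 0.5:
            raise GenerationError("contour irregularity produces degenerate radii")
        pts = pts * factor[:, None]
    else:
        rng.uniform(0.5, 1.5, size=5)
        rng.uniform(0.0, 2.0 * np.pi, size=5)  # keep the draw sequence stable

    # anterior cortical flat: straight chord clipped onto the unit-scale oval
    # at the same relative height as in shapes.base_outline, so the section
    # and footprint families stay congruent
    b_unit = 1.0 / np.sqrt(np.pi * params.aspect_ratio)
    if params.anterior_flat_fraction > 0:
        v_cut = b_unit * np.sqrt(max(1.0 - params.anterior_flat_fraction**2, 0.0))
        pts[:, 1] = np.minimum(pts[:, 1], v_cut)

    area0 = polygon_area(pts)
    if area0 <= 0:
        raise GenerationError("degenerate base contour")
    pts = pts * np.sqrt(target_area / area0)

    u_border = float(pts[:, 0].max())

    # medial malleolus bump: radial Gaussian lobe at theta = 0, per-subject size
    var = params.subject_variability
    amp = params.malleolus_bump_amplitude * rng.uniform(1.0 - var, 1.0 + var)
    width = params.malleolus_bump_width * rng.uniform(1.0 - var, 1.0 + var)
    if amp < 0 or width <= 0:
        raise GenerationError("degenerate malleolus bump parameters")
    if amp > 0:
        wrapped = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
        bump = amp * np.exp(-((wrapped / width) ** 2))
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts = pts + bump[:, None] * radial

    # final isotropic rescale to the exact target area
    scale = np.sqrt(target_area / polygon_area(pts))
    pts = pts * scale
    u_border *= scale
    return pts, u_border


def _margin_points(
    contour: np.ndarray, u_border: float, z_levels: tuple[float, float, float]
) -> np.ndarray:
    """Three points on the lateral border of the malleolus bump.

    The bump is the contiguous run of contour points medial of ``u_border``;
    the run's entry/exit crossings of the line u = u_border are located by
    linear interpolation and reused at three z levels (emulating margins
    marked on three different coronal sections).
    """
    u = contour[:, 0]
    over = u > u_border + 1e-12
    if not over.any():
        # bump-free model: collapse to the medial tangent point
        i = int(np.argmax(u))
        p = contour[i]
        return np.array([[p[0], p[1], z] for z in z_levels])
    n = len(contour)
    # contiguous run containing the medial extreme
    i_max = int(np.argmax(u))
    lo = i_max
    while over[(lo - 1) % n]:
        lo = (lo - 1) % n
    hi = i_max
    while over[(hi + 1) % n]:
        hi = (hi + 1) % n

    def crossing(i_out: int, i_in: int) -> np.ndarray:
        p0, p1 = contour[i_out], contour[i_in]
        t = (u_border - p0[0]) / (p1[0] - p0[0])
        return p0 + t * (p1 - p0)

    c_a = crossing((hi + 1) % n, hi)  # anterior-side crossing (theta > 0)
    c_p = crossing((lo - 1) % n, lo)  # posterior-side crossing
    z1, z2, z3 = z_levels
    return np.array(
        [
            [c_a[0], c_a[1], z1],
            [c_p[0], c_p[1], z2],
            [c_a[0], c_a[1], z3],
        ]
    )


_FACE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _ring_stack_faces(n_c: int, n_rings: int) -> np.ndarray:
    """Triangulation of an apex fan + ring strips + top fan (cached).

    Winding is outward for a solid whose rings are ordered from the dome
    apex (vertex 0) to the proximal cap centre (last vertex).
    """
    key = (n_c, n_rings)
    if key in _FACE_CACHE:
        return _FACE_CACHE[key]
    j = np.arange(n_c)
    jn = (j + 1) % n_c
    idx = lambda r, jj: 1 + r * n_c + jj  # noqa: E731
    fan = np.column_stack([np.zeros(n_c, dtype=np.int64), idx(0, jn), idx(0, j)])
    strips = []
    for r in range(n_rings - 1):
        a, b = idx(r, j), idx(r, jn)
        c, e = idx(r + 1, j), idx(r + 1, jn)
        strips.append(np.column_stack([a, b, e]))
        strips.append(np.column_stack([a, e, c]))
    top = 1 + n_rings * n_c
    cap = np.column_stack(
        [np.full(n_c, top, dtype=np.int64), idx(n_rings - 1, j), idx(n_rings - 1, jn)]
    )
    faces = np.vstack([fan, *strips, cap]).astype(np.int64)
    _FACE_CACHE[key] = faces
    return faces


def _wall_profile(z: np.ndarray, params: AnatomyParams) -> np.ndarray:
    """In-plane scale of the wall contour as a function of z.

    Constant (1.0) in a band around the resection level so the osteotomy
    cuts a generalized cylinder; quadratic narrowing to 75% up the shaft.
    """
    band_top = params.dome_depth + 6.0
    s = np.ones_like(z, dtype=float)
    up = z > band_top
    frac = (z[up] - band_top) / (params.shaft_length - band_top)
    s[up] = 1.0 - 0.25 * frac**2
    return s


def generate_tibia(
    profile: SubjectProfile,
    target_area: float,
    params: AnatomyParams,
    seed: int,
) -> TibiaModel:
    """Generate one watertight synthetic distal tibia.

    The resection-level cross-section has exact (dense-shoelace) area
    ``target_area``; ``true_area`` records the achieved value.  Deterministic
    under fixed ``(profile, target_area, params, seed)``.
    """
    if target_area <= 0:
        raise GenerationError("target_area must be > 0")
    params.validate()
    rng = np.random.default_rng(seed)

    dense, u_border = _dense_contour(target_area, params, rng)
    true_area = polygon_area(dense)

    n_c = params.n_circumference
    step = _N_DENSE // n_c
    ring = dense[::step]
    centroid = ring.mean(axis=0)
    d = params.dome_depth
    length = params.shaft_length

    # ring stack: dome (apex downward-opening paraboloid of revolution in the
    # scaled contour), then the wall from the rim (z=0) to the shaft top
    rho_levels = np.linspace(0.125, 0.875, 7)
    band_top = d + 6.0
    wall_z = np.concatenate(
        [np.linspace(0.0, band_top, 4), np.linspace(band_top, length, 7)[1:]]
    )
    wall_s = _wall_profile(wall_z, params)

    rings: list[np.ndarray] = []
    apex = np.array([centroid[0], centroid[1], d])
    for rho in rho_levels:  # dome, apex side first
        pts2 = centroid + rho * (ring - centroid)
        z = d * (1.0 - rho**2)
        rings.append(np.column_stack([pts2, np.full(n_c, z)]))
    for z, s in zip(wall_z, wall_s):
        pts2 = centroid + s * (ring - centroid)
        rings.append(np.column_stack([pts2, np.full(n_c, z)]))
    top_center = np.array([centroid[0], centroid[1], length])

    vertices = np.vstack([apex[None, :], np.vstack(rings), top_center[None, :]])
    n_rings = len(rings)
    mesh = trimesh.Trimesh(
        vertices=vertices, faces=_ring_stack_faces(n_c, n_rings), process=False
    )

    margin = _margin_points(dense, u_border, (d + 1.0, d + 2.0, d + 3.0))

    return TibiaModel(
        mesh=mesh,
        apex=apex,
        shaft_axis=np.array([0.0, 0.0, 1.0]),
        anterior_dir=np.array([0.0, 1.0, 0.0]),
        malleolus_margin_points=margin,
        true_area=float(true_area),
        subject_id=profile.subject_id,
    )


def export_model(model: TibiaModel, directory: str | Path, fmt: str = "stl") -> tuple[Path, Path]:
    """Write the surface (STL or PLY) plus a JSON landmark sidecar."""
    if fmt not in ("stl", "ply"):
        raise ValueError("fmt must be 'stl' or 'ply'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = model.subject_id or "tibia"
    mesh_path = directory / f"{stem}.{fmt}"
    model.mesh.export(mesh_path)
    landmarks = {
        "apex": model.apex.tolist(),
        "shaft_axis": model.shaft_axis.tolist(),
        "anterior_dir": model.anterior_dir.tolist(),
        "malleolus_margin_points": model.malleolus_margin_points.tolist(),
        "true_area": model.true_area,
        "subject_id": model.subject_id,
    }
    lm_path = directory / f"{stem}.landmarks.json"
    lm_path.write_text(json.dumps(landmarks, indent=1))
    return mesh_path, lm_path


def load_model(mesh_path: str | Path, landmarks_path: str | Path | None = None) -> TibiaModel:
    """Load a segmented tibia surface with its landmark sidecar."""
    mesh_path = Path(mesh_path)
    if landmarks_path is None:
        landmarks_path = mesh_path.with_suffix("").with_suffix(".landmarks.json")
        if not Path(landmarks_path).exists():
            landmarks_path = mesh_path.parent / (mesh_path.stem + ".landmarks.json")
    raw = json.loads(Path(landmarks_path).read_text())
    mesh = trimesh.load(mesh_path, force="mesh", process=False)
    return TibiaModel(
        mesh=mesh,
        apex=np.asarray(raw["apex"], dtype=float),
        shaft_axis=np.asarray(raw["shaft_axis"], dtype=float),
        anterior_dir=np.asarray(raw["anterior_dir"], dtype=float),
        malleolus_margin_points=np.asarray(raw["malleolus_margin_points"], dtype=float),
        true_area=raw.get("true_area"),
        subject_id=raw.get("subject_id", mesh_path.stem),
    )
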