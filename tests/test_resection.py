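"""Resection plane and cross-section extraction against analytic oracles."""

import numpy as np
import pytest
import trimesh
from dataclasses import replace

from conftest import make_cylinder
from tibiafit import (
    ResectionParams,
    TibiaModel,
    build_resection_plane,
    fit_closed_spline,
    mark_malleolus,
    slice_surface,
    spline_area,
)
from tibiafit.errors import AmbiguousTopologyError, EmptySliceError, LandmarkError
from tibiafit.resection import load_section, save_section


def _rigid_model(model: TibiaModel, matrix: np.ndarray) -> TibiaModel:
    """Apply a 4x4 rigid transform to a model including its landmarks."""
    mesh = model.mesh.copy()
    mesh.apply_transform(matrix)
    rot = matrix[:3, :3]
    t = matrix[:3, 3]
    return TibiaModel(
        mesh=mesh,
        apex=rot @ model.apex + t,
        shaft_axis=rot @ model.shaft_axis,
        anterior_dir=rot @ model.anterior_dir,
        malleolus_margin_points=model.malleolus_margin_points @ rot.T + t,
        true_area=model.true_area,
        subject_id=model.subject_id,
    )


def test_plane_zero_tilt(tibia_model):
    params = ResectionParams(proximal_offset=2.0, posterior_inclination=0.0)
    plane = build_resection_plane(tibia_model, params)
    assert np.allclose(plane.origin, tibia_model.apex + [0, 0, 2.0])
    assert np.allclose(plane.normal, [0, 0, 1])
    assert np.allclose(plane.u_dir, [1, 0, 0])
    assert np.allclose(plane.v_dir, [0, 1, 0])


def test_plane_posterior_slope_sign():
    """A point 10 mm posterior of the origin lies 10*tan(4 deg) more distal."""
    model = make_cylinder(radius=15.0)
    plane = build_resection_plane(
        model, ResectionParams(proximal_offset=2.0, posterior_inclination=4.0)
    )
    # z on the plane at (x=0, y=-10): n . (p - origin) = 0
    z = plane.origin[2] + 10.0 * plane.normal[1] / plane.normal[2]
    assert z == pytest.approx(2.0 - 10.0 * np.tan(np.deg2rad(4.0)), abs=1e-9)
    assert z == pytest.approx(1.3007319, abs=1e-6)
    # angle between normal and shaft axis equals the inclination
    ang = np.degrees(np.arccos(np.clip(plane.normal @ model.shaft_axis, -1, 1)))
    assert ang == pytest.approx(4.0, abs=1e-6)
    # frame orthonormality
    for a, b in [(plane.u_dir, plane.v_dir), (plane.u_dir, plane.normal),
                 (plane.v_dir, plane.normal)]:
        assert abs(a @ b) < 1e-9


def test_plane_rigid_equivariance(tibia_model, config):
    rng = np.random.default_rng(42)
    angle = rng.uniform(0, 2 * np.pi)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    matrix = trimesh.transformations.rotation_matrix(angle, direction)
    matrix[:3, 3] = rng.uniform(-30, 30, size=3)
    moved = _rigid_model(tibia_model, matrix)

    p0 = build_resection_plane(tibia_model, config.resection)
    p1 = build_resection_plane(moved, config.resection)
    rot, t = matrix[:3, :3], matrix[:3, 3]
    assert np.allclose(p1.origin, rot @ p0.origin + t, atol=1e-9)
    assert np.allclose(p1.normal, rot @ p0.normal, atol=1e-9)


def test_degenerate_landmarks_raise(tibia_model):
    bad = TibiaModel(
        mesh=tibia_model.mesh,
        apex=tibia_model.apex,
        shaft_axis=np.zeros(3),
        anterior_dir=tibia_model.anterior_dir,
        malleolus_margin_points=tibia_model.malleolus_margin_points,
        true_area=tibia_model.true_area,
    )
    with pytest.raises(LandmarkError):
        build_resection_plane(bad, ResectionParams())


def test_inclined_cylinder_slice_area():
    """Slicing a cylinder at 4 degrees gives an ellipse of area pi r^2 / cos."""
    model = make_cylinder(radius=15.0)
    plane = build_resection_plane(
        model, ResectionParams(proximal_offset=20.0, posterior_inclination=4.0)
    )
    section = slice_surface(model, plane)
    area = spline_area(fit_closed_spline(section.contour)).area
    expected = np.pi * 15.0**2 / np.cos(np.deg2rad(4.0))
    assert area == pytest.approx(expected, rel=1e-3)


def test_offset_correctness_zero_inclination(tibia_model):
    params = ResectionParams(proximal_offset=2.0, posterior_inclination=0.0)
    plane = build_resection_plane(tibia_model, params)
    section = slice_surface(tibia_model, plane)
    # reconstruct 3D points: all must sit at apex_z + offset
    pts3 = (
        plane.origin
        + section.contour[:, :1] * plane.u_dir
        + section.contour[:, 1:] * plane.v_dir
    )
    assert np.allclose(pts3[:, 2], tibia_model.apex[2] + 2.0, atol=1e-9)


def test_generated_section_area_matches_truth(tibia_model):
    params = ResectionParams(proximal_offset=2.0, posterior_inclination=0.0)
    plane = build_resection_plane(tibia_model, params)
    section = slice_surface(tibia_model, plane)
    area = spline_area(fit_closed_spline(section.contour)).area
    assert area == pytest.approx(tibia_model.true_area, rel=2e-3)
    assert section.anterior_arc is not None
    i0, i1 = section.anterior_arc
    assert (i1 - i0) % len(section.contour) + 1 >= 10


def test_empty_slice_raises(tibia_model):
    params = ResectionParams(proximal_offset=500.0, posterior_inclination=0.0)
    plane = build_resection_plane(tibia_model, params)
    with pytest.raises(EmptySliceError):
        slice_surface(tibia_model, plane)


def test_multiple_loops_raise():
    a = make_cylinder(radius=10.0)
    b = make_cylinder(radius=10.0)
    mesh_b = b.mesh.copy()
    mesh_b.apply_translation([50.0, 0.0, 0.0])
    double = TibiaModel(
        mesh=trimesh.util.concatenate([a.mesh, mesh_b]),
        apex=a.apex,
        shaft_axis=a.shaft_axis,
        anterior_dir=a.anterior_dir,
        malleolus_margin_points=a.malleolus_margin_points,
        true_area=None,
    )
    plane = build_resection_plane(double, ResectionParams(proximal_offset=20.0))
    with pytest.raises(AmbiguousTopologyError):
        slice_surface(double, plane)


def test_rigid_invariance_of_area_and_arc(tibia_model, config):
    plane = build_resection_plane(tibia_model, config.resection)
    s0 = slice_surface(tibia_model, plane)
    a0 = spline_area(fit_closed_spline(s0.contour)).area
    arc0 = len(s0.anterior_points())

    matrix = trimesh.transformations.rotation_matrix(0.7, [0.3, -0.5, 0.81])
    matrix[:3, 3] = [12.0, -7.0, 3.0]
    moved = _rigid_model(tibia_model, matrix)
    p1 = build_resection_plane(moved, config.resection)
    s1 = slice_surface(moved, p1)
    a1 = spline_area(fit_closed_spline(s1.contour)).area
    assert abs(a1 - a0) / a0 < 1e-4
    assert abs(len(s1.anterior_points()) - arc0) <= 2


def test_mark_malleolus_vertical_border(tibia_model, config):
    plane = build_resection_plane(tibia_model, config.resection)
    section = slice_surface(tibia_model, plane)
    marked = mark_malleolus(section, tibia_model)
    q0, m = marked.forbidden_halfplane()
    # the generator's margin points share one u coordinate: border is u = const
    assert m[0] > 0.99  # medial-pointing normal ~ +u
    u_border = q0 @ m
    assert np.any(marked.contour @ m > u_border)  # bump lies in forbidden side
    assert np.mean(marked.contour @ m > u_border) < 0.15  # but only a sliver


def test_mark_malleolus_all_lateral_is_unconstraining(tibia_model, config):
    """Margin points lateral of the whole contour leave fitting unconstrained."""
    plane = build_resection_plane(tibia_model, config.resection)
    section = slice_surface(tibia_model, plane)
    far = TibiaModel(
        mesh=tibia_model.mesh,
        apex=tibia_model.apex,
        shaft_axis=tibia_model.shaft_axis,
        anterior_dir=tibia_model.anterior_dir,
        malleolus_margin_points=np.array(
            [[100.0, -5.0, 8.0], [100.0, 0.0, 9.0], [100.0, 5.0, 10.0]]
        ),
        true_area=tibia_model.true_area,
    )
    marked = mark_malleolus(section, far)
    q0, m = marked.forbidden_halfplane()
    assert not np.any(marked.contour @ m > q0 @ m)


def test_mark_malleolus_projection_identity(tibia_model, config):
    """Points already in the plane project to their in-plane coordinates."""
    plane = build_resection_plane(
        tibia_model, ResectionParams(proximal_offset=2.0, posterior_inclination=0.0)
    )
    pts = np.array([[3.0, 4.0, plane.origin[2]], [-1.0, 2.0, plane.origin[2]]])
    uv = plane.project(pts)
    assert np.allclose(uv, pts[:, :2] - plane.origin[:2], atol=1e-12)


def test_mark_malleolus_degenerate_raises(tibia_model, config):
    plane = build_resection_plane(tibia_model, config.resection)
    section = slice_surface(tibia_model, plane)
    coincident = TibiaModel(
        mesh=tibia_model.mesh,
        apex=tibia_model.apex,
        shaft_axis=tibia_model.shaft_axis,
        anterior_dir=tibia_model.anterior_dir,
        malleolus_margin_points=np.array(
            [[20.0, 0.0, 9.0], [20.0, 0.0, 9.0], [20.0, 0.0, 9.0]]
        ),
        true_area=tibia_model.true_area,
    )
    with pytest.raises(LandmarkError):
        mark_malleolus(section, coincident)


def test_section_json_roundtrip(tmp_path, tibia_model, config):
    plane = build_resection_plane(tibia_model, config.resection)
    section = mark_malleolus(slice_surface(tibia_model, plane), tibia_model)
    path = tmp_path / "section.json"
    save_section(section, path)
    back = load_section(path)
    assert np.allclose(back.contour, section.contour)
    assert back.anterior_arc == tuple(section.anterior_arc)
    assert np.allclose(back.malleolus_border, section.malleolus_border)
    assert np.allclose(back.plane.normal, section.plane.normal)
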