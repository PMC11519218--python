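"""Footprint library and placement: printed areas, equivariances, selection."""

from dataclasses import replace

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from tibiafit import (
    build_resection_plane,
    fit_closed_spline,
    footprint_library,
    generate_tibia,
    mark_malleolus,
    place_implant,
    select_size,
    slice_surface,
    spline_area,
)
from tibiafit.fitting import placed_outline
from tibiafit.resection import CrossSection, _detect_anterior_arc
from tibiafit.shapes import ensure_ccw, resample_closed

PRINTED_AREAS = {1: 884.40, 2: 1028.60, 3: 1178.50, 4: 1403.60, 5: 1600.80}


def _section_from_polygon(pts: np.ndarray) -> CrossSection:
    contour = resample_closed(ensure_ccw(np.asarray(pts, float)), 256)
    return CrossSection(
        contour=contour, anterior_arc=_detect_anterior_arc(contour), plane=None
    )


def _dilated_section(fp, margin: float) -> CrossSection:
    outer = Polygon(fp.outline).buffer(margin, quad_segs=8)
    return _section_from_polygon(np.asarray(outer.exterior.coords)[:-1])


def _tibia_section(config, target, seed=5, regular=False, **anatomy_kw):
    from tibiafit import SubjectProfile

    params = config.anatomy
    if regular:
        params = replace(params, contour_irregularity=0.0, subject_variability=0.0)
    if anatomy_kw:
        params = replace(params, **anatomy_kw)
    profile = SubjectProfile("T", "female", 50.0, 165.0, 63.7, 23.4)
    model = generate_tibia(profile, target, params, seed=seed)
    plane = build_resection_plane(model, config.resection)
    return mark_malleolus(slice_surface(model, plane), model)


def test_footprint_areas_match_printed_values(library):
    for fp in library:
        measured = spline_area(fit_closed_spline(fp.outline)).area
        assert measured == pytest.approx(PRINTED_AREAS[fp.size_id], rel=5e-3)


def test_footprint_scaling_ratio(library):
    """Isotropic scaling: size-5/size-1 linear factor is sqrt of the area ratio."""
    span = lambda fp: fp.outline[:, 0].max() - fp.outline[:, 0].min()  # noqa: E731
    ratio = span(library[4]) / span(library[0])
    assert ratio == pytest.approx(np.sqrt(1600.80 / 884.40), rel=1e-9)
    assert ratio == pytest.approx(1.3454, abs=1e-4)


def test_footprint_areas_strictly_increasing(library):
    areas = [fp.nominal_area for fp in library]
    assert all(a < b for a, b in zip(areas, areas[1:]))


def test_shield_edge_is_straight(library):
    for fp in library:
        pts = fp.shield_points()
        assert len(pts) >= 3
        assert np.ptp(pts[:, 1]) < 0.05  # collinear within 0.05 mm


def test_dilated_section_perfect_fit(config, library):
    """A size-3 outline dilated by 1 mm hosts size 3 with no overhang and
    near-total cortical contact (every perimeter point is 1 mm from bone)."""
    fp = library[2]
    section = _dilated_section(fp, 1.0)
    result = place_implant(fp, section, config.fitting)
    assert result.feasible
    assert result.overhang_area < 1.0
    assert result.contact_score >= 0.9


def test_oversized_footprint_infeasible(config, library):
    """Size 5 cannot sit on a ~900 mm^2 section: overhang exceeds any slack."""
    section = _dilated_section(library[0], 0.3)  # ~920 mm^2
    result = place_implant(library[4], section, config.fitting)
    assert not result.feasible
    assert result.overhang_area > config.fitting.overhang_tol_mm2


def test_translation_equivariance(config, library):
    fp = library[1]
    section = _dilated_section(fp, 1.2)
    shift = np.array([3.7, -2.2])
    moved = CrossSection(
        contour=section.contour + shift,
        anterior_arc=section.anterior_arc,
        plane=None,
    )
    r0 = place_implant(fp, section, config.fitting)
    r1 = place_implant(fp, moved, config.fitting)
    assert np.allclose(r1.placement.translation - r0.placement.translation, shift, atol=1e-6)
    assert r1.overhang_area == pytest.approx(r0.overhang_area, abs=1e-6)
    assert r1.contact_score == pytest.approx(r0.contact_score, abs=1e-6)


def test_rotation_equivariance(config, library):
    fp = library[1]
    section = _dilated_section(fp, 1.2)
    phi = np.deg2rad(9.0)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    rotated = CrossSection(
        contour=section.contour @ rot.T,
        anterior_arc=section.anterior_arc,
        plane=None,
    )
    r0 = place_implant(fp, section, config.fitting)
    r1 = place_implant(fp, rotated, config.fitting)
    assert r1.placement.rotation == pytest.approx(r0.placement.rotation + 9.0, abs=1e-6)
    assert r1.overhang_area == pytest.approx(r0.overhang_area, abs=1e-5)
    assert r1.contact_score == pytest.approx(r0.contact_score, abs=1e-6)


def test_selected_size_monotone_in_scale(config, library):
    base = _tibia_section(config, 1064.0, regular=True)
    sizes = []
    for s in np.linspace(0.8, 1.4, 7):
        scaled = CrossSection(
            contour=base.contour * s,
            anterior_arc=base.anterior_arc,
            plane=None,
            malleolus_border=None
            if base.malleolus_border is None
            else base.malleolus_border * s,
        )
        fit = select_size(scaled, library, config.fitting)
        sizes.append(fit.size_id if fit.feasible else 0)
    ranked = [s for s in sizes if s]
    assert ranked == sorted(ranked)


def test_female_mean_area_selects_size_2(config, library):
    """At the female mean resection area (1064 mm^2) the modal tray is size 2."""
    section = _tibia_section(config, 1064.0, regular=True)
    fit = select_size(section, library, config.fitting)
    assert fit.feasible
    assert fit.size_id == 2


def test_scaling_congruence_maps_size1_fit_to_size5(config, library):
    small = _dilated_section(library[0], 0.3)
    fit_small = select_size(small, library, config.fitting)
    assert fit_small.size_id == 1
    factor = np.sqrt(1600.80 / 884.40)
    big = CrossSection(
        contour=small.contour * factor,
        anterior_arc=small.anterior_arc,
        plane=None,
    )
    fit_big5 = place_implant(library[4], big, config.fitting)
    assert fit_big5.feasible
    assert select_size(big, library, config.fitting).size_id == 5


def test_overhang_against_point_sampling_oracle(config, library):
    """Reported overhang matches an independent Monte-Carlo area estimate."""
    section = _tibia_section(config, 1290.0, regular=True)
    fp = library[3]  # size 4 on a 1290 mm^2 section: substantial overhang
    result = place_implant(fp, section, config.fitting)
    outline = placed_outline(fp, result.placement)
    fp_poly = Polygon(outline)
    sec_poly = Polygon(section.contour)
    rng = np.random.default_rng(0)
    lo = outline.min(axis=0)
    hi = outline.max(axis=0)
    pts = rng.uniform(lo, hi, size=(2_000_000, 2))
    in_fp = shapely.contains_xy(fp_poly, pts[:, 0], pts[:, 1])
    in_sec = shapely.contains_xy(sec_poly, pts[:, 0], pts[:, 1])
    box_area = np.prod(hi - lo)
    mc_overhang = box_area * np.mean(in_fp & ~in_sec)
    assert result.overhang_area == pytest.approx(mc_overhang, abs=1.0)


def test_malleolus_intrusion_blocks_placement(config, library):
    """A border cutting through the section centre makes every size infeasible
    or forces the tray entirely lateral of it."""
    fp = library[0]
    section = _dilated_section(fp, 6.0)
    u_mid = float(np.median(section.contour[:, 0]))
    border = np.array([[u_mid, -50.0], [u_mid, 50.0]])
    constrained = CrossSection(
        contour=section.contour,
        anterior_arc=section.anterior_arc,
        plane=None,
        malleolus_border=border,
    )
    result = place_implant(fp, constrained, config.fitting)
    if result.feasible:
        assert result.malleolus_intrusion_area <= 1e-6
        outline = placed_outline(fp, result.placement)
        assert outline[:, 0].max() <= u_mid + 0.05
    else:
        assert result.overhang_area + result.malleolus_intrusion_area > 0
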