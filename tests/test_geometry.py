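"""Synthetic vasculature: construction, measurement, IO."""

import numpy as np
import pytest
import trimesh

from aneutreat.geometry import (CASE_I_PARAMS, CASE_II_PARAMS,
                                AneurysmMeasures, BifurcationGeometry,
                                GeometryError, generate_bifurcation_aneurysm,
                                measure_aneurysm, read_geometry,
                                straight_tube_geometry, symmetric_y_geometry,
                                write_geometry)

COARSE = dict(edge_length=0.45)


@pytest.fixture(scope="module", params=["I", "II"])
def case_geometry(request):
    params = CASE_I_PARAMS if request.param == "I" else CASE_II_PARAMS
    geom = generate_bifurcation_aneurysm(**dict(params, **COARSE))
    return params, geom


class TestGenerator:
    def test_watertight_and_valid(self, case_geometry):
        _, geom = case_geometry
        assert geom.is_watertight()
        geom.validate()

    def test_measured_widths_match_request(self, case_geometry):
        params, geom = case_geometry
        m = measure_aneurysm(geom)
        assert m.d_n == pytest.approx(params["neck_width"], rel=0.02)
        assert m.d_a == pytest.approx(params["dome_width"], rel=0.02)
        assert m.d_a >= m.d_n
        assert np.linalg.norm(m.neck_normal) == pytest.approx(1.0)
        # normal points from the neck toward the dome centre
        assert (geom.dome_center - m.neck_origin) @ m.neck_normal > 0

    def test_caps_are_planar_and_labelled(self, case_geometry):
        _, geom = case_geometry
        for cap in geom.caps.values():
            assert len(cap.face_indices) > 0
            verts = geom.surface.vertices[
                np.unique(geom.surface.faces[cap.face_indices])]
            offs = (verts - cap.origin) @ cap.normal
            assert np.abs(offs).max() < 1e-6

    def test_centerlines_end_on_caps(self, case_geometry):
        _, geom = case_geometry
        for i in range(2):
            line = geom.centerlines[f"daughter_{i}"]
            cap = geom.caps[f"outlet_{i}"]
            assert np.allclose(line[-1], cap.origin)
            # daughters start on the parent axis (the bifurcation point)
            assert np.allclose(line[0], geom.centerlines["parent"][-1])

    def test_deterministic_bit_identical(self):
        a = generate_bifurcation_aneurysm(**dict(CASE_II_PARAMS, **COARSE))
        b = generate_bifurcation_aneurysm(**dict(CASE_II_PARAMS, **COARSE))
        assert np.array_equal(a.surface.vertices, b.surface.vertices)
        assert np.array_equal(a.surface.faces, b.surface.faces)

    @pytest.mark.parametrize("bad", [
        dict(dome_width=0.0),
        dict(neck_width=-1.0),
        dict(parent_diameter=0.0),
        dict(neck_width=9.4),              # exceeds the dome width
    ])
    def test_degenerate_parameters_raise(self, bad):
        params = dict(CASE_II_PARAMS, **COARSE)
        params.update(bad)
        with pytest.raises(GeometryError):
            generate_bifurcation_aneurysm(**params)

    def test_infeasible_dome_raises_with_reason(self):
        params = dict(CASE_II_PARAMS, **COARSE,
                      bulb_radius=0.4, neck_width=5.0, dome_width=5.56)
        with pytest.raises(GeometryError, match="infeasible|neck"):
            generate_bifurcation_aneurysm(**params)

    def test_seeded_perturbation_reproducible_and_optional(self):
        base = generate_bifurcation_aneurysm(**dict(CASE_II_PARAMS, **COARSE))
        p1 = generate_bifurcation_aneurysm(
            **dict(CASE_II_PARAMS, **COARSE), perturb=0.02, seed=7)
        p2 = generate_bifurcation_aneurysm(
            **dict(CASE_II_PARAMS, **COARSE), perturb=0.02, seed=7)
        assert np.array_equal(p1.surface.vertices, p2.surface.vertices)
        assert not np.array_equal(p1.surface.vertices, base.surface.vertices)


class TestMeasurement:
    def _dome_only_geometry(self, semi, center_z):
        """Dome over a half-space 'vessel' z<0 (idealized envelope)."""
        mesh = trimesh.creation.icosphere(2)
        return BifurcationGeometry(
            surface=mesh, caps={}, centerlines={},
            parent_diameter=2.0, daughter_diameters=(1.5, 1.5),
            bifurcation_angles=(45.0, 45.0),
            dome_center=np.array([0.0, 0.0, center_z]),
            dome_axes=np.eye(3),
            dome_semi_axes=np.asarray(semi, float),
            anatomy={"placeholder": True},
        )

    def test_sphere_cut_at_equator(self):
        # sphere of diameter 10 intersected at its equator: d_n = d_a = 10
        geom = self._dome_only_geometry([5.0, 5.0, 5.0], center_z=0.0)
        m = measure_aneurysm(geom, envelope_sdf=lambda p: p[:, 2])
        assert m.d_n == pytest.approx(10.0, rel=0.01)
        assert m.d_a == pytest.approx(10.0, rel=0.01)

    def test_hemisphere_on_neck_plane(self):
        # hemispherical dome of radius r sitting on the plane: d_n = d_a = 2r
        r = 3.0
        geom = self._dome_only_geometry([r, r, r], center_z=0.3)
        m = measure_aneurysm(geom, envelope_sdf=lambda p: p[:, 2])
        chord = 2 * np.sqrt(r**2 - 0.3**2)
        assert m.d_n == pytest.approx(chord, rel=0.01)
        assert m.d_a == pytest.approx(2 * r, rel=0.01)
        assert m.neck_normal @ np.array([0, 0, 1.0]) > 0.99

    def test_detached_dome_has_no_neck(self):
        geom = self._dome_only_geometry([2.0, 2.0, 2.0], center_z=5.0)
        with pytest.raises(GeometryError, match="neck"):
            measure_aneurysm(geom, envelope_sdf=lambda p: p[:, 2])


class TestIO:
    def test_vtk_roundtrip_exact(self, tmp_path, case_geometry):
        _, geom = case_geometry
        path = write_geometry(geom, tmp_path / "lumen.vtk")
        back = read_geometry(path)
        assert np.allclose(back.surface.vertices, geom.surface.vertices,
                           atol=1e-6)
        assert len(back.surface.faces) == len(geom.surface.faces)
        assert back.anatomy is not None
        # analytic SDF restored through the sidecar
        pts = geom.surface.vertices[::50]
        assert np.allclose(back.sdf(pts), geom.sdf(pts), atol=1e-9)

    def test_stl_roundtrip_welds_watertight(self, tmp_path):
        sphere = trimesh.creation.icosphere(3)
        # STL stores triangle soups: every vertex is duplicated on write
        path = tmp_path / "soup.stl"
        sphere.export(path)
        (tmp_path / "soup.json").unlink(missing_ok=True)
        back = read_geometry(path)
        assert back.surface.is_watertight
        assert len(back.surface.vertices) == len(sphere.vertices)

    def test_icosphere_connectivity_preserved(self, tmp_path):
        sphere = trimesh.creation.icosphere(2)
        geom = BifurcationGeometry(
            surface=sphere, caps={}, centerlines={},
            parent_diameter=1.0, daughter_diameters=(1.0, 1.0),
            bifurcation_angles=(45.0, 45.0), dome_center=np.zeros(3),
            dome_axes=np.eye(3), dome_semi_axes=np.ones(3), anatomy=None)
        path = write_geometry(geom, tmp_path / "ico.vtk")
        back = read_geometry(path)
        # identical vertex order for the lossless format -> identical faces
        assert np.array_equal(back.surface.faces, sphere.faces)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.stl"
        p.write_text("")
        with pytest.raises(GeometryError, match="empty"):
            read_geometry(p)

    def test_unsupported_format_raises(self, tmp_path, case_geometry):
        _, geom = case_geometry
        with pytest.raises(GeometryError, match="format"):
            write_geometry(geom, tmp_path / "lumen.obj")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(GeometryError):
            read_geometry(tmp_path / "nope.stl")


class TestAnalyticLumens:
    def test_tube_sdf_and_caps(self):
        g = straight_tube_geometry(1.5, 8.0)
        d = g.sdf(np.array([[4.0, 0, 0], [4.0, 2.0, 0], [9.0, 0, 0]]))
        assert d[0] < 0 < d[1] and d[2] > 0
        # cap cut removed when asked for the open vessel
        assert g.sdf(np.array([[9.0, 0, 0]]), with_caps=False)[0] < 0

    def test_symmetric_y_mirror(self):
        g = symmetric_y_geometry()
        pts = np.array([[2.0, 1.0, 0.2], [2.0, -1.0, 0.2]])
        d = g.sdf(pts)
        assert d[0] == pytest.approx(d[1], abs=1e-12)
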