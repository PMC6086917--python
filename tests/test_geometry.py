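import numpy as np
import pytest
from scipy import integrate

from flywind import geometry as geo


class TestPlanform:
    def test_default_area_and_span_exact(self, planform):
        assert planform.area == pytest.approx(2.59)
        assert planform.span == pytest.approx(2.87)
        poly_area = planform.polygon.area
        assert poly_area == pytest.approx(2.59, rel=1e-9)

    def test_mean_chord_is_area_over_span(self, planform):
        assert planform.mean_chord == pytest.approx(2.59 / 2.87)

    def test_outline_is_simple(self, planform):
        assert planform.polygon.is_simple

    def test_non_simple_outline_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]])
        with pytest.raises(geo.GeometryError):
            geo.WingPlanform(outline=bowtie, span=1.0, area=0.5)

    def test_inconsistent_area_rejected(self, planform):
        with pytest.raises(geo.GeometryError, match="area"):
            geo.WingPlanform(outline=planform.outline, span=2.87, area=5.0)


class TestClip:
    def test_default_clip_matches_modified_morphometrics(self, clipped_planform):
        assert clipped_planform.area == pytest.approx(2.09, abs=1e-6)
        assert round(clipped_planform.mean_chord, 2) == 0.73

    def test_removed_fraction_about_20_percent(self, planform, clipped_planform):
        removed = 100.0 * (planform.area - clipped_planform.area) / planform.area
        assert removed == pytest.approx(19.3, abs=1.0)

    def test_clip_never_increases_area_and_conserves_it(self, planform):
        curve = geo.default_clip_curve(planform, target_area=2.2)
        kept = geo.clip_trailing_edge(planform, curve)
        assert kept.area <= planform.area
        # S_kept + S_removed = S_original (removed = original - kept by
        # construction of the straight-line split)
        xc = curve[0, 0]
        from shapely.geometry import Polygon

        poly = planform.polygon
        xmin, ymin, xmax, ymax = poly.bounds
        removed_half = Polygon(
            [(xc, ymin - 1), (xmax + 1, ymin - 1), (xmax + 1, ymax + 1), (xc, ymax + 1)]
        )
        removed = poly.intersection(removed_half).area
        assert kept.area + removed == pytest.approx(planform.area, rel=1e-9)

    def test_span_unchanged(self, planform, clipped_planform):
        assert clipped_planform.span == planform.span
        y = clipped_planform.outline[:, 1]
        assert y.max() - y.min() == pytest.approx(planform.span, rel=1e-6)

    def test_degenerate_clip_returns_planform_unchanged(self, planform):
        xmax = planform.outline[:, 0].max()
        curve = np.array([[xmax + 0.5, -1.0], [xmax + 0.5, 4.0]])
        out = geo.clip_trailing_edge(planform, curve)
        assert out is planform

    def test_bad_crossing_count_raises(self, planform):
        # a short segment ending inside the outline crosses only once
        curve = np.array([[0.2, -1.0], [0.2, 0.8]])
        with pytest.raises(geo.ClippingError):
            geo.clip_trailing_edge(planform, curve)

    @pytest.mark.parametrize("target", [2.0, 2.2, 2.4])
    def test_clip_area_targets_hit(self, planform, target):
        curve = geo.default_clip_curve(planform, target_area=target)
        kept = geo.clip_trailing_edge(planform, curve)
        assert kept.area == pytest.approx(target, rel=1e-4)


class TestFlyGeometry:
    def test_wing_mesh_area_matches_planform(self, fly, planform):
        assert fly.wing_left.area == pytest.approx(planform.area, rel=0.01)

    def test_wings_mirror_vertex_for_vertex(self, fly):
        mirrored = fly.wing_left.mirrored(axis=1)
        assert np.array_equal(mirrored.vertices, fly.wing_right.vertices)

    def test_body_watertight(self, fly):
        assert fly.body.is_closed()

    def test_wing_open_surface(self, fly):
        assert not fly.wing_left.is_closed()

    def test_no_degenerate_faces(self, fly):
        for mesh in fly.parts().values():
            assert mesh.face_areas().min() > 0

    def test_resolution_too_coarse_refused(self, planform):
        with pytest.raises(geo.GeometryError, match="coarse"):
            geo.make_fly_geometry(planform, resolution=4)

    def test_ellipsoid_area_matches_quadrature_oracle(self):
        # oracle: dense quadrature of the analytic ellipsoid surface area
        a, b, c = 1.25, 0.45, 0.45

        def integrand(phi, th):
            # |r_theta x r_phi| for x=a cos(th), y=b sin(th) cos(phi),
            # z=c sin(th) sin(phi)
            st, ct = np.sin(th), np.cos(th)
            sp, cp = np.sin(phi), np.cos(phi)
            rx = np.array([-a * st, b * ct * cp, c * ct * sp])
            rp = np.array([0.0, -b * st * sp, c * st * cp])
            return np.linalg.norm(np.cross(rx, rp))

        area_quad, _ = integrate.dblquad(
            integrand, 1e-9, np.pi - 1e-9, 0, 2 * np.pi, epsabs=1e-8
        )
        mesh = geo._ellipsoid_mesh((a, b, c), n_lat=48, n_lon=96)
        assert mesh.area == pytest.approx(area_quad, rel=0.02)
        # Thomsen's approximation agrees with the quadrature oracle
        assert geo.ellipsoid_area_thomsen(a, b, c) == pytest.approx(area_quad, rel=0.011)

    def test_wing_area_converges_monotonically(self, planform):
        errs = []
        for res in (8, 16, 32):
            f = geo.make_fly_geometry(planform, resolution=res)
            errs.append(abs(f.wing_left.area - planform.area) / planform.area)
        assert errs[0] > errs[1] > errs[2]

    def test_antenna_landmark_on_body_surface(self, fly):
        ant = fly.landmarks["antenna"]
        d = np.linalg.norm(fly.body.vertices - ant, axis=1).min()
        # within one local element size
        elem = np.sqrt(fly.body.face_areas().mean())
        assert d <= elem

    def test_antenna_on_sagittal_plane(self, fly):
        assert fly.landmarks["antenna"][1] == pytest.approx(0.0, abs=1e-12)


class TestSagittalSection:
    def test_closed_and_head_up_front(self):
        poly = geo.sagittal_body_section()
        assert poly.shape[1] == 2
        # head (most negative x) is above the centroid for a 45-degree incline
        head = poly[np.argmin(poly[:, 0])]
        assert head[1] > 0
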