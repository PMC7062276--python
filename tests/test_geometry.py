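"""Sectioning stereology: closed forms, Monte Carlo, truncation, particles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from mcpsize import geometry as g


class TestSectionDiameterAt:
    @pytest.mark.parametrize(
        "r, d, expected",
        [
            (0.0, 100.0, 100.0),       # equatorial section equals the diameter
            (50.0, 100.0, 0.0),        # tangent plane
            (25.0, 100.0, 100.0 * math.sqrt(3) / 2),  # closed form
        ],
    )
    def test_closed_form(self, r, d, expected):
        assert g.section_diameter_at(r, d) == pytest.approx(expected, abs=1e-9)

    def test_decreasing_in_r(self):
        r = np.linspace(0, 50, 200)
        d = g.section_diameter_at(r, 100.0)
        assert np.all(np.diff(d) < 0)

    @pytest.mark.parametrize("r, d", [(-1, 100), (51, 100), (0, 0), (0, -5)])
    def test_domain_errors(self, r, d):
        with pytest.raises(g.GeometryError):
            g.section_diameter_at(r, d)


class TestExpectedSectionDiameter:
    def test_volume_weighted_unit_sphere(self):
        model = g.SectioningModel(1.0)
        assert g.expected_section_diameter(model) == pytest.approx(3 * math.pi / 16, rel=1e-12)

    def test_linearity(self):
        assert g.expected_section_diameter(g.SectioningModel(140.0)) == pytest.approx(
            140.0 * 3 * math.pi / 16, rel=1e-12
        )

    def test_uniform_plane_matches_brute_force(self):
        """π/4 closed form vs direct Monte Carlo with uniform plane offsets."""
        rng = np.random.default_rng(7)
        r = 0.5 * rng.random(10**6)
        mc = float(np.mean(2 * np.sqrt(0.25 - r**2)))
        model = g.SectioningModel(1.0, g.UNIFORM_PLANE)
        assert g.expected_section_diameter(model) == pytest.approx(math.pi / 4, rel=1e-12)
        assert mc == pytest.approx(math.pi / 4, abs=3 * 0.2 / 1000)

    def test_analytic_branch_unavailable_with_truncation(self):
        with pytest.raises(g.AnalyticUnavailableError):
            g.expected_section_diameter(g.SectioningModel(100.0, detection_limit=10.0))

    def test_scheme_ordering(self):
        vw = g.expected_section_diameter(g.SectioningModel(138.0))
        up = g.expected_section_diameter(g.SectioningModel(138.0, g.UNIFORM_PLANE))
        assert vw < up < 138.0


class TestUnderestimationPercent:
    def test_volume_weighted_is_about_41(self):
        pct = g.underestimation_percent(g.SectioningModel(1.0))
        assert pct == pytest.approx(100 * (1 - 3 * math.pi / 16), rel=1e-12)
        assert round(pct) == 41

    def test_uniform_plane_is_about_21(self):
        pct = g.underestimation_percent(g.SectioningModel(1.0, g.UNIFORM_PLANE))
        assert pct == pytest.approx(100 * (1 - math.pi / 4), rel=1e-12)

    @given(st_.floats(min_value=1.0, max_value=1e4))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, d):
        assert g.underestimation_percent(g.SectioningModel(d)) == pytest.approx(
            g.underestimation_percent(g.SectioningModel(102.0)), rel=1e-12
        )


class TestMcSectionSphere:
    @pytest.mark.parametrize("scheme", g.SCHEMES)
    def test_mean_matches_closed_form_within_3se(self, scheme):
        model = g.SectioningModel(100.0, scheme)
        d = g.mc_section_sphere(model, 10**6, seed=11)
        expected = g.expected_section_diameter(model)
        se = d.std(ddof=1) / math.sqrt(d.size)
        assert abs(d.mean() - expected) < 3 * se

    def test_detection_limit_raises_mean(self):
        base = g.mc_section_sphere(g.SectioningModel(100.0), 10**5, seed=5)
        trunc = g.mc_section_sphere(
            g.SectioningModel(100.0, detection_limit=40.0), 10**5, seed=5
        )
        assert trunc.mean() > base.mean()
        assert trunc.min() >= 40.0

    def test_everything_truncated_is_empty_signal(self):
        with pytest.raises(g.GeometryError):
            g.SectioningModel(100.0, detection_limit=100.0)  # invariant: limit < d
        with pytest.raises(g.EmptySectionError):
            g.mc_section_sphere(g.SectioningModel(100.0, detection_limit=99.999999), 3, seed=0)

    def test_reproducible_and_n_validation(self):
        model = g.SectioningModel(100.0)
        a = g.mc_section_sphere(model, 100, seed=3)
        b = g.mc_section_sphere(model, 100, seed=3)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(g.GeometryError):
            g.mc_section_sphere(model, 0)

    def test_sectioning_inflates_variance_beyond_cryo_spread(self):
        """Apparent SD from sectioning a 138±21 population exceeds 21 nm."""
        rng = np.random.default_rng(17)
        true_d = rng.normal(138, 21, 10**5)
        true_d = true_d[true_d > 0]
        r = (true_d / 2) * np.cbrt(rng.random(true_d.size))
        apparent = 2 * np.sqrt((true_d / 2) ** 2 - r**2)
        assert apparent.std(ddof=1) > 21.0
        # and the CV exceeds that of a degenerate true-size distribution (0)
        assert apparent.std(ddof=1) / apparent.mean() > 0.2


class TestTruncatedExpectation:
    def test_monotone_and_spans_range(self):
        model = lambda L: g.SectioningModel(100.0, detection_limit=L)
        limits = [0.0, 10.0, 30.0, 60.0, 90.0, 99.0]
        means = [g.truncated_expected_diameter(model(L)) for L in limits]
        assert means[0] == pytest.approx(100 * 3 * math.pi / 16, rel=1e-6)
        assert all(a < b for a, b in zip(means, means[1:]))
        assert means[-1] < 100.0


class TestFitDetectionLimit:
    def test_zero_truncation_at_base_ratio(self):
        model = g.SectioningModel(138.0)
        assert g.fit_detection_limit(3 * math.pi / 16, model) == 0.0

    def test_self_consistency_at_observed_ratio(self):
        """Threshold explaining the 28% observed (vs 41% predicted) shortfall."""
        model = g.SectioningModel(138.0)
        ratio = 99.0 / 138.0
        limit = g.fit_detection_limit(ratio, model)
        assert limit > 0
        back = g.truncated_expected_diameter(
            g.SectioningModel(138.0, detection_limit=limit)
        )
        assert back / 138.0 == pytest.approx(ratio, abs=1e-6)

    def test_population_fit_self_consistency(self):
        model = g.SectioningModel(138.0)
        limit = g.fit_detection_limit(99.0 / 138.0, model, size_sd=21.0)
        back = g.truncated_expected_diameter(
            g.SectioningModel(138.0, detection_limit=limit), size_sd=21.0
        )
        assert back == pytest.approx(99.0, abs=1e-4)

    def test_extreme_ratio_approaches_half_diameter(self):
        model = g.SectioningModel(100.0)
        limit = g.fit_detection_limit(0.99, model)
        assert limit > 90.0

    def test_unattainable_ratio_raises(self):
        model = g.SectioningModel(100.0)
        with pytest.raises(g.NoSolutionError):
            g.fit_detection_limit(0.3, model)  # below 3π/16
        with pytest.raises(g.NoSolutionError):
            g.fit_detection_limit(1.2, model)


class TestConvexParticle:
    def test_zero_irregularity_is_regular_icosahedron(self):
        p = g.make_irregular_particle(140.0, 0.0)
        assert len(p.vertices) == 12
        assert p.max_feret == pytest.approx(140.0, rel=1e-9)
        radii = np.linalg.norm(p.vertices - p.centroid, axis=1)
        assert radii.std() < 1e-9 * radii.mean()

    def test_perturbed_particle_postconditions(self):
        p = g.make_irregular_particle(140.0, 0.15, seed=1)
        assert p.max_feret == pytest.approx(140.0, rel=1e-9)
        # centroid of the re-centred hull sits at the origin
        assert np.linalg.norm(p.centroid) < 1e-9 * 140
        q = g.make_irregular_particle(140.0, 0.15, seed=1)
        np.testing.assert_allclose(p.vertices, q.vertices)

    def test_irregularity_bounds(self):
        with pytest.raises(g.GeometryError):
            g.make_irregular_particle(140.0, 0.31)
        with pytest.raises(g.GeometryError):
            g.make_irregular_particle(-1.0, 0.1)

    def test_degenerate_vertices_rejected(self):
        flat = np.column_stack([np.random.default_rng(0).random((6, 2)), np.zeros(6)])
        with pytest.raises(g.DegenerateGeometryError):
            g.ConvexParticle(flat)


class TestSectionParticle:
    def test_unit_cube_axis_plane_gives_face_diagonal(self):
        corners = np.array(
            [[x, y, z] for x in (-0.5, 0.5) for y in (-0.5, 0.5) for z in (-0.5, 0.5)]
        )
        cube = g.ConvexParticle(corners)
        sample = g.section_particle(cube, [0, 0, 1], 0.0)
        assert sample.section_feret_max == pytest.approx(math.sqrt(2), rel=1e-9)

    def test_plane_missing_particle_gives_zero(self):
        p = g.make_irregular_particle(100.0, 0.0)
        sample = g.section_particle(p, [1, 0, 0], p.circumscribed_radius * 1.01)
        assert sample.section_feret_max == 0.0

    def test_equatorial_cut_near_max_feret(self):
        p = g.make_irregular_particle(100.0, 0.0)
        # cut through the centroid perpendicular to a vertex direction
        normal = p.vertices[0] - p.centroid
        sample = g.section_particle(p, normal, 0.0)
        assert sample.section_feret_max > 0.7 * p.max_feret

    def test_zero_normal_rejected(self):
        p = g.make_irregular_particle(100.0, 0.0)
        with pytest.raises(g.GeometryError):
            g.section_particle(p, [0, 0, 0], 0.0)

    def test_section_never_exceeds_particle_feret(self):
        p = g.make_irregular_particle(120.0, 0.2, seed=4)
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.normal(size=3)
            off = rng.uniform(0, p.circumscribed_radius)
            s = g.section_particle(p, n, off)
            assert s.section_feret_max <= p.max_feret * (1 + 1e-9)


class TestMcSectionParticle:
    def test_fine_sphere_tessellation_matches_sphere_theory(self):
        """A ~1000-vertex sphere tessellation reproduces the 3π/16 ratio."""
        i = np.arange(1000)
        golden = math.pi * (3 - math.sqrt(5))
        z = 1 - 2 * (i + 0.5) / 1000
        rho = np.sqrt(1 - z**2)
        verts = np.column_stack([rho * np.cos(golden * i), rho * np.sin(golden * i), z])
        sphere = g.ConvexParticle(verts * 70.0)
        sections = g.mc_section_particle(sphere, n=20000, seed=2)
        ratio = sections.mean() / sphere.max_feret
        assert 0.55 < ratio < 0.62

    def test_icosahedron_ratio_below_sphere_ratio(self):
        """Angular shapes with vertex-defined Feret fall below 3π/16."""
        ico = g.make_irregular_particle(140.0, 0.0)
        sections = g.mc_section_particle(ico, n=10000, seed=2)
        assert sections.mean() / ico.max_feret < 3 * math.pi / 16

    def test_detection_limit_raises_filtered_mean(self):
        p = g.make_irregular_particle(140.0, 0.0)
        base = g.mc_section_particle(p, n=4000, seed=9)
        trunc = g.mc_section_particle(p, n=4000, seed=9, detection_limit=40.0)
        assert trunc.mean() > base.mean()

    def test_n_validation(self):
        p = g.make_irregular_particle(140.0, 0.0)
        with pytest.raises(g.GeometryError):
            g.mc_section_particle(p, n=0)
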