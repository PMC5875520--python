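"""Monte Carlo transport: geometry layout, ray-tracing oracles,
closed-form limits and estimator contracts."""

import dataclasses
import math

import numpy as np
import pytest

from kermastack import (
    CapsuleSpec,
    MaterialSpec,
    UnitGeometry,
    ValidationError,
    attenuation_correction,
    distance_correction,
)
from kermastack.mc import (
    AxialRegion,
    TransportConfig,
    build_geometry,
    estimate_relative_kerma,
    mc_vs_analytic_table,
    optical_depth,
    sample_emission,
)


def degenerate_capsule(mu_rho_active=0.0527, mu_rho_shell=0.0535,
                       rho_active=5.88, rho_shell=7.85):
    """A point-like capsule: zero active height and radius, zero shells,
    keeping the reference pitch so sources still recede 2.72 cm per slot."""
    return CapsuleSpec(
        active_material=MaterialSpec("active", mu_rho_active, rho_active),
        shell_material=MaterialSpec("shell", mu_rho_shell, rho_shell),
        active_height=0.0, shell_front_height=0.0, shell_back_height=0.0,
        capsule_pitch=2.72, active_radius=0.0)


class TestBuildGeometry:
    def test_reference_active_column_span(self, capsule, geometry):
        geo = build_geometry(capsule, geometry, n_front=0)
        assert geo.emitter.z0 == pytest.approx(0.12)
        assert geo.emitter.z1 == pytest.approx(2.12)

    def test_front_sources_shift_emitter_by_pitch(self, capsule, geometry):
        ref = build_geometry(capsule, geometry, 0)
        geo = build_geometry(capsule, geometry, 1)
        assert geo.emitter.z0 - ref.emitter.z0 == pytest.approx(2.72)
        # three capsules in total: the front one plus the emitter
        assert len(geo.regions) == 6

    def test_abutting_pitch_is_valid(self, capsule, geometry):
        snug = dataclasses.replace(capsule, capsule_pitch=2.61)
        geo = build_geometry(snug, geometry, 2)
        assert geo.emitter.z0 == pytest.approx(2 * 2.61 + 0.12)

    def test_overlapping_layers_rejected_with_lengths(self, capsule, geometry):
        bad = dataclasses.replace(capsule, capsule_pitch=2.0)
        with pytest.raises(ValidationError, match="pitch"):
            build_geometry(bad, geometry, 1)

    def test_focus_is_at_nominal_distance_from_reference_midpoint(
            self, capsule, geometry):
        geo = build_geometry(capsule, geometry, 0)
        mid = 0.12 + 1.0
        assert mid - geo.focus_z == pytest.approx(40.1)


class TestSampleEmission:
    def test_degenerate_region_yields_single_point(self):
        region = AxialRegion("pt", 1.5, 1.5, 0.0, 0.0)
        rng = np.random.default_rng(0)
        pts = sample_emission(rng, region, size=10)
        assert np.allclose(pts, [0.0, 0.0, 1.5])

    def test_axial_mean_matches_uniform_moments(self):
        region = AxialRegion("act", 0.12, 2.12, 0.05, 0.0)
        rng = np.random.default_rng(42)
        n = 100_000
        pts = sample_emission(rng, region, size=n)
        height = region.z1 - region.z0
        sigma = height / math.sqrt(12.0)
        assert abs(pts[:, 2].mean() - 1.12) < 4.0 * sigma / math.sqrt(n)
        assert np.all(pts[:, 0] ** 2 + pts[:, 1] ** 2 <= region.radius ** 2)

    def test_same_seed_same_stream(self):
        region = AxialRegion("act", 0.0, 2.0, 0.05, 0.0)
        a = sample_emission(np.random.default_rng(7), region, 100)
        b = sample_emission(np.random.default_rng(7), region, 100)
        assert np.array_equal(a, b)


class TestOpticalDepth:
    def test_vacuum_geometry(self, capsule, geometry):
        transparent = dataclasses.replace(
            capsule,
            active_material=MaterialSpec("v", 0.0, 1.0),
            shell_material=MaterialSpec("v", 0.0, 1.0))
        geo = build_geometry(transparent, geometry, 2)
        tau = optical_depth([0, 0, geo.emitter.z0 + 1.0],
                            [0, 0, geo.focus_z], geo)
        assert tau == 0.0

    def test_axial_ray_through_one_capsule(self, capsule, geometry):
        """An axial ray through one full capsule accumulates
        mu_src*h_src + mu_shell*h_shell, and exp(-tau) reproduces the
        single-capsule attenuation factor."""
        geo = build_geometry(capsule, geometry, 1)
        # start in the air gap behind capsule 0, so exactly one full
        # capsule (front shell + active + back shell) lies on the ray
        tau = optical_depth([0, 0, 2.65], [0, 0, geo.focus_z], geo)
        expected = 0.0527 * 5.88 * 2.0 + 0.0535 * 7.85 * 0.61
        assert tau == pytest.approx(expected, rel=1e-12)
        assert round(math.exp(-tau), 3) == 0.416

    def test_self_attenuation_excluded_by_default(self, capsule, geometry):
        """From the back of the emitter's own active column, the default
        depth sees only the capsule's front shell; include_self adds the
        full 2 cm of pellet column."""
        geo = build_geometry(capsule, geometry, 0)
        point = [0, 0, geo.emitter.z1 - 1e-9]
        own_shell = 0.0535 * 7.85 * 0.12
        assert optical_depth(point, [0, 0, geo.focus_z], geo) == \
            pytest.approx(own_shell, rel=1e-6)
        with_self = optical_depth(point, [0, 0, geo.focus_z], geo,
                                  include_self=True)
        assert with_self == pytest.approx(own_shell + 0.0527 * 5.88 * 2.0,
                                          rel=1e-6)

    def test_oblique_chord_matches_analytic_cylinder_oracle(self):
        """A tilted ray through a finite cylinder: chord from the quadratic
        for an infinite cylinder clipped by the end planes."""
        mu = 0.7
        region = AxialRegion("cyl", 0.0, 1.0, 0.3, mu)
        geo_like = type("G", (), {"regions": (region,), "emitter": None})
        start = np.array([-1.0, 0.1, -1.0])
        end = np.array([1.0, 0.1, 2.0])

        # independent fine-sampling oracle along the segment
        ts = np.linspace(0.0, 1.0, 2_000_001)
        pts = start[None, :] + ts[:, None] * (end - start)[None, :]
        inside = ((pts[:, 0] ** 2 + pts[:, 1] ** 2 <= 0.3 ** 2)
                  & (pts[:, 2] >= 0.0) & (pts[:, 2] <= 1.0))
        chord = inside.mean() * np.linalg.norm(end - start)

        tau = optical_depth(start, end, geo_like)
        assert tau == pytest.approx(mu * chord, rel=1e-4)

    def test_ray_missing_all_regions(self):
        region = AxialRegion("cyl", 0.0, 1.0, 0.3, 0.9)
        geo_like = type("G", (), {"regions": (region,), "emitter": None})
        tau = optical_depth([5.0, 5.0, 0.5], [5.0, 5.0, -3.0], geo_like)
        assert tau == 0.0


class TestEstimator:
    def test_determinism(self, capsule, geometry):
        cfg = TransportConfig(capsule=capsule, geometry=geometry,
                              histories=5_000, seed=123)
        a = estimate_relative_kerma(cfg, 2)
        b = estimate_relative_kerma(cfg, 2)
        assert a == b

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_vacuum_point_source_recovers_inverse_square(self, n):
        cap = degenerate_capsule(mu_rho_active=0.0, mu_rho_shell=0.0)
        geo = UnitGeometry(40.1)
        cfg = TransportConfig(capsule=cap, geometry=geo, histories=2_000,
                              seed=5)
        tally = estimate_relative_kerma(cfg, n)
        expected = (40.1 / (40.1 + n * 2.72)) ** 2
        assert abs(tally.mean - expected) <= max(3 * tally.standard_error,
                                                 1e-12)

    @pytest.mark.parametrize("n", [1, 3])
    def test_point_source_recovers_closed_form_product(self, n):
        """With the source collapsed to a point the estimator must equal
        the attenuation x inverse-square product for the same capsule."""
        cap = degenerate_capsule()
        # give the shells finite thickness so attenuation is non-trivial
        cap = dataclasses.replace(cap, shell_front_height=0.12,
                                  shell_back_height=0.49, active_height=0.0)
        geo = UnitGeometry(40.1)
        cfg = TransportConfig(capsule=cap, geometry=geo, histories=2_000,
                              seed=11)
        tally = estimate_relative_kerma(cfg, n)
        expected = (attenuation_correction(n, cap)
                    * distance_correction(n, cap, geo))
        assert abs(tally.mean - expected) <= max(3 * tally.standard_error,
                                                 1e-9)

    def test_standard_error_scales_inverse_root(self, capsule, geometry):
        cfg_small = TransportConfig(capsule=capsule, geometry=geometry,
                                    histories=10_000, seed=3)
        cfg_big = TransportConfig(capsule=capsule, geometry=geometry,
                                  histories=1_000_000, seed=3)
        se_small = estimate_relative_kerma(cfg_small, 1).standard_error
        se_big = estimate_relative_kerma(cfg_big, 1).standard_error
        ratio = se_small / se_big
        assert 10 / math.sqrt(10) < ratio < 10 * math.sqrt(10)

    def test_extended_source_at_or_below_analytic(self, capsule, geometry):
        """Off-axis and oblique rays see more material and a longer path,
        so the extended-source estimate cannot exceed the on-axis
        point-source closed form."""
        cfg = TransportConfig(capsule=capsule, geometry=geometry,
                              histories=100_000, seed=17)
        for n in (1, 2, 3):
            tally = estimate_relative_kerma(cfg, n)
            analytic = (attenuation_correction(n, capsule)
                        * distance_correction(n, capsule, geometry))
            assert tally.mean <= analytic + 3 * tally.standard_error

    def test_invalid_configs_rejected(self, capsule, geometry):
        with pytest.raises(ValidationError):
            TransportConfig(capsule=capsule, geometry=geometry, histories=0)
        with pytest.raises(ValidationError):
            estimate_relative_kerma(
                TransportConfig(capsule=capsule, geometry=UnitGeometry(0.5),
                                histories=10), 0)


class TestComparisonTable:
    def test_reference_position_is_exact(self, capsule, geometry):
        cfg = TransportConfig(capsule=capsule, geometry=geometry,
                              histories=2_000, seed=1)
        report = mc_vs_analytic_table(cfg, [0])
        row = report.rows[0]
        assert row.analytic == 1.0
        assert row.mc_mean == pytest.approx(1.0, abs=1e-12)
        assert report.max_difference_pp == pytest.approx(0.0, abs=1e-10)

    def test_transparent_materials_leave_geometry_only(self, geometry):
        cap = degenerate_capsule(mu_rho_active=0.0, mu_rho_shell=0.0)
        cap = dataclasses.replace(cap, active_height=2.0, active_radius=0.05,
                                  shell_front_height=0.12,
                                  shell_back_height=0.49)
        cfg = TransportConfig(capsule=cap, geometry=geometry,
                              histories=50_000, seed=9)
        report = mc_vs_analytic_table(cfg, [1, 2])
        for row in report.rows:
            geo_only = distance_correction(row.n_front, cap, geometry)
            assert row.mc_mean == pytest.approx(geo_only, abs=5e-4)

    def test_fixture_agreement_within_published_spread(self, capsule,
                                                       geometry):
        cfg = TransportConfig(capsule=capsule, geometry=geometry,
                              histories=100_000, seed=2)
        report = mc_vs_analytic_table(cfg, [1, 2, 3])
        assert report.max_difference_pp <= 2.4

    def test_empty_ns_rejected(self, capsule, geometry):
        cfg = TransportConfig(capsule=capsule, geometry=geometry,
                              histories=10, seed=0)
        with pytest.raises(ValidationError):
            mc_vs_analytic_table(cfg, [])
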