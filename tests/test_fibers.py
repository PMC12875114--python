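"""Cylinder fitting, fiber segmentation, and DNA-density arithmetic."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chromaflux import (
    DegenerateGeometryError,
    dna_density,
    fiber_summary,
    fit_cylinder,
    segment_fiber,
)
from chromaflux.fibers import FiberSegment
from chromaflux.simgen import AcquisitionParams, SyntheticScene, make_fiber, simulate_localizations

from conftest import NOISE_SIGMA, surface_cylinder


class TestFitCylinder:
    def test_exact_surface_recovers_radius(self, rng):
        pts = surface_cylinder(rng, 5.73, 50.0, 20)
        rot = Rotation.random(random_state=8).as_matrix()
        m = fit_cylinder(pts @ rot.T + [30, -10, 5])
        assert m.radius == pytest.approx(5.73, abs=1e-6)
        assert m.rms_radial_residual < 1e-9
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_equivariance(self, rng):
        pts = surface_cylinder(rng, 8.0, 40.0, 50, NOISE_SIGMA)
        m0 = fit_cylinder(pts)
        rot = Rotation.random(random_state=2).as_matrix()
        shift = np.array([12.0, -7.0, 80.0])
        m1 = fit_cylinder(pts @ rot.T + shift)
        assert m1.radius == pytest.approx(m0.radius, rel=1e-6)
        assert m1.length == pytest.approx(m0.length, rel=1e-6)
        assert m1.rms_radial_residual == pytest.approx(
            m0.rms_radial_residual, rel=1e-5, abs=1e-9
        )

    def test_axis_sign_convention(self, rng):
        pts = surface_cylinder(rng, 5.0, 30.0, 30)
        assert fit_cylinder(pts).axis[2] > 0

    def test_noisy_nucleosome_scale_recovery(self):
        rng = np.random.default_rng(21)
        diams = [
            fit_cylinder(surface_cylinder(rng, 5.73, 2.35, 20, NOISE_SIGMA)).diameter
            for _ in range(100)
        ]
        assert abs(np.mean(diams) - 11.46) < 0.5

    def test_uniform_ball_poor_fit(self, rng):
        v = rng.normal(size=(500, 3))
        pts = 20.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        pts *= rng.uniform(0, 1, 500)[:, None] ** (1 / 3)
        m = fit_cylinder(pts)
        assert m.rms_radial_residual > 2.0
        assert m.r_squared < 0.95  # far from the exact-surface value of 1

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            fit_cylinder(pts)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_cylinder(np.zeros((4, 3)))


class TestSegmentFiber:
    def test_constant_diameter_merges_to_single_segment(self):
        rng = np.random.default_rng(6)
        scene = SyntheticScene(box=((0, 600),) * 3)
        fib = make_fiber(200, [(200, 35.0)], 0.0, rng, start=(200, 300, 300), scene=scene)
        scene.fibers.append(fib)
        table = simulate_localizations(scene, AcquisitionParams(rng_seed=1))
        fiber = segment_fiber(table.coords())
        assert len(fiber.segments) == 1
        assert fiber.segments[0].diameter == pytest.approx(35.0, abs=2.0)
        assert fiber.total_length == pytest.approx(200.0, abs=10.0)

    def test_two_diameter_fiber_recovers_both(self):
        rng = np.random.default_rng(8)
        scene = SyntheticScene(box=((0, 600),) * 3)
        fib = make_fiber(
            200, [(100, 20.0), (100, 50.0)], 0.0, rng,
            target_density_mbp_um3=80.0, start=(200, 300, 300), scene=scene,
        )
        scene.fibers.append(fib)
        table = simulate_localizations(scene, AcquisitionParams(rng_seed=1))
        fiber = segment_fiber(table.coords())
        assert len(fiber.segments) == 2
        assert sorted(s.diameter for s in fiber.segments) == pytest.approx(
            [20.0, 50.0], abs=3.0
        )

    def test_short_cluster_single_window(self, rng):
        pts = surface_cylinder(rng, 6.0, 8.0, 40, NOISE_SIGMA)
        fiber = segment_fiber(pts, segment_window_nm=25.0)
        whole = fit_cylinder(pts, fixed_axis=fiber.segments[0].cylinder.axis)
        assert len(fiber.segments) == 1
        assert fiber.segments[0].diameter == pytest.approx(whole.diameter, rel=0.05)

    def test_every_point_in_exactly_one_segment(self, rng):
        pts = surface_cylinder(rng, 10.0, 80.0, 300, NOISE_SIGMA)
        fiber = segment_fiber(pts)
        all_idx = np.concatenate([s.member_indices for s in fiber.segments])
        assert sorted(all_idx) == list(range(len(pts)))

    def test_unsegmentable_cluster_flagged(self):
        pts = np.column_stack([np.arange(30.0), np.zeros(30), np.zeros(30)])
        fiber = segment_fiber(pts)
        assert fiber.unsegmentable
        assert fiber.segments == []


class TestDnaDensity:
    @staticmethod
    def _segment(n, radius, length):
        from chromaflux.fibers import CylinderModel

        cyl = CylinderModel(
            base_point=np.zeros(3), axis=np.array([0, 0, 1.0]), radius=radius,
            length=length, rms_radial_residual=0.0, r_squared=1.0, n_points=n,
        )
        return FiberSegment(cyl, np.arange(n))

    def test_hand_arithmetic_example(self):
        # 100 probes x 12 bp / 0.8 = 1500 bp in pi * 15^2 * 100 nm^3
        seg = self._segment(100, 15.0, 100.0)
        assert dna_density(seg, 12, 0.8) == pytest.approx(21.2207, abs=0.001)

    def test_density_linear_in_count(self):
        d1 = dna_density(self._segment(50, 15.0, 100.0))
        d2 = dna_density(self._segment(100, 15.0, 100.0))
        assert d2 == pytest.approx(2 * d1)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            dna_density(self._segment(0, 15.0, 100.0))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="density undefined"):
            dna_density(self._segment(10, 15.0, 0.0))

    def test_generator_density_recovered_within_20_percent(self):
        # longer fibers at low density keep per-fiber probe counts comparable
        rng = np.random.default_rng(3)
        for density, length in ((8.87, 900.0), (34.0, 300.0), (69.87, 300.0)):
            scene = SyntheticScene(box=((0, 2000),) * 3)
            fib = make_fiber(
                length, [(length, 35.0)], 0.0, rng,
                target_density_mbp_um3=density, start=(100, 1000, 1000), scene=scene,
            )
            scene.fibers.append(fib)
            table = simulate_localizations(scene, AcquisitionParams(rng_seed=5))
            pts = table.coords()
            seg = FiberSegment(fit_cylinder(pts), np.arange(len(pts)))
            assert dna_density(seg) == pytest.approx(density, rel=0.20)


class TestFiberSummary:
    def test_empty(self):
        s = fiber_summary([])
        assert len(s["lengths"]) == 0
        assert np.isnan(s["modal_diameter_nm"])

    def test_known_lengths_reported(self, rng):
        fibers = []
        for k, length in enumerate((60.0, 120.0)):
            pts = surface_cylinder(rng, 12.0, length / 2, 200, NOISE_SIGMA)
            fibers.append(segment_fiber(pts, cluster_id=k))
        s = fiber_summary(fibers)
        np.testing.assert_allclose(
            s["lengths"]["total_length_nm"], [60.0, 120.0], rtol=0.1
        )

    def test_modal_diameter_bin_contains_mode(self, rng):
        fibers = []
        for _ in range(8):
            pts = surface_cylinder(rng, 17.5, 40.0, 250, NOISE_SIGMA)
            fibers.append(segment_fiber(pts))
        for _ in range(2):
            pts = surface_cylinder(rng, 10.0, 40.0, 250, NOISE_SIGMA)
            fibers.append(segment_fiber(pts))
        s = fiber_summary(fibers, bin_nm=5.0)
        assert abs(s["modal_diameter_nm"] - 35.0) <= 5.0
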