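"""Synthetic scene generator: geometry, stochastics, and truth bookkeeping."""

import math

import numpy as np
import pytest

from chromaflux import FWHM_PER_SIGMA, fwhm_to_sigma, sigma_to_fwhm
from chromaflux.simgen import (
    PROBE_RADIAL_BAND_NM,
    AcquisitionParams,
    SyntheticScene,
    apply_tsa,
    make_fiber,
    make_nucleosome,
    make_nucleosome_chain,
    random_unit_vector,
    simulate_localizations,
)

from conftest import NOISE_SIGMA, simulate


class TestMakeNucleosome:
    def test_full_availability_capped_at_coverage_limit(self, rng):
        # floor(147 * 0.8 / 12) = 9 bound probes at most
        for _ in range(20):
            nuc = make_nucleosome([0, 0, 0], [0, 0, 1], 1.0, rng)
            assert len(nuc.bound_sites) == 9

    def test_zero_availability_zero_bound(self, rng):
        nuc = make_nucleosome([0, 0, 0], [0, 0, 1], 0.0, rng)
        assert len(nuc.bound_sites) == 0

    def test_bound_count_matches_binomial_expectation(self):
        rng = np.random.default_rng(11)
        at = 0.6
        n_candidates = 147 // 12  # 12 candidate footprints
        draws = [
            len(make_nucleosome([0, 0, 0], [0, 0, 1], at, rng).bound_sites)
            for _ in range(1000)
        ]
        # truncation at 9 is rare at p=0.6; compare against the truncated
        # binomial expectation computed by enumeration
        from scipy.stats import binom

        k = np.arange(n_candidates + 1)
        pmf = binom.pmf(k, n_candidates, at)
        expect = float(np.sum(np.minimum(k, 9) * pmf))
        se = float(np.sqrt(np.sum((np.minimum(k, 9) - expect) ** 2 * pmf) / 1000))
        assert abs(np.mean(draws) - expect) < 3 * se

    def test_sites_within_probe_envelope_of_axis(self, rng):
        axis = random_unit_vector(rng)
        nuc = make_nucleosome([5, -3, 2], axis, 1.0, rng)
        rel = np.array([s.position for s in nuc.sites]) - nuc.center
        radial = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
        assert radial.max() <= nuc.diameter_nm / 2 + 1
        assert radial.min() >= PROBE_RADIAL_BAND_NM[0] - 1e-9


class TestMakeFiber:
    def test_zero_curvature_straight_centerline(self, rng):
        fib = make_fiber(100, [(100, 35.0)], 0.0, rng)
        d = np.diff(fib.centerline, axis=0)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        assert np.allclose(d, d[0])

    def test_nucleosome_centers_near_segment_surface_ring(self, rng):
        fib = make_fiber(100, [(100, 35.0)], 0.0, rng)
        centers = np.array([n.center for n in fib.nucleosomes])
        radial = np.linalg.norm(centers[:, 1:], axis=1)  # fiber along +x
        assert np.all(radial <= 35.0 / 2 + 1e-9)

    def test_two_segment_radial_spread_differs(self, rng):
        fib = make_fiber(200, [(100, 20.0), (100, 50.0)], 0.0, rng,
                         target_density_mbp_um3=40.0)
        pos = np.array([s.position for s in fib.bound_sites()])
        first = pos[pos[:, 0] < 100]
        second = pos[pos[:, 0] >= 100]
        rms1 = np.sqrt(np.mean(first[:, 1:] ** 2))
        rms2 = np.sqrt(np.mean(second[:, 1:] ** 2))
        assert rms2 > 1.5 * rms1

    def test_thin_segment_rejected(self, rng):
        with pytest.raises(ValueError, match="pack"):
            make_fiber(50, [(50, 10.0)], 0.0, rng)


class TestSimulateLocalizations:
    def test_fwhm_sigma_conversion_constant(self):
        assert fwhm_to_sigma(1.08) == pytest.approx(0.45864, abs=1e-4)
        assert sigma_to_fwhm(fwhm_to_sigma(2.0)) == pytest.approx(2.0)
        assert FWHM_PER_SIGMA == pytest.approx(2 * math.sqrt(2 * math.log(2)))

    def test_perfect_detection_zero_noise_reproduces_truth(self, rng):
        scene = SyntheticScene()
        scene.add_nucleosome([250, 250, 250], [0, 0, 1], 1.0, rng)
        table = simulate_localizations(
            scene,
            AcquisitionParams(precision_fwhm=(0, 0, 0), detection_prob=1.0, rng_seed=1),
        )
        truth = {s.site_id: s.position for s in scene.all_bound_sites()}
        assert len(table) == len(truth)
        for uid, sid in scene.truth_links.items():
            row = table.frame.loc[table.frame.uid == uid].iloc[0]
            np.testing.assert_allclose(
                [row.x_nm, row.y_nm, row.z_nm], truth[sid], atol=1e-12
            )

    def test_partial_detection_binomial_count(self, rng):
        scene = SyntheticScene(box=((0, 3000), (0, 3000), (0, 3000)))
        scene.add_scatter(10_000, rng)
        table = simulate(scene, seed=4, detection_prob=0.5)
        n, p = 10_000, 0.5
        assert abs(len(table) - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_empirical_fwhm_matches_configuration(self, rng):
        from chromaflux.simgen import ProbeSite

        scene = SyntheticScene()
        pos = np.array([250.0, 250.0, 250.0])
        scene.scattered = [ProbeSite(i, pos, "scatter", -1, True) for i in range(10_000)]
        scene._next_site_id = 10_000
        table = simulate(scene, seed=7)
        emp = (table.coords() - pos).std(axis=0) * FWHM_PER_SIGMA
        np.testing.assert_allclose(emp, [1.08, 0.96, 0.63], rtol=0.05)

    def test_every_localization_linked_or_background(self, rng):
        scene = SyntheticScene(box=((0, 500), (0, 500), (0, 500)))
        scene.add_nucleosome([250, 250, 250], [0, 0, 1], 0.8, rng)
        scene.add_scatter(50, rng)
        table = simulate(scene, seed=2, background_rate_per_um3=200.0)
        site_ids = {s.site_id for s in scene.all_bound_sites()}
        assert set(scene.truth_links) == set(table.uids)
        for sid in scene.truth_links.values():
            assert sid == -1 or sid in site_ids

    def test_timestamps_sequential_at_configured_spacing(self, rng):
        scene = SyntheticScene(box=((0, 500),) * 3)
        scene.add_scatter(100, rng)
        table = simulate(scene, seed=3)
        t = np.sort(table.frame["t_us"].to_numpy())
        np.testing.assert_allclose(np.diff(t), 93.7)


class TestApplyTsa:
    def _scene(self, seed=5):
        rng = np.random.default_rng(seed)
        scene = SyntheticScene(box=((0, 1000),) * 3)
        for _ in range(20):
            make_nucleosome_chain(
                scene, rng.uniform(100, 900, 3), rng.normal(size=3), 5, 14.0, 0.7, rng
            )
        return scene

    def test_zero_severity_unchanged(self, rng):
        scene = self._scene()
        assert apply_tsa(scene, 0.0, rng) is scene

    def test_full_severity_no_long_fibers(self, rng):
        out = apply_tsa(self._scene(), 1.0, rng)
        assert all(f.length_nm < 50 for f in out.fibers)

    def test_surviving_fiber_count_binomial(self):
        rng = np.random.default_rng(9)
        scene = SyntheticScene(box=((0, 3000),) * 3)
        for _ in range(100):
            make_nucleosome_chain(
                scene, rng.uniform(100, 2900, 3), rng.normal(size=3), 4, 14.0, 0.6, rng
            )
        out = apply_tsa(scene, 0.9, np.random.default_rng(1))
        n, p = 100, 0.1  # survivors
        assert abs(len(out.fibers) - n * p) < 3 * math.sqrt(n * p * (1 - p)) + 1

    def test_input_scene_not_mutated(self, rng):
        scene = self._scene()
        before = np.array([s.position for s in scene.all_bound_sites()])
        apply_tsa(scene, 1.0, rng)
        after = np.array([s.position for s in scene.all_bound_sites()])
        np.testing.assert_array_equal(before, after)
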