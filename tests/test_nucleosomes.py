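"""Ring, nucleosome, and dimer fits; diameter statistics; classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chromaflux import (
    DegenerateGeometryError,
    classify_region,
    dbscan,
    diameter_histogram,
    extract_nucleosomes,
    fit_dimer,
    fit_nucleosome,
    fit_ring,
)
from chromaflux.simgen import (
    make_nucleosome,
    random_unit_vector,
)

from conftest import NOISE_SIGMA, build_polymer_scene, simulate


def _circle(radius, n, z=0.0):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi), np.full(n, z)])


def _noisy_nucleosome_points(rng, at_fraction=0.7):
    while True:
        nuc = make_nucleosome(np.zeros(3), random_unit_vector(rng), at_fraction, rng)
        pts = np.array([s.position for s in nuc.bound_sites])
        if len(pts) >= 5:
            return pts + rng.normal(size=pts.shape) * NOISE_SIGMA, nuc


class TestFitRing:
    def test_exact_circle(self):
        m = fit_ring(_circle(5.81, 8))
        assert m.radius == pytest.approx(5.81, abs=1e-6)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)
        assert m.out_of_plane_rms == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_equivariance(self, rng):
        pts = _circle(5.81, 9) + rng.normal(size=(9, 3)) * NOISE_SIGMA
        m0 = fit_ring(pts)
        rot = Rotation.random(random_state=4).as_matrix()
        m1 = fit_ring(pts @ rot.T + [50, 20, -10])
        assert m1.radius == pytest.approx(m0.radius, rel=1e-6)

    def test_tilted_noisy_circle_mean_recovery(self):
        rng = np.random.default_rng(12)
        rot = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        diams = []
        for _ in range(100):
            pts = _circle(5.81, 10) @ rot.T
            pts = pts + rng.normal(size=pts.shape) * NOISE_SIGMA
            diams.append(fit_ring(pts).diameter)
        assert abs(np.mean(diams) - 11.62) < 0.5

    def test_filled_disk_markedly_worse_than_circle(self, rng):
        # a uniform disk concentrates its in-plane scatter at ~0.89 under
        # the explained-cross-section convention; an exact ring gives 1
        r = 6.0 * np.sqrt(rng.uniform(0, 1, 300))
        phi = rng.uniform(0, 2 * np.pi, 300)
        disk = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(300)])
        assert fit_ring(disk).r_squared < 0.95

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0), np.zeros(6)])
        with pytest.raises(DegenerateGeometryError):
            fit_ring(pts)


class TestFitNucleosome:
    def test_simgen_recovery_accept_rate_and_diameter(self):
        rng = np.random.default_rng(14)
        accepted, diams = 0, []
        for _ in range(100):
            pts, nuc = _noisy_nucleosome_points(rng)
            fit = fit_nucleosome(pts)
            if fit.accepted:
                accepted += 1
                diams.append(fit.diameter)
                assert fit.n_attached >= 5
                assert fit.height < fit.diameter
        assert accepted >= 80
        assert abs(np.mean(diams) - nuc.probe_ring_diameter_nm) < 0.6

    def test_attached_count_by_residual_threshold(self, rng):
        on_cyl = np.column_stack(
            [5.73 * np.cos(np.linspace(0, 2 * np.pi, 8, endpoint=False)),
             5.73 * np.sin(np.linspace(0, 2 * np.pi, 8, endpoint=False)),
             rng.uniform(-2, 2, 8)]
        )
        # scatter placed >= 3 nm away from the cylinder surface in radius
        far = []
        while len(far) < 6:
            p = rng.uniform(-9, 9, 3)
            if abs(np.hypot(p[0], p[1]) - 5.73) > 3:
                far.append(p)
        fit = fit_nucleosome(np.vstack([on_cyl, np.array(far)]))
        assert fit.n_attached == 8

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_nucleosome(np.zeros((4, 3)))

    def test_oversized_structure_not_accepted(self, rng):
        pts = _circle(12.0, 10) + rng.normal(size=(10, 3)) * NOISE_SIGMA
        assert not fit_nucleosome(pts).accepted

    def test_rigid_motion_diameter_invariant(self, rng):
        pts, _ = _noisy_nucleosome_points(rng)
        f0 = fit_nucleosome(pts)
        rot = Rotation.random(random_state=9).as_matrix()
        f1 = fit_nucleosome(pts @ rot.T + [10, 20, 30])
        assert f1.diameter == pytest.approx(f0.diameter, rel=1e-4)


class TestFitDimer:
    def test_exact_coaxial_rings(self):
        pts = np.vstack([_circle(5.75, 6, z=0.0), _circle(5.75, 6, z=6.0)])
        d = fit_dimer(pts)
        assert d is not None and d.accepted
        assert d.offset_nm == pytest.approx(6.0, abs=1e-6)

    def test_simgen_dimer_diameters_in_band(self):
        rng = np.random.default_rng(23)
        found = 0
        for _ in range(20):
            axis = random_unit_vector(rng)
            p1 = np.array(
                [s.position for s in make_nucleosome(np.zeros(3), axis, 0.8, rng).bound_sites]
            )
            p2 = np.array(
                [s.position for s in make_nucleosome(7.0 * axis, axis, 0.8, rng).bound_sites]
            )
            pts = np.vstack([p1, p2]) + rng.normal(size=(len(p1) + len(p2), 3)) * NOISE_SIGMA
            if len(pts) < 10:
                continue
            d = fit_dimer(pts)
            if d is not None:
                found += 1
                for f in (d.first, d.second):
                    assert 9.0 <= f.diameter <= 14.0
        assert found >= 10

    def test_single_nucleosome_yields_no_dimer(self):
        rng = np.random.default_rng(25)
        pts, _ = _noisy_nucleosome_points(rng, at_fraction=0.9)
        pts = np.vstack([pts, pts + rng.normal(size=pts.shape) * 0.3])[:11]
        assert fit_dimer(pts) is None


class TestDiameterHistogram:
    def test_single_population_single_peak(self):
        class F:
            def __init__(self, d):
                self.diameter = d

        h = diameter_histogram([F(11.5)] * 20, 0.5)
        assert h["peaks_nm"] == [pytest.approx(11.75)]

    def test_two_delta_populations_two_peaks(self):
        class F:
            def __init__(self, d):
                self.diameter = d

        h = diameter_histogram([F(11.4)] * 20 + [F(12.4)] * 10, 0.5)
        assert len(h["peaks_nm"]) == 2

    def test_empty(self):
        h = diameter_histogram([], 0.5)
        assert len(h["counts"]) == 0


class TestClassification:
    def test_pure_background_all_scattered(self, rng):
        from chromaflux.simgen import SyntheticScene

        scene = SyntheticScene(box=((0, 2000),) * 3)
        scene.add_scatter(300, rng)
        table = simulate(scene, seed=1)
        lab = dbscan(table.coords(), 20.0, 5)
        c = classify_region(table, lab)
        assert c.fraction_scattered > 0.95

    def test_polymer_scene_recovers_constructed_fraction(self):
        scene = build_polymer_scene(42)
        table = simulate(scene, seed=2)
        lab = dbscan(table.coords(), 20.0, 5)
        c = classify_region(table, lab)
        assert c.fraction_3plus == pytest.approx(0.60, abs=0.05)
        total = c.fraction_scattered + c.fraction_1_2 + c.fraction_3plus
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_single_nucleosome_cluster_counts_as_1_2(self, rng):
        from chromaflux.simgen import SyntheticScene

        scene = SyntheticScene(box=((0, 400),) * 3)
        scene.add_nucleosome([200, 200, 200], random_unit_vector(rng), 0.8, rng)
        table = simulate(scene, seed=3)
        lab = dbscan(table.coords(), 20.0, 5)
        c = classify_region(table, lab)
        assert c.fraction_1_2 == pytest.approx(1.0)

    def test_greedy_extraction_claims_each_point_once(self):
        scene = build_polymer_scene(7)
        table = simulate(scene, seed=4)
        lab = dbscan(table.coords(), 20.0, 5)
        coords = table.coords()
        for label in range(min(lab.n_clusters, 5)):
            idx = np.flatnonzero(lab.labels == label)
            fits = extract_nucleosomes(coords[idx])
            total_attached = sum(f.n_attached for f in fits)
            assert total_attached <= len(idx)

    def test_empty_region_flagged(self):
        from chromaflux import LocalizationTable
        from chromaflux.cluster import ClusterLabeling

        table = LocalizationTable.from_arrays(np.empty((0, 3)))
        lab = ClusterLabeling(np.empty(0, int), 20.0, 5, np.empty(0, bool))
        c = classify_region(table, lab)
        assert c.undefined and c.n_locs == 0
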