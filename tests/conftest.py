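"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chromaflux import fwhm_to_sigma
from chromaflux.simgen import (
    AcquisitionParams,
    SyntheticScene,
    make_nucleosome_chain,
    simulate_localizations,
)

#: Per-axis localization noise sigmas at the instrument's precision.
NOISE_SIGMA = np.array([fwhm_to_sigma(f) for f in (1.08, 0.96, 0.63)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """O(n^2) density-reachability reference implementation.

    Core points have >= min_pts neighbors (closed eps-ball, counting self);
    clusters are the connected components of the core eps-graph; border
    points join the cluster of their lowest-index core neighbor.
    """
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None], axis=2)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    current = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            stack = [i]
            labels[i] = current
            while stack:
                j = stack.pop()
                for k in neighbors[j]:
                    if core[k] and labels[k] == -1:
                        labels[k] = current
                        stack.append(k)
            current += 1
    for i in range(n):
        if not core[i]:
            core_nb = [j for j in sorted(neighbors[i]) if core[j]]
            labels[i] = labels[core_nb[0]] if core_nb else -1
    return labels, core


def surface_cylinder(
    rng: np.random.Generator,
    radius: float,
    half_height: float,
    n: int,
    noise_sigma: np.ndarray | None = None,
) -> np.ndarray:
    """Points sampled exactly on a cylinder surface, optional Gaussian noise."""
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-half_height, half_height, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    if noise_sigma is not None:
        pts = pts + rng.normal(size=pts.shape) * noise_sigma
    return pts


def build_polymer_scene(seed: int) -> SyntheticScene:
    """Scene whose localizations are ~60% in >= 3-nucleosome chains.

    12 chains of 5 nucleosomes (~40 bound probes each), 14 isolated
    mono-nucleosomes, and 205 scattered free probes: the expected chain
    share of localizations is 474 / 790 ~ 0.60.
    """
    rng = np.random.default_rng(seed)
    scene = SyntheticScene(box=((0, 1500), (0, 1500), (0, 1500)))
    for _ in range(12):
        start = rng.uniform(150, 1350, 3)
        make_nucleosome_chain(scene, start, rng.normal(size=3), 5, 14.0, 0.7, rng)
    for _ in range(14):
        from chromaflux.simgen import random_unit_vector

        scene.add_nucleosome(
            rng.uniform(150, 1350, 3), random_unit_vector(rng), 0.7, rng
        )
    scene.add_scatter(205, rng)
    return scene


def simulate(scene: SyntheticScene, seed: int = 0, **kwargs):
    return simulate_localizations(scene, AcquisitionParams(rng_seed=seed, **kwargs))
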