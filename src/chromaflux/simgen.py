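"""Synthetic chromatin scenes and simulated MINFLUX localizations.

The generator builds ground-truth structures — nucleosomes carrying probe
sites on a left-handed superhelical DNA path, chromatin fibers assembled
from nucleosomes around a curved centerline, and scattered free probes —
and then simulates the measurement: stochastic detection of each bound
probe (the dye blinks spontaneously and probe exchange means a molecule is
rarely seen twice), anisotropic Gaussian localization error, uniform
background, and sequential timestamps.  Every simulated localization keeps
a link to the truth site it came from (or is flagged as background), so
recovery of structure by the analysis modules can be scored exactly.

Probe model: a minor-groove dye with a 12-bp footprint binding AT-rich
stretches; a 147-bp nucleosome therefore offers at most
``floor(147 * 0.8 / 12) = 9`` simultaneously bound probes, and AT-content
variation is modeled as an independent Bernoulli draw per footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .config import DEFAULT_PRECISION_FWHM_NM, fwhm_to_sigma
from .locio import LocalizationTable

#: Superhelical wrap of nucleosomal DNA in turns.
SUPERHELIX_TURNS = 1.65
#: Radius of the DNA-center superhelical path, nm.
SUPERHELIX_PATH_RADIUS_NM = 4.2
#: Total rise of the wrap along the nucleosome axis, nm.
SUPERHELIX_RISE_NM = 5.7
#: Radial band (nm from the nucleosome axis) in which probe fluorophores sit;
#: emulates minor-groove positions across the 2.5-nm DNA cross-section.
PROBE_RADIAL_BAND_NM = (4.2, 5.5)


@dataclass
class ProbeSite:
    """One potential dye binding footprint on the DNA path."""

    site_id: int
    position: np.ndarray  # (3,) nm
    parent_type: Literal["nucleosome", "fiber", "scatter"]
    parent_id: int
    bound: bool = True


@dataclass
class NucleosomeTruth:
    """Ground-truth nucleosome: an ~11-nm disk wrapped by ~1.65 DNA turns."""

    nucleosome_id: int
    center: np.ndarray
    axis: np.ndarray
    sites: list[ProbeSite]
    diameter_nm: float = 11.0
    wrap_bp: int = 147
    fiber_id: int | None = None

    @property
    def bound_sites(self) -> list[ProbeSite]:
        return [s for s in self.sites if s.bound]

    @property
    def probe_ring_diameter_nm(self) -> float:
        """Mean diameter of the ring traced by the probe fluorophores.

        Probe radial positions are drawn uniformly from
        ``PROBE_RADIAL_BAND_NM``, so the expected fitted diameter of an
        ideal cylinder fit is twice the band mean, slightly below the
        outer envelope ``diameter_nm``.
        """
        return sum(PROBE_RADIAL_BAND_NM)


@dataclass
class FiberTruth:
    """Ground-truth chromatin fiber: nucleosomes around a curved centerline."""

    fiber_id: int
    centerline: np.ndarray  # (k, 3) polyline, nm
    segments: list[tuple[float, float, float]]  # (arc_start, arc_end, diameter)
    nucleosomes: list[NucleosomeTruth] = field(default_factory=list)

    @property
    def length_nm(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    def bound_sites(self) -> list[ProbeSite]:
        return [s for nuc in self.nucleosomes for s in nuc.sites if s.bound]


@dataclass
class AcquisitionParams:
    """Measurement model parameters for the simulated MINFLUX acquisition."""

    precision_fwhm: tuple[float, float, float] = DEFAULT_PRECISION_FWHM_NM
    detection_prob: float = 1.0
    relocalization_rate: float = 0.0
    background_rate_per_um3: float = 0.0
    t_per_loc_us: float = 93.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.relocalization_rate < 0 or self.background_rate_per_um3 < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SyntheticScene:
    """Ground truth plus (after simulation) observation→truth bookkeeping."""

    box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (0.0, 500.0),
        (0.0, 500.0),
        (0.0, 500.0),
    )
    nucleosomes: list[NucleosomeTruth] = field(default_factory=list)
    fibers: list[FiberTruth] = field(default_factory=list)
    scattered: list[ProbeSite] = field(default_factory=list)
    truth_links: dict[int, int] = field(default_factory=dict)  # uid -> site_id; -1 = background
    _next_site_id: int = 0
    _next_struct_id: int = 0

    def _take_site_ids(self, n: int) -> range:
        r = range(self._next_site_id, self._next_site_id + n)
        self._next_site_id += n
        return r

    def _take_struct_id(self) -> int:
        self._next_struct_id += 1
        return self._next_struct_id - 1

    def all_bound_sites(self) -> list[ProbeSite]:
        sites: list[ProbeSite] = []
        for nuc in self.nucleosomes:
            sites.extend(nuc.bound_sites)
        for fib in self.fibers:
            sites.extend(fib.bound_sites())
        sites.extend(s for s in self.scattered if s.bound)
        return sites

    def site_index(self) -> dict[int, ProbeSite]:
        return {s.site_id: s for s in self.all_bound_sites()}

    # -- construction helpers -------------------------------------------
    def add_nucleosome(self, center, axis, at_fraction: float, rng: np.random.Generator,
                       **kwargs) -> NucleosomeTruth:
        nuc = make_nucleosome(center, axis, at_fraction, rng, scene=self, **kwargs)
        self.nucleosomes.append(nuc)
        return nuc

    def add_fiber(self, length_nm: float, diameter_profile, curvature: float,
                  rng: np.random.Generator, **kwargs) -> FiberTruth:
        fib = make_fiber(length_nm, diameter_profile, curvature, rng, scene=self, **kwargs)
        self.fibers.append(fib)
        return fib

    def add_scatter(self, n: int, rng: np.random.Generator) -> list[ProbeSite]:
        """Add free probes uniformly distributed in the scene box."""
        lo = np.array([b[0] for b in self.box])
        hi = np.array([b[1] for b in self.box])
        pos = rng.uniform(lo, hi, size=(n, 3))
        ids = self._take_site_ids(n)
        sites = [ProbeSite(i, p, "scatter", -1, True) for i, p in zip(ids, pos)]
        self.scattered.extend(sites)
        return sites


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector cannot be normalized")
    return v / n


def orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic right-handed frame (e1, e2, axis) for a unit axis."""
    axis = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(helper, axis))
    e2 = np.cross(axis, e1)
    return e1, e2, axis


def random_unit_vector(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    v = rng.normal(size=(size or 1, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v if size else v[0]


# ---------------------------------------------------------------------------
# nucleosome generator
# ---------------------------------------------------------------------------

def make_nucleosome(
    center,
    axis,
    at_fraction: float,
    rng: np.random.Generator,
    *,
    diameter_nm: float = 11.0,
    wrap_bp: int = 147,
    footprint_bp: int = 12,
    max_coverage_fraction: float = 0.8,
    scene: SyntheticScene | None = None,
    fiber_id: int | None = None,
) -> NucleosomeTruth:
    """Build one ground-truth nucleosome with stochastically bound probe sites.

    Candidate footprints are spaced ``footprint_bp`` apart along the
    left-handed superhelix (1.65 turns, total rise ~5.7 nm); each is bound
    with probability ``at_fraction`` (AT-availability), then the bound set
    is thinned so that at most ``floor(wrap_bp * max_coverage_fraction /
    footprint_bp)`` probes remain (steric coverage cap; 9 for the
    defaults).
    """
    if not 0 <= at_fraction <= 1:
        raise ValueError("at_fraction must be in [0, 1]")
    center = np.asarray(center, float)
    e1, e2, ax = orthonormal_frame(axis)

    n_candidates = wrap_bp // footprint_bp
    max_bound = int(math.floor(wrap_bp * max_coverage_fraction / footprint_bp))

    # footprint centers in bp along the wrap
    bp_centers = (np.arange(n_candidates) + 0.5) * footprint_bp
    frac = bp_centers / wrap_bp
    phi = -2.0 * math.pi * SUPERHELIX_TURNS * frac  # left-handed
    height = SUPERHELIX_RISE_NM * (frac - 0.5)
    rho = rng.uniform(*PROBE_RADIAL_BAND_NM, size=n_candidates)

    local = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), height])
    world = center + local[:, 0:1] * e1 + local[:, 1:2] * e2 + local[:, 2:3] * ax

    bound = rng.uniform(size=n_candidates) < at_fraction
    n_bound = int(bound.sum())
    if n_bound > max_bound:
        keep = rng.choice(np.flatnonzero(bound), size=max_bound, replace=False)
        bound = np.zeros(n_candidates, bool)
        bound[keep] = True

    if scene is not None:
        ids = list(scene._take_site_ids(n_candidates))
        nid = scene._take_struct_id()
    else:
        ids = list(range(n_candidates))
        nid = 0
    ptype = "fiber" if fiber_id is not None else "nucleosome"
    pid = fiber_id if fiber_id is not None else nid
    sites = [
        ProbeSite(ids[i], world[i], ptype, pid, bool(bound[i]))
        for i in range(n_candidates)
    ]
    return NucleosomeTruth(nid, center, ax, sites, diameter_nm, wrap_bp, fiber_id)


# ---------------------------------------------------------------------------
# fiber generator
# ---------------------------------------------------------------------------

def _smoothed_centerline(
    length_nm: float,
    curvature: float,
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    step_nm: float = 5.0,
) -> np.ndarray:
    """Random walk whose direction bends by at most ``curvature`` rad per nm."""
    n_steps = max(1, int(math.ceil(length_nm / step_nm)))
    pts = [start.copy()]
    d = _unit(direction)
    remaining = length_nm
    for _ in range(n_steps):
        ds = min(step_nm, remaining)
        pts.append(pts[-1] + d * ds)
        remaining -= ds
        if curvature > 0:
            angle = rng.uniform(-curvature * ds, curvature * ds)
            perp = _unit(np.cross(d, random_unit_vector(rng)))
            d = _unit(d * math.cos(angle) + perp * math.sin(angle))
    return np.asarray(pts)


def _arc_point(centerline: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and tangent at arc length ``s`` along a polyline."""
    seg = np.diff(centerline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    return centerline[i] + frac * seg[i], _unit(seg[i])


def target_probe_count(
    density_mbp_um3: float,
    diameter_nm: float,
    length_nm: float,
    footprint_bp: int = 12,
    max_coverage_fraction: float = 0.8,
) -> int:
    """Bound probes needed so the density estimator recovers the target.

    Inverts the density formula: ``bp = n * footprint / coverage`` and
    ``density = bp / volume`` for a cylinder of the given diameter/length.
    """
    vol_um3 = math.pi * (diameter_nm / 2.0) ** 2 * length_nm / 1e9
    bp = density_mbp_um3 * 1e6 * vol_um3
    return max(1, round(bp * max_coverage_fraction / footprint_bp))


def make_fiber(
    length_nm: float,
    diameter_profile: Sequence[tuple[float, float]],
    curvature: float,
    rng: np.random.Generator,
    *,
    target_density_mbp_um3: float = 34.0,
    at_fraction: float = 0.6,
    start=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
    scene: SyntheticScene | None = None,
    footprint_bp: int = 12,
    max_coverage_fraction: float = 0.8,
) -> FiberTruth:
    """Build a segmented chromatin fiber with its nucleosomes and probe sites.

    ``diameter_profile`` is a list of (segment length nm, diameter nm)
    partitioning the fiber; diameters must exceed the nucleosome diameter
    so nucleosomes can pack inside.  Nucleosome centers sit on a ring whose
    radius is chosen so the expected probe distance from the fiber axis
    equals half the segment diameter — a least-squares cylinder fit of the
    probe cloud then recovers the nominal diameter.  Per segment, exactly
    the number of bound probes implied by ``target_density_mbp_um3`` is
    kept, so the density estimator can be validated against the target.
    """
    if length_nm <= 0:
        raise ValueError("fiber length must be positive")
    profile = [(float(l), float(d)) for l, d in diameter_profile]
    if abs(sum(l for l, _ in profile) - length_nm) > 1e-6:
        raise ValueError("diameter_profile lengths must sum to length_nm")
    for _, d in profile:
        if d <= 11.0:
            raise ValueError(
                f"segment diameter {d} nm <= 11 nm: cannot pack nucleosomes"
            )

    centerline = _smoothed_centerline(
        length_nm, curvature, rng, np.asarray(start, float), np.asarray(direction, float)
    )
    fid = scene._take_struct_id() if scene is not None else 0
    fiber = FiberTruth(fid, centerline, [])

    # mean squared probe offset from the nucleosome center (radial band +
    # rise), used to de-bias the nucleosome-center ring radius
    band_lo, band_hi = PROBE_RADIAL_BAND_NM
    mean_sq_offset = (band_lo**2 + band_lo * band_hi + band_hi**2) / 3.0 + (
        SUPERHELIX_RISE_NM**2 / 12.0
    )

    s0 = 0.0
    for seg_len, diameter in profile:
        s1 = s0 + seg_len
        fiber.segments.append((s0, s1, diameter))
        n_target = target_probe_count(
            target_density_mbp_um3, diameter, seg_len, footprint_bp, max_coverage_fraction
        )
        ring_radius = max(0.0, diameter / 2.0 - mean_sq_offset / (3.0 * (diameter / 2.0)))
        nucs: list[NucleosomeTruth] = []
        bound_total = 0
        guard = 0
        while bound_total < n_target and guard < 10000:
            guard += 1
            s = rng.uniform(s0, s1)
            base, tangent = _arc_point(centerline, s)
            e1, e2, _ = orthonormal_frame(tangent)
            theta = rng.uniform(0, 2 * math.pi)
            center = base + ring_radius * (math.cos(theta) * e1 + math.sin(theta) * e2)
            nuc = make_nucleosome(
                center,
                random_unit_vector(rng),
                at_fraction,
                rng,
                scene=scene,
                fiber_id=fid,
                footprint_bp=footprint_bp,
                max_coverage_fraction=max_coverage_fraction,
            )
            nucs.append(nuc)
            bound_total += len(nuc.bound_sites)
        # unbind surplus probes so the segment hits the target count exactly
        surplus = bound_total - n_target
        if surplus > 0:
            all_bound = [s for nuc in nucs for s in nuc.bound_sites]
            for site in rng.choice(len(all_bound), size=surplus, replace=False):
                all_bound[site].bound = False
        fiber.nucleosomes.extend(nucs)
        s0 = s1
    return fiber


def make_nucleosome_chain(
    scene: SyntheticScene,
    start,
    direction,
    n_nucleosomes: int,
    spacing_nm: float,
    at_fraction: float,
    rng: np.random.Generator,
    as_fiber: bool = True,
) -> list[NucleosomeTruth]:
    """Place ``n_nucleosomes`` along a straight line at fixed spacing.

    A resolvable beads-on-a-string arrangement: nucleosome centers sit on
    the line with independent random axis orientations.  With
    ``as_fiber=True`` the chain is registered as one fiber truth object
    (nominal diameter: nucleosome disk + probe envelope), otherwise the
    nucleosomes are added as free mono-nucleosomes.
    """
    start = np.asarray(start, float)
    d = _unit(np.asarray(direction, float))
    length = spacing_nm * max(n_nucleosomes - 1, 1)
    fid = scene._take_struct_id() if as_fiber else None
    nucs = []
    for k in range(n_nucleosomes):
        nuc = make_nucleosome(
            start + k * spacing_nm * d,
            random_unit_vector(rng),
            at_fraction,
            rng,
            scene=scene,
            fiber_id=fid,
        )
        nucs.append(nuc)
    if as_fiber:
        centerline = np.vstack([start, start + length * d])
        fiber = FiberTruth(fid, centerline, [(0.0, length, 2 * PROBE_RADIAL_BAND_NM[1] + 11.0)], nucs)
        scene.fibers.append(fiber)
    else:
        scene.nucleosomes.extend(nucs)
    return nucs


# ---------------------------------------------------------------------------
# measurement simulation
# ---------------------------------------------------------------------------

def simulate_localizations(
    scene: SyntheticScene, acq: AcquisitionParams
) -> LocalizationTable:
    """Simulate a MINFLUX acquisition of every bound probe site in the scene.

    Each bound probe is detected independently with ``detection_prob`` and,
    if detected, seen ``1 + Poisson(relocalization_rate)`` times (the
    default of zero extra sightings reflects that the blinking/exchange
    kinetics make a second sighting of the same molecule rare).  Each
    sighting is displaced by independent per-axis Gaussian error with
    ``sigma = FWHM / (2 sqrt(2 ln 2))``.  Background localizations are
    Poisson-distributed over the scene box.  Sightings receive timestamps
    in randomized order at ``t_per_loc_us`` spacing.  ``scene.truth_links``
    maps each output uid to its truth site id (-1 for background).
    """
    rng = np.random.default_rng(acq.rng_seed)
    sites = scene.all_bound_sites()
    lo = np.array([b[0] for b in scene.box])
    hi = np.array([b[1] for b in scene.box])
    vol_um3 = float(np.prod(hi - lo)) / 1e9
    n_background = int(rng.poisson(acq.background_rate_per_um3 * vol_um3))
    if not sites and n_background == 0 and acq.background_rate_per_um3 == 0:
        if not scene.fibers and not scene.nucleosomes and not scene.scattered:
            raise ValueError("scene is empty and background rate is zero")

    positions: list[np.ndarray] = []
    links: list[int] = []
    if sites:
        detected = rng.uniform(size=len(sites)) < acq.detection_prob
        for site, det in zip(sites, detected):
            if not det:
                continue
            n_sight = 1 + (
                int(rng.poisson(acq.relocalization_rate))
                if acq.relocalization_rate > 0
                else 0
            )
            for _ in range(n_sight):
                positions.append(site.position)
                links.append(site.site_id)
    if n_background:
        for p in rng.uniform(lo, hi, size=(n_background, 3)):
            positions.append(p)
            links.append(-1)

    n = len(positions)
    xyz = np.asarray(positions, float).reshape(n, 3)
    sigma = np.array([fwhm_to_sigma(f) for f in acq.precision_fwhm])
    if n and np.any(sigma > 0):
        xyz = xyz + rng.normal(size=(n, 3)) * sigma

    order = rng.permutation(n)
    t = np.empty(n)
    t[order] = np.arange(n) * acq.t_per_loc_us

    table = LocalizationTable.from_arrays(
        xyz, t=t, photons=np.full(n, 100.0), precision_fwhm=acq.precision_fwhm
    )
    scene.truth_links = {int(u): int(l) for u, l in zip(table.uids, links)}
    return table


# ---------------------------------------------------------------------------
# TSA perturbation
# ---------------------------------------------------------------------------

def apply_tsa(
    scene: SyntheticScene,
    severity: float,
    rng: np.random.Generator,
    *,
    rescatter_fraction: float = 0.7,
    truncated_length_nm: float = 45.0,
) -> SyntheticScene:
    """Emulate histone-hyperacetylation-driven fiber disruption.

    A fraction ``severity`` of fibers dissolves: ``rescatter_fraction`` of
    their bound probes become free scattered probes (DNA released from
    histones) and the rest persist as free nucleosomes.  Surviving fibers
    are truncated to under 50 nm, while their segment diameters are left
    unchanged — decompaction shortens fibers without thinning them.
    ``severity = 0`` returns the scene unchanged.  The input scene is not
    modified; whether a given fiber dissolves is decided by one uniform
    draw per fiber (drawn first), so runs at increasing severity with
    identically seeded generators dissolve nested fiber sets.
    """
    import copy

    if not 0 <= severity <= 1:
        raise ValueError("severity must be in [0, 1]")
    if severity == 0:
        return scene
    scene = copy.deepcopy(scene)

    new = SyntheticScene(
        box=scene.box,
        nucleosomes=list(scene.nucleosomes),
        scattered=list(scene.scattered),
        _next_site_id=scene._next_site_id,
        _next_struct_id=scene._next_struct_id,
    )
    u = rng.uniform(size=len(scene.fibers))
    lo = np.array([b[0] for b in scene.box])
    hi = np.array([b[1] for b in scene.box])
    for fib, ui in zip(scene.fibers, u):
        if ui < severity:
            # dissolved: release nucleosomes
            for nuc in fib.nucleosomes:
                if rng.uniform() < rescatter_fraction:
                    for site in nuc.bound_sites:
                        site.parent_type = "scatter"
                        site.parent_id = -1
                        site.position = rng.uniform(lo, hi)
                        new.scattered.append(site)
                else:
                    # persisting nucleosome drifts away from its former
                    # neighbors as the fiber decompacts
                    shift = random_unit_vector(rng) * rng.uniform(30.0, 80.0)
                    nuc.center = nuc.center + shift
                    nuc.fiber_id = None
                    for site in nuc.sites:
                        site.position = site.position + shift
                        site.parent_type = "nucleosome"
                        site.parent_id = nuc.nucleosome_id
                    new.nucleosomes.append(nuc)
        else:
            new.fibers.append(
                _truncate_fiber(fib, min(truncated_length_nm, fib.length_nm), rng)
            )
    return new


def _truncate_fiber(fib: FiberTruth, keep_nm: float, rng: np.random.Generator) -> FiberTruth:
    """Keep a random ``keep_nm`` window of the fiber; drop the rest."""
    total = fib.length_nm
    if keep_nm >= total:
        return fib
    start = rng.uniform(0, total - keep_nm)
    end = start + keep_nm
    # project nucleosomes onto arc positions via nearest centerline vertex
    seg = np.diff(fib.centerline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    kept: list[NucleosomeTruth] = []
    for nuc in fib.nucleosomes:
        d = np.linalg.norm(fib.centerline - nuc.center, axis=1)
        s = cum[int(np.argmin(d))]
        if start <= s <= end:
            kept.append(nuc)
    segments = []
    for s0, s1, dia in fib.segments:
        a, b = max(s0, start), min(s1, end)
        if a < b:
            segments.append((a - start, b - start, dia))
    return FiberTruth(fib.fiber_id, fib.centerline, segments, kept)


# ---------------------------------------------------------------------------
# structured point patterns for resolution tests
# ---------------------------------------------------------------------------

def make_stripe_pattern(
    n_fibers: int,
    width_nm: float,
    field_nm: float,
    n_locs: int,
    rng: np.random.Generator,
    jitter_fwhm_nm: float = 1.08,
) -> np.ndarray:
    """2D localizations of parallel fiber-like stripes of known width.

    Emulates the projected image of ``n_fibers`` straight cylinders of
    diameter ``width_nm`` at uniformly random positions across a square
    field: the cross-section offset follows the projected uniform-in-disk
    (semicircle) profile, plus Gaussian localization jitter.  The
    characteristic structure scale of the image is ``width_nm``, which is
    what a Fourier-ring-correlation resolution estimate should report.
    """
    sigma = fwhm_to_sigma(jitter_fwhm_nm)
    centers = rng.uniform(0, field_nm, n_fibers)
    which = rng.integers(0, n_fibers, n_locs)
    # rejection-sample a point in the unit disk; x-coordinate has the
    # semicircle marginal of a projected cylinder cross-section
    u = rng.uniform(-1, 1, n_locs)
    v = rng.uniform(-1, 1, n_locs)
    inside = u**2 + v**2 <= 1
    while not inside.all():
        m = ~inside
        u[m] = rng.uniform(-1, 1, m.sum())
        v[m] = rng.uniform(-1, 1, m.sum())
        inside = u**2 + v**2 <= 1
    x = centers[which] + u * width_nm / 2
    y = rng.uniform(0, field_nm, n_locs)
    pts = np.column_stack([x, y])
    return pts + rng.normal(size=(n_locs, 2)) * sigma


def make_line_pattern(
    n_lines: int,
    spacing_nm: float,
    length_nm: float,
    locs_per_line: int,
    rng: np.random.Generator,
    jitter_fwhm_nm: float = 1.08,
) -> np.ndarray:
    """2D localizations on parallel lines — a known-period resolution target.

    Returns an (n, 2) array: ``n_lines`` vertical lines ``spacing_nm``
    apart, each sampled at ``locs_per_line`` uniform positions with
    Gaussian jitter of the given FWHM on both axes.
    """
    sigma = fwhm_to_sigma(jitter_fwhm_nm)
    xs = np.repeat(np.arange(n_lines) * spacing_nm, locs_per_line)
    ys = rng.uniform(0, length_nm, size=n_lines * locs_per_line)
    pts = np.column_stack([xs, ys]) + rng.normal(size=(len(xs), 2)) * sigma
    return pts
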