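"""Nucleosome-scale model fitting and nucleosome-content classification.

At the ~11-nm scale the DNA path around a single histone octamer appears
as 5-10 probe localizations on a short cylinder (a disk ~11 nm wide and a
few nm high).  This module fits three models to candidate point windows:

* a ring (circle on the best-fit plane) — the projected DNA wrap;
* a constrained cylinder — diameter restricted to the nucleosome band,
  height capped, with an explicit count of "attached" localizations whose
  radial residual is within tolerance;
* a stacked dimer — two coaxial nucleosome cylinders split along a shared
  axis.

Regions are classified by greedily extracting nucleosome fits from each
density cluster: clusters supporting no accepted fit are scattered signal,
1-2 fits are mono/di-nucleosomes, >= 3 fits are nucleosome polymers (the
fiber interior).  Fractions are localization-weighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .cluster import ClusterLabeling
from .config import PipelineConfig
from .fibers import CylinderModel, DegenerateGeometryError
from .locio import LocalizationTable

#: Default cylinder-radius search band for a nucleosome fit, nm.
RADIUS_BAND_NM = (4.5, 7.0)
#: Maximum height of an accepted nucleosome cylinder, nm.
MAX_HEIGHT_NM = 8.0


@dataclass
class RingModel:
    """Circle fitted on the best-fit plane of a 3D point set."""

    center: np.ndarray
    normal: np.ndarray
    radius: float
    r_squared: float
    out_of_plane_rms: float
    n_points: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class NucleosomeFit:
    """Constrained cylinder fit of a candidate nucleosome window."""

    cylinder: CylinderModel
    n_points_total: int
    n_attached: int
    attach_tol: float
    attached_mask: np.ndarray
    accepted: bool

    @property
    def diameter(self) -> float:
        return self.cylinder.diameter

    @property
    def height(self) -> float:
        return self.cylinder.length


@dataclass
class DimerFit:
    first: NucleosomeFit
    second: NucleosomeFit
    axis: np.ndarray
    offset_nm: float
    accepted: bool


@dataclass
class RegionClassification:
    region_id: int
    n_locs: int
    fraction_scattered: float
    fraction_1_2: float
    fraction_3plus: float
    n_fits_per_cluster: dict[int, int] = field(default_factory=dict)
    undefined: bool = False


# ---------------------------------------------------------------------------
# ring fit
# ---------------------------------------------------------------------------

def fit_ring(
    points: np.ndarray, tilt_corrected: bool = False, plane: str = "auto"
) -> RingModel:
    """Fit a circle in 3D to >= 5 points.

    Default (``plane='auto'``): the fit plane is the span of the two
    leading principal axes, points are projected onto it, and the circle
    center/radius are refined geometrically (Gauss-Newton on radial
    residuals from a Kasa algebraic start).  ``plane='xy'`` instead fits
    in the instrument focal plane — the naive projection, in which a
    tilted nucleosome's superhelical rise leaks into the apparent ring and
    biases the diameter with orientation angle.  With
    ``tilt_corrected=True`` the plane normal is refined jointly with the
    circle, removing residual plane-misalignment bias.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 5:
        raise ValueError(f"ring fit needs >= 5 points, got {len(points)}")
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / max(len(points) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] / max(evals[-1], 1e-300) < 1e-12:
        raise DegenerateGeometryError("points are collinear: ring is unidentifiable")
    if plane == "auto":
        e1, e2, normal = evecs[:, 2], evecs[:, 1], evecs[:, 0]
    elif plane == "xy":
        e1, e2, normal = np.eye(3)[0], np.eye(3)[1], np.eye(3)[2]
    else:
        raise ValueError(f"unknown plane {plane!r} (use 'auto' or 'xy')")

    def _circle_2d(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
        # Kasa algebraic fit: u^2 + v^2 = 2a u + 2b v + c
        A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
        y = u**2 + v**2
        (a, b, c), *_ = np.linalg.lstsq(A, y, rcond=None)
        r = math.sqrt(max(c + a**2 + b**2, 0.0))
        return a, b, r

    if not tilt_corrected:
        u, v = centered @ e1, centered @ e2
        a, b, _ = _circle_2d(u, v)

        def resid(p):
            r = np.hypot(u - p[0], v - p[1])
            return r - r.mean()

        sol = least_squares(resid, [a, b], method="lm", xtol=1e-12, ftol=1e-12)
        a, b = sol.x
        r_all = np.hypot(u - a, v - b)
        radius = float(r_all.mean())
        center = centroid + a * e1 + b * e2
        w = centered @ normal
        oop = float(np.sqrt(np.mean(w**2)))
    else:
        def resid3(p):
            alpha, beta, a, b = p
            nrm = normal + alpha * e1 + beta * e2
            nrm = nrm / np.linalg.norm(nrm)
            f1 = np.cross(nrm, e1)
            f1 -= (f1 @ nrm) * nrm
            f1 /= np.linalg.norm(f1)
            f2 = np.cross(nrm, f1)
            u, v = centered @ f1, centered @ f2
            r = np.hypot(u - a, v - b)
            return r - r.mean()

        sol = least_squares(resid3, [0.0, 0.0, 0.0, 0.0], method="lm",
                            xtol=1e-12, ftol=1e-12)
        alpha, beta, a, b = sol.x
        normal = normal + alpha * e1 + beta * e2
        normal = normal / np.linalg.norm(normal)
        f1 = np.cross(normal, e1)
        f1 -= (f1 @ normal) * normal
        f1 /= np.linalg.norm(f1)
        f2 = np.cross(normal, f1)
        u, v = centered @ f1, centered @ f2
        r_all = np.hypot(u - a, v - b)
        radius = float(r_all.mean())
        center = centroid + a * f1 + b * f2
        w = centered @ normal
        oop = float(np.sqrt(np.mean((w - w.mean()) ** 2)))

    ss_res = float(np.sum((r_all - radius) ** 2))
    # in-plane scatter about the in-plane centroid
    uc, vc = u - u.mean(), v - v.mean()
    ss_tot = float(np.sum(uc**2 + vc**2))
    r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - ss_res / ss_tot
    if normal[2] < 0 or (normal[2] == 0 and (normal[1] < 0 or (normal[1] == 0 and normal[0] < 0))):
        normal = -normal
    return RingModel(center, normal, radius, r2, oop, len(points))


# ---------------------------------------------------------------------------
# constrained cylinder (single nucleosome)
# ---------------------------------------------------------------------------

def _fit_disk_cylinder(
    points: np.ndarray,
    axis: np.ndarray,
    attach_tol: float,
    radius_band: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Refine a nucleosome cylinder around a fixed axis direction.

    Returns (axis, attached mask, radius from attached points, radial
    residuals).  The perpendicular axis offset is refined by least squares
    with the radius clipped to ``radius_band``; attachment requires a
    radial residual within ``attach_tol`` and an axial position within the
    height cap around the median.
    """
    axis = axis / np.linalg.norm(axis)
    centroid = points.mean(axis=0)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def radial_about(p, subset):
        p0 = centroid + p[0] * e1 + p[1] * e2
        rel = points[subset] - p0
        perp = rel - np.outer(rel @ axis, axis)
        return np.linalg.norm(perp, axis=1)

    def solve_offset(subset, x0, robust=False):
        def resid(p):
            r = radial_about(p, subset)
            return r - float(np.clip(r.mean(), *radius_band))

        if robust:
            # soft-L1 keeps off-cylinder scatter from dragging the offset
            # before the first attachment-based trim
            sol = least_squares(
                resid, x0, method="trf", loss="soft_l1", f_scale=attach_tol,
                xtol=1e-12, ftol=1e-12,
            )
        else:
            sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        return sol.x

    # iteratively trim to attached points so off-cylinder scatter cannot
    # drag the axis offset or the radius estimate
    subset = np.ones(len(points), bool)
    x = np.zeros(2)
    attached = subset.copy()
    for it in range(4):
        x = solve_offset(subset, x, robust=(it == 0))
        p0 = centroid + x[0] * e1 + x[1] * e2
        rel = points - p0
        axial = rel @ axis
        r = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
        base = r[subset].mean() if subset.any() else r.mean()
        radius = float(np.clip(base, *radius_band))
        ax_center = float(np.median(axial[subset]))
        new_attached = (np.abs(r - radius) <= attach_tol) & (
            np.abs(axial - ax_center) <= MAX_HEIGHT_NM / 2
        )
        if new_attached.sum() >= 5:
            if (new_attached == attached).all() and not subset.all():
                attached = new_attached
                break
            attached = new_attached
            subset = new_attached.copy()
        else:
            attached = new_attached
            break
    if attached.sum() >= 3:
        # final radius from attached points only, no clipping
        radius = float(r[attached].mean())
        attached = (np.abs(r - radius) <= attach_tol) & (
            np.abs(axial - ax_center) <= MAX_HEIGHT_NM / 2
        )
    return p0, attached, radius, r


def fit_nucleosome(
    points: np.ndarray,
    config: PipelineConfig | None = None,
    axis: np.ndarray | None = None,
) -> NucleosomeFit:
    """Fit a single-nucleosome cylinder to a candidate point window.

    Each principal axis of the window is tried as the cylinder axis (the
    disk axis of a flat nucleosome is the *minor* principal direction, but
    noise can reorder the spectrum); the candidate attaching the most
    points with the smallest residual wins.  A fit is accepted when at
    least 5 probes attach (the 5-10 probes a nucleosome's AT content
    admits) and the diameter falls in the nucleosome band.
    """
    config = config or PipelineConfig()
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 5:
        raise ValueError(f"nucleosome fit needs >= 5 points, got {len(points)}")
    band = tuple(config.nucleosome_band_nm)
    tol = config.attach_tol_nm

    if axis is not None:
        candidates = [np.asarray(axis, float)]
    else:
        centroid = points.mean(axis=0)
        centered = points - centroid
        cov = centered.T @ centered / max(len(points) - 1, 1)
        _, evecs = np.linalg.eigh(cov)
        candidates = [evecs[:, k] for k in range(3)]

    def _evaluate(cands):
        best = None
        for cand in cands:
            try:
                p0, attached, radius, r = _fit_disk_cylinder(
                    points, cand, tol, RADIUS_BAND_NM
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            n_att = int(attached.sum())
            rms = (
                float(np.sqrt(np.mean((r[attached] - radius) ** 2)))
                if n_att
                else float("inf")
            )
            key = (-n_att, rms)
            if best is None or key < best[0]:
                best = (key, cand / np.linalg.norm(cand), p0, attached, radius, r)
        return best

    best = _evaluate(candidates)
    if axis is None and (
        best is None or int(best[3].sum()) < max(5, len(points) // 2)
    ):
        # heavily contaminated windows defeat the PCA axes; retry with a
        # deterministic hemisphere grid of directions (golden spiral)
        k = np.arange(16)
        zg = (k + 0.5) / 16
        phi = k * np.pi * (3 - np.sqrt(5))
        sg = np.sqrt(1 - zg**2)
        grid = np.column_stack([sg * np.cos(phi), sg * np.sin(phi), zg])
        fallback = _evaluate(list(grid))
        if fallback is not None and (best is None or fallback[0] < best[0]):
            best = fallback

    if best is None:
        raise DegenerateGeometryError("no cylinder axis candidate converged")
    _, ax, p0, attached, radius, r = best
    rel = points - p0
    axial = rel @ ax
    if attached.any():
        height = float(axial[attached].max() - axial[attached].min())
        base = p0 + axial[attached].min() * ax
    else:
        height = 0.0
        base = p0
    n_att = int(attached.sum())
    ss_res = float(np.sum((r[attached] - radius) ** 2)) if n_att else 0.0
    perp = rel - np.outer(axial, ax)
    pc = perp[attached] - perp[attached].mean(axis=0) if n_att else perp
    ss_tot = float(np.sum(pc**2))
    r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - ss_res / ss_tot
    cyl = CylinderModel(
        base_point=base,
        axis=ax,
        radius=radius,
        length=height,
        rms_radial_residual=float(np.sqrt(ss_res / max(n_att, 1))),
        r_squared=r2,
        n_points=len(points),
    )
    diameter = 2 * radius
    accepted = n_att >= 5 and band[0] <= diameter <= band[1]
    return NucleosomeFit(cyl, len(points), n_att, tol, attached, accepted)


# ---------------------------------------------------------------------------
# dimer fit
# ---------------------------------------------------------------------------

def _two_means_1d(values: np.ndarray) -> np.ndarray:
    """Optimal 1D two-class split (exhaustive over sorted cut points).

    Returns a boolean mask for the upper class.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = len(v)
    best_cut, best_cost = 1, math.inf
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    for k in range(1, n):
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        cost = (q1 - s1**2 / k) + (q2 - s2**2 / (n - k))
        if cost < best_cost - 1e-15:
            best_cost, best_cut = cost, k
    upper = np.zeros(n, bool)
    upper[order[best_cut:]] = True
    return upper


def fit_dimer(points: np.ndarray, config: PipelineConfig | None = None) -> DimerFit | None:
    """Fit two coaxial stacked nucleosome cylinders to >= 10 points.

    A shared axis candidate (each principal direction is tried) splits the
    axial coordinates by an exact 1D two-means partition; both halves are
    then fitted as nucleosomes with the shared axis fixed.  Returns the
    accepted dimer, or ``None`` when no axis yields two accepted halves.
    """
    config = config or PipelineConfig()
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 10:
        raise ValueError(f"dimer fit needs >= 10 points, got {len(points)}")
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / max(len(points) - 1, 1)
    _, evecs = np.linalg.eigh(cov)

    best: DimerFit | None = None
    for k in (2, 1, 0):
        ax = evecs[:, k]
        axial = centered @ ax
        upper = _two_means_1d(axial)
        if upper.sum() < 5 or (~upper).sum() < 5:
            continue
        try:
            f1 = fit_nucleosome(points[~upper], config, axis=ax)
            f2 = fit_nucleosome(points[upper], config, axis=ax)
        except (ValueError, DegenerateGeometryError):
            continue
        if not (f1.accepted and f2.accepted):
            continue
        c1 = f1.cylinder.base_point + f1.cylinder.axis * f1.cylinder.length / 2
        c2 = f2.cylinder.base_point + f2.cylinder.axis * f2.cylinder.length / 2
        offset = float(abs((c2 - c1) @ (ax / np.linalg.norm(ax))))
        cand = DimerFit(f1, f2, ax, offset, True)
        if best is None or (f1.n_attached + f2.n_attached) > (
            best.first.n_attached + best.second.n_attached
        ):
            best = cand
    return best


# ---------------------------------------------------------------------------
# diameter statistics
# ---------------------------------------------------------------------------

def diameter_histogram(
    fits: list, bin_nm: float = 0.5, max_diameter_nm: float = 13.0
) -> dict:
    """Histogram of fitted diameters below ``max_diameter_nm`` with peaks.

    ``fits`` may mix :class:`NucleosomeFit` and :class:`RingModel` objects
    (anything exposing ``diameter``).  Peaks are bins whose count exceeds
    both neighbors (boundary bins compare against their single neighbor).
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be positive")
    diameters = np.array([f.diameter for f in fits], float)
    diameters = diameters[diameters < max_diameter_nm]
    if len(diameters) == 0:
        return {"counts": np.empty(0, int), "edges": np.empty(0), "peaks_nm": []}
    lo = math.floor(diameters.min() / bin_nm) * bin_nm
    edges = np.arange(lo, max_diameter_nm + bin_nm / 2, bin_nm)
    counts, edges = np.histogram(diameters, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    peaks = []
    for i, c in enumerate(counts):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < len(counts) - 1 else -1
        if c > left and c > right and c > 0:
            peaks.append(float(centers[i]))
    return {"counts": counts, "edges": edges, "peaks_nm": peaks}


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def extract_nucleosomes(
    points: np.ndarray, config: PipelineConfig | None = None
) -> list[NucleosomeFit]:
    """Greedy nucleosome extraction from one cluster's point cloud.

    Repeatedly centers a cubic window (edge ``nucleosome_window_nm``) on
    the densest unclaimed localization, fits a nucleosome, and claims the
    attached points of accepted fits.  Seeds whose window fails are not
    revisited; extraction stops when no seed yields an accepted fit.  Each
    localization is claimed by at most one fit.
    """
    config = config or PipelineConfig()
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    half = config.nucleosome_window_nm / 2
    claimed = np.zeros(n, bool)
    exhausted = np.zeros(n, bool)
    fits: list[NucleosomeFit] = []
    tree = cKDTree(points)
    neighbor_lists = tree.query_ball_tree(tree, half)

    while True:
        avail = ~claimed & ~exhausted
        if not avail.any():
            break
        density = np.array(
            [
                np.count_nonzero(~claimed[neighbor_lists[i]]) if avail[i] else -1
                for i in range(n)
            ]
        )
        order = np.argsort(-density, kind="stable")
        progressed = False
        for seed in order:
            if not avail[seed]:
                continue
            center = points[seed]
            in_win = np.all(np.abs(points - center) <= half, axis=1) & ~claimed
            idx = np.flatnonzero(in_win)
            if len(idx) < 5:
                exhausted[seed] = True
                continue
            try:
                fit = fit_nucleosome(points[idx], config)
            except (ValueError, DegenerateGeometryError):
                exhausted[seed] = True
                continue
            if fit.accepted:
                fits.append(fit)
                claimed[idx[fit.attached_mask]] = True
                progressed = True
                break
            exhausted[seed] = True
        if not progressed:
            break
    return fits


def classify_region(
    table: LocalizationTable,
    labeling: ClusterLabeling,
    config: PipelineConfig | None = None,
    region_id: int = 0,
) -> RegionClassification:
    """Classify a region's localizations by nucleosome content.

    Noise localizations are scattered signal.  Each cluster undergoes
    greedy nucleosome extraction; its localizations count toward the
    scattered (0 accepted fits), mono/di-nucleosome (1-2 fits) or
    nucleosome-polymer (>= 3 fits) fraction.  Fractions are per
    localization over the whole region.
    """
    config = config or PipelineConfig()
    labels = labeling.labels
    if len(labels) != len(table):
        raise ValueError("labeling does not cover the table")
    n = len(table)
    if n == 0:
        return RegionClassification(region_id, 0, 0.0, 0.0, 0.0, {}, undefined=True)
    coords = table.coords()
    n_scattered = int(np.count_nonzero(labels == -1))
    n_12 = 0
    n_3plus = 0
    fits_per_cluster: dict[int, int] = {}
    for label in range(labeling.n_clusters):
        idx = np.flatnonzero(labels == label)
        fits = extract_nucleosomes(coords[idx], config)
        fits_per_cluster[label] = len(fits)
        if len(fits) == 0:
            n_scattered += len(idx)
        elif len(fits) <= 2:
            n_12 += len(idx)
        else:
            n_3plus += len(idx)
    return RegionClassification(
        region_id,
        n,
        n_scattered / n,
        n_12 / n,
        n_3plus / n,
        fits_per_cluster,
    )
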