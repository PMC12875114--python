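"""Fourier ring correlation (FRC) resolution and localization precision.

FRC renders two statistically independent half-sets of the localizations
as 2D histogram images, cross-correlates their Fourier transforms over
rings of constant spatial frequency, and reads the resolution off the
first crossing of the (lightly smoothed) curve below a fixed threshold —
1/7 by convention.  3D data are projected to the xy plane.

Localization precision is estimated from repeated sightings of the same
emitter: the pooled within-group standard deviation per axis, reported as
an FWHM via the Gaussian relation FWHM = 2 sqrt(2 ln 2) sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import sigma_to_fwhm


@dataclass
class FrcCurve:
    spatial_frequency: np.ndarray  # 1/nm, strictly increasing
    correlation: np.ndarray  # raw FRC per ring
    smoothed: np.ndarray  # 3-bin centered moving average
    threshold: float
    resolution_nm: float
    crossed: bool
    pixel_nm: float


@dataclass
class PrecisionEstimate:
    fwhm_nm: np.ndarray  # per axis
    sigma_nm: np.ndarray
    n_sightings: int
    n_groups: int
    degenerate: bool = False


def _render(points: np.ndarray, origin: np.ndarray, shape: int, pixel_nm: float) -> np.ndarray:
    ij = np.floor((points - origin) / pixel_nm).astype(int)
    ok = (ij >= 0).all(axis=1) & (ij < shape).all(axis=1)
    ij = ij[ok]
    img = np.zeros((shape, shape))
    np.add.at(img, (ij[:, 1], ij[:, 0]), 1.0)
    return img


def split_half_sets(
    points: np.ndarray,
    uids: np.ndarray | None = None,
    rule: str = "odd-even",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split localizations into two half-sets.

    ``odd-even`` (default) interleaves by uid — deterministic and robust
    to density gradients; ``random`` uses the provided generator;
    ``duplicate`` returns the full set twice (a self-consistency control
    whose FRC is identically 1).
    """
    n = len(points)
    if rule == "duplicate":
        return points, points
    if rule == "random":
        if rng is None:
            raise ValueError("random split requires an rng")
        mask = rng.uniform(size=n) < 0.5
    elif rule == "odd-even":
        ids = uids if uids is not None else np.arange(n)
        mask = np.asarray(ids) % 2 == 0
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    return points[mask], points[~mask]


def compute_frc(
    points2d: np.ndarray,
    pixel_nm: float = 2.0,
    split_rule: str = "odd-even",
    uids: np.ndarray | None = None,
    threshold: float = 1.0 / 7.0,
    rng: np.random.Generator | None = None,
) -> FrcCurve:
    """Fourier ring correlation of a 2D localization data set.

    The two half-set images share a common square grid covering the data.
    FRC(q) = Re(sum F1 F2*) / sqrt(sum |F1|^2 sum |F2|^2) over rings one
    frequency bin wide; the curve is smoothed by a centered 3-bin moving
    average before the threshold crossing is located.
    """
    points2d = np.atleast_2d(np.asarray(points2d, float))[:, :2]
    if len(points2d) < 2:
        raise ValueError("FRC needs at least 2 localizations")
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    span = points2d.max(axis=0) - points2d.min(axis=0)
    if np.all(span == 0):
        # all localizations identical: the image carries no structure
        q = np.array([0.0])
        return FrcCurve(q, np.ones(1), np.ones(1), threshold,
                        2 * pixel_nm, False, pixel_nm)
    shape = int(math.ceil(span.max() / pixel_nm)) + 1
    shape += shape % 2  # even for a clean Nyquist bin
    origin = points2d.min(axis=0)

    half1, half2 = split_half_sets(points2d, uids, split_rule, rng)
    img1 = _render(half1, origin, shape, pixel_nm)
    img2 = _render(half2, origin, shape, pixel_nm)

    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    c = shape // 2
    yy, xx = np.indices((shape, shape))
    ring = np.round(np.hypot(xx - c, yy - c)).astype(int)
    n_rings = shape // 2
    flat = ring.ravel()
    num = np.bincount(flat, weights=(f1 * np.conj(f2)).real.ravel(), minlength=n_rings)
    den1 = np.bincount(flat, weights=(np.abs(f1) ** 2).ravel(), minlength=n_rings)
    den2 = np.bincount(flat, weights=(np.abs(f2) ** 2).ravel(), minlength=n_rings)
    num, den1, den2 = num[:n_rings], den1[:n_rings], den2[:n_rings]
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(den1 * den2)
    frc = np.nan_to_num(frc, nan=0.0)
    q = np.arange(n_rings) / (shape * pixel_nm)  # cycles per nm

    smoothed = frc.copy()
    if len(frc) >= 3:
        kernel = np.ones(3) / 3
        inner = np.convolve(frc, kernel, mode="valid")
        smoothed[1:-1] = inner

    res, crossed = _first_crossing(q, smoothed, threshold, pixel_nm)
    return FrcCurve(q, frc, smoothed, threshold, res, crossed, pixel_nm)


def _first_crossing(
    q: np.ndarray, curve: np.ndarray, threshold: float, pixel_nm: float
) -> tuple[float, bool]:
    for i in range(1, len(curve)):
        if curve[i] < threshold <= curve[i - 1]:
            # linear interpolation between bins i-1 and i
            f = (curve[i - 1] - threshold) / (curve[i - 1] - curve[i])
            qc = q[i - 1] + f * (q[i] - q[i - 1])
            if qc > 0:
                return 1.0 / qc, True
    return 2 * pixel_nm, False


def frc_resolution(curve: FrcCurve, threshold: float | None = None) -> tuple[float, bool]:
    """Resolution (nm) at the first downward threshold crossing of a curve.

    Returns ``(resolution_nm, crossed)``; when the smoothed curve never
    drops below the threshold the Nyquist limit ``2 * pixel_nm`` is
    returned with ``crossed=False``.
    """
    thr = curve.threshold if threshold is None else threshold
    return _first_crossing(curve.spatial_frequency, curve.smoothed, thr, curve.pixel_nm)


def estimate_precision(groups: list[np.ndarray]) -> PrecisionEstimate:
    """Per-axis localization precision from repeated sightings.

    ``groups`` holds one (n_i, d) array of sightings per emitter.  The
    pooled within-group standard deviation per axis is converted to FWHM.
    Groups with a single sighting contribute nothing; if no group has
    two or more sightings the precision is undefined.
    """
    usable = [np.atleast_2d(np.asarray(g, float)) for g in groups]
    usable = [g for g in usable if len(g) >= 2]
    if not usable:
        raise ValueError("precision undefined: all emitter groups are singletons")
    d = usable[0].shape[1]
    ss = np.zeros(d)
    dof = 0
    n_sight = 0
    for g in usable:
        ss += ((g - g.mean(axis=0)) ** 2).sum(axis=0)
        dof += len(g) - 1
        n_sight += len(g)
    sigma = np.sqrt(ss / dof)
    fwhm = sigma_to_fwhm(sigma)
    return PrecisionEstimate(
        fwhm_nm=fwhm,
        sigma_nm=sigma,
        n_sightings=n_sight,
        n_groups=len(usable),
        degenerate=bool(np.any(sigma == 0)),
    )
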