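"""Pipeline configuration.

All length-like parameters are in nanometres.  The defaults encode the
biophysical constants of the assay: a minor-groove DNA dye with a 12-bp
footprint that can cover at most 80% of the AT-rich nucleosomal DNA, an
11-nm nucleosome disk, and a Fourier-ring-correlation threshold of 1/7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

#: Gaussian FWHM = _FWHM_PER_SIGMA * sigma.
FWHM_PER_SIGMA: float = 2.3548200450309493  # 2 * sqrt(2 * ln 2)

#: Per-axis localization precision of the instrument, FWHM in nm (x, y, z).
DEFAULT_PRECISION_FWHM_NM: tuple[float, float, float] = (1.08, 0.96, 0.63)


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    """Convert a Gaussian standard deviation to its full width at half maximum."""
    return sigma * FWHM_PER_SIGMA


@dataclass
class PipelineConfig:
    """Tunable parameters of the chromatin-structure pipeline.

    Attributes
    ----------
    dbscan_eps:
        Neighborhood radius (nm) for density-based clustering of
        localizations into condensed-signal clusters.
    dbscan_min_pts:
        Minimum neighbor count (including the point itself) for a core point.
    probe_footprint_bp:
        DNA footprint of one bound probe molecule in base pairs.
    max_coverage_fraction:
        Maximum fraction of a DNA stretch the probe can cover; used to
        convert probe counts into base-pair estimates.
    nucleosomal_dna_bp:
        Base pairs of DNA wrapped on one nucleosome used for probe-count
        arithmetic (the outer ~140 bp accessible to the dye).
    nucleosome_diameter_nm:
        Nominal nucleosome disk diameter.
    ratio_threshold:
        Spectral-ratio threshold separating the DNA dye channel from the
        antibody label channel in dual-color data.
    frc_threshold:
        Correlation threshold at which FRC resolution is read off.
    frc_pixel_nm:
        Pixel size for rendering half-set images before the FRC.
    attach_tol_nm:
        Radial residual below which a localization counts as attached to a
        fitted nucleosome cylinder (about three localization sigmas).
    segment_window_nm:
        Window length along the fiber axis for piecewise cylinder fits.
    segment_merge_tol:
        Relative diameter difference below which adjacent segments merge.
    nucleosome_window_nm:
        Edge length of the cubic candidate domain for single-nucleosome fits.
    nucleosome_band_nm:
        Accepted fitted-diameter band for nucleosome-scale cylinders.
    rng_seed:
        Seed for every stochastic stage of the pipeline.
    """

    dbscan_eps: float = 20.0
    dbscan_min_pts: int = 5
    probe_footprint_bp: int = 12
    max_coverage_fraction: float = 0.8
    nucleosomal_dna_bp: int = 140
    nucleosome_diameter_nm: float = 11.0
    ratio_threshold: float = 0.415
    frc_threshold: float = 1.0 / 7.0
    frc_pixel_nm: float = 2.0
    attach_tol_nm: float = 1.5
    segment_window_nm: float = 25.0
    segment_merge_tol: float = 0.20
    nucleosome_window_nm: float = 18.0
    nucleosome_band_nm: tuple[float, float] = (9.0, 14.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dbscan_eps", "attach_tol_nm", "segment_window_nm",
                     "nucleosome_diameter_nm", "frc_pixel_nm", "nucleosome_window_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.probe_footprint_bp <= 0 or self.nucleosomal_dna_bp <= 0:
            raise ValueError("base-pair parameters must be positive")
        if not 0 < self.max_coverage_fraction <= 1:
            raise ValueError("max_coverage_fraction must be in (0, 1]")
        if not 0 < self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be in (0, 1)")
        if not 0 < self.frc_threshold < 1:
            raise ValueError("frc_threshold must be in (0, 1)")
        if self.dbscan_min_pts < 1:
            raise ValueError("dbscan_min_pts must be >= 1")
        lo, hi = self.nucleosome_band_nm
        if not 0 < lo < hi:
            raise ValueError("nucleosome_band_nm must be an increasing positive pair")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a config from a flat YAML mapping; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        if "nucleosome_band_nm" in data:
            data["nucleosome_band_nm"] = tuple(data["nucleosome_band_nm"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["nucleosome_band_nm"] = list(self.nucleosome_band_nm)
        return out

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
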