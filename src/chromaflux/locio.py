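"""Localization-table input/output, validation and region-of-interest filtering.

The central container is :class:`LocalizationTable`: an ordered set of
single-fluorophore sightings, each with a 3D (or 2D) position in nm, an
acquisition timestamp in microseconds, a photon count and, for dual-color
acquisitions, two spectral-detector counts.  The canonical on-disk form is
a delimited text file with header ``uid,x_nm,y_nm,z_nm,t_us,photons,ch1,ch2``
preceded by a ``# units=nm`` comment line; alternative delimited dialects
(different column names, coordinates in micrometres) are described by a
:class:`TableDialect`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_PRECISION_FWHM_NM

CANONICAL_COLUMNS = ["uid", "x_nm", "y_nm", "z_nm", "t_us", "photons", "ch1", "ch2"]

_UNIT_SCALE_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "μm": 1000.0}


class FormatError(ValueError):
    """A localization file does not conform to the declared dialect."""


@dataclass(frozen=True)
class TableDialect:
    """Describes a delimited localization-table layout.

    ``unit`` applies to the coordinate columns; coordinates are always
    converted to nm on load.  A ``# units=<unit>`` comment on the first
    line of the file overrides ``unit``.
    """

    delimiter: str = ","
    x: str = "x_nm"
    y: str = "y_nm"
    z: str | None = "z_nm"
    t: str | None = "t_us"
    photons: str | None = "photons"
    ch1: str | None = "ch1"
    ch2: str | None = "ch2"
    unit: str = "nm"


CANONICAL_DIALECT = TableDialect()


@dataclass
class LocalizationTable:
    """Validated set of localizations with nm coordinates.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; optional
    columns (``t_us``, ``photons``, ``ch1``, ``ch2``) hold NaN when absent
    from the source.  ``dim`` is 2 when every z is identical (2D
    acquisitions are stored with z = 0 by convention).
    """

    frame: pd.DataFrame
    precision_fwhm: tuple[float, float, float] = DEFAULT_PRECISION_FWHM_NM
    units: str = "nm"

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"table missing canonical columns: {missing}")
        f = self.frame
        xyz = f[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        if not np.isfinite(xyz).all():
            raise FormatError("coordinates must be finite")
        if f["uid"].duplicated().any():
            raise FormatError("uid values must be unique")
        for col in ("photons", "ch1", "ch2"):
            vals = f[col].to_numpy(float)
            if (vals[~np.isnan(vals)] < 0).any():
                raise FormatError(f"{col} must be non-negative")

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dim(self) -> int:
        z = self.frame["z_nm"].to_numpy(float)
        return 2 if len(z) == 0 or np.all(z == z[0]) else 3

    @property
    def uids(self) -> np.ndarray:
        return self.frame["uid"].to_numpy(int)

    def coords(self, dim: int = 3) -> np.ndarray:
        """Positions as an (n, dim) float array in nm."""
        cols = ["x_nm", "y_nm", "z_nm"][:dim]
        return self.frame[cols].to_numpy(float)

    def sort_by_time(self) -> "LocalizationTable":
        """Stable sort by timestamp, ties broken by uid."""
        f = self.frame.sort_values(["t_us", "uid"], kind="stable").reset_index(drop=True)
        return LocalizationTable(f, self.precision_fwhm, self.units)

    @classmethod
    def from_arrays(
        cls,
        xyz: np.ndarray,
        t: np.ndarray | None = None,
        photons: np.ndarray | None = None,
        ch1: np.ndarray | None = None,
        ch2: np.ndarray | None = None,
        uid: np.ndarray | None = None,
        precision_fwhm: tuple[float, float, float] = DEFAULT_PRECISION_FWHM_NM,
    ) -> "LocalizationTable":
        xyz = np.atleast_2d(np.asarray(xyz, float))
        n = len(xyz)
        if xyz.shape[1] == 2:
            xyz = np.column_stack([xyz, np.zeros(n)])
        nan = np.full(n, np.nan)
        frame = pd.DataFrame(
            {
                "uid": np.arange(n) if uid is None else np.asarray(uid, int),
                "x_nm": xyz[:, 0],
                "y_nm": xyz[:, 1],
                "z_nm": xyz[:, 2],
                "t_us": nan if t is None else np.asarray(t, float),
                "photons": nan if photons is None else np.asarray(photons, float),
                "ch1": nan if ch1 is None else np.asarray(ch1, float),
                "ch2": nan if ch2 is None else np.asarray(ch2, float),
            }
        )
        return cls(frame, precision_fwhm)


def read_localizations(
    path: str | Path, dialect: TableDialect = CANONICAL_DIALECT
) -> LocalizationTable:
    """Read a delimited localization table and convert coordinates to nm.

    The first line may be a comment ``# units=<nm|um>`` declaring the
    coordinate unit; otherwise the dialect's unit applies.  ``dim`` is
    inferred from the presence of the z column.
    """
    path = Path(path)
    text = path.read_text()
    unit = dialect.unit
    if text.startswith("#"):
        header_line, _, rest = text.partition("\n")
        for tokenset in header_line.lstrip("#").split():
            if tokenset.startswith("units="):
                unit = tokenset.split("=", 1)[1]
        text = rest
    if unit not in _UNIT_SCALE_NM:
        raise FormatError(f"unknown coordinate unit {unit!r}")
    scale = _UNIT_SCALE_NM[unit]

    try:
        raw = pd.read_csv(io.StringIO(text), sep=dialect.delimiter)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    for required in (dialect.x, dialect.y):
        if required not in raw.columns:
            raise FormatError(f"missing coordinate column {required!r} in {path}")

    def _numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(raw[col], errors="coerce").to_numpy(float)
        raw_nonempty = raw[col].notna().to_numpy()
        bad = np.isnan(vals) & raw_nonempty
        if bad.any():
            row = int(np.argmax(bad))
            raise FormatError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}"
            )
        return vals

    n = len(raw)
    x = _numeric(dialect.x) * scale
    y = _numeric(dialect.y) * scale
    has_z = dialect.z is not None and dialect.z in raw.columns
    z = _numeric(dialect.z) * scale if has_z else np.zeros(n)

    def _optional(col: str | None) -> np.ndarray | None:
        if col is not None and col in raw.columns:
            return _numeric(col)
        return None

    uid = None
    if "uid" in raw.columns:
        uid = _numeric("uid").astype(int)
    table = LocalizationTable.from_arrays(
        np.column_stack([x, y, z]),
        t=_optional(dialect.t),
        photons=_optional(dialect.photons),
        ch1=_optional(dialect.ch1),
        ch2=_optional(dialect.ch2),
        uid=uid,
    )
    return table


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table in the canonical CSV dialect (nm, ``# units=nm`` header).

    Output is byte-stable for a fixed table so that repeated exports of the
    same data compare equal.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("# units=nm\n")
    frame = table.frame[CANONICAL_COLUMNS].copy()
    frame["uid"] = frame["uid"].astype(int)
    frame.to_csv(buf, index=False, float_format="%.9g", lineterminator="\n")
    path.write_text(buf.getvalue())


def filter_roi(table: LocalizationTable, box: Sequence[Sequence[float]]) -> LocalizationTable:
    """Keep localizations inside an axis-aligned half-open box.

    ``box`` is ``((xmin, xmax), (ymin, ymax), (zmin, zmax))`` in nm; the
    z range may be omitted for 2D selections.  Boundaries are closed on the
    low edge and open on the high edge so that tiling boxes partition space
    exactly.  Record order is preserved.
    """
    box = [tuple(map(float, b)) for b in box]
    for lo, hi in box:
        if not lo < hi:
            raise ValueError(f"degenerate ROI box: min {lo} >= max {hi}")
    coords = table.coords(dim=len(box))
    mask = np.ones(len(table), bool)
    for axis, (lo, hi) in enumerate(box):
        mask &= (coords[:, axis] >= lo) & (coords[:, axis] < hi)
    frame = table.frame.loc[mask].reset_index(drop=True)
    return LocalizationTable(frame, table.precision_fwhm, table.units)
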