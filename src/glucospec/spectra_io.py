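"""Data model and I/O for NIR spectra and reference chemistry.

Spectra are absorbance (log10 of 1/reflectance) sampled on a shared,
uniformly spaced wavelength grid — by default 950-1650 nm at 5 nm,
i.e. 141 points. The canonical on-disk dialect is a wide CSV whose
first column is ``sample_id`` and whose remaining headers are numeric
wavelengths in nm; reference chemistry travels in a separate CSV with
columns ``sample_id, gbs_fresh, gbs_dry, dry_matter_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, SpectraParseError

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectrumSet",
    "ReferenceTable",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "average_replicates",
    "absorbance_from_reflectance",
]

_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, strictly increasing wavelength axis in nanometres."""

    start: float = 950.0
    stop: float = 1650.0
    step: float = 5.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop <= self.start:
            raise FormatError(
                f"invalid grid: start={self.start}, stop={self.stop}, step={self.step}"
            )
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-6:
            raise FormatError(
                f"grid step {self.step} does not divide range [{self.start}, {self.stop}]"
            )

    @property
    def points(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.size)

    @property
    def size(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @classmethod
    def from_points(cls, points: np.ndarray) -> "WavelengthGrid":
        points = np.asarray(points, dtype=float)
        if points.ndim != 1 or points.size < 2:
            raise FormatError("a wavelength grid needs at least two points")
        diffs = np.diff(points)
        if np.any(diffs <= 0):
            raise FormatError("wavelength header is not strictly increasing")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=_GRID_RTOL, atol=1e-9):
            raise FormatError("wavelength header is not uniformly spaced")
        return cls(float(points[0]), float(points[-1]), float(step))


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum tied to a sample identifier."""

    sample_id: str
    values: np.ndarray
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.size,):
            raise FormatError(
                f"spectrum '{self.sample_id}' has {values.size} values for a "
                f"{self.grid.size}-point grid"
            )
        if not np.all(np.isfinite(values)):
            raise FormatError(f"spectrum '{self.sample_id}' contains non-finite values")


@dataclass
class SpectrumSet:
    """An n x p matrix of absorbance spectra sharing one wavelength grid."""

    grid: WavelengthGrid
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(
            len(self.ids), self.grid.size
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.grid.size

    def validate_unique_ids(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sample ids: {dupes}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.grid.points)
        df.insert(0, "sample_id", self.ids)
        return df

    def copy_with(self, matrix: np.ndarray) -> "SpectrumSet":
        """New set with the same grid/ids and a transformed matrix (no resampling)."""
        return SpectrumSet(self.grid, list(self.ids), matrix)


@dataclass
class ReferenceTable:
    """Per-sample glucobrassicin reference chemistry.

    gbs_fresh is in µmol GBS per 100 g fresh weight, gbs_dry in µmol GBS
    per g dry weight, and the two are linked through the dry-matter
    fraction: gbs_dry = gbs_fresh / (100 * dry_matter_fraction).
    """

    ids: list[str]
    gbs_fresh: np.ndarray
    gbs_dry: np.ndarray
    dry_matter_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        for name in ("gbs_fresh", "gbs_dry", "dry_matter_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise FormatError(f"{name} has length {arr.size}, expected {n}")
            setattr(self, name, arr)
        if np.any(self.gbs_fresh <= 0) or np.any(self.gbs_dry <= 0):
            raise FormatError("GBS concentrations must be positive")
        if np.any((self.dry_matter_fraction <= 0) | (self.dry_matter_fraction >= 1)):
            raise FormatError("dry_matter_fraction must lie in (0, 1)")
        implied = self.gbs_fresh / (100.0 * self.dry_matter_fraction)
        if not np.allclose(implied, self.gbs_dry, rtol=1e-3):
            raise FormatError(
                "gbs_dry inconsistent with gbs_fresh / (100 * dry_matter_fraction)"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def values(self, basis: str) -> np.ndarray:
        if basis == "fresh":
            return self.gbs_fresh
        if basis == "dry":
            return self.gbs_dry
        raise ValueError(f"basis must be 'fresh' or 'dry', got {basis!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.ids,
                "gbs_fresh": self.gbs_fresh,
                "gbs_dry": self.gbs_dry,
                "dry_matter_fraction": self.dry_matter_fraction,
            }
        )


def read_spectra(path: str | Path, dialect: str = "wide_csv") -> SpectrumSet:
    """Read a wide-CSV spectra file: sample_id column + numeric wavelength headers."""
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header: {exc}") from exc
    grid = WavelengthGrid.from_points(wavelengths)
    ids = df["sample_id"].tolist()
    if len(ids) == 0:
        return SpectrumSet(grid, [], np.empty((0, grid.size)))
    body = df.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        row, col = np.argwhere(~np.isfinite(values))[0]
        raise SpectraParseError(
            f"{path}: non-numeric value at row {row + 2} (sample {ids[row]!r}), "
            f"wavelength {wavelengths[col]:g} nm"
        )
    return SpectrumSet(grid, ids, values)


def write_spectra(spectra: SpectrumSet, path: str | Path) -> Path:
    """Write the canonical wide CSV; read_spectra round-trips it exactly."""
    spectra.validate_unique_ids()
    path = Path(path)
    df = spectra.to_frame()
    df.columns = ["sample_id"] + [f"{w:g}" for w in spectra.grid.points]
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_reference(path: str | Path) -> ReferenceTable:
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    required = {"sample_id", "gbs_fresh", "gbs_dry", "dry_matter_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing reference columns {sorted(missing)}")
    return ReferenceTable(
        df["sample_id"].tolist(),
        df["gbs_fresh"].to_numpy(float),
        df["gbs_dry"].to_numpy(float),
        df["dry_matter_fraction"].to_numpy(float),
    )


def write_reference(table: ReferenceTable, path: str | Path) -> Path:
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def average_replicates(
    scans: SpectrumSet, replicate_map: dict[str, str] | None = None
) -> SpectrumSet:
    """Average replicate scans into one spectrum per sample.

    ``replicate_map`` assigns each scan id to a sample id; when omitted the
    scan ids themselves are taken as sample ids (so 184 scans carrying 92
    distinct ids average to 92 spectra). Sample order follows first
    appearance; averaging an already one-scan-per-sample set is the identity.
    """
    if replicate_map is None:
        sample_of = {scan_id: scan_id for scan_id in scans.ids}
    else:
        orphans = [scan_id for scan_id in scans.ids if scan_id not in replicate_map]
        if orphans:
            raise FormatError(f"scans with no replicate mapping: {orphans}")
        sample_of = replicate_map
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for row, scan_id in enumerate(scans.ids):
        sid = sample_of[scan_id]
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(row)
    matrix = np.empty((len(order), scans.p))
    for i, sid in enumerate(order):
        matrix[i] = scans.matrix[groups[sid]].mean(axis=0)
    return SpectrumSet(scans.grid, order, matrix)


def absorbance_from_reflectance(reflectance: np.ndarray | float) -> np.ndarray | float:
    """Convert reflectance in (0, 1] to absorbance, log10(1/R)."""
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0):
        raise ValueError("reflectance must be > 0 for log(1/R)")
    out = -np.log10(r)
    return float(out) if np.isscalar(reflectance) else out
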