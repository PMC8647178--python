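"""Electron-density map I/O and map-quality feature extraction.

The predictive layer characterises a starting electron-density map by four
global statistics of the density histogram — r.m.s.d. about the mean, the
third central moment (skew), and the extreme densities — plus the resolution
of the diffraction data and, for molecular-replacement cases, the sequence
identity of the search model.  A noisy experimental-phasing map has a nearly
symmetric density histogram (low skew), while an interpretable map has a
long positive tail of strong peaks.

Maps are read and written in CCP4/MRC format (data mode 2, 32-bit float)
via gemmi.  All statistics are computed over every stored grid point; no
masking or asymmetric-unit reduction is applied.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "MapFeatureVector",
    "MapError",
    "MapReadError",
    "TruncatedMapError",
    "MapSizeMismatchError",
    "EmptyMapError",
    "DegenerateMapError",
    "PHASING_MODES",
    "FEATURE_COLUMNS",
    "read_map",
    "write_map",
    "density_rmsd",
    "density_skew",
    "density_extrema",
    "extract_features",
    "write_feature_table",
    "read_feature_table",
]

PHASING_MODES = ("experimental", "MR")

#: Column order used by the delimited feature-table format.
FEATURE_COLUMNS = [
    "dataset_id",
    "phasing_mode",
    "resolution",
    "rmsd",
    "skew",
    "max_density",
    "min_density",
    "sequence_identity",
]

_CCP4_HEADER_BYTES = 1024
_MODE_ITEMSIZE = {0: 1, 1: 2, 2: 4, 6: 2}


class MapError(Exception):
    """Base class for density-map failures."""


class MapReadError(MapError):
    """File is unreadable or not a CCP4/MRC map."""


class TruncatedMapError(MapError):
    """File ends before the header-declared data block."""


class MapSizeMismatchError(MapError):
    """Header grid dimensions disagree with the stored sample count."""


class EmptyMapError(MapError):
    """Operation requires at least one density sample."""


class DegenerateMapError(MapError):
    """Operation undefined on a constant (zero-spread) map."""


@dataclass
class DensityMap:
    """A sampled electron-density grid with its crystallographic frame.

    Parameters
    ----------
    values
        3-D array of density samples in arbitrary map units.
    cell
        Unit-cell parameters ``(a, b, c, alpha, beta, gamma)`` with lengths
        in angstroms and angles in degrees.
    origin
        Grid-unit origin of the stored block (CCP4 ``NXSTART/NYSTART/NZSTART``).
    spacegroup_label
        Hermann-Mauguin symbol recorded in the header; informational only.
    """

    values: np.ndarray
    cell: tuple[float, float, float, float, float, float] = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    origin: tuple[int, int, int] = (0, 0, 0)
    spacegroup_label: str = "P 1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"density grid must be 3-D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"grid_shape must be strictly positive, got {self.values.shape}")
        if any(length <= 0 for length in self.cell[:3]):
            raise ValueError(f"cell lengths must be positive, got {self.cell[:3]}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_samples(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class MapFeatureVector:
    """The per-dataset predictor features.

    ``sequence_identity`` (fraction in [0, 1]) is present exactly when
    ``phasing_mode == "MR"``; experimental-phasing datasets have no search
    model to compare against.
    """

    resolution: float
    rmsd: float
    skew: float
    max_density: float
    min_density: float
    phasing_mode: str
    sequence_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phasing_mode not in PHASING_MODES:
            raise ValueError(f"phasing_mode must be one of {PHASING_MODES}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if self.min_density > self.max_density:
            raise ValueError("min_density may not exceed max_density")
        if self.phasing_mode == "MR":
            if self.sequence_identity is None:
                raise ValueError("MR datasets require a sequence_identity")
            if not 0.0 <= self.sequence_identity <= 1.0:
                raise ValueError("sequence_identity must lie in [0, 1]")
        elif self.sequence_identity is not None:
            raise ValueError(
                "sequence_identity is only meaningful for MR datasets; "
                "got one in experimental mode (likely a pipeline wiring error)"
            )

    def feature_values(self) -> dict[str, float]:
        """Numeric features keyed by column name (mode-dependent set)."""
        out = {
            "resolution": self.resolution,
            "rmsd": self.rmsd,
            "skew": self.skew,
            "max_density": self.max_density,
            "min_density": self.min_density,
        }
        if self.phasing_mode == "MR":
            out["sequence_identity"] = float(self.sequence_identity)  # type: ignore[arg-type]
        return out


def _validate_ccp4_sizes(path: Path) -> None:
    """Check header-declared data size against the file size.

    Reads only the fixed 1024-byte header (grid dims at words 1-3, mode at
    word 4, symmetry-block size at word 24) so that truncation and
    header/data inconsistencies surface as distinct errors instead of an
    opaque parser failure.
    """
    size = path.stat().st_size
    if size < _CCP4_HEADER_BYTES:
        raise TruncatedMapError(f"{path}: file shorter than the 1024-byte CCP4 header")
    with open(path, "rb") as fh:
        header = fh.read(_CCP4_HEADER_BYTES)
    stamp = header[212:214]
    endian = "<" if stamp not in (b"\x11\x11", b"\x17\x17") else ">"
    nx, ny, nz, mode = struct.unpack(endian + "4i", header[:16])
    (nsymbt,) = struct.unpack(endian + "i", header[92:96])
    if min(nx, ny, nz) <= 0 or mode not in _MODE_ITEMSIZE:
        raise MapReadError(f"{path}: implausible CCP4 header (grid {nx}x{ny}x{nz}, mode {mode})")
    expected = _CCP4_HEADER_BYTES + max(nsymbt, 0) + nx * ny * nz * _MODE_ITEMSIZE[mode]
    actual_samples = (size - _CCP4_HEADER_BYTES - max(nsymbt, 0)) // _MODE_ITEMSIZE[mode]
    if size < expected:
        raise MapSizeMismatchError(
            f"{path}: header declares {nx}x{ny}x{nz} = {nx * ny * nz} samples "
            f"but the data block holds only {actual_samples}"
        )


def read_map(path: str | Path) -> DensityMap:
    """Read a CCP4/MRC map file into a :class:`DensityMap`.

    Raises
    ------
    MapReadError
        The file is missing, unreadable, or not a CCP4/MRC map.
    TruncatedMapError
        The file ends inside the header.
    MapSizeMismatchError
        The header grid dimensions exceed the stored data block.
    """
    path = Path(path)
    if not path.is_file():
        raise MapReadError(f"{path}: no such file")
    _validate_ccp4_sizes(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapReadError(f"{path}: not a readable CCP4/MRC map ({exc})") from exc
    grid = ccp4.grid
    values = np.array(grid, copy=True)
    cell = grid.unit_cell
    origin = tuple(int(ccp4.header_i32(w)) for w in (5, 6, 7))
    label = grid.spacegroup.hm if grid.spacegroup is not None else "P 1"
    return DensityMap(
        values=values,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        origin=origin,  # type: ignore[arg-type]
        spacegroup_label=label,
    )


def write_map(density_map: DensityMap, path: str | Path) -> None:
    """Write a :class:`DensityMap` as a CCP4 map (data mode 2, float32)."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.values, dtype=np.float32))
    ccp4.grid.unit_cell = gemmi.UnitCell(*density_map.cell)
    try:
        ccp4.grid.spacegroup = gemmi.SpaceGroup(density_map.spacegroup_label)
    except (RuntimeError, ValueError):
        ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(2, True)
    for word, value in zip((5, 6, 7), density_map.origin):
        ccp4.set_header_i32(word, int(value))
    ccp4.write_ccp4_map(str(Path(path)))


def _flat(density_map: DensityMap) -> np.ndarray:
    if density_map.n_samples == 0:
        raise EmptyMapError("map has no density samples")
    return density_map.values.ravel()


def density_rmsd(density_map: DensityMap) -> float:
    """Root-mean-square deviation of the density from the map mean.

    Population convention (divisor N): ``sqrt(mean((v - mean(v))**2))``.
    """
    v = _flat(density_map)
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def density_skew(density_map: DensityMap, standardized: bool = False) -> float:
    """Third central moment of the density histogram.

    By default this is the raw (scale-dependent) moment
    ``mean((v - mean(v))**3)``, in map-units cubed; with
    ``standardized=True`` it is divided by rmsd**3, giving the familiar
    unitless skewness coefficient.
    """
    v = _flat(density_map)
    centered = v - v.mean()
    third = float(np.mean(centered**3))
    if not standardized:
        return third
    rmsd = float(np.sqrt(np.mean(centered**2)))
    if rmsd == 0.0:
        raise DegenerateMapError("standardized skew undefined for a constant map")
    return third / rmsd**3


def density_extrema(density_map: DensityMap) -> tuple[float, float]:
    """Exact ``(min, max)`` density over all grid samples."""
    v = _flat(density_map)
    return float(v.min()), float(v.max())


def extract_features(
    density_map: DensityMap,
    resolution: float,
    phasing_mode: str,
    sequence_identity: Optional[float] = None,
    standardized_skew: bool = False,
) -> MapFeatureVector:
    """Assemble the full predictor vector for one dataset.

    ``resolution`` is the diffraction-data resolution in angstroms, supplied
    as metadata (it is a property of the dataset, not of the sampled grid).
    ``sequence_identity`` must be given exactly when ``phasing_mode`` is
    ``"MR"``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    low, high = density_extrema(density_map)
    return MapFeatureVector(
        resolution=float(resolution),
        rmsd=density_rmsd(density_map),
        skew=density_skew(density_map, standardized=standardized_skew),
        max_density=high,
        min_density=low,
        phasing_mode=phasing_mode,
        sequence_identity=sequence_identity,
    )


def write_feature_table(
    rows: Iterable[tuple[str, MapFeatureVector]], path: str | Path
) -> None:
    """Write ``(dataset_id, feature vector)`` pairs as delimited text.

    The ``sequence_identity`` field is left empty for experimental-phasing
    rows.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FEATURE_COLUMNS)
        for dataset_id, vec in rows:
            writer.writerow(
                [
                    dataset_id,
                    vec.phasing_mode,
                    repr(vec.resolution),
                    repr(vec.rmsd),
                    repr(vec.skew),
                    repr(vec.max_density),
                    repr(vec.min_density),
                    "" if vec.sequence_identity is None else repr(vec.sequence_identity),
                ]
            )


def read_feature_table(path: str | Path) -> list[tuple[str, MapFeatureVector]]:
    """Inverse of :func:`write_feature_table`."""
    out: list[tuple[str, MapFeatureVector]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(FEATURE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
        for row in reader:
            sid = row["sequence_identity"].strip()
            out.append(
                (
                    row["dataset_id"],
                    MapFeatureVector(
                        resolution=float(row["resolution"]),
                        rmsd=float(row["rmsd"]),
                        skew=float(row["skew"]),
                        max_density=float(row["max_density"]),
                        min_density=float(row["min_density"]),
                        phasing_mode=row["phasing_mode"],
                        sequence_identity=float(sid) if sid else None,
                    ),
                )
            )
    return out
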