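"""Raster and occurrence I/O on ESRI ASCII grids.

All layers live on a single shared grid (cell-centre registration); a point
maps to the cell ``col = floor((lon - xll) / cellsize)`` with the row index
flipped so that row 0 is the northernmost row.  Cells are half-open
``[edge, edge + cellsize)`` so edge points deterministically belong to the
cell with the larger index.  No resampling is performed: every layer of a
stack must already share one grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "RasterLayer",
    "EnvStack",
    "OccurrenceSet",
    "FormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrence_csv",
    "write_occurrence_csv",
    "thin_occurrences",
    "extract_values",
    "cell_areas_km2",
]

#: mean kilometres per degree of latitude used for geographic cell areas
KM_PER_DEGREE = 111.32


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: size, lower-left corner, cell size, nodata."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    def aligned_with(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
            and abs(self.nodata_value - other.nodata_value) <= tol
        )

    def point_to_rowcol(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing (lon, lat); raises if the point is outside the extent."""
        col = math.floor((lon - self.xllcorner) / self.cellsize)
        row_from_bottom = math.floor((lat - self.yllcorner) / self.cellsize)
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= col < self.ncols and 0 <= row < self.nrows):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - 1 - row + 0.5) * self.cellsize
        return lon, lat


@dataclass
class RasterLayer:
    """A named single-band raster; ``values`` is a masked array, row 0 = north."""

    name: str
    spec: GridSpec
    values: np.ma.MaskedArray
    kind: str = "continuous"  # continuous | categorical

    def __post_init__(self) -> None:
        arr = np.ma.masked_invalid(np.ma.asarray(self.values, dtype=float))
        if arr.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"layer {self.name!r}: shape {arr.shape} does not match spec "
                f"({self.spec.nrows}, {self.spec.ncols})"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "categorical":
            valid = arr.compressed()
            if valid.size and not np.allclose(valid, np.round(valid)):
                raise ValueError("categorical layer must hold integer codes")
        self.values = arr

    @property
    def mask(self) -> np.ndarray:
        return np.ma.getmaskarray(self.values)

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.name, self.spec, self.values.copy(), self.kind)


@dataclass
class EnvStack:
    """Ordered collection of aligned raster layers (the covariate space)."""

    layers: list[RasterLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        if self.layers:
            ref = self.layers[0].spec
            for l in self.layers[1:]:
                if not l.spec.aligned_with(ref):
                    raise ValueError(f"layer {l.name!r} is not aligned with the stack")

    @property
    def spec(self) -> GridSpec:
        if not self.layers:
            raise ValueError("empty stack")
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> RasterLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.layers)

    def shared_mask(self) -> np.ndarray:
        """True where *any* layer is masked (cell invalid for the stack)."""
        m = np.zeros((self.spec.nrows, self.spec.ncols), dtype=bool)
        for l in self.layers:
            m |= l.mask
        return m

    def subset(self, names: list[str]) -> "EnvStack":
        return EnvStack([self[n].copy() for n in names])

    def valid_table(self) -> pd.DataFrame:
        """Layer values at every shared-valid cell, plus row/col indices."""
        valid = ~self.shared_mask()
        rows, cols = np.nonzero(valid)
        data = {"row": rows, "col": cols}
        for l in self.layers:
            data[l.name] = np.asarray(l.values)[rows, cols]
        return pd.DataFrame(data)


@dataclass
class OccurrenceSet:
    """Presence points of one species, longitude/latitude in decimal degrees."""

    species: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for lon, lat in self.points:
            if not (-180 <= lon <= 180 and -90 <= lat <= 90):
                raise ValueError(f"coordinate out of range: ({lon}, {lat})")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path, name: str | None = None, kind: str = "continuous") -> RasterLayer:
    """Read an ESRI ASCII grid (.asc); nodata cells are masked."""
    path = str(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS:
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric header value") from exc
            else:
                data_lines.append(line)

    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing header key {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    # corner vs centre registration: centre = corner + cellsize/2
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
    else:
        raise FormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise FormatError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", -9999.0)

    tokens: list[str] = []
    for line in data_lines:
        tokens.extend(line.split())
    if len(tokens) != nrows * ncols:
        raise FormatError(
            f"{path}: expected {nrows}x{ncols}={nrows * ncols} values, got {len(tokens)}"
        )
    try:
        arr = np.array(tokens, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data value") from exc

    spec = GridSpec(ncols, nrows, xll, yll, cellsize, nodata)
    masked = np.ma.masked_values(arr, nodata)
    masked = np.ma.masked_invalid(masked)
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(path))[0]
    return RasterLayer(name, spec, masked, kind)


def write_ascii_grid(layer: RasterLayer, path) -> str:
    """Write an ESRI ASCII grid; masked cells become the nodata value."""
    vals = layer.values
    if not np.all(np.isfinite(np.ma.filled(vals, 0.0))):
        raise ValueError("non-finite unmasked values present; mask them first")
    spec = layer.spec
    filled = np.ma.filled(vals, spec.nodata_value)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.xllcorner!r}\n")
        fh.write(f"yllcorner {spec.yllcorner!r}\n")
        fh.write(f"cellsize {spec.cellsize!r}\n")
        fh.write(f"NODATA_value {spec.nodata_value!r}\n")
        for row in filled:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Occurrences


def read_occurrence_csv(path) -> OccurrenceSet:
    """Read a species,longitude,latitude CSV; bad rows are dropped with a warning."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for req in ("species", "longitude", "latitude"):
        if req not in cols:
            raise FormatError(f"{path}: missing column {req!r}")
    species = str(df[cols["species"]].iloc[0]) if len(df) else ""
    points: list[tuple[float, float]] = []
    for i, row in df.iterrows():
        try:
            lon = float(row[cols["longitude"]])
            lat = float(row[cols["latitude"]])
        except (TypeError, ValueError):
            logger.warning("%s: row %d has unparseable coordinates; skipped", path, i + 2)
            continue
        if not (-180 <= lon <= 180 and -90 <= lat <= 90):
            logger.warning("%s: row %d coordinate out of bounds; skipped", path, i + 2)
            continue
        points.append((lon, lat))
    return OccurrenceSet(species, points)


def write_occurrence_csv(occ: OccurrenceSet, path) -> str:
    df = pd.DataFrame(occ.points, columns=["longitude", "latitude"])
    df.insert(0, "species", occ.species)
    df.to_csv(path, index=False)
    return str(path)


def thin_occurrences(occ: OccurrenceSet, spec: GridSpec) -> OccurrenceSet:
    """Keep at most one point per grid cell (the first in input order)."""
    seen: set[tuple[int, int]] = set()
    kept: list[tuple[float, float]] = []
    for lon, lat in occ.points:
        try:
            cell = spec.point_to_rowcol(lon, lat)
        except ValueError:
            logger.warning("occurrence (%s, %s) outside grid; dropped", lon, lat)
            continue
        if cell not in seen:
            seen.add(cell)
            kept.append((lon, lat))
    return OccurrenceSet(occ.species, kept)


def extract_values(stack: EnvStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Layer values at each point's cell (nearest cell, no interpolation).

    Returns one row per point with columns longitude, latitude, row, col,
    one column per layer, and a boolean ``valid`` flag; points on masked
    cells or outside the extent have ``valid=False`` and NaN values.
    """
    spec = stack.spec
    shared_bad = stack.shared_mask()
    records = []
    for lon, lat in occ.points:
        rec: dict = {"longitude": lon, "latitude": lat}
        try:
            row, col = spec.point_to_rowcol(lon, lat)
        except ValueError:
            logger.warning("point (%s, %s) outside extent; excluded", lon, lat)
            rec.update({"row": -1, "col": -1, "valid": False})
            for l in stack.layers:
                rec[l.name] = np.nan
            records.append(rec)
            continue
        rec["row"], rec["col"] = row, col
        if shared_bad[row, col]:
            logger.warning("point (%s, %s) falls on a masked cell; excluded", lon, lat)
            rec["valid"] = False
            for l in stack.layers:
                rec[l.name] = np.nan
        else:
            rec["valid"] = True
            for l in stack.layers:
                rec[l.name] = float(l.values[row, col])
        records.append(rec)
    return pd.DataFrame.from_records(records)


def cell_areas_km2(spec: GridSpec, degrees: bool = True) -> np.ndarray:
    """Per-row cell areas in km², broadcast to the full grid.

    For a degree grid the area of a cell at latitude φ is
    (cellsize · 111.32 km)² · cos φ; for a metre grid it is cellsize² / 10⁶.
    """
    if not degrees:
        area = (spec.cellsize / 1000.0) ** 2
        return np.full((spec.nrows, spec.ncols), area)
    rows = np.arange(spec.nrows)
    lat_centers = spec.yllcorner + (spec.nrows - 1 - rows + 0.5) * spec.cellsize
    row_area = (spec.cellsize * KM_PER_DEGREE) ** 2 * np.cos(np.deg2rad(lat_centers))
    return np.repeat(row_area[:, None], spec.ncols, axis=1)
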