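"""Raster, vector and tabular I/O with explicit geotransform conventions.

All coordinates are projected easting/northing in meters (abstract metric
grid, no CRS handling). Rasters are north-up with square pixels: row index
increases southward, column index increases eastward. The canonical on-disk
raster format is the ESRI ASCII grid (``.asc``) — text-diffable and
lossless at the stored precision; a five-band reflectance stack is a set of
sibling files ``<stem>.<band>.asc``. Plot polygons travel as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping as geom_mapping, shape as geom_shape

BAND_NAMES = ("B", "G", "R", "RE", "NIR")

_NODATA = -99999.0


class GeoIOError(ValueError):
    """Raised when a file violates the raster/vector/table contracts."""


@dataclass(frozen=True)
class GeoTransform:
    """North-up geotransform with square pixels.

    ``origin_easting``/``origin_northing`` locate the *outer corner* of the
    top-left pixel; pixel (row, col) covers the half-open square
    ``[E0 + col*s, E0 + (col+1)*s) x (N0 - (row+1)*s, N0 - row*s]``.
    """

    origin_easting: float
    origin_northing: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise GeoIOError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def pixel_area(self) -> float:
        return self.pixel_size * self.pixel_size

    def pixel_center(self, row, col):
        """Map coordinates (easting, northing) of pixel centers."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        e = self.origin_easting + (col + 0.5) * self.pixel_size
        n = self.origin_northing - (row + 0.5) * self.pixel_size
        return e, n

    def map_to_pixel(self, easting, northing):
        """(row, col) of the pixel containing a map point (half-open cells)."""
        easting = np.asarray(easting, dtype=float)
        northing = np.asarray(northing, dtype=float)
        col = np.floor((easting - self.origin_easting) / self.pixel_size)
        row = np.floor((self.origin_northing - northing) / self.pixel_size)
        return row.astype(int), col.astype(int)


@dataclass
class BandStack:
    """Aligned per-band reflectance grids {B, G, R, RE, NIR}."""

    bands: dict[str, np.ndarray]
    transform: GeoTransform
    nodata_mask: np.ndarray | None = None  # True where INVALID

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise GeoIOError(f"band stack missing expected bands {missing}; "
                             f"expected {len(BAND_NAMES)} bands {list(BAND_NAMES)}")
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise GeoIOError(f"bands have mismatched shapes: {shapes}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        elif self.nodata_mask.shape != self.shape:
            raise GeoIOError("nodata_mask shape differs from band shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands[BAND_NAMES[0]].shape

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise GeoIOError(f"unknown band {name!r}; have {list(self.bands)}") from None


@dataclass
class ElevationGrid:
    """Single-band elevation surface in meters.

    ``role`` records what the elevation is relative to: DSM and DTM are
    meters above the vertical datum (sea level), CSM is meters above ground
    level (the per-pixel DSM - DTM difference).
    """

    values: np.ndarray
    transform: GeoTransform
    role: str = "DSM"
    nodata_mask: np.ndarray | None = None

    VALID_ROLES = ("DSM", "DTM", "CSM")

    def __post_init__(self) -> None:
        if self.role not in self.VALID_ROLES:
            raise GeoIOError(f"role must be one of {self.VALID_ROLES}, got {self.role!r}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        elif self.nodata_mask.shape != self.values.shape:
            raise GeoIOError("nodata_mask shape differs from values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PlotRecord:
    """A single trial plot: polygon in map coordinates plus trial metadata."""

    plot_id: str
    entry: str
    replicate: int
    polygon: Polygon
    role: str = "plot"  # "plot" or "panel" (radiometric reference region)

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid:
            raise GeoIOError(f"plot {self.plot_id!r}: polygon is not simple/valid")
        if not self.polygon.area > 0:
            raise GeoIOError(f"plot {self.plot_id!r}: polygon area must be > 0")


# ---------------------------------------------------------------------------
# Raster I/O — ESRI ASCII grid
# ---------------------------------------------------------------------------

def _write_asc(path: Path, values: np.ndarray, transform: GeoTransform,
               nodata_mask: np.ndarray) -> None:
    nrows, ncols = values.shape
    yll = transform.origin_northing - nrows * transform.pixel_size
    out = np.array(values, dtype=float, copy=True)
    out[nodata_mask] = _NODATA
    header = (f"ncols {ncols}\n"
              f"nrows {nrows}\n"
              f"xllcorner {transform.origin_easting!r}\n"
              f"yllcorner {yll!r}\n"
              f"cellsize {transform.pixel_size!r}\n"
              f"NODATA_value {_NODATA!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def _read_asc(path: Path) -> tuple[np.ndarray, GeoTransform, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                raise GeoIOError(f"{path}: malformed ASCII-grid header line {line!r}")
            header[parts[0].lower()] = float(parts[1])
        values = np.loadtxt(fh, ndmin=2)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise GeoIOError(f"{path}: header missing geotransform keys "
                         f"{sorted(required - set(header))}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise GeoIOError(f"{path}: data shape {values.shape} does not match "
                         f"declared ({nrows}, {ncols})")
    transform = GeoTransform(
        origin_easting=header["xllcorner"],
        origin_northing=header["yllcorner"] + nrows * header["cellsize"],
        pixel_size=header["cellsize"],
    )
    nodata = header.get("nodata_value", _NODATA)
    mask = values == nodata
    values = values.copy()
    values[mask] = np.nan
    return values, transform, mask


def write_raster(grid: BandStack | ElevationGrid, path: str | Path) -> Path:
    """Write a band stack or elevation grid as ASCII grid file(s).

    A :class:`BandStack` at stem ``path`` becomes five sibling files
    ``<stem>.B.asc`` ... ``<stem>.NIR.asc``; an :class:`ElevationGrid`
    becomes the single file ``path`` (``.asc`` appended if absent).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(grid, BandStack):
        stem = path.with_suffix("") if path.suffix == ".asc" else path
        for b in BAND_NAMES:
            _write_asc(Path(f"{stem}.{b}.asc"), grid.bands[b], grid.transform,
                       grid.nodata_mask)
        return Path(f"{stem}")
    if isinstance(grid, ElevationGrid):
        if path.suffix != ".asc":
            path = path.with_suffix(".asc")
        _write_asc(path, grid.values, grid.transform, grid.nodata_mask)
        return path
    raise GeoIOError(f"cannot write object of type {type(grid).__name__}")


def read_raster(path: str | Path, kind: str = "auto",
                role: str = "DSM") -> BandStack | ElevationGrid:
    """Read an ASCII-grid raster back as a BandStack or ElevationGrid.

    ``kind`` is ``"bands"`` (stem of a 5-file stack), ``"elevation"``, or
    ``"auto"`` which picks bands when ``<path>.B.asc`` exists.
    """
    path = Path(path)
    if kind == "auto":
        kind = "bands" if Path(f"{path.with_suffix('') if path.suffix == '.asc' else path}.B.asc").exists() else "elevation"
    if kind == "bands":
        stem = path.with_suffix("") if path.suffix == ".asc" else path
        band_files = [Path(f"{stem}.{b}.asc") for b in BAND_NAMES]
        missing = [f.name for f in band_files if not f.exists()]
        if missing:
            raise GeoIOError(
                f"expected 5 bands {list(BAND_NAMES)} at stem {stem}; missing {missing}")
        bands, transform, mask = {}, None, None
        for b, f in zip(BAND_NAMES, band_files):
            values, tf, m = _read_asc(f)
            if transform is None:
                transform, mask = tf, m
            elif tf != transform or values.shape != next(iter(bands.values())).shape:
                raise GeoIOError(f"band {b}: shape/transform mismatch across stack")
            else:
                mask = mask | m
            bands[b] = values
        return BandStack(bands=bands, transform=transform, nodata_mask=mask)
    if kind == "elevation":
        values, transform, mask = _read_asc(path if path.suffix == ".asc"
                                            else path.with_suffix(".asc"))
        return ElevationGrid(values=values, transform=transform, role=role,
                             nodata_mask=mask)
    raise GeoIOError(f"unknown raster kind {kind!r}")


# ---------------------------------------------------------------------------
# Vector I/O — GeoJSON plot layers
# ---------------------------------------------------------------------------

def write_plots(plots: Sequence[PlotRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for p in plots:
        features.append({
            "type": "Feature",
            "geometry": geom_mapping(p.polygon),
            "properties": {"plot_id": p.plot_id, "entry": p.entry,
                           "replicate": p.replicate, "role": p.role},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    return path


def read_plots(path: str | Path) -> list[PlotRecord]:
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"plot layer not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeoIOError(f"{path}: expected a GeoJSON FeatureCollection")
    plots: list[PlotRecord] = []
    seen: set[str] = set()
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "plot_id" not in props or props["plot_id"] is None:
            raise GeoIOError(f"{path}: feature without plot_id property")
        pid = str(props["plot_id"])
        if pid in seen:
            raise GeoIOError(f"{path}: duplicate plot_id {pid!r}")
        seen.add(pid)
        geom = geom_shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise GeoIOError(f"plot {pid!r}: geometry must be a Polygon")
        if not geom.is_valid:
            raise GeoIOError(f"plot {pid!r}: self-intersecting polygon")
        plots.append(PlotRecord(
            plot_id=pid,
            entry=str(props.get("entry", pid)),
            replicate=int(props.get("replicate", 1)),
            polygon=geom,
            role=str(props.get("role", "plot")),
        ))
    return plots


# ---------------------------------------------------------------------------
# Tabular I/O — CSV with a light schema
# ---------------------------------------------------------------------------

#: Ground-truth trait schema. AGBM units differ by season (kg fresh weight
#: in winter trials, g dry weight in spring); units are metadata, not data.
TRAIT_SCHEMA: dict[str, type] = {
    "plot_id": str, "entry": str, "replicate": int,
    "AGBM": float, "F50": float, "PM": float, "FN": float, "SY": float,
    "CH_gt": float, "lodging_ratio": float, "leaf_type": str,
}


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path, schema: Mapping[str, type] | None = None,
               required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a headered CSV, typing known columns and keeping unknown ones as text."""
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"table not found: {path}")
    df = pd.read_csv(path, dtype=str)
    for col in required:
        if col not in df.columns:
            raise GeoIOError(f"{path}: missing required column {col!r}")
    if schema:
        for col, typ in schema.items():
            if col in df.columns and typ is not str:
                # Series.astype uses the correctly-rounded strtod, so the
                # %.17g round trip is lossless (pd.to_numeric is not)
                try:
                    df[col] = df[col].astype(float)
                except ValueError:
                    df[col] = pd.to_numeric(df[col], errors="coerce")
                if typ is int:
                    df[col] = df[col].astype("Int64")
    return df
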