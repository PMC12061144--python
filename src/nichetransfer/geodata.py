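"""Georeferenced raster grids, predictor stacks, and occurrence tables.

Everything is geographic WGS84 lon/lat. Grids follow the dominant GeoTIFF
convention: row 0 is the northernmost row, pixel-is-area, cells are half-open
``[west, east) x (south, north]``. Cell areas are spherical with the IUGG mean
Earth radius, which is accurate to well under 0.3 % of the ellipsoidal value —
far below the precision at which range areas are ever reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

EARTH_RADIUS_KM = 6371.0088

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

_GEOKEY_MODEL_TYPE = 1024
_GEOKEY_RASTER_TYPE = 1025
_GEOKEY_GEOGRAPHIC_TYPE = 2048
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2
_RASTER_PIXEL_IS_AREA = 1
_RASTER_PIXEL_IS_POINT = 2
_EPSG_WGS84 = 4326


class GeoreferencingError(ValueError):
    """Raised when a raster file lacks usable geographic referencing."""


@dataclass
class RasterGrid:
    """A single-band raster on a regular lon/lat grid.

    Parameters
    ----------
    values : 2-D float array, row 0 = northernmost row.
    nodata_mask : boolean array, True where the cell carries no data.
    origin_lon, origin_lat : west / north edge of the top-left cell (degrees).
    cell_size : cell edge length in degrees (square cells).
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def geometry(self) -> tuple[float, float, float, int, int]:
        return (self.origin_lon, self.origin_lat, self.cell_size, *self.shape)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point.

        Cells are ``[west, east)`` in longitude and ``(south, north]`` in
        latitude; indices may fall outside ``[0, n)`` for points off the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        # (south, north] in latitude: a point exactly on a cell's north edge
        # belongs to that cell, so integer rel maps to row rel, else ceil-1
        rel = (self.origin_lat - lat) / self.cell_size
        on_edge = rel == np.floor(rel)
        row = np.where(on_edge, rel, np.ceil(rel) - 1).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_index(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            nodata_mask=self.nodata_mask.copy() if mask is None else np.asarray(mask, bool),
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
        )


@dataclass
class PredictorStack:
    """Aligned named predictor grids with per-predictor category labels."""

    grids: dict[str, RasterGrid]
    category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.grids)
        if not names:
            raise ValueError("empty stack")
        ref = self.grids[names[0]]
        for name in names[1:]:
            if not self.grids[name].same_geometry(ref):
                raise ValueError(f"grid {name!r} is not aligned with {names[0]!r}")
        for name in names:
            self.category.setdefault(name, "climate")

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.grids.values()))

    def combined_nodata(self) -> np.ndarray:
        """True wherever any layer is nodata."""
        mask = np.zeros(self.template.shape, dtype=bool)
        for g in self.grids.values():
            mask |= g.nodata_mask
        return mask

    def as_array(self) -> np.ndarray:
        """(n_predictors, rows, cols) value cube in stack order."""
        return np.stack([self.grids[n].values for n in self.names])


@dataclass
class OccurrenceSet:
    """Labelled presence points: one row per (population, lon, lat, source)."""

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        req = {"population", "lon", "lat"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        if "source" not in self.records.columns:
            self.records = self.records.assign(source="")
        lon = self.records["lon"].to_numpy(float)
        lat = self.records["lat"].to_numpy(float)
        if np.any((lon < -180) | (lon >= 180)) or np.any(np.abs(lat) > 90):
            raise ValueError("coordinates outside valid lon/lat ranges")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def populations(self) -> list[str]:
        return sorted(self.records["population"].unique())

    def subset(self, population: str) -> "OccurrenceSet":
        sub = self.records[self.records["population"] == population]
        return OccurrenceSet(sub.copy(), provenance=self.provenance)

    def counts(self) -> dict[str, int]:
        return self.records["population"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path, nodata_value: float = -9999.0) -> None:
    """Write a RasterGrid as a single-band float64 GeoTIFF (WGS84, pixel-is-area)."""
    data = grid.values.astype(np.float64).copy()
    data[grid.nodata_mask] = nodata_value
    cs = float(grid.cell_size)
    geokeys = (
        1, 1, 0, 3,
        _GEOKEY_MODEL_TYPE, 0, 1, _MODEL_TYPE_GEOGRAPHIC,
        _GEOKEY_RASTER_TYPE, 0, 1, _RASTER_PIXEL_IS_AREA,
        _GEOKEY_GEOGRAPHIC_TYPE, 0, 1, _EPSG_WGS84,
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_lon), float(grid.origin_lat), 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata_value))),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_raster(path) -> RasterGrid:
    """Read a single-band geographic GeoTIFF into a RasterGrid.

    Raises :class:`GeoreferencingError` for projected CRSs (reproject to WGS84
    lon/lat first) and for files without georeferencing tags.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}

    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise GeoreferencingError(f"{path}: missing GeoTIFF georeferencing tags")

    raster_type = _RASTER_PIXEL_IS_AREA
    if _TAG_GEO_KEYS in tags:
        keys = np.asarray(tags[_TAG_GEO_KEYS]).ravel()
        for i in range(4, len(keys) - 3, 4):
            key_id, _, _, value = keys[i : i + 4]
            if key_id == _GEOKEY_MODEL_TYPE and value == _MODEL_TYPE_PROJECTED:
                raise GeoreferencingError(
                    f"{path}: projected CRS; reproject to geographic WGS84 lon/lat first"
                )
            if key_id == _GEOKEY_RASTER_TYPE:
                raster_type = int(value)

    sx, sy = float(tags[_TAG_PIXEL_SCALE][0]), float(tags[_TAG_PIXEL_SCALE][1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise GeoreferencingError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    tie = tags[_TAG_TIEPOINT]
    # tiepoint: raster (i, j, k) -> model (x, y, z); we require the common (0, 0) anchor
    px_i, px_j = float(tie[0]), float(tie[1])
    origin_lon = float(tie[3]) - px_i * sx
    origin_lat = float(tie[4]) + px_j * sy
    if raster_type == _RASTER_PIXEL_IS_POINT:
        # stored coordinates refer to cell centers: shift to the area convention
        origin_lon -= sx / 2
        origin_lat += sy / 2

    mask = ~np.isfinite(data)
    if _TAG_GDAL_NODATA in tags:
        try:
            nd = float(str(tags[_TAG_GDAL_NODATA]).strip().strip("\x00"))
        except ValueError:
            nd = None
        if nd is not None:
            mask |= np.isnan(data) if math.isnan(nd) else (data == nd)
    values = data.copy()
    values[mask] = np.nan
    return RasterGrid(values, mask, origin_lon, origin_lat, sx)


# ---------------------------------------------------------------------------
# Occurrence CSV I/O
# ---------------------------------------------------------------------------

def read_occurrences(path, provenance: str = "") -> tuple[OccurrenceSet, int]:
    """Load an occurrence CSV (``species,lon,lat[,source]``).

    Exact duplicate (population, lon, lat) triples are dropped; the count of
    dropped duplicates is returned alongside the set.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "species" in cols:
        df = df.rename(columns={cols["species"]: "population"})
    n0 = len(df)
    df = df.drop_duplicates(subset=["population", "lon", "lat"])
    n_dup = n0 - len(df)
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate occurrence records")
    return OccurrenceSet(df.reset_index(drop=True), provenance=provenance or str(path)), n_dup


def write_occurrences(occ: OccurrenceSet, path) -> None:
    out = occ.records.rename(columns={"population": "species"})
    out[["species", "lon", "lat"] + (["source"] if out["source"].any() else [])].to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Alignment / resampling
# ---------------------------------------------------------------------------

def _resample(grid: RasterGrid, template: RasterGrid, method: str) -> RasterGrid:
    if grid.same_geometry(template):
        return RasterGrid(
            grid.values.copy(), grid.nodata_mask.copy(),
            template.origin_lon, template.origin_lat, template.cell_size,
        )
    lon = template.lon_centers()
    lat = template.lat_centers()
    # fractional source indices of the template cell centers
    col_f = (lon - grid.origin_lon) / grid.cell_size - 0.5
    row_f = (grid.origin_lat - lat) / grid.cell_size - 0.5
    cc, rr = np.meshgrid(col_f, row_f)
    inside = (
        (cc >= -0.5) & (cc <= grid.n_cols - 0.5) & (rr >= -0.5) & (rr <= grid.n_rows - 0.5)
    )
    src = grid.values.copy()
    src[grid.nodata_mask] = np.nan
    order = {"bilinear": 1, "nearest": 0}[method]
    out = ndimage.map_coordinates(src, [rr, cc], order=order, mode="nearest", cval=np.nan)
    mask = ~inside | ~np.isfinite(out)
    out = np.where(mask, np.nan, out)
    return RasterGrid(out, mask, template.origin_lon, template.origin_lat, template.cell_size)


def align_stack(
    stacks: list[PredictorStack],
    template: RasterGrid,
    method_by_category: dict[str, str] | None = None,
) -> PredictorStack:
    """Resample every layer of the given stacks onto the template geometry.

    Continuous (climate, topography) layers are resampled bilinearly; fraction
    or categorical (land-use) layers by nearest neighbour, so bounded fractions
    stay within their bounds. A cell whose interpolation footprint touches
    nodata becomes nodata.
    """
    methods = {"climate": "bilinear", "topography": "bilinear", "landuse": "nearest"}
    if method_by_category:
        methods.update(method_by_category)
    grids: dict[str, RasterGrid] = {}
    category: dict[str, str] = {}
    non_overlapping: list[str] = []
    for stack in stacks:
        for name in stack.names:
            grid = stack.grids[name]
            cat = stack.category.get(name, "climate")
            res = _resample(grid, template, methods.get(cat, "bilinear"))
            if res.nodata_mask.all():
                non_overlapping.append(name)
            grids[name] = res
            category[name] = cat
    if non_overlapping:
        raise ValueError(f"layers do not overlap the template extent: {non_overlapping}")
    return PredictorStack(grids, category)


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractionReport:
    n_input: int
    n_kept: int
    n_outside: int
    n_nodata: int


def extract_values(
    points: OccurrenceSet | pd.DataFrame, stack: PredictorStack
) -> tuple[pd.DataFrame, ExtractionReport]:
    """Design matrix of stack values at each point's cell.

    Points outside the extent or on a cell that is nodata in any layer are
    dropped and counted. Raises if no point survives.
    """
    df = points.records if isinstance(points, OccurrenceSet) else points
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    tmpl = stack.template
    row, col = tmpl.cell_index(lon, lat)
    inside = (row >= 0) & (row < tmpl.n_rows) & (col >= 0) & (col < tmpl.n_cols)
    combined = stack.combined_nodata()
    valid = inside.copy()
    valid[inside] = ~combined[row[inside], col[inside]]
    n_outside = int((~inside).sum())
    n_nodata = int(inside.sum() - valid.sum())
    if not valid.any():
        raise ValueError("no points fall on valid cells")
    out = pd.DataFrame(
        {name: stack.grids[name].values[row[valid], col[valid]] for name in stack.names},
        index=df.index[valid],
    )
    report = ExtractionReport(len(df), int(valid.sum()), n_outside, n_nodata)
    return out, report


# ---------------------------------------------------------------------------
# Cell areas
# ---------------------------------------------------------------------------

def cell_area_km2(grid: RasterGrid) -> RasterGrid:
    """Spherical per-cell area: A = R^2 * dlambda * (sin(phi_top) - sin(phi_bot)).

    Constant along each row (independent of longitude).
    """
    cs = grid.cell_size
    lat_top = grid.origin_lat - np.arange(grid.n_rows) * cs
    lat_bot = lat_top - cs
    dlon = math.radians(cs)
    band = EARTH_RADIUS_KM**2 * dlon * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    areas = np.repeat(band[:, None], grid.n_cols, axis=1)
    return RasterGrid(
        areas, np.zeros_like(areas, dtype=bool), grid.origin_lon, grid.origin_lat, cs
    )
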