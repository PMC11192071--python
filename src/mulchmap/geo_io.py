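"""Raster and vector I/O plus raster/vector/sample conversions.

All geometry lives in a projected CRS with metre units (default UTM zone
12S, EPSG:32712).  The grid convention is 0-based row/col with the origin at
the upper-left corner; world coordinates of a cell centre are

    x = x0 + (col + 0.5) * pixel_size
    y = y0 - (row + 0.5) * pixel_size

Areas are always computed in square metres and only converted to ha/km**2
at reporting edges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

DEFAULT_CRS = "EPSG:32712"

#: GeoTIFF / GDAL tag codes used for georeferencing metadata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Affine map from (row, col) pixel indices to projected coordinates.

    Only axis-aligned, north-up grids are supported: ``x = x0 + col * px``,
    ``y = y0 - row * px`` for the upper-left corner of a cell.
    """

    pixel_size: float
    x0: float = 0.0
    y0: float = 0.0

    def cell_center(self, row, col):
        """World coordinates of cell centres (vectorised)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        return (self.x0 + (col + 0.5) * self.pixel_size,
                self.y0 - (row + 0.5) * self.pixel_size)

    def world_to_rc(self, x, y):
        """Fractional (row, col) indices of world points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((self.y0 - y) / self.pixel_size - 0.5,
                (x - self.x0) / self.pixel_size - 0.5)


@dataclass
class MultibandRaster:
    """Georeferenced multiband reflectance grid (band, row, col)."""

    values: np.ndarray
    band_names: list[str]
    transform: GridTransform
    crs: str = DEFAULT_CRS
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a (band, row, col) array")
        if len(self.band_names) != self.values.shape[0]:
            raise ValueError("band_names length must equal the band count")
        if self.transform.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    def valid_mask(self) -> np.ndarray:
        """Boolean (row, col) mask of cells valid in *all* bands."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return ~np.any(self.values == self.nodata, axis=0)

    def select_bands(self, names: Sequence[str]) -> "MultibandRaster":
        idx = [self.band_names.index(n) for n in names]
        return replace(self, values=self.values[idx], band_names=list(names))


@dataclass
class LabelRaster:
    """Integer class-label grid sharing georeferencing with its rasters.

    ``labels`` holds indices into ``class_names``; ``UNLABELED`` (-1) marks
    cells outside every polygon / nodata.
    """

    labels: np.ndarray
    class_names: list[str]
    transform: GridTransform
    crs: str = DEFAULT_CRS

    UNLABELED: int = field(default=-1, init=False, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    def class_fraction(self, name: str) -> float:
        return float(np.mean(self.labels == self.class_names.index(name)))


@dataclass
class LabeledPolygon:
    """A vector feature with an optional land-cover class label."""

    geometry: BaseGeometry
    label: str | None = None
    polygon_id: int = 0
    properties: dict = field(default_factory=dict)


@dataclass
class TrainingSet:
    """Labelled pixel spectra grouped by source polygon.

    Attributes
    ----------
    X : (n_samples, n_bands) float array of reflectance spectra.
    y : (n_samples,) int array of class indices into ``class_names``.
    polygon_id : (n_samples,) int array mapping samples to source polygons.
    """

    X: np.ndarray
    y: np.ndarray
    polygon_id: np.ndarray
    class_names: list[str]
    band_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.polygon_id = np.asarray(self.polygon_id, dtype=int)
        if not (len(self.X) == len(self.y) == len(self.polygon_id)):
            raise ValueError("X, y and polygon_id must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "TrainingSet":
        return TrainingSet(self.X[mask], self.y[mask], self.polygon_id[mask],
                           list(self.class_names), list(self.band_names))

    def classes_present(self) -> list[str]:
        return [self.class_names[i] for i in np.unique(self.y)]


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile)
# ---------------------------------------------------------------------------

def write_raster(raster: MultibandRaster, path) -> None:
    """Write a raster as a band-sequential GeoTIFF.

    Georeferencing is stored in the standard GeoTIFF tags; band names and the
    CRS string are additionally kept in a JSON ImageDescription so the
    round-trip is lossless.
    """
    px = raster.transform.pixel_size
    desc = json.dumps({
        "band_names": raster.band_names,
        "crs": raster.crs,
        "nodata": raster.nodata,
    })
    epsg = _epsg_code(raster.crs)
    # minimal GeoKeyDirectory: projected model type + projected CS code
    geokeys = (1, 1, 0, 2,
               1024, 0, 1, 1,
               3072, 0, 1, epsg)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, raster.transform.x0, raster.transform.y0, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
    ]
    if raster.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(raster.nodata)))
    values = raster.values
    kwargs = {}
    if values.shape[0] == 1:
        values = values[0]  # single band stored as a plain 2-D page
    else:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(path, values, photometric="minisblack",
                     description=desc, extratags=extratags, **kwargs)


def read_raster(path) -> MultibandRaster:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = tif.asarray()
        tags = page.tags
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
            px = float(tags[_TAG_MODEL_PIXEL_SCALE].value[0])
            tie = tags[_TAG_MODEL_TIEPOINT].value
            x0, y0 = float(tie[3]), float(tie[4])
        else:
            warnings.warn("no GeoTIFF georeferencing tags; assuming unit grid "
                          "at the origin")
            px, x0, y0 = 1.0, 0.0, 0.0
    if values.ndim == 2:
        values = values[None]
    crs = meta.get("crs")
    if crs is None:
        warnings.warn(f"no CRS recorded; assuming {DEFAULT_CRS}")
        crs = DEFAULT_CRS
    band_names = meta.get("band_names") or [f"band_{i + 1}"
                                            for i in range(values.shape[0])]
    return MultibandRaster(values=values, band_names=band_names,
                           transform=GridTransform(px, x0, y0),
                           crs=crs, nodata=meta.get("nodata"))


def _epsg_code(crs: str) -> int:
    try:
        return int(str(crs).split(":")[-1])
    except ValueError:
        return 32712


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def write_polygons(polygons: Iterable[LabeledPolygon], path,
                   crs: str = DEFAULT_CRS) -> None:
    features = []
    for p in polygons:
        props = dict(p.properties)
        if p.label is not None:
            props["class"] = p.label
        props.setdefault("polygon_id", p.polygon_id)
        features.append({"type": "Feature", "properties": props,
                         "geometry": geom_mapping(p.geometry)})
    doc = {"type": "FeatureCollection", "crs_name": crs, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_polygons(path) -> list[LabeledPolygon]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for i, feat in enumerate(doc.get("features", [])):
        props = dict(feat.get("properties") or {})
        label = props.pop("class", None)
        pid = props.pop("polygon_id", i)
        out.append(LabeledPolygon(geom_shape(feat["geometry"]), label,
                                  int(pid), props))
    return out


# ---------------------------------------------------------------------------
# Raster <-> vector conversions
# ---------------------------------------------------------------------------

def _cells_in_polygon(geom: BaseGeometry, transform: GridTransform,
                      shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of cells whose centre lies inside ``geom`` (row-major)."""
    nrows, ncols = shape
    minx, miny, maxx, maxy = geom.bounds
    r0f, c0f = transform.world_to_rc(minx, maxy)
    r1f, c1f = transform.world_to_rc(maxx, miny)
    r0 = max(int(np.floor(r0f)), 0)
    c0 = max(int(np.floor(c0f)), 0)
    r1 = min(int(np.ceil(r1f)) + 1, nrows)
    c1 = min(int(np.ceil(c1f)) + 1, ncols)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x, y = transform.cell_center(rr, cc)
    inside = shapely.contains_xy(geom, x.ravel(), y.ravel())
    return rr.ravel()[inside], cc.ravel()[inside]


def rasterize_polygons(polygons: Sequence[LabeledPolygon],
                       template: MultibandRaster | LabelRaster,
                       class_names: Sequence[str] | None = None) -> LabelRaster:
    """Burn labelled polygons onto the template grid.

    A cell is labelled iff its centre lies inside a polygon; where polygons
    overlap, the polygon listed first wins.
    """
    if not polygons:
        raise ValueError("empty polygon set")
    if class_names is None:
        seen: list[str] = []
        for p in polygons:
            if p.label is not None and p.label not in seen:
                seen.append(p.label)
        class_names = seen
    shape = template.shape
    labels = np.full(shape, LabelRaster.UNLABELED, dtype=np.int16)
    for p in polygons:
        if p.label is None:
            continue
        idx = class_names.index(p.label)
        rr, cc = _cells_in_polygon(p.geometry, template.transform, shape)
        free = labels[rr, cc] == LabelRaster.UNLABELED
        labels[rr[free], cc[free]] = idx
    return LabelRaster(labels=labels, class_names=list(class_names),
                       transform=template.transform, crs=template.crs)


def extract_training_pixels(raster: MultibandRaster,
                            polygons: Sequence[LabeledPolygon],
                            class_names: Sequence[str] | None = None,
                            ) -> TrainingSet:
    """One sample per labelled, non-nodata cell, in row-major cell order.

    Cell membership follows the centre-containment rule of
    :func:`rasterize_polygons`.  Polygons covering no valid cell are skipped
    with a warning.
    """
    if class_names is None:
        seen: list[str] = []
        for p in polygons:
            if p.label is not None and p.label not in seen:
                seen.append(p.label)
        class_names = list(seen)
    valid = raster.valid_mask()
    xs, ys, pids = [], [], []
    for p in polygons:
        if p.label is None:
            continue
        rr, cc = _cells_in_polygon(p.geometry, raster.transform, raster.shape)
        keep = valid[rr, cc]
        rr, cc = rr[keep], cc[keep]
        if rr.size == 0:
            warnings.warn(f"polygon {p.polygon_id} yields no valid cells; "
                          "skipped")
            continue
        order = np.lexsort((cc, rr))
        rr, cc = rr[order], cc[order]
        xs.append(raster.values[:, rr, cc].T)
        ys.append(np.full(rr.size, class_names.index(p.label), dtype=int))
        pids.append(np.full(rr.size, p.polygon_id, dtype=int))
    if not xs:
        X = np.empty((0, raster.n_bands))
        y = pid = np.empty(0, dtype=int)
    else:
        X = np.vstack(xs)
        y = np.concatenate(ys)
        pid = np.concatenate(pids)
    return TrainingSet(X=X, y=y, polygon_id=pid,
                       class_names=list(class_names),
                       band_names=list(raster.band_names))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(raster: MultibandRaster, target_pixel_size: float,
             method: str = "cubic",
             target_shape: tuple[int, int] | None = None) -> MultibandRaster:
    """Resample to a new pixel size with cubic (spline) interpolation.

    The output grid shares the raster's upper-left origin; its dimensions are
    ``round(extent / target_pixel_size)`` unless ``target_shape`` pins them
    (used to co-register with an existing grid).  Nodata cells are propagated
    by nearest-neighbour and excluded from interpolation support.
    """
    if target_pixel_size <= 0:
        raise ValueError("target_pixel_size must be positive")
    order = {"nearest": 0, "linear": 1, "cubic": 3}[method]
    nrows, ncols = raster.shape
    px = raster.pixel_size
    if min(nrows, ncols) < 1:
        raise ValueError("degenerate raster extent")
    if target_shape is None:
        out_rows = int(round(nrows * px / target_pixel_size))
        out_cols = int(round(ncols * px / target_pixel_size))
    else:
        out_rows, out_cols = target_shape
    if out_rows < 1 or out_cols < 1:
        raise ValueError("degenerate output extent")
    # fractional source indices of output cell centres
    rr = (np.arange(out_rows) + 0.5) * target_pixel_size / px - 0.5
    cc = (np.arange(out_cols) + 0.5) * target_pixel_size / px - 0.5
    coords = np.meshgrid(rr, cc, indexing="ij")
    values = raster.values.astype(float, copy=True)
    nodata_mask = None
    if raster.nodata is not None:
        nodata_mask = ~raster.valid_mask()
        if nodata_mask.any():
            for b in range(values.shape[0]):
                band = values[b]
                fill = band[~nodata_mask].mean() if (~nodata_mask).any() else 0
                band[nodata_mask] = fill
    out = np.empty((raster.n_bands, out_rows, out_cols), dtype=float)
    for b in range(raster.n_bands):
        out[b] = ndimage.map_coordinates(values[b], coords, order=order,
                                         mode="nearest")
    nodata = raster.nodata
    if nodata_mask is not None and nodata_mask.any():
        m = ndimage.map_coordinates(nodata_mask.astype(np.uint8), coords,
                                    order=0, mode="nearest").astype(bool)
        out[:, m] = nodata
    tf = GridTransform(target_pixel_size, raster.transform.x0,
                       raster.transform.y0)
    return MultibandRaster(values=out, band_names=list(raster.band_names),
                           transform=tf, crs=raster.crs, nodata=nodata)


def block_average(raster: MultibandRaster, target_pixel_size: float,
                  target_shape: tuple[int, int] | None = None
                  ) -> MultibandRaster:
    """Aggregate to a coarser grid by averaging member cells.

    Each fine cell contributes to the coarse cell containing its centre;
    coarse values are the plain mean of contributors.  Used to degrade a
    sharpened product back to a sensor's native resolution.
    """
    if target_pixel_size <= raster.pixel_size:
        raise ValueError("target pixel size must be coarser than the source")
    nrows, ncols = raster.shape
    px = raster.pixel_size
    if target_shape is None:
        out_rows = max(1, int(round(nrows * px / target_pixel_size)))
        out_cols = max(1, int(round(ncols * px / target_pixel_size)))
    else:
        out_rows, out_cols = target_shape
    fr = np.minimum(((np.arange(nrows) + 0.5) * px
                     / target_pixel_size).astype(int), out_rows - 1)
    fc = np.minimum(((np.arange(ncols) + 0.5) * px
                     / target_pixel_size).astype(int), out_cols - 1)
    idx = (fr[:, None] * out_cols + fc[None, :]).ravel()
    counts = np.bincount(idx, minlength=out_rows * out_cols).astype(float)
    counts[counts == 0] = np.nan
    out = np.empty((raster.n_bands, out_rows, out_cols))
    for b in range(raster.n_bands):
        sums = np.bincount(idx, weights=raster.values[b].ravel(),
                           minlength=out_rows * out_cols)
        out[b] = (sums / counts).reshape(out_rows, out_cols)
    tf = GridTransform(target_pixel_size, raster.transform.x0,
                       raster.transform.y0)
    return MultibandRaster(values=out, band_names=list(raster.band_names),
                           transform=tf, crs=raster.crs,
                           nodata=raster.nodata)
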