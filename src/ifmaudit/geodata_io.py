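"""Raster/vector plumbing shared by every stage of the audit.

Annual raster stacks (carbon density, binary harvest) live in
:class:`AnnualRasterStack`: a (year, row, col) array plus an affine
georeference.  The affine transform is the usual 6-tuple (a, b, c, d, e, f)
mapping pixel-corner coordinates, ``x = a*col + b*row + c`` and
``y = d*col + e*row + f``; pixel centers sit at (col + 0.5, row + 0.5).
Grids are row-major with (row, col) indexing and half-open edges.

On disk each year is a single-band TIFF whose ImageDescription tag carries a
JSON georeference record (year, transform, crs, nodata, units), so every file
is self-describing and stack consistency can be checked file by file.
Polygons are read from GeoJSON.  Zonal statistics use the pixel-center
inclusion rule and valid (non-nodata) pixels only; a region-year with fewer
than 50% valid pixels is reported missing, never zero.
"""

from __future__ import annotations

import glob as _glob
import json
import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry

from .trend_stats import TimeSeries

__all__ = [
    "AnnualRasterStack",
    "RegionMask",
    "read_stack",
    "write_stack",
    "read_polygons",
    "write_polygons",
    "rasterize",
    "block_aggregate",
    "zonal_series",
    "zonal_fraction",
    "series_to_csv",
]

Transform = tuple[float, float, float, float, float, float]


def grid_transform(origin_x: float, origin_y: float, cell_size: float) -> Transform:
    """North-up transform with the grid origin at the upper-left corner."""
    return (cell_size, 0.0, origin_x, 0.0, -cell_size, origin_y)


@dataclass
class AnnualRasterStack:
    """A year-indexed stack of co-registered single-band grids."""

    values: np.ndarray          # (n_years, rows, cols)
    years: np.ndarray           # (n_years,), strictly increasing
    transform: Transform
    crs: str = "local"
    nodata: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be (years, rows, cols)")
        if self.years.size != self.values.shape[0]:
            raise ValueError("years length must match first axis of values")
        if self.years.size >= 2 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        self.transform = tuple(float(t) for t in self.transform)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    @property
    def cell_area_ha(self) -> float:
        a, b, _, d, e, _ = self.transform
        return abs(a * e - b * d) / 1e4

    def year(self, y: int) -> np.ndarray:
        idx = np.flatnonzero(self.years == y)
        if idx.size == 0:
            raise KeyError(f"year {y} not in stack ({self.years[0]}–{self.years[-1]})")
        return self.values[idx[0]]

    def valid_mask(self) -> np.ndarray:
        """(years, rows, cols) boolean: finite and not nodata."""
        v = np.isfinite(self.values.astype(float))
        if self.nodata is not None and not math.isnan(self.nodata):
            v &= self.values != self.nodata
        return v

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of pixel centers, each (rows, cols)."""
        rows, cols = self.shape
        cc, rr = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
        a, b, c, d, e, f = self.transform
        return a * cc + b * rr + c, d * cc + e * rr + f

    def window(self, start: int, end: int) -> "AnnualRasterStack":
        sel = (self.years >= start) & (self.years <= end)
        return replace(self, values=self.values[sel], years=self.years[sel])

    def assert_binary(self) -> None:
        v = self.values[self.valid_mask()]
        if not np.isin(v, (0, 1)).all():
            raise ValueError("stack is not binary: values other than {0, 1, nodata} present")


@dataclass
class RegionMask:
    """A boolean pixel set aligned to a stack, labelled with its provenance."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> "RegionMask":
        if not self.mask.any():
            raise ValueError(f"region mask {self.label!r} is empty")
        return self


# ---------------------------------------------------------------------------
# GeoTIFF-style stack IO


def write_stack(stack: AnnualRasterStack, prefix: str) -> list[str]:
    """Write one single-band TIFF per year as ``{prefix}_{year}.tif``.

    Each file's ImageDescription tag holds a JSON georeference record, making
    the files self-describing.  Integer data round-trip bit-exactly; float
    data are stored as float64.
    """
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    paths = []
    arr = stack.values
    if arr.dtype.kind == "f" and arr.dtype != np.float64:
        arr = arr.astype(np.float64)
    for i, y in enumerate(stack.years):
        meta = {
            "year": int(y),
            "transform": list(stack.transform),
            "crs": stack.crs,
            "nodata": stack.nodata,
            "units": stack.units,
        }
        path = f"{prefix}_{int(y)}.tif"
        tifffile.imwrite(path, arr[i], description=json.dumps(meta))
        paths.append(path)
    return paths


def _read_one(path: str) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: no georeference record in ImageDescription")
        meta = json.loads(desc.value)
    return data, meta


def read_stack(source: str | list[str], years: tuple[int, int] | None = None) -> AnnualRasterStack:
    """Read a stack from a glob pattern, prefix, or explicit file list.

    All files must agree on grid shape, transform, CRS, nodata and units; a
    mismatch raises an error naming the offending file.  If ``years`` declares
    an inclusive range, any missing year raises an explicit gap error.
    """
    if isinstance(source, str):
        paths = sorted(_glob.glob(source))
        if not paths:
            paths = sorted(_glob.glob(f"{source}_*.tif"))
        if not paths:
            raise FileNotFoundError(f"no stack files match {source!r}")
    else:
        paths = list(source)
    grids, metas = [], []
    for p in paths:
        g, m = _read_one(p)
        grids.append(g)
        metas.append(m)
    ref = metas[0]
    for p, g, m in zip(paths, grids, metas):
        if tuple(m["transform"]) != tuple(ref["transform"]) or m["crs"] != ref["crs"]:
            raise ValueError(f"grid mismatch: {p} (year {m['year']}) has a different transform/CRS")
        if g.shape != grids[0].shape:
            raise ValueError(f"grid mismatch: {p} has shape {g.shape}, expected {grids[0].shape}")
    order = np.argsort([m["year"] for m in metas])
    yrs = np.array([metas[i]["year"] for i in order])
    if years is not None:
        declared = np.arange(years[0], years[1] + 1)
        missing = np.setdiff1d(declared, yrs)
        if missing.size:
            raise ValueError(f"missing years in declared range {years}: {missing.tolist()}")
        keep = np.isin(yrs, declared)
        order = order[keep]
        yrs = yrs[keep]
    return AnnualRasterStack(
        values=np.stack([grids[i] for i in order]),
        years=yrs,
        transform=tuple(ref["transform"]),
        crs=ref["crs"],
        nodata=ref["nodata"],
        units=ref.get("units", ""),
    )


# ---------------------------------------------------------------------------
# vector IO


def read_polygons(path: str) -> list[tuple[BaseGeometry, dict]]:
    """Read a GeoJSON FeatureCollection as (geometry, properties) pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    return [(_geojson_shape(f["geometry"]), f.get("properties") or {}) for f in feats]


def write_polygons(path: str, geoms_props: list[tuple[BaseGeometry, dict]]) -> None:
    feats = [
        {"type": "Feature", "geometry": shapely.geometry.mapping(g), "properties": p}
        for g, p in geoms_props
    ]
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# rasterization and regridding


def rasterize(
    polygons: BaseGeometry | list[BaseGeometry],
    template: AnnualRasterStack,
    label: str = "",
) -> RegionMask:
    """Burn polygons onto the template grid: a pixel is inside iff its center is covered.

    Multiple polygons are unioned.  An empty intersection with the grid is an
    error — a silent empty mask would poison every downstream statistic.
    """
    if isinstance(polygons, BaseGeometry):
        polygons = [polygons]
    geom = shapely.union_all(list(polygons))
    x, y = template.pixel_centers()
    mask = shapely.contains_xy(geom, x.ravel(), y.ravel()).reshape(template.shape)
    if not mask.any():
        raise ValueError("polygon(s) cover no pixel centers on the template grid")
    return RegionMask(mask, label=label)


def block_aggregate(stack: AnnualRasterStack, factor: int) -> AnnualRasterStack:
    """Aggregate to a coarser grid by block means over ``factor`` x ``factor`` pixels.

    A coarse cell is the mean of its valid fine cells, and nodata (NaN) when
    fewer than 50% of its fine cells are valid; partial edge blocks are padded
    and judged against the full block size.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    rows, cols = stack.shape
    if factor > rows or factor > cols:
        raise ValueError(f"factor {factor} exceeds grid shape {stack.shape}")
    ny = stack.n_years
    pr = (-rows) % factor
    pc = (-cols) % factor
    vals = stack.values.astype(float)
    valid = stack.valid_mask()
    vals = np.where(valid, vals, np.nan)
    if pr or pc:
        vals = np.pad(vals, ((0, 0), (0, pr), (0, pc)), constant_values=np.nan)
    R, C = vals.shape[1] // factor, vals.shape[2] // factor
    blocks = vals.reshape(ny, R, factor, C, factor)
    nvalid = np.isfinite(blocks).sum(axis=(2, 4))
    with np.errstate(invalid="ignore"):
        means = np.nanmean(blocks, axis=(2, 4))
    means[nvalid < 0.5 * factor * factor] = np.nan
    a, b, c, d, e, f = stack.transform
    return AnnualRasterStack(
        values=means,
        years=stack.years.copy(),
        transform=(a * factor, b * factor, c, d * factor, e * factor, f),
        crs=stack.crs,
        nodata=float("nan"),
        units=stack.units,
    )


# ---------------------------------------------------------------------------
# zonal statistics


def zonal_series(stack: AnnualRasterStack, mask: RegionMask | np.ndarray) -> TimeSeries:
    """Per-year mean of the stack over a region (valid pixels only).

    A year with fewer than 50% valid masked pixels (including all-nodata
    years) is reported as missing (NaN), with the valid-pixel count alongside.
    """
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    if m.shape != stack.shape:
        raise ValueError(f"mask shape {m.shape} does not match stack {stack.shape}")
    if not m.any():
        raise ValueError("zonal mask is empty")
    total = int(m.sum())
    valid = stack.valid_mask()[:, m]
    vals = stack.values.astype(float)[:, m]
    n = valid.sum(axis=1)
    means = np.full(stack.n_years, np.nan)
    ok = n > 0
    with np.errstate(invalid="ignore"):
        means[ok] = np.nanmean(np.where(valid, vals, np.nan)[ok], axis=1)
    means[n < 0.5 * total] = np.nan
    label = mask.label if isinstance(mask, RegionMask) else ""
    return TimeSeries(stack.years.copy(), means, n_pixels=n,
                      variable=stack.units or "value", units=stack.units, label=label)


def zonal_fraction(stack: AnnualRasterStack, mask: RegionMask | np.ndarray) -> TimeSeries:
    """Per-year harvested-area fraction of a region for a binary 0/1 stack.

    The fraction is (valid pixels equal to 1) / (valid masked pixels); the
    50%-valid missing rule of :func:`zonal_series` applies.
    """
    stack.assert_binary()
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    if m.shape != stack.shape:
        raise ValueError(f"mask shape {m.shape} does not match stack {stack.shape}")
    if not m.any():
        raise ValueError("zonal mask is empty")
    total = int(m.sum())
    valid = stack.valid_mask()[:, m]
    ones = (stack.values[:, m] == 1) & valid
    n = valid.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n > 0, ones.sum(axis=1) / n, np.nan)
    frac[n < 0.5 * total] = np.nan
    label = mask.label if isinstance(mask, RegionMask) else ""
    return TimeSeries(stack.years.copy(), frac, n_pixels=n,
                      variable="harvest_fraction", units="fraction", label=label)


def series_to_csv(series: dict[str, TimeSeries], path: str) -> pd.DataFrame:
    """Write extracted series as tidy CSV: region_id, year, variable, value, n_pixels."""
    rows = []
    for region_id, ts in series.items():
        npix = ts.n_pixels if ts.n_pixels is not None else np.full(len(ts), np.nan)
        for y, v, n in zip(ts.years, ts.values, npix):
            rows.append((region_id, int(y), ts.variable, v, n))
    df = pd.DataFrame(rows, columns=["region_id", "year", "variable", "value", "n_pixels"])
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)
    return df
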