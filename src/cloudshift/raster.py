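"""Lightweight georeferenced raster containers.

A :class:`Grid` is a single-band raster on a north-up, row-major grid in a
projected, metre-unit coordinate system: 2-D values plus an upper-left origin
and a square pixel size.  Missing data are represented as NaN in floating
grids; an explicit ``nodata`` sentinel is only materialised on write.

Grids are written as plain single-band TIFF files with a JSON sidecar
(``<name>.tif`` + ``<name>.tif.json``) holding the origin, pixel size, nodata
value and a CRS label.  Multi-variable monthly cubes are ordinary
:class:`xarray.Dataset` objects sharing the grid geometry (see
:func:`make_cube`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

__all__ = ["Grid", "make_cube", "cube_geometry", "array_checksum"]

_DEFAULT_CRS = "local-equal-area-metres"


@dataclasses.dataclass
class Grid:
    """Single-band raster: values + affine geometry (north-up, square pixels).

    Parameters
    ----------
    values : 2-D array. Floating grids use NaN for nodata.
    origin : (x, y) of the upper-left *corner* of the upper-left pixel,
        in projected metres.
    pixel_size : side length of a pixel in metres (> 0).
    crs : free-text label of the projected CRS (metre units assumed).
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 1000.0
    crs: str = _DEFAULT_CRS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive and finite")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple[tuple[float, float], float, tuple[int, int]]:
        return (self.origin, self.pixel_size, self.shape)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_geometry(self, other: "Grid", what: str = "grid") -> None:
        if not self.same_geometry(other):
            raise ValueError(f"geometry mismatch: {what} does not share this grid's geometry")

    def xy_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D x (west→east) and y (north→south) pixel-centre coordinates."""
        nrow, ncol = self.shape
        x = self.origin[0] + (np.arange(ncol) + 0.5) * self.pixel_size
        y = self.origin[1] - (np.arange(nrow) + 0.5) * self.pixel_size
        return x, y

    def centre_coords(self) -> np.ndarray:
        """(nrow*ncol, 2) array of (x, y) centres in row-major order."""
        x, y = self.xy_centres()
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    # ------------------------------------------------------------------ derivation
    def with_values(self, values: np.ndarray) -> "Grid":
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError("replacement values must match grid shape")
        return Grid(values, self.origin, self.pixel_size, self.crs)

    def block_reduce(self, factor: int, func=np.nanmean) -> "Grid":
        """Aggregate ``factor``×``factor`` blocks with ``func`` (default mean).

        The grid shape must be divisible by ``factor``.  NaN-aware reducers
        (nanmean, nanmin, ...) ignore missing fine pixels.
        """
        nrow, ncol = self.shape
        if factor < 1 or nrow % factor or ncol % factor:
            raise ValueError(f"shape {self.shape} not divisible by block factor {factor}")
        v = self.values.astype(float).reshape(nrow // factor, factor, ncol // factor, factor)
        with np.errstate(invalid="ignore"):
            out = func(v.swapaxes(1, 2).reshape(nrow // factor, ncol // factor, factor * factor), axis=-1)
        return Grid(out, self.origin, self.pixel_size * factor, self.crs)

    def upsample_nearest(self, factor: int) -> "Grid":
        v = np.repeat(np.repeat(self.values, factor, axis=0), factor, axis=1)
        return Grid(v, self.origin, self.pixel_size / factor, self.crs)

    # ------------------------------------------------------------------ I/O
    def write_tif(self, path: str | Path, nodata: float = -9999.0) -> Path:
        path = Path(path)
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            vals = np.where(np.isnan(vals), nodata, vals).astype("float32")
        elif vals.dtype == bool:
            vals = vals.astype("uint8")
        tifffile.imwrite(path, vals)
        sidecar = {
            "origin": list(self.origin),
            "pixel_size": self.pixel_size,
            "crs": self.crs,
            "nodata": nodata,
            "dtype": str(self.values.dtype),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def read_tif(cls, path: str | Path) -> "Grid":
        path = Path(path)
        vals = tifffile.imread(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        if meta.get("dtype") == "bool":
            vals = vals.astype(bool)
        elif np.issubdtype(np.asarray(vals).dtype, np.floating):
            vals = np.asarray(vals, dtype=float)
            vals[vals == meta["nodata"]] = np.nan
        return cls(vals, tuple(meta["origin"]), meta["pixel_size"], meta["crs"])


def make_cube(variables: dict[str, np.ndarray], times, template: Grid) -> xr.Dataset:
    """Assemble monthly/annual variable stacks into a Dataset on a Grid geometry.

    ``variables`` maps name → (time, y, x) array; ``times`` labels the leading
    axis.  Geometry metadata is carried in attrs so grids can be round-tripped
    with :func:`cube_geometry`.
    """
    x, y = template.xy_centres()
    data = {}
    for name, arr in variables.items():
        arr = np.asarray(arr)
        if arr.shape[1:] != template.shape:
            raise ValueError(f"variable {name!r} does not match template geometry")
        data[name] = xr.DataArray(arr, dims=("time", "y", "x"),
                                  coords={"time": list(times), "y": y, "x": x})
    ds = xr.Dataset(data)
    ds.attrs.update(origin_x=template.origin[0], origin_y=template.origin[1],
                    pixel_size=template.pixel_size, crs=template.crs)
    return ds


def cube_geometry(ds: xr.Dataset) -> Grid:
    """Template Grid (NaN values) matching a cube's geometry."""
    shape = (ds.sizes["y"], ds.sizes["x"])
    return Grid(np.full(shape, np.nan),
                (ds.attrs["origin_x"], ds.attrs["origin_y"]),
                ds.attrs["pixel_size"], ds.attrs.get("crs", _DEFAULT_CRS))


def array_checksum(arr: np.ndarray) -> str:
    """SHA-256 of an array's bytes (C-order), used for determinism manifests."""
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes()).hexdigest()
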