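"""Montane forest delineation from elevation, local relief, and tree cover.

A pixel is montane forest when its elevation lies in a fixed band
(1200–3500 m a.s.l. by default), the local elevation range (LER: max minus
min elevation over all pixels whose centres fall within a 5-km radius)
exceeds 300 m, and tree cover is at least 30%.  The elevation band and the
tree-cover threshold are inclusive; the LER threshold is strict.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

from .raster import Grid

__all__ = ["MaskParams", "local_elevation_range", "montane_forest_mask",
           "coarsen_mask"]


@dataclasses.dataclass
class MaskParams:
    elev_min_m: float = 1200.0
    elev_max_m: float = 3500.0
    ler_radius_m: float = 5000.0
    ler_min_m: float = 300.0
    treecover_min_pct: float = 30.0

    def validate(self) -> None:
        if not self.elev_min_m < self.elev_max_m:
            raise ValueError("elev_min_m must be < elev_max_m")
        if self.ler_radius_m <= 0 or self.ler_min_m <= 0 or self.treecover_min_pct <= 0:
            raise ValueError("radii and thresholds must be positive")


def _disc_footprint(radius_px: float) -> np.ndarray:
    """Boolean disc: offsets whose centre distance is <= radius (pixels)."""
    r = int(np.floor(radius_px))
    di = np.arange(-r, r + 1)
    dj = np.arange(-r, r + 1)
    dist2 = di[:, None] ** 2 + dj[None, :] ** 2
    return dist2 <= radius_px ** 2 + 1e-9


def local_elevation_range(dem: Grid, radius_m: float) -> Grid:
    """Max minus min elevation within a circular neighbourhood of each pixel.

    The neighbourhood contains every pixel whose centre lies within
    ``radius_m`` (Euclidean, projected metres) of the target pixel centre;
    nodata pixels inside the window are ignored, and the output is nodata
    wherever the target pixel itself is nodata.
    """
    if radius_m < dem.pixel_size:
        raise ValueError("radius_m must be at least one pixel size")
    fp = _disc_footprint(radius_m / dem.pixel_size)
    vals = dem.values.astype(float)
    nan = np.isnan(vals)
    if nan.all():
        return dem.with_values(np.full(dem.shape, np.nan))
    vmax = maximum_filter(np.where(nan, -np.inf, vals), footprint=fp,
                          mode="constant", cval=-np.inf)
    vmin = minimum_filter(np.where(nan, np.inf, vals), footprint=fp,
                          mode="constant", cval=np.inf)
    ler = vmax - vmin
    ler[nan] = np.nan
    return dem.with_values(ler)


def montane_forest_mask(dem: Grid, ler: Grid, treecover: Grid,
                        params: MaskParams | None = None) -> Grid:
    """Boolean montane-forest mask from elevation, LER and tree cover.

    True iff ``elev_min <= dem <= elev_max`` and ``ler > ler_min`` (strict)
    and ``treecover >= treecover_min`` (inclusive).  Nodata in any input
    yields False.
    """
    params = params or MaskParams()
    params.validate()
    dem.require_same_geometry(ler, "LER grid")
    dem.require_same_geometry(treecover, "tree-cover grid")
    with np.errstate(invalid="ignore"):
        mask = ((dem.values >= params.elev_min_m)
                & (dem.values <= params.elev_max_m)
                & (ler.values > params.ler_min_m)
                & (treecover.values >= params.treecover_min_pct))
    return dem.with_values(mask)


def coarsen_mask(fine_mask: Grid, factor: int, min_frac: float = 0.5) -> Grid:
    """Aggregate a fine boolean mask: a coarse pixel is set when at least
    ``min_frac`` of its fine pixels are set."""
    frac = fine_mask.with_values(fine_mask.values.astype(float)).block_reduce(factor, np.nanmean)
    return frac.with_values(frac.values >= min_frac)
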