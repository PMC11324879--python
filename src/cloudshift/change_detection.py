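"""Deforestation detection and recovery filtering.

Two ingredients: (1) the normalised difference fraction index (NDFI),
computed from fully constrained spectral-mixture fractions of green
vegetation (GV), non-photosynthetic vegetation (NPV), soil and shade; and
(2) a non-parametric trend test on the annual NDFI series (Theil–Sen slope
plus two-sided Mann–Kendall) that classifies each pixel as loss, gain, or
stable.  A pixel is kept as deforested only when its recorded loss year
falls in 2004–2022, it lies inside the montane-forest mask, and the NDFI
trend confirms statistically significant loss (recovered pixels drop out).

NDFI is defined as

    NDFI = (GV_shade - (NPV + Soil)) / (GV_shade + NPV + Soil),

with the shade-normalised GV fraction GV_shade = GV / (1 - Shade); it is 1
for intact shaded-canopy forest and falls towards -1 as soil and NPV
dominate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .raster import Grid

__all__ = ["SpectralEndmembers", "TrendResult", "unmix_and_ndfi", "ndfi",
           "mann_kendall", "ndfi_trend", "ndfi_trend_grid", "select_loss_pixels"]

CLASS_LOSS, CLASS_GAIN, CLASS_STABLE = "loss", "gain", "stable"
# numeric codes for grid-valued trend classes
CODE = {CLASS_LOSS: -1, CLASS_STABLE: 0, CLASS_GAIN: 1}

# Landsat-style default endmember reflectances (blue, green, red, NIR, SWIR1,
# SWIR2), rescaled to [0, 1]; a configurable input with these documented
# defaults.
DEFAULT_ENDMEMBERS = {
    "gv": (0.05, 0.09, 0.04, 0.61, 0.30, 0.10),
    "npv": (0.14, 0.17, 0.22, 0.30, 0.55, 0.30),
    "soil": (0.20, 0.30, 0.34, 0.58, 0.60, 0.58),
    "shade": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}


@dataclasses.dataclass
class SpectralEndmembers:
    """Per-class endmember reflectance vectors, stacked bands x classes."""

    gv: np.ndarray
    npv: np.ndarray
    soil: np.ndarray
    shade: np.ndarray

    @classmethod
    def default(cls) -> "SpectralEndmembers":
        return cls(**{k: np.asarray(v, float) for k, v in DEFAULT_ENDMEMBERS.items()})

    def matrix(self) -> np.ndarray:
        m = np.column_stack([np.asarray(self.gv, float), np.asarray(self.npv, float),
                             np.asarray(self.soil, float), np.asarray(self.shade, float)])
        if m.shape[0] < 4:
            raise ValueError("need at least 4 spectral bands")
        if np.any((m < 0) | (m > 1)):
            raise ValueError("endmember reflectances must lie in [0, 1]")
        if np.linalg.matrix_rank(np.vstack([m, np.ones(4)])) < 4:
            raise ValueError("endmember matrix is singular; classes must be independent")
        return m


@dataclasses.dataclass
class TrendResult:
    slope: float          # NDFI units per year
    p_value: float
    klass: str            # loss / gain / stable


def unmix(reflectance: np.ndarray, endmembers: SpectralEndmembers,
          sum_weight: float = 1e3) -> np.ndarray:
    """Fully constrained unmixing: non-negative fractions summing to one.

    ``reflectance`` is (bands,) or (n, bands); returns fractions in the
    order (GV, NPV, soil, shade).  The sum-to-one constraint is enforced by
    an appended heavily weighted row in the non-negative least-squares
    system.
    """
    m = endmembers.matrix()
    a = np.vstack([m, sum_weight * np.ones((1, 4))])
    refl = np.atleast_2d(np.asarray(reflectance, float))
    if refl.shape[1] != m.shape[0]:
        raise ValueError(f"reflectance has {refl.shape[1]} bands, endmembers {m.shape[0]}")
    out = np.empty((refl.shape[0], 4))
    for i, row in enumerate(refl):
        b = np.concatenate([row, [sum_weight]])
        out[i], _ = optimize.nnls(a, b)
    return out[0] if np.asarray(reflectance).ndim == 1 else out


def ndfi(fractions: np.ndarray) -> np.ndarray:
    """NDFI from (..., 4) fractions ordered (GV, NPV, soil, shade)."""
    fr = np.asarray(fractions, float)
    gv, npv, soil, shade = fr[..., 0], fr[..., 1], fr[..., 2], fr[..., 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        gv_shade = np.where(shade < 1.0, gv / (1.0 - shade), 0.0)
        denom = gv_shade + npv + soil
        val = np.where(denom > 0, (gv_shade - (npv + soil)) / denom, 0.0)
    return np.clip(val, -1.0, 1.0)


def unmix_and_ndfi(reflectance: Grid | np.ndarray,
                   endmembers: SpectralEndmembers | None = None) -> Grid | np.ndarray:
    """NDFI of a multi-band reflectance stack ((bands, y, x) array or a list
    of band Grids); NaN in any band propagates."""
    endmembers = endmembers or SpectralEndmembers.default()
    if isinstance(reflectance, (list, tuple)):
        geometry = reflectance[0]
        arr = np.stack([g.values for g in reflectance])
    else:
        geometry, arr = None, np.asarray(reflectance, float)
    bands = arr.shape[0]
    flat = arr.reshape(bands, -1).T
    ok = np.isfinite(flat).all(axis=1)
    out = np.full(flat.shape[0], np.nan)
    if ok.any():
        out[ok] = ndfi(unmix(flat[ok], endmembers))
    out = out.reshape(arr.shape[1:])
    return geometry.with_values(out) if geometry is not None else out


def mann_kendall(y: np.ndarray) -> tuple[int, float]:
    """Two-sided Mann–Kendall trend test (tie-corrected normal approximation).

    Returns (S, p).  A constant series has S = 0 and, by convention, p = 1.
    """
    y = np.asarray(y, float)
    n = len(y)
    s = 0
    for i in range(n - 1):
        s += int(np.sign(y[i + 1:] - y[i]).sum())
    _, counts = np.unique(y, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5) - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var <= 0:
        return s, 1.0
    z = (s - np.sign(s)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(min(p, 1.0))


def ndfi_trend(years: np.ndarray, series: np.ndarray, alpha: float = 0.05) -> TrendResult:
    """Theil–Sen slope + Mann–Kendall significance of an annual NDFI series.

    Missing years (NaN) are dropped; at least 10 non-missing values are
    required.  Class is loss/gain when the slope is negative/positive and
    the Mann–Kendall p-value is below ``alpha``, else stable.
    """
    years = np.asarray(years, float)
    series = np.asarray(series, float)
    ok = np.isfinite(series) & np.isfinite(years)
    if ok.sum() < 10:
        raise ValueError("need at least 10 non-missing years for a trend")
    yy, ss = years[ok], series[ok]
    if np.ptp(ss) == 0:
        return TrendResult(slope=0.0, p_value=1.0, klass=CLASS_STABLE)
    slope = float(stats.theilslopes(ss, yy).slope)
    s, p = mann_kendall(ss[np.argsort(yy)])
    # direction from the Mann–Kendall statistic: for step-like series the
    # Theil–Sen slope can be exactly 0 while the association is significant
    direction = np.sign(s) if s != 0 else np.sign(slope)
    if p < alpha and direction < 0:
        klass = CLASS_LOSS
    elif p < alpha and direction > 0:
        klass = CLASS_GAIN
    else:
        klass = CLASS_STABLE
    return TrendResult(slope=slope, p_value=p, klass=klass)


def ndfi_trend_grid(years: np.ndarray, series: np.ndarray,
                    alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-pixel trend of an (n_years, ...) NDFI stack.

    Returns (slope, p_value, class_code) arrays; class codes are -1 loss,
    0 stable, +1 gain.  Pixels whose series contain tied values (common in
    noise-free scenes) fall back to the tie-corrected scalar test; the
    tie-free majority is fully vectorised.
    """
    years = np.asarray(years, float)
    y = np.asarray(series, float)
    n = len(years)
    ii, jj = np.triu_indices(n, 1)
    dy = y[jj] - y[ii]                       # (pairs, ...)
    slopes = dy / (years[jj] - years[ii])[(...,) + (None,) * (y.ndim - 1)]
    slope = np.median(slopes, axis=0)
    s = np.sign(dy).sum(axis=0)
    var = n * (n - 1) * (2 * n + 5) / 18.0
    z = (s - np.sign(s)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    constant = np.ptp(y, axis=0) == 0
    p = np.where(constant, 1.0, p)
    slope = np.where(constant, 0.0, slope)
    tied = (dy == 0).any(axis=0) & ~constant
    if np.any(tied):
        flat = y.reshape(n, -1)
        p_flat = p.reshape(-1)
        for k in np.flatnonzero(tied.reshape(-1)):
            _, p_flat[k] = mann_kendall(flat[:, k])
        p = p_flat.reshape(p.shape)
    direction = np.where(s != 0, np.sign(s), np.sign(slope))
    code = np.zeros(slope.shape, dtype=int)
    code[(p < alpha) & (direction < 0)] = CODE[CLASS_LOSS]
    code[(p < alpha) & (direction > 0)] = CODE[CLASS_GAIN]
    return slope, p, code


def select_loss_pixels(loss_year: Grid, trend_code: Grid, montane: Grid,
                       first_year: int = 2004, last_year: int = 2022) -> Grid:
    """Deforestation mask: montane pixels whose recorded loss year falls in
    2004–2022 and whose NDFI trend confirms loss (recovered/gain pixels and
    pre-2004 losses are discarded)."""
    loss_year.require_same_geometry(trend_code, "trend grid")
    loss_year.require_same_geometry(montane, "montane mask")
    ly = loss_year.values
    sel = (montane.values.astype(bool)
           & (ly >= first_year) & (ly <= last_year)
           & (trend_code.values == CODE[CLASS_LOSS]))
    return loss_year.with_values(sel)
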