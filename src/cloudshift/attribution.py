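"""Decomposition of temperature change into climate and deforestation parts.

For each deforested pixel, the background climate signal ΔT_cc is estimated
from nearby *stable* forest pixels — pixels with no significant tree-cover
change within a 5-km search radius whose elevation lies inside the
fine-scale elevation envelope of the loss pixel — combined by power-1
inverse distance weighting:

    ΔT_cc = Σ_x (ΔT_x / d_x) / Σ_x (1 / d_x)

The deforestation-induced change is then the residual ΔT_fcc = ΔT − ΔT_cc,
so the identity ΔT = ΔT_fcc + ΔT_cc holds exactly wherever ΔT_cc is
defined.  Loss pixels with fewer than ``n_min`` admissible references are
flagged excluded and carry no attribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .raster import Grid

__all__ = ["ReferenceSet", "AttributionResult", "find_stable_references",
           "idw_climate_signal", "decompose", "attribute"]


@dataclasses.dataclass
class ReferenceSet:
    """Per-loss-pixel stable references: indices, distances, exclusion flags.

    ``loss_rc`` is the (n_loss, 2) array of loss pixel (row, col); entry *i*
    of ``ref_indices`` holds flat indices (row-major) of that pixel's
    admissible stable references and ``ref_distances`` the matching
    centre-to-centre distances in metres.
    """

    loss_rc: np.ndarray
    ref_indices: list[np.ndarray]
    ref_distances: list[np.ndarray]
    n_min: int
    radius_m: float
    grid_shape: tuple[int, int]

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(r) for r in self.ref_indices])

    @property
    def excluded(self) -> np.ndarray:
        return self.counts < self.n_min

    def count_grid(self, template: Grid) -> Grid:
        out = np.zeros(template.shape, dtype=int)
        out[self.loss_rc[:, 0], self.loss_rc[:, 1]] = self.counts
        return template.with_values(out)


@dataclasses.dataclass
class AttributionResult:
    """ΔT decomposition grids for one temperature variable."""

    variable: str
    dT_total: Grid
    dT_cc: Grid
    dT_fcc: Grid
    reference_count: Grid


def find_stable_references(loss_mask: Grid, stable_mask: Grid, dem: Grid,
                           radius_m: float = 5000.0, n_min: int = 3,
                           elev_min: Grid | None = None,
                           elev_max: Grid | None = None) -> ReferenceSet:
    """Admissible stable references for every loss pixel.

    A stable pixel qualifies when its centre lies within ``radius_m`` of the
    loss pixel centre and its elevation falls inside the loss pixel's
    elevation envelope ``[elev_min, elev_max]`` (fine-scale min/max within
    the pixel; when the envelope grids are omitted the pixel's own DEM value
    is used for both bounds, i.e. a flat-terrain degenerate envelope).
    """
    loss_mask.require_same_geometry(stable_mask, "stable mask")
    loss_mask.require_same_geometry(dem, "DEM")
    lm = loss_mask.values.astype(bool)
    sm = stable_mask.values.astype(bool)
    if np.any(lm & sm):
        raise ValueError("loss and stable masks must be disjoint")
    emin = (elev_min.values if elev_min is not None else dem.values)
    emax = (elev_max.values if elev_max is not None else dem.values)

    coords = loss_mask.centre_coords()
    loss_rc = np.argwhere(lm)
    stable_flat = np.flatnonzero(sm.ravel())
    ref_indices: list[np.ndarray] = []
    ref_distances: list[np.ndarray] = []
    if len(stable_flat) == 0:
        import warnings
        warnings.warn("empty stable mask: every loss pixel is excluded", stacklevel=2)
        for _ in loss_rc:
            ref_indices.append(np.empty(0, int))
            ref_distances.append(np.empty(0))
    else:
        tree = cKDTree(coords[stable_flat])
        stable_elev = dem.values.ravel()[stable_flat]
        for r, c in loss_rc:
            centre = coords[r * loss_mask.shape[1] + c]
            hits = tree.query_ball_point(centre, r=radius_m)
            hits = np.asarray(hits, int)
            if hits.size:
                lo, hi = emin[r, c], emax[r, c]
                ok = (stable_elev[hits] >= lo) & (stable_elev[hits] <= hi)
                hits = hits[ok]
            d = np.linalg.norm(coords[stable_flat[hits]] - centre, axis=1) if hits.size else np.empty(0)
            ref_indices.append(stable_flat[hits])
            ref_distances.append(d)
    return ReferenceSet(loss_rc=loss_rc, ref_indices=ref_indices,
                        ref_distances=ref_distances, n_min=n_min,
                        radius_m=radius_m, grid_shape=loss_mask.shape)


def idw_climate_signal(refs: ReferenceSet, dT: Grid) -> np.ndarray:
    """Power-1 IDW of reference ΔT values, one value per loss pixel.

    Excluded pixels (fewer than ``n_min`` references) return NaN.  A
    reference at zero distance is used directly (its weight is infinite in
    the limit); the output always lies within [min ΔT_x, max ΔT_x].
    """
    flat = dT.values.ravel()
    out = np.full(len(refs.loss_rc), np.nan)
    for i, (idx, d) in enumerate(zip(refs.ref_indices, refs.ref_distances)):
        if len(idx) < refs.n_min:
            continue
        vals = flat[idx]
        ok = np.isfinite(vals)
        vals, dd = vals[ok], d[ok]
        if len(vals) < refs.n_min:
            continue
        zero = dd == 0
        if zero.any():
            out[i] = vals[zero][0]
        else:
            w = 1.0 / dd
            out[i] = np.sum(vals * w) / np.sum(w)
    return out


def decompose(variable: str, dT_total: Grid, dT_cc_values: np.ndarray,
              refs: ReferenceSet) -> AttributionResult:
    """ΔT_fcc = ΔT − ΔT_cc on loss pixels; the sum identity is exact.

    ``dT_cc_values`` is the per-loss-pixel IDW output aligned with
    ``refs.loss_rc``; pixels excluded (NaN) stay undefined in every output
    grid.
    """
    dT_cc = np.full(dT_total.shape, np.nan)
    dT_cc[refs.loss_rc[:, 0], refs.loss_rc[:, 1]] = dT_cc_values
    total = np.where(np.isfinite(dT_cc), dT_total.values, np.nan)
    dT_fcc = total - dT_cc
    return AttributionResult(
        variable=variable,
        dT_total=dT_total.with_values(total),
        dT_cc=dT_total.with_values(dT_cc),
        dT_fcc=dT_total.with_values(dT_fcc),
        reference_count=refs.count_grid(dT_total),
    )


def attribute(variable: str, dT_total: Grid, loss_mask: Grid, stable_mask: Grid,
              dem: Grid, radius_m: float = 5000.0, n_min: int = 3,
              elev_min: Grid | None = None, elev_max: Grid | None = None,
              refs: ReferenceSet | None = None) -> AttributionResult:
    """End-to-end attribution for one variable; ``refs`` may be reused
    across variables sharing the same masks."""
    if refs is None:
        refs = find_stable_references(loss_mask, stable_mask, dem,
                                      radius_m=radius_m, n_min=n_min,
                                      elev_min=elev_min, elev_max=elev_max)
    cc = idw_climate_signal(refs, dT_total)
    return decompose(variable, dT_total, cc, refs)
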