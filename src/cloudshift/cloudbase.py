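"""Cloud base height via the Espy approximation and its change decomposition.

The cloud base height (CBH) — the lifting condensation level of a
near-surface parcel — is approximated as

    CBH = 125 m/°C × (T_air − T_dew),

which is accurate to within about 2% for relative humidity above 50% and
temperatures between 0 and 30 °C.  Because the relation is linear in the
dew-point depression, a temperature-change decomposition carries over
exactly:  ΔCBH_cc = 125 (ΔT_air,cc − ΔT_dew,cc)  and
ΔCBH_fcc = ΔCBH − ΔCBH_cc.

An independent iterative adiabatic parcel-lifting LCL computation
(:func:`parcel_lcl`) is provided as the physical reference: the parcel is
lifted dry-adiabatically at constant mixing ratio from a standard surface
pressure until saturation, and the geometric ascent height follows from the
hydrostatic relation using the parcel's virtual temperature.

The 30-year climate-only CBH change uses a coarse reanalysis cube with a
static vegetation state: CBH is evaluated per year from annual-mean air and
dew-point temperature and the change is the ordinary-least-squares trend
slope times the record length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import xarray as xr

from .attribution import AttributionResult
from .raster import Grid
from .temperature import saturation_vapour_pressure

__all__ = ["EspyParams", "CBHResult", "espy_cbh", "espy_validity",
           "parcel_lcl", "decompose_cbh", "climate_cbh_change"]

# thermodynamic constants for the parcel oracle
_RD = 287.04        # J kg-1 K-1, dry air gas constant
_CP = 1004.7        # J kg-1 K-1, dry air isobaric heat capacity
_G = 9.80665        # m s-2
_EPS = 0.622        # molecular weight ratio water/dry air
_KAPPA = _RD / _CP
_P0_KPA = 101.325   # standard surface pressure


@dataclasses.dataclass
class EspyParams:
    coefficient_m_per_K: float = 125.0
    # validity envelope of the approximation
    rh_min: float = 0.5
    t_min_c: float = 0.0
    t_max_c: float = 30.0

    def validate(self) -> None:
        if self.coefficient_m_per_K <= 0:
            raise ValueError("coefficient must be positive")


@dataclasses.dataclass
class CBHResult:
    air_variable: str
    cbh_2003: Grid
    cbh_2022: Grid
    dCBH_total: Grid
    dCBH_cc: Grid
    dCBH_fcc: Grid


def espy_cbh(t_air: Grid, t_dew: Grid, params: EspyParams | None = None) -> Grid:
    """CBH (m) = coefficient × (t_air − t_dew); negative spreads give
    negative heights (supersaturation; see :func:`espy_validity`)."""
    params = params or EspyParams()
    params.validate()
    t_air.require_same_geometry(t_dew, "dew-point grid")
    return t_air.with_values(params.coefficient_m_per_K * (t_air.values - t_dew.values))


def espy_validity(t_air: Grid, t_dew: Grid, params: EspyParams | None = None) -> Grid:
    """Boolean grid: True where the Espy approximation's stated validity
    holds (RH = es(Td)/es(T) above 50%, T in [0, 30] °C, no supersaturation)."""
    params = params or EspyParams()
    ta, td = t_air.values, t_dew.values
    with np.errstate(invalid="ignore"):
        rh = saturation_vapour_pressure(np.where(np.isfinite(td), td, 0.0)) \
            / saturation_vapour_pressure(np.where(np.isfinite(ta), ta, 1.0))
        ok = (np.isfinite(ta) & np.isfinite(td)
              & (rh > params.rh_min) & (ta >= params.t_min_c) & (ta <= params.t_max_c)
              & (td <= ta))
    return t_air.with_values(ok)


def parcel_lcl(t_air_c, rh, p0_kpa: float = _P0_KPA, tol_kpa: float = 1e-7) -> np.ndarray:
    """Lifting condensation level (m) by iterative adiabatic parcel ascent.

    The parcel starts at temperature ``t_air_c`` (°C), relative humidity
    ``rh`` (0–1], pressure ``p0_kpa``, and is lifted along the dry adiabat
    T(p) = T0 (p/p0)^(Rd/cp) at constant water-vapour mixing ratio, so the
    parcel's vapour pressure scales as e(p) = e0 p/p0.  The LCL pressure
    solves es(T(p)) = e(p) (bisection to ``tol_kpa``); the ascent height is
    the hydrostatic integral along the adiabat, cp (T0 − T_lcl) / g.
    Because both the adiabat and the vapour-pressure dilution depend only on
    the ratio p/p0, the result is independent of the chosen surface
    pressure.

    This routine shares no algebra with :func:`espy_cbh` beyond the Magnus
    saturation-pressure formula and serves as its independent physical
    check.  Note the check exposes the approximation's limits: very close
    to saturation at warm temperatures the true height-per-degree exceeds
    125 m/°C by slightly more than 2%.
    """
    t0 = np.atleast_1d(np.asarray(t_air_c, float)) + 273.15
    rh = np.broadcast_to(np.atleast_1d(np.asarray(rh, float)), t0.shape).astype(float)
    if np.any((rh <= 0) | (rh > 1)):
        raise ValueError("relative humidity must lie in (0, 1]")
    es0 = saturation_vapour_pressure(t0 - 273.15)
    e0 = rh * es0

    def excess(p):
        """es(T(p)) - e(p); positive while the parcel is unsaturated."""
        t = t0 * (p / p0_kpa) ** _KAPPA
        return saturation_vapour_pressure(t - 273.15) - e0 * p / p0_kpa

    lo = np.full_like(t0, 0.2 * p0_kpa)
    hi = np.full_like(t0, p0_kpa)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        pos = excess(mid) > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
        if np.max(hi - lo) < tol_kpa:
            break
    p_lcl = 0.5 * (lo + hi)
    t_lcl = t0 * (p_lcl / p0_kpa) ** _KAPPA
    z = _CP * (t0 - t_lcl) / _G
    return z if np.asarray(t_air_c).ndim or np.asarray(rh).ndim else float(z[0])


def decompose_cbh(cbh_2003: Grid, cbh_2022: Grid, attr_air: AttributionResult,
                  attr_dew: AttributionResult, params: EspyParams | None = None,
                  air_variable_2003: str | None = None,
                  air_variable_2022: str | None = None) -> CBHResult:
    """Split the 2003→2022 CBH change into climate and deforestation parts.

    ``attr_air`` is the attribution result of the air-temperature variable
    that entered the Espy equation (Tmean by default in the pipeline;
    configurable to Tmax) and ``attr_dew`` the dew-point attribution.  The
    identity ΔCBH = ΔCBH_fcc + ΔCBH_cc holds exactly wherever the climate
    component is defined.
    """
    params = params or EspyParams()
    params.validate()
    if attr_dew.variable != "tdew":
        raise ValueError("attr_dew must be the dew-point attribution")
    if attr_air.variable not in ("tmax", "tmean"):
        raise ValueError(f"unsupported air-temperature variable {attr_air.variable!r}")
    v03 = air_variable_2003 or attr_air.variable
    v22 = air_variable_2022 or attr_air.variable
    if not (v03 == v22 == attr_air.variable):
        raise ValueError("mixing air-temperature variables across years: "
                         f"2003={v03!r}, 2022={v22!r}, attribution={attr_air.variable!r}")
    cbh_2003.require_same_geometry(cbh_2022, "2022 CBH grid")
    c = params.coefficient_m_per_K
    d_total = cbh_2022.values - cbh_2003.values
    d_cc = c * (attr_air.dT_cc.values - attr_dew.dT_cc.values)
    d_total = np.where(np.isfinite(d_cc), d_total, np.nan)
    d_fcc = d_total - d_cc
    return CBHResult(air_variable=attr_air.variable,
                     cbh_2003=cbh_2003, cbh_2022=cbh_2022,
                     dCBH_total=cbh_2003.with_values(d_total),
                     dCBH_cc=cbh_2003.with_values(d_cc),
                     dCBH_fcc=cbh_2003.with_values(d_fcc))


def climate_cbh_change(reanalysis: xr.Dataset, params: EspyParams | None = None,
                       fine_factor: int = 1, min_valid_years: int = 10) -> Grid:
    """Climate-only CBH change over a multi-decade coarse reanalysis record.

    Per coarse pixel, CBH is computed per year from annual-mean ``t_air``
    and ``t_dew``, an ordinary-least-squares trend is fitted against year,
    and the change is slope × record length (30 years for 1992–2022).
    Pixels with fewer than ``min_valid_years`` valid years are nodata.  The
    result is resampled to the fine analysis grid by nearest neighbour when
    ``fine_factor`` > 1.
    """
    params = params or EspyParams()
    years = np.asarray(reanalysis["year"].values, float)
    if len(years) < 30:
        raise ValueError("need at least 30 annual steps of reanalysis")
    span = years.max() - years.min()
    cbh = params.coefficient_m_per_K * (reanalysis["t_air"].values
                                        - reanalysis["t_dew"].values)
    ny, nr, nc = cbh.shape
    flat = cbh.reshape(ny, -1)
    valid = np.isfinite(flat)
    slope = np.full(flat.shape[1], np.nan)
    enough = valid.sum(axis=0) >= min_valid_years
    # OLS slope, tolerant of per-pixel gaps
    for j in np.flatnonzero(enough):
        ok = valid[:, j]
        slope[j] = np.polyfit(years[ok], flat[ok, j], 1)[0]
    change = (slope * span).reshape(nr, nc)
    from .raster import cube_geometry
    coarse = cube_geometry(reanalysis).with_values(change)
    return coarse.upsample_nearest(fine_factor) if fine_factor > 1 else coarse
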