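"""Synthetic montane scenes with known deforestation and climate signals.

The generator builds a self-consistent toy landscape on a projected metric
grid: smooth terrain, fractional tree cover, discrete tree-loss events (some
of which partially recover), monthly satellite-like observables (day/night
surface temperature, NDVI, albedo), monthly "actual weather" air-temperature
fields, an annual NDFI series for change detection, and a coarse 31-year
reanalysis cube with a static vegetation state.

Every injected signal is stored as ground truth so each downstream stage
(masking, change detection, temperature modelling, attribution, cloud-base
decomposition) can be tested by recovery.

Construction of the temperature fields
--------------------------------------
Monthly maximum air temperature at pixel *p*, month *m*, year *y*:

    Tmax = T0_max - lapse * elev(p)/1000 + A * cos(2*pi*(m-1)/12)
           + trend * (y - 2003)/10 + warming * loss_frac(p, y) + eps(p, m, y)

with ``eps`` spatially correlated Gaussian noise (zero outside noisy runs).
Minimum air temperature uses a smaller seasonal amplitude and the same
warming; dew point follows Tmin minus a fixed spread, dried by
``dewpoint_drying_K`` per unit fractional loss, and warmed by half the
climate trend (so the climate signal changes the dew-point depression).
Surface temperature observables are the air-temperature fields plus constant
offsets; NDVI increases monotonically with tree cover; albedo decreases.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .raster import Grid, make_cube

__all__ = ["SceneConfig", "SceneTruth", "Scene", "generate_scene", "sample_stations"]

BASE_YEAR = 2003
END_YEAR = 2022
MONTHS = np.arange(1, 13)

# Fixed scene constants (documented in docs/methods.md).
T0_MAX_C = 30.0          # sea-level monthly-mean Tmax
T0_MIN_C = 18.0          # sea-level monthly-mean Tmin
SEASONAL_AMP_K = 3.0     # Tmax seasonal half-amplitude; Tmin uses 0.6x
DEW_SPREAD_K = 2.0       # Tdew = Tmin - DEW_SPREAD_K before drying
DEW_TREND_RATIO = 0.5    # dew point warms at half the air-temperature trend
LST_DAY_OFFSET = 2.0     # LST_day = Tmax + offset
LST_NIGHT_OFFSET = -1.0  # LST_night = Tmin + offset
RECOVERY_FRACTION = 0.9  # recovered patches regain 90% of lost cover by 2022
RECOVERY_YEARS = 8.0


@dataclasses.dataclass
class SceneConfig:
    """Parameters of a synthetic scene; all randomness flows from ``seed``."""

    grid_shape: tuple[int, int] = (100, 100)
    pixel_size_m: float = 1000.0
    elevation_range_m: tuple[float, float] = (800.0, 3600.0)
    lapse_rate_K_per_km: float = 6.5
    deforestation_warming_K: float = 2.0     # per unit fractional tree-cover loss
    climate_trend_K_per_decade: float = 0.2
    dewpoint_drying_K: float = 1.0           # per unit fractional loss (lowers Tdew)
    noise_sd_K: float = 0.3
    spatial_corr_length_m: float = 5000.0
    n_loss_events: int = 15
    loss_year_range: tuple[int, int] = (2004, 2020)
    seed: int = 0
    fine_factor: int = 5      # terrain/tree-cover generated at this subdivision
    coarse_factor: int = 10   # reanalysis block size, in analysis pixels
    nodata_frac: float = 0.01  # per-month missing-observation fraction in LST
    recovered_event_frac: float = 0.25

    def validate(self) -> None:
        nr, nc = self.grid_shape
        if nr <= 0 or nc <= 0:
            raise ValueError("grid_shape must be strictly positive")
        lo, hi = self.elevation_range_m
        for name in ("pixel_size_m", "lapse_rate_K_per_km", "deforestation_warming_K",
                     "climate_trend_K_per_decade", "dewpoint_drying_K", "noise_sd_K",
                     "spatial_corr_length_m"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite config value: {name}={v}")
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("elevation_range_m must be finite with min < max")
        if self.noise_sd_K < 0:
            raise ValueError("noise_sd_K must be >= 0")
        y0, y1 = self.loss_year_range
        if not (BASE_YEAR < y0 <= y1 <= END_YEAR):
            raise ValueError(f"loss_year_range must lie within ({BASE_YEAR + 1}, {END_YEAR})")


@dataclasses.dataclass
class SceneTruth:
    """Ground-truth grids of a synthetic scene (analysis resolution)."""

    dem: Grid                 # m a.s.l.
    dem_fine: Grid            # fine-resolution terrain (fine_factor x denser)
    elev_min: Grid            # per-pixel min of fine elevation (envelope)
    elev_max: Grid
    treecover_2003: Grid      # percent, 0..100
    treecover_2022: Grid
    loss_year: Grid           # calendar year of loss, 0 = stable
    loss_fraction: Grid       # fractional loss at event time (0..1)
    recovered: Grid           # bool: loss patch that regrew by 2022
    effective_loss_2022: Grid  # fractional loss still present in 2022
    true_dT_fcc: Grid         # injected deforestation warming (air temperature, K)
    true_dT_cc: Grid          # injected climate warming 2003->2022 (K)
    true_dTdew_fcc: Grid      # injected dew-point change from loss (K, negative)
    true_dCBH_fcc: Grid       # implied cloud-base rise from loss (m)


@dataclasses.dataclass
class Scene:
    config: SceneConfig
    truth: SceneTruth
    cube: xr.Dataset          # monthly observables + air fields, 2003 and 2022
    reanalysis: xr.Dataset    # annual coarse t_air/t_dew, 1992..2022
    ndfi_annual: xr.DataArray  # (year, y, x) annual NDFI, 2003..2022


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=max(sigma_px, 1e-6), mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _grow_patch(rng: np.random.Generator, shape: tuple[int, int], start: tuple[int, int],
                size: int) -> list[tuple[int, int]]:
    """Contiguous patch grown by a random walk from ``start``."""
    nr, nc = shape
    patch = {start}
    frontier = [start]
    while len(patch) < size and frontier:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = ((0, 1), (0, -1), (1, 0), (-1, 0))[rng.integers(4)]
        nr_, nc_ = r + dr, c + dc
        if 0 <= nr_ < nr and 0 <= nc_ < nc:
            if (nr_, nc_) not in patch:
                patch.add((nr_, nc_))
                frontier.append((nr_, nc_))
        if rng.random() < 0.05:  # occasionally drop stale frontier cells
            frontier.pop(rng.integers(len(frontier)))
            if not frontier:
                frontier = list(patch)
    return sorted(patch)


def _effective_loss(loss_fraction: np.ndarray, loss_year: np.ndarray,
                    recovered: np.ndarray, year: int) -> np.ndarray:
    """Fractional tree-cover loss still present in ``year``."""
    occurred = (loss_year > 0) & (loss_year <= year)
    eff = np.where(occurred, loss_fraction, 0.0)
    years_since = np.clip(year - loss_year, 0.0, None)
    regrown = RECOVERY_FRACTION * np.clip(years_since / RECOVERY_YEARS, 0.0, 1.0)
    eff = np.where(occurred & recovered, eff * (1.0 - regrown), eff)
    return eff


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a full synthetic scene from a validated config.

    Returns the scene bundle: ground truth, the monthly observable cube for
    2003 and 2022, and the 1992–2022 coarse reanalysis cube (fine truth
    block-averaged to ``coarse_factor`` × the analysis pixel, with a static
    vegetation state, i.e. no deforestation signal).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nr, nc = config.grid_shape
    f = config.fine_factor
    fine_shape = (nr * f, nc * f)
    fine_px = config.pixel_size_m / f
    template = Grid(np.zeros(config.grid_shape), origin=(0.0, 0.0),
                    pixel_size=config.pixel_size_m)

    # --- terrain: smoothed random field rescaled to the elevation range
    sigma_fine = max(config.spatial_corr_length_m, 4 * config.pixel_size_m) / fine_px
    terrain = _smooth_field(rng, fine_shape, sigma_fine)
    lo, hi = config.elevation_range_m
    terrain = lo + (hi - lo) * (terrain - terrain.min()) / np.ptp(terrain)
    dem_fine = Grid(terrain, origin=(0.0, 0.0), pixel_size=fine_px)
    dem = dem_fine.block_reduce(f, np.nanmean)
    elev_min = dem_fine.block_reduce(f, np.nanmin)
    elev_max = dem_fine.block_reduce(f, np.nanmax)

    # --- baseline tree cover: smooth field, denser at mid elevations
    cover_field = _smooth_field(rng, fine_shape, sigma_fine / 2)
    cover_fine = np.clip(55.0 + 30.0 * cover_field - 10.0 * np.abs(terrain - 2000.0) / 1000.0,
                         0.0, 100.0)
    tc2003 = Grid(cover_fine, origin=(0.0, 0.0), pixel_size=fine_px).block_reduce(f, np.nanmean)

    # --- discrete loss events: contiguous random-walk patches
    loss_fraction = np.zeros(config.grid_shape)
    loss_year = np.zeros(config.grid_shape)
    recovered = np.zeros(config.grid_shape, dtype=bool)
    candidates = np.argwhere(tc2003.values >= 30.0)
    y0, y1 = config.loss_year_range
    for _ in range(config.n_loss_events):
        if len(candidates) == 0:
            break
        r, c = candidates[rng.integers(len(candidates))]
        size = int(rng.integers(3, 21))
        patch = _grow_patch(rng, config.grid_shape, (int(r), int(c)), size)
        frac = rng.uniform(0.05, 0.90)
        is_recovered = rng.random() < config.recovered_event_frac
        year = int(rng.integers(y0, min(y1, 2010) + 1)) if is_recovered \
            else int(rng.integers(y0, y1 + 1))
        for rr, cc in patch:
            if loss_year[rr, cc] == 0:  # first event wins; no stacking
                loss_fraction[rr, cc] = frac
                loss_year[rr, cc] = year
                recovered[rr, cc] = is_recovered
    eff_2022 = _effective_loss(loss_fraction, loss_year, recovered, END_YEAR)
    tc2022 = tc2003.values * (1.0 - eff_2022)

    # --- truth grids
    trend_total = config.climate_trend_K_per_decade * (END_YEAR - BASE_YEAR) / 10.0
    true_dT_fcc = config.deforestation_warming_K * eff_2022
    true_dTdew_fcc = -config.dewpoint_drying_K * eff_2022
    true_dCBH_fcc = 125.0 * (true_dT_fcc - true_dTdew_fcc)

    truth = SceneTruth(
        dem=dem, dem_fine=dem_fine, elev_min=elev_min, elev_max=elev_max,
        treecover_2003=tc2003, treecover_2022=tc2003.with_values(tc2022),
        loss_year=template.with_values(loss_year),
        loss_fraction=template.with_values(loss_fraction),
        recovered=template.with_values(recovered),
        effective_loss_2022=template.with_values(eff_2022),
        true_dT_fcc=template.with_values(true_dT_fcc),
        true_dT_cc=template.with_values(np.full(config.grid_shape, trend_total)),
        true_dTdew_fcc=template.with_values(true_dTdew_fcc),
        true_dCBH_fcc=template.with_values(true_dCBH_fcc),
    )

    # --- monthly observable cube for 2003 and 2022
    elev_km = dem.values / 1000.0
    sigma_analysis = config.spatial_corr_length_m / config.pixel_size_m

    def noise() -> np.ndarray:
        if config.noise_sd_K == 0:
            return np.zeros(config.grid_shape)
        return config.noise_sd_K * _smooth_field(rng, config.grid_shape, sigma_analysis)

    times, fields = [], {k: [] for k in
                         ("lst_day", "lst_night", "ndvi", "albedo",
                          "air_tmax", "air_tmin", "air_tdew")}
    for year in (BASE_YEAR, END_YEAR):
        eff = _effective_loss(loss_fraction, loss_year, recovered, year)
        cover = tc2003.values * (1.0 - eff)
        dec = (year - BASE_YEAR) / 10.0
        for month in MONTHS:
            seas = SEASONAL_AMP_K * np.cos(2 * np.pi * (month - 1) / 12.0)
            base_max = (T0_MAX_C - config.lapse_rate_K_per_km * elev_km + seas
                        + config.climate_trend_K_per_decade * dec
                        + config.deforestation_warming_K * eff)
            base_min = (T0_MIN_C - config.lapse_rate_K_per_km * elev_km + 0.6 * seas
                        + config.climate_trend_K_per_decade * dec
                        + config.deforestation_warming_K * eff)
            # dew point tracks elevation/season like Tmin but carries its own
            # signals: drying with loss, and half the climate trend
            base_dew = (T0_MIN_C - DEW_SPREAD_K
                        - config.lapse_rate_K_per_km * elev_km + 0.6 * seas
                        + DEW_TREND_RATIO * config.climate_trend_K_per_decade * dec
                        - config.dewpoint_drying_K * eff)
            air_tmax = base_max + noise()
            air_tmin = base_min + noise()
            air_tdew = base_dew + noise()
            lst_day = air_tmax + LST_DAY_OFFSET
            lst_night = air_tmin + LST_NIGHT_OFFSET
            if config.nodata_frac > 0:
                holes = rng.random(config.grid_shape) < config.nodata_frac
                lst_day = np.where(holes, np.nan, lst_day)
                lst_night = np.where(holes, np.nan, lst_night)
            ndvi_noise = 0.01 * noise() / max(config.noise_sd_K, 1.0) \
                if config.noise_sd_K > 0 else 0.0
            ndvi = np.clip(0.15 + 0.0075 * cover + 0.01 * seas / SEASONAL_AMP_K
                           + ndvi_noise, 0.0, 1.0)
            albedo = np.clip(0.23 - 0.0008 * cover, 0.05, 0.40)
            for name, arr in (("lst_day", lst_day), ("lst_night", lst_night),
                              ("ndvi", ndvi), ("albedo", albedo),
                              ("air_tmax", air_tmax), ("air_tmin", air_tmin),
                              ("air_tdew", air_tdew)):
                fields[name].append(arr)
            times.append(year * 100 + int(month))
    cube = make_cube({k: np.stack(v) for k, v in fields.items()}, times, template)
    # latitude/longitude pseudo-degrees from the metric coordinates
    xs, ys = template.xy_centres()
    lon2d, lat2d = np.meshgrid(xs / 111000.0, ys / 111000.0)
    cube["lat"] = (("y", "x"), lat2d)
    cube["lon"] = (("y", "x"), lon2d)

    # --- annual NDFI series 2003..2022 (degradation-sensitive index)
    years = np.arange(BASE_YEAR, END_YEAR + 1)
    ndfi = np.empty((len(years), nr, nc))
    ndfi_sd = 0.03 if config.noise_sd_K > 0 else 0.0
    for i, year in enumerate(years):
        cover = tc2003.values * (1.0 - _effective_loss(loss_fraction, loss_year,
                                                       recovered, int(year)))
        layer = -0.2 + 0.011 * cover
        if ndfi_sd > 0:
            layer = layer + ndfi_sd * rng.standard_normal(config.grid_shape)
        ndfi[i] = np.clip(layer, -1.0, 1.0)
    x, y = template.xy_centres()
    ndfi_annual = xr.DataArray(ndfi, dims=("year", "y", "x"),
                               coords={"year": years, "y": y, "x": x})

    # --- coarse reanalysis 1992..2022: static vegetation, climate trend only
    cf = config.coarse_factor
    if nr % cf or nc % cf:
        raise ValueError(f"grid_shape {config.grid_shape} must be divisible by "
                         f"coarse_factor {cf}")
    coarse_template = template.block_reduce(cf, np.nanmean)
    elev_km_coarse = dem.block_reduce(cf, np.nanmean).values / 1000.0
    re_years = np.arange(1992, END_YEAR + 1)
    t_air = np.empty((len(re_years),) + coarse_template.shape)
    t_dew = np.empty_like(t_air)
    re_noise_sd = config.noise_sd_K / 3.0
    tmean0 = (T0_MAX_C + T0_MIN_C) / 2.0
    for i, year in enumerate(re_years):
        dec = (year - BASE_YEAR) / 10.0
        base_air = tmean0 - config.lapse_rate_K_per_km * elev_km_coarse \
            + config.climate_trend_K_per_decade * dec
        base_dew = (T0_MIN_C - DEW_SPREAD_K - config.lapse_rate_K_per_km * elev_km_coarse
                    + DEW_TREND_RATIO * config.climate_trend_K_per_decade * dec)
        if re_noise_sd > 0:
            base_air = base_air + re_noise_sd * rng.standard_normal(coarse_template.shape)
            base_dew = base_dew + re_noise_sd * rng.standard_normal(coarse_template.shape)
        t_air[i], t_dew[i] = base_air, base_dew
    reanalysis = make_cube({"t_air": t_air, "t_dew": t_dew}, re_years, coarse_template)
    reanalysis = reanalysis.rename({"time": "year"})

    return Scene(config=config, truth=truth, cube=cube,
                 reanalysis=reanalysis, ndfi_annual=ndfi_annual)


def sample_stations(scene: Scene, n_stations: int, obs_noise_sd: float = 0.5,
                    seed: int | None = None, test_frac: float = 0.3) -> pd.DataFrame:
    """Sample synthetic weather stations from a scene's monthly air fields.

    Stations sit at pixel centres, sampled without replacement; observations
    are the scene's air temperatures plus independent Gaussian noise.  A
    70/30 train/test split tag (stratified by station) is included.
    """
    cube = scene.cube
    valid = np.isfinite(scene.truth.dem.values)
    idx = np.argwhere(valid)
    if n_stations > len(idx):
        raise ValueError(f"n_stations={n_stations} exceeds {len(idx)} valid pixels")
    rng = np.random.default_rng(scene.config.seed + 1 if seed is None else seed)
    chosen = idx[rng.choice(len(idx), size=n_stations, replace=False)]
    n_test = int(round(test_frac * n_stations))
    split = np.array(["train"] * n_stations)
    split[rng.choice(n_stations, size=n_test, replace=False)] = "test"

    xs, ys = scene.truth.dem.xy_centres()
    rows = []
    times = np.asarray(cube["time"].values)
    for sid, ((r, c), tag) in enumerate(zip(chosen, split)):
        for t_i, t in enumerate(times):
            year, month = int(t) // 100, int(t) % 100
            rec = {
                "station_id": sid, "row": int(r), "col": int(c),
                "x": xs[c], "y": ys[r],
                "lon": xs[c] / 111000.0, "lat": ys[r] / 111000.0,
                "year": year, "month": month, "split": tag,
            }
            for var, col in (("air_tmax", "tmax"), ("air_tmin", "tmin"),
                             ("air_tdew", "tdew")):
                val = float(cube[var].values[t_i, r, c])
                if obs_noise_sd > 0:
                    val += rng.normal(0.0, obs_noise_sd)
                rec[col] = val
            rows.append(rec)
    return pd.DataFrame(rows)
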