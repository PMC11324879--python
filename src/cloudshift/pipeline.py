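"""End-to-end orchestration of the attribution pipeline.

Stages run in dependency order from a single :class:`RunConfig`:

  scene → mask → loss → temperature → attribution → cbh → assessment

In synthetic mode the scene stage generates the inputs with known injected
signals; every stage writes its grids/tables under the output directory and
records an array checksum in the manifest, so a rerun with the same config
is bit-identical.  Summary tables (means by elevation band and by latitude
interval) are produced at the end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assessment as assess_mod
from . import attribution as attr_mod
from . import change_detection as cd
from . import cloudbase as cb
from . import montane
from . import synthetic
from . import temperature as tm
from .raster import Grid, array_checksum

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_by_bins"]

log = logging.getLogger("cloudshift")

ALL_STAGES = ("scene", "mask", "loss", "temperature", "attribution", "cbh", "assessment")
_DEPS = {
    "mask": ("scene",),
    "loss": ("scene", "mask"),
    "temperature": ("scene",),
    "attribution": ("scene", "loss", "temperature"),
    "cbh": ("scene", "attribution"),
    "assessment": ("scene", "loss", "temperature", "attribution", "cbh"),
}


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; synthetic mode when ``scene`` is set,
    otherwise ``inputs`` must point at real rasters (exactly one of the
    two)."""

    scene: synthetic.SceneConfig | None = None
    inputs: dict | None = None
    outdir: str = "cloudshift_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # stage parameters
    mask_params: montane.MaskParams = dataclasses.field(default_factory=montane.MaskParams)
    trend_alpha: float = 0.05
    search_radius_m: float = 5000.0
    n_min_references: int = 3
    air_variable: str = "tmean"          # Espy air temperature: tmean | tmax
    n_stations: int = 150
    station_noise_sd: float = 0.5
    rf_trees: int = 150
    accuracy_sample_per_stratum: int = 100

    def __post_init__(self):
        if (self.scene is None) == (self.inputs is None):
            raise ValueError("exactly one of scene (synthetic) or inputs (real) "
                             "must be specified")
        self.stages = tuple(self.stages)
        if self.air_variable not in ("tmean", "tmax"):
            raise ValueError("air_variable must be 'tmean' or 'tmax'")

    # ------------------------------------------------------------ serialisation
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scene is not None:
            d["scene"] = dataclasses.asdict(self.scene)
        d["mask_params"] = dataclasses.asdict(self.mask_params)
        d["stages"] = list(self.stages)
        return d

    def to_yaml(self) -> str:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj
        return yaml.safe_dump(listify(self.to_dict()), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if d.get("scene") is not None:
            sc = d["scene"]
            for key in ("grid_shape", "elevation_range_m", "loss_year_range"):
                sc[key] = tuple(sc[key])
            d["scene"] = synthetic.SceneConfig(**sc)
        d["mask_params"] = montane.MaskParams(**d.get("mask_params", {}))
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def summarize_by_bins(grid: Grid, by: Grid, bin_edges: np.ndarray) -> pd.DataFrame:
    """Per-bin mean/SD/count of ``grid`` grouped by ``by`` (e.g. elevation
    bands or latitude intervals).

    Bins are half-open [lo, hi) with the last bin closed; nodata in either
    grid is ignored.  Empty bins get count 0 and NaN mean/SD.
    """
    grid.require_same_geometry(by, "binning grid")
    edges = np.asarray(bin_edges, float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least two edges")
    v = grid.values.ravel()
    b = by.values.ravel()
    ok = np.isfinite(v) & np.isfinite(b)
    v, b = v[ok], b[ok]
    if len(b) and (b.min() < edges[0] or b.max() > edges[-1]):
        raise ValueError("bin_edges do not cover the data range")
    idx = np.digitize(b, edges, right=False) - 1
    idx[b == edges[-1]] = len(edges) - 2      # last bin closed
    rows = []
    for i in range(len(edges) - 1):
        sel = v[idx == i]
        rows.append({
            "bin_lo": edges[i], "bin_hi": edges[i + 1], "count": int(len(sel)),
            "mean": float(sel.mean()) if len(sel) else np.nan,
            "sd": float(sel.std(ddof=1)) if len(sel) > 1 else
                  (0.0 if len(sel) == 1 else np.nan),
        })
    return pd.DataFrame(rows)


def _write_grid(outdir: Path, name: str, grid: Grid, manifest: dict) -> None:
    path = outdir / f"{name}.tif"
    grid.write_tif(path)
    manifest["outputs"][name] = {"path": str(path),
                                 "checksum": array_checksum(np.asarray(grid.values, float))}


def _annual_mean(da, year: int) -> np.ndarray:
    codes = np.asarray(da["time"].values)
    sel = (codes // 100) == year
    return np.nanmean(da.values[sel], axis=0)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the output manifest."""
    if config.inputs is not None:
        raise NotImplementedError("real-data mode requires externally prepared "
                                  "rasters; only synthetic mode is wired end-to-end")
    for stage in config.stages:
        for dep in _DEPS.get(stage, ()):
            if dep not in config.stages:
                raise PipelineError(f"stage {stage!r} requires stage {dep!r}, "
                                    "which is toggled off")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "stages": {}, "outputs": {}}
    (outdir / "run_config.yaml").write_text(config.to_yaml())
    ctx: dict = {}

    def stage_enabled(name):
        return name in config.stages

    def record(name, t0):
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    # ---------------------------------------------------------------- scene
    if stage_enabled("scene"):
        t0 = time.perf_counter()
        scene_cfg = dataclasses.replace(config.scene, seed=config.seed)
        scene = synthetic.generate_scene(scene_cfg)
        stations = synthetic.sample_stations(scene, config.n_stations,
                                             config.station_noise_sd)
        ctx["scene"], ctx["stations"] = scene, stations
        for name in ("dem", "treecover_2003", "treecover_2022", "loss_year",
                     "effective_loss_2022", "true_dT_fcc", "true_dCBH_fcc"):
            _write_grid(outdir, name, getattr(scene.truth, name), manifest)
        stations.to_csv(outdir / "stations.csv", index=False)
        manifest["outputs"]["stations"] = {
            "path": str(outdir / "stations.csv"),
            "checksum": hashlib.sha256(
                stations.to_csv(index=False).encode()).hexdigest()}
        record("scene", t0)

    # ---------------------------------------------------------------- mask
    if stage_enabled("mask"):
        t0 = time.perf_counter()
        scene = ctx["scene"]
        ler = montane.local_elevation_range(scene.truth.dem, config.mask_params.ler_radius_m)
        mask = montane.montane_forest_mask(scene.truth.dem, ler,
                                           scene.truth.treecover_2003,
                                           config.mask_params)
        ctx["ler"], ctx["montane_mask"] = ler, mask
        _write_grid(outdir, "ler", ler, manifest)
        _write_grid(outdir, "montane_mask", mask, manifest)
        record("mask", t0)

    # ---------------------------------------------------------------- loss
    if stage_enabled("loss"):
        t0 = time.perf_counter()
        scene, mask = ctx["scene"], ctx["montane_mask"]
        years = np.asarray(scene.ndfi_annual["year"].values)
        slope, p, code = cd.ndfi_trend_grid(years, scene.ndfi_annual.values,
                                            alpha=config.trend_alpha)
        trend_code = scene.truth.dem.with_values(code)
        loss_mask = cd.select_loss_pixels(scene.truth.loss_year, trend_code, mask)
        stable_mask = mask.with_values(mask.values.astype(bool)
                                       & (scene.truth.loss_year.values == 0)
                                       & (code == 0))
        ctx.update(trend_code=trend_code, loss_mask=loss_mask, stable_mask=stable_mask)
        _write_grid(outdir, "ndfi_trend_slope", scene.truth.dem.with_values(slope), manifest)
        _write_grid(outdir, "loss_mask", loss_mask, manifest)
        _write_grid(outdir, "stable_mask", stable_mask, manifest)
        record("loss", t0)

    # ---------------------------------------------------------- temperature
    if stage_enabled("temperature"):
        t0 = time.perf_counter()
        scene, stations = ctx["scene"], ctx["stations"]
        cube = scene.cube
        codes = np.asarray(cube["time"].values)
        t_index = {int(c): i for i, c in enumerate(codes)}
        rows_t = np.array([t_index[y * 100 + m] for y, m in
                           zip(stations["year"], stations["month"])])
        rr = stations["row"].to_numpy()
        cc = stations["col"].to_numpy()

        def feat(var):
            da = cube[var]
            if "time" in da.dims:
                return da.values[rows_t, rr, cc]
            return da.values[rr, cc]

        feats = pd.DataFrame({v: feat(v) for v in
                              ("lst_day", "lst_night", "ndvi", "albedo", "lat", "lon")})
        test_mask = (stations["split"] == "test").to_numpy()
        models = {}
        for target in ("tmax", "tmin"):
            models[target] = tm.fit_stacked(target, feats, feats,
                                            stations[target].to_numpy(),
                                            test_mask=test_mask,
                                            n_estimators=config.rf_trees,
                                            seed=config.seed)
        # dew point: es feature from the modelled minimum temperature
        tmin_hat = models["tmin"].predict(feats, feats)
        feats_dew = feats.assign(es=tm.saturation_vapour_pressure(tmin_hat))
        models["tdew"] = tm.fit_stacked("tdew", feats_dew, feats_dew,
                                        stations["tdew"].to_numpy(),
                                        test_mask=test_mask,
                                        n_estimators=config.rf_trees,
                                        seed=config.seed)
        pred = {}
        for target in ("tmax", "tmin"):
            pred[target] = tm.predict_grids(models[target], cube)
        cube_dew = cube.assign(es=(("time", "y", "x"),
                                   tm.saturation_vapour_pressure(pred["tmin"].values)))
        pred["tdew"] = tm.predict_grids(models["tdew"], cube_dew)
        pred["tmean"] = tm.mean_air_temperature(pred["tmax"], pred["tmin"])

        template = ctx["scene"].truth.dem
        annual = {(v, y): template.with_values(_annual_mean(pred[v], y))
                  for v in pred for y in (synthetic.BASE_YEAR, synthetic.END_YEAR)}
        ctx.update(models=models, annual=annual)
        for target, model in models.items():
            model.save(outdir / f"model_{target}.joblib")
        for (v, y), g in annual.items():
            _write_grid(outdir, f"{v}_{y}", g, manifest)
        manifest["outputs"]["model_diagnostics"] = {
            "path": str(outdir / "model_diagnostics.json")}
        (outdir / "model_diagnostics.json").write_text(
            json.dumps({t: m.diagnostics for t, m in models.items()}, indent=1))
        record("temperature", t0)

    # ---------------------------------------------------------- attribution
    if stage_enabled("attribution"):
        t0 = time.perf_counter()
        scene, annual = ctx["scene"], ctx["annual"]
        refs = attr_mod.find_stable_references(
            ctx["loss_mask"], ctx["stable_mask"], scene.truth.dem,
            radius_m=config.search_radius_m, n_min=config.n_min_references,
            elev_min=scene.truth.elev_min, elev_max=scene.truth.elev_max)
        results = {}
        for var in ("tmax", "tmin", "tmean", "tdew"):
            d_total = scene.truth.dem.with_values(
                annual[(var, synthetic.END_YEAR)].values
                - annual[(var, synthetic.BASE_YEAR)].values)
            results[var] = attr_mod.attribute(var, d_total, ctx["loss_mask"],
                                              ctx["stable_mask"], scene.truth.dem,
                                              refs=refs)
        ctx.update(refs=refs, attribution=results)
        n_excl = int(refs.excluded.sum())
        if n_excl:
            log.warning("%d loss pixels excluded (fewer than %d references)",
                        n_excl, config.n_min_references)
        manifest["stages"].setdefault("attribution", {})
        manifest["attribution_excluded_pixels"] = n_excl
        for var, res in results.items():
            for comp in ("dT_total", "dT_cc", "dT_fcc"):
                _write_grid(outdir, f"{var}_{comp}", getattr(res, comp), manifest)
        _write_grid(outdir, "reference_count", results["tmax"].reference_count, manifest)
        record("attribution", t0)

    # ------------------------------------------------------------------ cbh
    if stage_enabled("cbh"):
        t0 = time.perf_counter()
        scene, annual = ctx["scene"], ctx["annual"]
        air = config.air_variable
        cbh03 = cb.espy_cbh(annual[(air, synthetic.BASE_YEAR)],
                            annual[("tdew", synthetic.BASE_YEAR)])
        cbh22 = cb.espy_cbh(annual[(air, synthetic.END_YEAR)],
                            annual[("tdew", synthetic.END_YEAR)])
        result = cb.decompose_cbh(cbh03, cbh22, ctx["attribution"][air],
                                  ctx["attribution"]["tdew"])
        cc30 = cb.climate_cbh_change(scene.reanalysis,
                                     fine_factor=scene.config.coarse_factor)
        ctx.update(cbh=result, cbh_cc_30yr=cc30)
        for name in ("cbh_2003", "cbh_2022", "dCBH_total", "dCBH_cc", "dCBH_fcc"):
            _write_grid(outdir, name, getattr(result, name), manifest)
        _write_grid(outdir, "dCBH_cc_30yr", cc30, manifest)
        record("cbh", t0)

    # ------------------------------------------------------------ assessment
    if stage_enabled("assessment"):
        t0 = time.perf_counter()
        scene, stations = ctx["scene"], ctx["stations"]
        train = stations[stations["split"] == "train"]
        # cross-validation needs station features; reuse one month of 2003
        cube = scene.cube
        feats = train[train["month"] == 7].copy()
        feats = feats[feats["year"] == synthetic.BASE_YEAR]
        t_i = list(np.asarray(cube["time"].values)).index(synthetic.BASE_YEAR * 100 + 7)
        for v in ("lst_day", "ndvi", "albedo"):
            feats[v] = cube[v].values[t_i, feats["row"], feats["col"]]
        feats = feats.dropna(subset=["lst_day"])
        block = 5 * scene.config.spatial_corr_length_m
        validation = {}
        if len(feats) >= 20:
            validation["random_holdout"] = dataclasses.asdict(
                assess_mod.random_holdout_cv(feats, target_col="tmax",
                                             seed=config.seed))
            validation["spatial_block"] = dataclasses.asdict(
                assess_mod.spatial_block_cv(feats, block, target_col="tmax",
                                            seed=config.seed))
            for rep in validation.values():
                rep["per_fold"] = rep["per_fold"].to_dict(orient="records") \
                    if hasattr(rep["per_fold"], "to_dict") else rep["per_fold"]

        # stratified accuracy sample of the loss map against truth
        rng = np.random.default_rng(config.seed + 17)
        truth_loss = ((scene.truth.loss_year.values >= 2004)
                      & ~scene.truth.recovered.values.astype(bool)
                      & ctx["montane_mask"].values.astype(bool))
        map_loss = ctx["loss_mask"].values.astype(bool)
        rows = []
        counts = {}
        for stratum, sel in (("loss", map_loss), ("no-loss", ~map_loss)):
            pool = np.flatnonzero(sel)
            counts[stratum] = float(len(pool))
            take = rng.choice(pool, size=min(config.accuracy_sample_per_stratum,
                                             len(pool)), replace=False)
            for j in take:
                rows.append({"stratum": stratum,
                             "map_class": "loss" if map_loss.ravel()[j] else "no-loss",
                             "ref_class": "loss" if truth_loss.ravel()[j] else "no-loss"})
        accuracy = assess_mod.accuracy_area_estimate(pd.DataFrame(rows), counts)

        # GAM: deforestation warming vs fractional tree-cover loss
        fcc = scene.truth.effective_loss_2022.values[map_loss]
        dtfcc = ctx["attribution"]["tmax"].dT_fcc.values[map_loss]
        gam = None
        ok = np.isfinite(fcc) & np.isfinite(dtfcc)
        if ok.sum() >= 30 and np.ptp(fcc[ok]) > 0:
            gam = assess_mod.gam_summary(fcc[ok], dtfcc[ok], k_basis=6)

        report = {
            "validation": validation,
            "accuracy": {
                "overall_accuracy": accuracy.overall_accuracy,
                "overall_ci95": accuracy.overall_ci95,
                "omission_error": accuracy.omission_error,
                "commission_error": accuracy.commission_error,
                "area_pixels": accuracy.area_pixels,
                "area_ci95": accuracy.area_ci95,
            },
            "gam": None if gam is None else {
                "r2": gam.r2, "deviance_explained": gam.deviance_explained,
                "edf": gam.edf},
        }
        (outdir / "assessment.json").write_text(json.dumps(report, indent=1))
        manifest["outputs"]["assessment"] = {"path": str(outdir / "assessment.json")}

        # summary tables: elevation bands and latitude intervals
        dem = scene.truth.dem
        dcbh = ctx["cbh"].dCBH_fcc
        elev_edges = np.arange(np.floor(np.nanmin(dem.values) / 100) * 100,
                               np.nanmax(dem.values) + 100, 100.0)
        by_elev = summarize_by_bins(dcbh, dem, elev_edges)
        lat = dem.with_values(np.broadcast_to(
            (dem.xy_centres()[1] / 111000.0)[:, None], dem.shape))
        lat_vals = lat.values[np.isfinite(dcbh.values)]
        if lat_vals.size:
            lo = np.floor(lat_vals.min() * 100) / 100
            hi = np.ceil(lat_vals.max() * 100) / 100 + 1e-9
            n_bins = max(int(np.ceil((hi - lo) / 0.01)), 1)
            lat_edges = lo + 0.01 * np.arange(n_bins + 1)
            by_lat = summarize_by_bins(dcbh, lat, lat_edges)
        else:
            by_lat = pd.DataFrame()
        by_elev.to_csv(outdir / "dcbh_fcc_by_elevation.csv", index=False)
        by_lat.to_csv(outdir / "dcbh_fcc_by_latitude.csv", index=False)
        manifest["outputs"]["dcbh_fcc_by_elevation"] = {
            "path": str(outdir / "dcbh_fcc_by_elevation.csv")}
        record("assessment", t0)

    manifest["n_outputs"] = len(manifest["outputs"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    ctx["manifest"] = manifest
    run_pipeline.last_context = ctx  # handy for interactive inspection/tests
    return manifest
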