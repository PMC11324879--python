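"""Air and dew-point temperature estimation by stacked per-sensor ensembles.

Monthly maximum and minimum 2-m air temperature and dew point are estimated
from satellite-like observables by random-forest base learners fitted
separately per sensor overpass (a "Terra-like" and an "Aqua-like" view),
combined by a random-forest meta-learner trained on the base learners'
out-of-fold predictions (so the meta-learner never sees in-sample base
predictions).  Mean air temperature is the arithmetic mean of the predicted
maximum and minimum.

Feature schemas
---------------
Tmax:  LST_day, NDVI, albedo, latitude, longitude
Tmin:  LST_night, NDVI, albedo, latitude, longitude
Tdew:  saturation vapour pressure es(Tmin), LST_night, latitude, longitude

The saturation vapour pressure (kPa) uses the Magnus-type form
es(T) = 0.6108 * exp(17.27 T / (T + 237.3)) with T in degrees Celsius.
"""

from __future__ import annotations

import dataclasses

import joblib
import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GroupKFold, KFold, cross_val_predict

__all__ = ["FeatureSchema", "StackedModel", "saturation_vapour_pressure",
           "fit_stacked", "predict_grids", "mean_air_temperature",
           "spatial_forward_feature_selection",
           "TMAX_SCHEMA", "TMIN_SCHEMA", "TDEW_SCHEMA"]

_ES_POLE_C = -237.3


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure es (kPa) at air temperature ``t_c`` (°C).

    es = 0.6108 exp(17.27 t / (t + 237.3)); strictly increasing in t.
    Temperatures at or below the pole at -237.3 °C are rejected.
    """
    t = np.asarray(t_c, dtype=float)
    if np.any(t[np.isfinite(t)] <= _ES_POLE_C):
        raise ValueError(f"temperature must exceed {_ES_POLE_C} °C")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(es) if np.isscalar(t_c) else es


@dataclasses.dataclass(frozen=True)
class FeatureSchema:
    """Ordered, frozen predictor names checked at predict time."""

    names: tuple[str, ...]
    target: str

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def check(self, columns) -> None:
        missing = [n for n in self.names if n not in columns]
        if missing:
            raise KeyError(f"missing feature(s) for target {self.target!r}: {missing}")


TMAX_SCHEMA = FeatureSchema(("lst_day", "ndvi", "albedo", "lat", "lon"), "tmax")
TMIN_SCHEMA = FeatureSchema(("lst_night", "ndvi", "albedo", "lat", "lon"), "tmin")
TDEW_SCHEMA = FeatureSchema(("es", "lst_night", "lat", "lon"), "tdew")

SCHEMAS = {"tmax": TMAX_SCHEMA, "tmin": TMIN_SCHEMA, "tdew": TDEW_SCHEMA}

FORMAT_VERSION = 1


@dataclasses.dataclass
class StackedModel:
    """Two per-sensor base regressors stacked by a meta regressor."""

    base_terra: RandomForestRegressor
    base_aqua: RandomForestRegressor
    meta: RandomForestRegressor
    schema: FeatureSchema
    diagnostics: dict = dataclasses.field(default_factory=dict)
    degenerate: bool = False
    version: int = FORMAT_VERSION

    def predict(self, terra_features: pd.DataFrame, aqua_features: pd.DataFrame) -> np.ndarray:
        self.schema.check(terra_features.columns)
        self.schema.check(aqua_features.columns)
        xt = terra_features[list(self.schema.names)].to_numpy()
        xa = aqua_features[list(self.schema.names)].to_numpy()
        ok = np.isfinite(xt).all(axis=1) & np.isfinite(xa).all(axis=1)
        out = np.full(len(xt), np.nan)
        if ok.any():
            pt = self.base_terra.predict(xt[ok])
            pa = self.base_aqua.predict(xa[ok])
            out[ok] = self.meta.predict(np.column_stack([pt, pa]))
        return out

    def save(self, path) -> None:
        joblib.dump({"version": self.version, "model": self}, path)

    @classmethod
    def load(cls, path) -> "StackedModel":
        payload = joblib.load(path)
        if payload["version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version {payload['version']}")
        return payload["model"]


def _metrics(y_true, y_pred) -> dict:
    resid = np.asarray(y_true) - np.asarray(y_pred)
    return {
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "mae": float(mean_absolute_error(y_true, y_pred)),
        "r2": float(r2_score(y_true, y_pred)) if np.ptp(y_true) > 0 else np.nan,
    }


def fit_stacked(target: str, terra_features: pd.DataFrame, aqua_features: pd.DataFrame,
                labels: np.ndarray, test_mask: np.ndarray | None = None,
                n_estimators: int = 300, n_folds: int = 5, seed: int = 0,
                schema: FeatureSchema | None = None) -> StackedModel:
    """Fit the per-sensor base learners and the out-of-fold meta learner.

    ``test_mask`` marks held-out rows (e.g. the stations' 30% test split);
    when omitted a random 30% of rows is held out.  Diagnostics (RMSE, MAE,
    R² of each base learner and of the stack on the held-out rows) are
    attached to the returned model.
    """
    schema = schema or SCHEMAS[target]
    schema.check(terra_features.columns)
    schema.check(aqua_features.columns)
    labels = np.asarray(labels, float)
    if len(labels) < 50:
        raise ValueError("need at least 50 training rows")
    if not np.isfinite(labels).all():
        raise ValueError("labels must be finite")

    xt = terra_features[list(schema.names)].to_numpy()
    xa = aqua_features[list(schema.names)].to_numpy()
    finite = np.isfinite(xt).all(axis=1) & np.isfinite(xa).all(axis=1)
    xt, xa, labels = xt[finite], xa[finite], labels[finite]
    if test_mask is None:
        rng = np.random.default_rng(seed)
        test_mask = np.zeros(len(labels), bool)
        test_mask[rng.choice(len(labels), size=int(0.3 * len(labels)), replace=False)] = True
    else:
        test_mask = np.asarray(test_mask, bool)[finite]
    train = ~test_mask

    degenerate = np.ptp(labels[train]) == 0

    def rf(offset, **kw):
        return RandomForestRegressor(n_estimators=n_estimators, random_state=seed + offset,
                                     n_jobs=1, **kw)

    # the meta learner smooths over the two base predictions; small leaves
    # would chase out-of-fold noise and degrade the stack
    base_terra, base_aqua, meta = rf(0), rf(1), rf(2, min_samples_leaf=5)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof_t = cross_val_predict(rf(0), xt[train], labels[train], cv=cv)
    oof_a = cross_val_predict(rf(1), xa[train], labels[train], cv=cv)
    base_terra.fit(xt[train], labels[train])
    base_aqua.fit(xa[train], labels[train])
    meta.fit(np.column_stack([oof_t, oof_a]), labels[train])

    diagnostics = {}
    if test_mask.any():
        pt = base_terra.predict(xt[test_mask])
        pa = base_aqua.predict(xa[test_mask])
        stacked = meta.predict(np.column_stack([pt, pa]))
        diagnostics = {
            "terra": _metrics(labels[test_mask], pt),
            "aqua": _metrics(labels[test_mask], pa),
            "stacked": _metrics(labels[test_mask], stacked),
            "n_train": int(train.sum()), "n_test": int(test_mask.sum()),
        }
    return StackedModel(base_terra, base_aqua, meta, schema,
                        diagnostics=diagnostics, degenerate=bool(degenerate))


def _features_at_time(cube: xr.Dataset, names, t_index: int) -> pd.DataFrame:
    cols = {}
    for name in names:
        if name not in cube:
            raise KeyError(f"cube is missing variable {name!r}")
        da = cube[name]
        arr = da.isel(time=t_index).values if "time" in da.dims else da.values
        cols[name] = arr.ravel()
    return pd.DataFrame(cols)


def predict_grids(model: StackedModel, terra_cube: xr.Dataset,
                  aqua_cube: xr.Dataset | None = None) -> xr.DataArray:
    """Per-pixel, per-month temperature predictions on a cube's grid.

    ``aqua_cube`` defaults to the terra cube (a single synthetic view feeds
    both sensors).  NaN in any schema variable propagates to the output.
    """
    aqua_cube = aqua_cube if aqua_cube is not None else terra_cube
    shape = (terra_cube.sizes["y"], terra_cube.sizes["x"])
    out = np.empty((terra_cube.sizes["time"],) + shape)
    for t_i in range(terra_cube.sizes["time"]):
        ft = _features_at_time(terra_cube, model.schema.names, t_i)
        fa = _features_at_time(aqua_cube, model.schema.names, t_i)
        out[t_i] = model.predict(ft, fa).reshape(shape)
    return xr.DataArray(out, dims=("time", "y", "x"),
                        coords={"time": terra_cube["time"].values,
                                "y": terra_cube["y"].values,
                                "x": terra_cube["x"].values},
                        name=model.schema.target)


def mean_air_temperature(tmax: xr.DataArray, tmin: xr.DataArray) -> xr.DataArray:
    """Tmean = (Tmax + Tmin) / 2, elementwise; nodata propagates."""
    tmean = (tmax + tmin) / 2.0
    tmean.name = "tmean"
    return tmean


def spatial_forward_feature_selection(candidates: list[str], train_table: pd.DataFrame,
                                      block_assignment: np.ndarray, target_col: str,
                                      estimator_factory=None, n_folds: int = 5,
                                      seed: int = 0, min_improvement: float = 0.01) -> list[str]:
    """Greedy forward feature selection under spatially blocked CV.

    Starts from the best pair of candidates and adds one feature at a time,
    keeping it only if the spatially blocked cross-validated RMSE improves
    by more than the relative fraction ``min_improvement`` (1% by default —
    chance-level fluctuations of blocked CV should not admit a feature).
    Deterministic given the seed and the block assignment.
    """
    blocks = np.asarray(block_assignment)
    if len(np.unique(blocks)) < 2:
        raise ValueError("need at least 2 spatial blocks")
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    # exact duplicates carry no information; keep the first occurrence only
    deduped = []
    for cand in candidates:
        col = train_table[cand].to_numpy()
        if not any(np.array_equal(col, train_table[kept].to_numpy()) for kept in deduped):
            deduped.append(cand)
    candidates = deduped
    if len(candidates) < 2:
        raise ValueError("need at least 2 distinct candidate features")
    if estimator_factory is None:
        def estimator_factory():
            return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)

    y = train_table[target_col].to_numpy()
    k = min(n_folds, len(np.unique(blocks)))
    cv = GroupKFold(n_splits=k)

    def cv_rmse(feats):
        x = train_table[list(feats)].to_numpy()
        pred = cross_val_predict(estimator_factory(), x, y, cv=cv, groups=blocks)
        return float(np.sqrt(np.mean((y - pred) ** 2)))

    best_pair, best_rmse = None, np.inf
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            rmse = cv_rmse([candidates[i], candidates[j]])
            if rmse < best_rmse:
                best_pair, best_rmse = [candidates[i], candidates[j]], rmse
    selected, current = list(best_pair), best_rmse
    improved = True
    while improved:
        improved = False
        for cand in candidates:
            if cand in selected:
                continue
            rmse = cv_rmse(selected + [cand])
            if rmse < current * (1.0 - min_improvement):
                selected.append(cand)
                current = rmse
                improved = True
                break
    return selected
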