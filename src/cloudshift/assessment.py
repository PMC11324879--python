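"""Model validation, map accuracy/area estimation, and GAM summaries.

Three independent assessment tools:

* cross-validation of the station-based temperature models under a random
  holdout and under contiguous spatial blocks (spatially autocorrelated
  residuals make the random scheme optimistic; the spatial scheme exposes
  that optimism);
* stratified sample-based accuracy and error-adjusted area estimation for
  the binary loss map, with normal-approximation 95% confidence intervals
  (the good-practice protocol for change maps);
* penalized cubic-spline summaries (GAM) of an effect variable against a
  single predictor, with smoothing chosen by generalized cross-validation,
  reporting R², deviance explained and a 95% confidence band.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold
from statsmodels.gam.api import BSplines, GLMGam

__all__ = ["ValidationReport", "AccuracyEstimate", "SplineSummary",
           "spatial_block_cv", "random_holdout_cv", "accuracy_area_estimate",
           "gam_summary"]

_Z95 = 1.959963984540054


@dataclasses.dataclass
class ValidationReport:
    scheme: str                # random_holdout | spatial_block
    per_fold: pd.DataFrame     # fold, rmse, mae, r2, n_test
    rmse: float
    mae: float
    r2: float

    def __post_init__(self):
        if self.rmse < 0 or self.mae > self.rmse + 1e-12:
            raise ValueError("invalid metrics: need 0 <= MAE <= RMSE")


@dataclasses.dataclass
class AccuracyEstimate:
    overall_accuracy: float
    overall_ci95: float                 # half-width
    user_accuracy: dict[str, float]     # commission = 1 - user's
    producer_accuracy: dict[str, float]  # omission = 1 - producer's
    commission_error: dict[str, float]
    omission_error: dict[str, float]
    area_pixels: dict[str, float]       # error-adjusted area, in pixels
    area_ci95: dict[str, float]
    strata_weights: dict[str, float]


@dataclasses.dataclass
class SplineSummary:
    x_grid: np.ndarray
    smooth: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    r2: float                   # adjusted for effective degrees of freedom
    deviance_explained: float
    edf: float
    alpha: float                # selected smoothing weight


def _cv_metrics(table: pd.DataFrame, folds, feature_cols, target_col,
                estimator_factory, scheme: str) -> ValidationReport:
    x = table[list(feature_cols)].to_numpy()
    y = table[target_col].to_numpy()
    rows = []
    for i, (tr, te) in enumerate(folds):
        est = estimator_factory()
        est.fit(x[tr], y[tr])
        pred = est.predict(x[te])
        resid = y[te] - pred
        ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
        rows.append({
            "fold": i,
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "mae": float(np.mean(np.abs(resid))),
            "r2": float(1 - np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else np.nan,
            "n_test": len(te),
        })
    per_fold = pd.DataFrame(rows)
    return ValidationReport(scheme=scheme, per_fold=per_fold,
                            rmse=float(per_fold["rmse"].mean()),
                            mae=float(per_fold["mae"].mean()),
                            r2=float(per_fold["r2"].mean()))


def _default_estimator_factory(seed: int):
    def make():
        return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    return make


def spatial_block_cv(train_table: pd.DataFrame, block_size_m: float, k: int = 5,
                     feature_cols=("lst_day", "ndvi", "albedo", "lat", "lon"),
                     target_col: str = "tmax", estimator_factory=None,
                     seed: int = 0) -> ValidationReport:
    """K-fold CV whose folds are contiguous spatial blocks of stations.

    Stations are assigned to square blocks of side ``block_size_m`` from
    their projected (x, y); folds are grouped by block, so no station (nor
    its block neighbours) appears in both train and test of a fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    bx = np.floor(train_table["x"].to_numpy() / block_size_m).astype(int)
    by = np.floor(train_table["y"].to_numpy() / block_size_m).astype(int)
    blocks = bx * 100003 + by
    n_blocks = len(np.unique(blocks))
    if n_blocks < 2:
        raise ValueError("all stations fall in a single spatial block")
    k_eff = min(k, n_blocks)
    folds = list(GroupKFold(n_splits=k_eff).split(train_table, groups=blocks))
    for tr, te in folds:  # disjointness is structural; assert cheaply
        assert not set(blocks[tr]) & set(blocks[te])
    estimator_factory = estimator_factory or _default_estimator_factory(seed)
    return _cv_metrics(train_table, folds, feature_cols, target_col,
                       estimator_factory, "spatial_block")


def random_holdout_cv(train_table: pd.DataFrame, k: int = 5,
                      feature_cols=("lst_day", "ndvi", "albedo", "lat", "lon"),
                      target_col: str = "tmax", estimator_factory=None,
                      seed: int = 0) -> ValidationReport:
    """Plain shuffled K-fold CV; the optimistic baseline for comparison."""
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed)
                 .split(train_table))
    estimator_factory = estimator_factory or _default_estimator_factory(seed)
    return _cv_metrics(train_table, folds, feature_cols, target_col,
                       estimator_factory, "random_holdout")


def accuracy_area_estimate(sample: pd.DataFrame,
                           strata_pixel_counts: dict[str, float]) -> AccuracyEstimate:
    """Stratified accuracy and error-adjusted area from a reference sample.

    ``sample`` has columns (stratum, map_class, ref_class); strata are
    typically the map classes themselves.  Estimators follow the standard
    stratified good-practice protocol: cell proportions are estimated per
    stratum and combined with the strata area weights; overall/user's/
    producer's accuracies and error-adjusted areas come with
    normal-approximation 95% intervals (for overall accuracy and areas).
    """
    strata = sorted(strata_pixel_counts)
    n_total = float(sum(strata_pixel_counts.values()))
    weights = {h: strata_pixel_counts[h] / n_total for h in strata}
    sampled = set(sample["stratum"].unique())
    missing = [h for h in strata if h not in sampled]
    if missing:
        raise ValueError(f"unsampled stratum(a): {missing}")
    extra = sampled - set(strata)
    if extra:
        raise ValueError(f"sample references unknown stratum(a): {sorted(extra)}")

    classes = sorted(set(sample["map_class"]) | set(sample["ref_class"]))
    # estimated population proportions p[map, ref]
    p = {(m, r): 0.0 for m in classes for r in classes}
    var_overall = 0.0
    var_area = {c: 0.0 for c in classes}
    for h in strata:
        sub = sample[sample["stratum"] == h]
        n_h = len(sub)
        w = weights[h]
        correct = float((sub["map_class"] == sub["ref_class"]).mean())
        if n_h > 1:
            var_overall += w ** 2 * correct * (1 - correct) / (n_h - 1)
        for m in classes:
            for r in classes:
                p[(m, r)] += w * float(((sub["map_class"] == m)
                                        & (sub["ref_class"] == r)).mean())
        for c in classes:
            prop = float((sub["ref_class"] == c).mean())
            if n_h > 1:
                var_area[c] += w ** 2 * prop * (1 - prop) / (n_h - 1)

    overall = sum(p[(c, c)] for c in classes)
    user, producer, commission, omission = {}, {}, {}, {}
    area, area_ci = {}, {}
    for c in classes:
        p_map = sum(p[(c, r)] for r in classes)
        p_ref = sum(p[(m, c)] for m in classes)
        user[c] = p[(c, c)] / p_map if p_map > 0 else np.nan
        producer[c] = p[(c, c)] / p_ref if p_ref > 0 else np.nan
        commission[c] = 1.0 - user[c]
        omission[c] = 1.0 - producer[c]
        area[c] = p_ref * n_total
        area_ci[c] = _Z95 * np.sqrt(var_area[c]) * n_total
    return AccuracyEstimate(
        overall_accuracy=float(overall),
        overall_ci95=float(_Z95 * np.sqrt(var_overall)),
        user_accuracy=user, producer_accuracy=producer,
        commission_error=commission, omission_error=omission,
        area_pixels=area, area_ci95=area_ci, strata_weights=weights,
    )


def gam_summary(x: np.ndarray, y: np.ndarray, k_basis: int = 10,
                n_grid: int = 200, alphas: np.ndarray | None = None) -> SplineSummary:
    """Penalized cubic regression spline of y on x, smoothing by GCV.

    Fits a B-spline GAM over a grid of penalty weights and keeps the one
    minimizing GCV(λ) = n·RSS / (n − tr(H))².  Reports the smooth on an
    evaluation grid with a pointwise 95% confidence band, the
    deviance explained 1 − RSS/TSS, and an R² adjusted for the effective
    degrees of freedom (the hat-matrix trace).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: cannot fit a spline")
    if n < k_basis + 5:
        raise ValueError(f"need at least {k_basis + 5} points for df={k_basis}")
    bs = BSplines(x[:, None], df=[k_basis], degree=[3])
    exog = np.ones((n, 1))
    if alphas is None:
        alphas = np.logspace(-8, 8, 33)
    best = None
    for alpha in alphas:
        res = GLMGam(y, exog=exog, smoother=bs, alpha=[float(alpha)]).fit()
        rss = float(np.sum(res.resid_response ** 2))
        tr = float(res.hat_matrix_trace)
        gcv = n * rss / (n - tr) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, float(alpha), res, rss, tr)
    _, alpha, res, rss, edf = best
    tss = float(np.sum((y - y.mean()) ** 2))
    deviance_explained = 1.0 - rss / tss if tss > 0 else np.nan
    r2 = 1.0 - (rss / max(n - edf, 1.0)) / (tss / (n - 1)) if tss > 0 else np.nan

    xg = np.linspace(x.min(), x.max(), n_grid)
    design_grid = np.column_stack([np.ones(n_grid), bs.transform(xg[:, None])])
    smooth = design_grid @ res.params
    cov = np.asarray(res.cov_params())
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", design_grid, cov, design_grid), 0, None))
    return SplineSummary(x_grid=xg, smooth=smooth,
                         band_lo=smooth - _Z95 * se, band_hi=smooth + _Z95 * se,
                         r2=float(r2), deviance_explained=float(deviance_explained),
                         edf=float(edf), alpha=alpha)
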