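"""Nested cross-validation for the penalized mixed model.

The inner loop (10-fold by default) selects the overall penalty ``lam`` by
the median out-of-fold RMSE over a decreasing grid of 90 log-spaced values;
the outer loop (20-fold) estimates out-of-bag RMSE, MAE, RRMSE (RMSE as a
percent of the observed fold mean), and R^2 (squared Pearson correlation of
observed and predicted), and collects the per-fold coefficient vectors from
which median coefficients, zero-shrinkage flags, and importance clusters
are derived.  Covariables are standardized inside each outer-training set
only, and held-out rows never touch scaling, penalty selection, or fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold

from . import _solver, features as feat
from .containers import FeatureTable
from .penlmm import PenalizedLMMFit, PenaltySpec, fit_enet_lmm, fit_null, predict

__all__ = ["CVConfig", "CVResult", "lambda_grid", "inner_select_lambda",
           "nested_cv", "metrics"]


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation settings (defaults: 20 outer / 10 inner
    folds, 90-value log-spaced penalty grid, elastic-net mixing 0.5)."""

    outer_k: int = 20
    inner_k: int = 10
    n_lambda: int = 90
    alpha: float = 0.5
    seed: int = 0
    grouped_folds: bool = False
    lambda_min_ratio: float = 1e-3
    penalized: bool = True
    tol: float = 1e-6        # coefficient tolerance of the per-fold refits
    inner_tol: float = 1e-4  # coarser tolerance for penalty-selection paths
    max_iter: int = 500

    def validate(self, n_obs: int) -> None:
        if self.outer_k < 2 or self.outer_k > n_obs:
            raise ValueError(f"outer_k must lie in [2, {n_obs}]")
        min_train = n_obs - (n_obs // self.outer_k + 1)
        if self.inner_k < 2 or self.inner_k > min_train:
            raise ValueError("inner_k exceeds the smallest outer-training size")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")


def metrics(obs, pred, strict: bool = False) -> dict[str, float]:
    """RMSE, MAE, RRMSE (% of observed mean), and R^2 (squared Pearson r).

    R^2 is undefined for fewer than two points or a zero-variance side; it
    is returned as NaN, or raised when ``strict`` (zero-variance
    *observations* always raise — nothing can be scored against them).
    """
    o = np.asarray(obs, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if len(o) == 0 or len(o) != len(p):
        raise ValueError("obs and pred must be equal-length and nonempty")
    err = o - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.mean(o) == 0:
        raise ValueError("RRMSE undefined: observed mean is zero")
    rrmse = 100.0 * rmse / abs(float(np.mean(o)))
    if len(o) >= 2 and o.std() == 0:
        raise ValueError("zero-variance observations cannot be scored")
    if len(o) < 2 or o.std() == 0 or p.std() == 0:
        if strict:
            raise ValueError(
                "R^2 undefined: zero-variance observations or predictions"
            )
        r2 = float("nan")
    else:
        r = float(np.corrcoef(o, p)[0, 1])
        r2 = r * r
    return {"RMSE": rmse, "MAE": mae, "RRMSE": rrmse, "R2": r2}


def lambda_grid(
    X,
    y,
    n_lambda: int = 90,
    ratio: float = 1e-3,
    alpha: float = 0.5,
    groups=None,
) -> np.ndarray:
    """Decreasing log-spaced penalty grid from ``lam_max`` down to
    ``lam_max * ratio``.

    ``lam_max`` is the smallest penalty at which every penalized coefficient
    is zero: ``max_j |x_j' r| / (n * alpha)`` where ``r`` is the response
    centered by the intercept-only fit (with the site intercepts partialled
    out when ``groups`` is given).
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if Xa.size == 0 or not np.any(Xa != 0):
        raise ValueError("cannot build a penalty grid from an all-zero design")
    if groups is not None and len(np.unique(np.asarray(groups))) >= 2:
        null = fit_null(ya, groups)
        r = ya - predict(null, np.empty((len(ya), 0)), groups, mode="conditional")
    else:
        r = ya - ya.mean()
    n = len(ya)
    lam_max = float(np.max(np.abs(Xa.T @ r)) / (n * max(alpha, 1e-3)))
    lam_max *= 1.0 + 1e-8  # keep the argmax coordinate strictly at zero
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), n_lambda)


def _path_predictions(X_tr, y_tr, g_tr_idx, n_groups, grid, alpha, tol, max_iter,
                      X_val, g_val_idx, var_tol=1e-5):
    """Fit the warm-started penalty path on the training block and return
    (conditional predictions for the validation block per penalty, conv).

    Variance components only steer the ridge weight on the site intercepts
    during penalty selection, so the path runs them at a looser tolerance
    than a final fit.
    """
    gsize = np.bincount(g_tr_idx, minlength=n_groups).astype(np.float64)
    vy = float(np.var(y_tr)) or 1.0
    B, b0s, U, _, _, conv = _solver.fit_path_kernel(
        np.asfortranarray(X_tr), y_tr, g_tr_idx.astype(np.int64), gsize,
        grid * alpha, grid * (1.0 - alpha), tol, max_iter,
        0.4 * vy, 0.6 * vy, True, var_tol, n_groups >= 2,
    )
    # rows: penalty index; columns: validation rows
    pred = B @ X_val.T + b0s[:, None]
    known = g_val_idx >= 0
    if known.any() and n_groups >= 2:
        pred[:, known] += U[:, g_val_idx[known]]
    return pred, conv


def inner_select_lambda(
    X_train,
    y_train,
    groups,
    grid: np.ndarray,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Select the penalty minimizing the median out-of-fold RMSE.

    Ties go to the larger (more parsimonious) penalty.  A penalty whose fit
    fails to converge in any fold is excluded; if none survive, an error is
    raised.
    """
    Xa = np.asarray(X_train, dtype=float)
    ya = np.asarray(y_train, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("penalty grid must be decreasing")
    if k > len(ya):
        raise ValueError("inner k exceeds the training size")
    labels = np.asarray(groups)
    uniq, g_idx = np.unique(labels, return_inverse=True)
    n_groups = len(uniq)

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    rmse = np.empty((k, len(grid)))
    bad = np.zeros(len(grid), dtype=bool)
    for f, (tr, val) in enumerate(kf.split(Xa)):
        # group codes local to this inner-training block; unseen sites in the
        # validation block get BLUP 0 (code -1)
        tr_labels, tr_codes = np.unique(labels[tr], return_inverse=True)
        lookup = {lab: i for i, lab in enumerate(tr_labels)}
        val_codes = np.array([lookup.get(lab, -1) for lab in labels[val]],
                             dtype=np.int64)
        pred, conv = _path_predictions(
            Xa[tr], ya[tr], tr_codes.astype(np.int64), len(tr_labels),
            grid, alpha, tol, max_iter, Xa[val], val_codes,
        )
        bad |= ~conv
        rmse[f] = np.sqrt(np.mean((pred - ya[val][None, :]) ** 2, axis=1))
    med = np.median(rmse, axis=0)
    med[bad] = np.inf
    if not np.isfinite(med).any():
        raise RuntimeError("no penalty in the grid produced convergent inner fits")
    return float(grid[int(np.argmin(med))])  # first minimum = largest penalty


@dataclass
class CVResult:
    """Outer-loop results: per-fold penalties, metrics, variance components,
    and coefficient vectors, plus their medians and spreads."""

    fold_records: pd.DataFrame
    coef_matrix: pd.DataFrame  # outer folds x covariables
    feature_names: list[str]
    config: CVConfig
    notices: list[str] = field(default_factory=list)

    @property
    def metric_summary(self) -> pd.DataFrame:
        cols = ["RMSE", "MAE", "RRMSE", "R2", "sigma2_site", "sigma2_res"]
        rows = {
            "median": self.fold_records[cols].median(),
            "sd": self.fold_records[cols].std(ddof=1),
        }
        return pd.DataFrame(rows).T

    @property
    def coef_summary(self) -> pd.DataFrame:
        """Per-covariable median/min/max coefficient across outer folds,
        zero fraction, the >=50%-of-folds zero flag, and the sign of the
        median coefficient (0 when zero-flagged)."""
        med = self.coef_matrix.median()
        zero_frac = (self.coef_matrix == 0.0).mean()
        zero_flag = zero_frac >= 0.5
        sign = np.sign(med).where(~zero_flag, 0.0)
        return pd.DataFrame(
            {
                "median": med,
                "min": self.coef_matrix.min(),
                "max": self.coef_matrix.max(),
                "abs_median": med.abs(),
                "zero_frac": zero_frac,
                "zero_flag": zero_flag,
                "sign": sign,
            }
        )

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "config": self.config.__dict__,
                "folds": self.fold_records.to_dict(orient="records"),
                "coefficients": self.coef_matrix.to_dict(orient="list"),
                "metric_summary": self.metric_summary.to_dict(),
                "notices": self.notices,
            },
            indent=2,
            default=float,
        )


def _outer_folds(n, groups, config: CVConfig):
    if config.grouped_folds:
        kf = GroupKFold(n_splits=config.outer_k)
        return list(kf.split(np.arange(n), groups=groups))
    kf = KFold(n_splits=config.outer_k, shuffle=True, random_state=config.seed)
    return list(kf.split(np.arange(n)))


def nested_cv(
    table: FeatureTable | None,
    y,
    groups,
    config: CVConfig | None = None,
    columns: Sequence[str] | None = None,
) -> CVResult:
    """Run the nested cross-validation protocol.

    Per outer fold: standardize on the training rows only, select the
    penalty by inner CV (skipped when ``config.penalized`` is false or the
    table has no columns), refit on the full outer-training block, predict
    the held-out rows marginally plus the BLUP of sites seen in training,
    and score.  ``table=None`` (or an empty column list) runs the intercept-
    only null model under the same outer folds.
    """
    cfg = config or CVConfig()
    ya = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(groups)
    cfg.validate(len(ya))
    if table is not None and columns is not None:
        table = table.copy_with(table.df[list(columns)])
    names = table.columns if table is not None else []
    p = len(names)

    folds = _outer_folds(len(ya), labels, cfg)
    records = []
    coefs = np.zeros((len(folds), p))
    notices: list[str] = []
    for f, (tr, te) in enumerate(folds):
        if p > 0:
            std = feat.standardize(table, fit_rows=tr)
            X = std.matrix()
            X_tr, X_te = X[tr], X[te]
        else:
            X_tr = np.empty((len(tr), 0))
            X_te = np.empty((len(te), 0))
        g_tr, g_te = labels[tr], labels[te]
        if p > 0 and cfg.penalized:
            grid = lambda_grid(
                X_tr, ya[tr], cfg.n_lambda, cfg.lambda_min_ratio, cfg.alpha,
                groups=g_tr,
            )
            lam = inner_select_lambda(
                X_tr, ya[tr], g_tr, grid, k=cfg.inner_k,
                seed=cfg.seed + 1000 + f, alpha=cfg.alpha,
                tol=cfg.inner_tol, max_iter=cfg.max_iter,
            )
        else:
            lam = 0.0
        if p > 0:
            fit = fit_enet_lmm(
                pd.DataFrame(X_tr, columns=names), ya[tr], g_tr,
                PenaltySpec(lam, cfg.alpha), tol=cfg.tol, max_iter=cfg.max_iter,
            )
        else:
            fit = fit_null(ya[tr], g_tr)
        pred = predict(fit, X_te, g_te, mode="conditional")
        try:
            m = metrics(ya[te], pred)
        except ValueError as exc:
            notices.append(f"fold {f}: {exc}; fold excluded from metric summaries")
            m = {"RMSE": np.nan, "MAE": np.nan, "RRMSE": np.nan, "R2": np.nan}
        else:
            if np.isnan(m["R2"]):
                notices.append(
                    f"fold {f}: R^2 undefined (too few rows or zero-variance "
                    "predictions); excluded from the R^2 summary"
                )
        records.append(
            {
                "fold": f,
                "lam": lam,
                "n_test": len(te),
                **m,
                "sigma2_site": fit.sigma2_site,
                "sigma2_res": fit.sigma2_res,
                "converged": fit.converged,
            }
        )
        if p > 0:
            coefs[f] = fit.beta
    return CVResult(
        fold_records=pd.DataFrame(records),
        coef_matrix=pd.DataFrame(coefs, columns=names),
        feature_names=list(names),
        config=cfg,
        notices=notices,
    )
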