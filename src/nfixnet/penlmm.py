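"""Elastic-net penalized linear mixed models with a grouped random intercept.

The fixed effects carry an elastic-net penalty
``lam * (alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2)`` on the
mean-squared-error scale (the residual term is ``1/(2n) ||.||^2``), exactly
the parameterization of generic elastic-net solvers, so a single-group fit
is directly comparable to them.  The intercept and the site intercepts are
never penalized.  Fitting alternates best linear unbiased prediction of the
site intercepts and EM-type variance-component updates with cyclic
coordinate descent (soft-thresholding) on the group-effect-adjusted
residuals; zeros produced by the soft threshold are exact 0.0.

Entry points: :func:`fit_enet_lmm`, :func:`fit_ml_lmm` (unpenalized maximum
likelihood), :func:`fit_null` (intercept-only), :func:`predict`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _solver

__all__ = [
    "PenaltySpec",
    "PenalizedLMMFit",
    "fit_enet_lmm",
    "fit_ml_lmm",
    "fit_null",
    "predict",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PenaltySpec:
    """Overall penalty ``lam >= 0`` and L1 proportion ``alpha in [0, 1]``."""

    lam: float
    alpha: float = 0.5

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def lam_l1(self) -> float:
        return self.lam * self.alpha

    @property
    def lam_l2(self) -> float:
        return self.lam * (1.0 - self.alpha)

    def value(self, beta: np.ndarray) -> float:
        """The penalty functional evaluated at ``beta``."""
        b = np.asarray(beta, dtype=float)
        return float(
            self.lam * (self.alpha * np.abs(b).sum()
                        + 0.5 * (1 - self.alpha) * (b ** 2).sum())
        )


@dataclass
class PenalizedLMMFit:
    """Fitted penalized (or unpenalized) linear mixed model."""

    intercept: float
    beta: np.ndarray
    feature_names: list[str]
    u: dict  # group label -> BLUP (response units)
    sigma2_site: float
    sigma2_res: float
    lam: float
    alpha: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def coef_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.feature_names)

    @property
    def active_set(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.beta) if b != 0.0]

    def to_json(self, scaling: Mapping[str, tuple[float, float]] | None = None) -> str:
        payload = {
            "intercept": self.intercept,
            "beta": dict(zip(self.feature_names, map(float, self.beta))),
            "u": {str(k): float(v) for k, v in self.u.items()},
            "sigma2_site": self.sigma2_site,
            "sigma2_res": self.sigma2_res,
            "lam": self.lam,
            "alpha": self.alpha,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "objective_trace": [float(v) for v in self.objective_trace],
        }
        if scaling is not None:
            from .features import destandardize_coefficients

            raw_beta, raw_b0 = destandardize_coefficients(
                payload["beta"], scaling, self.intercept
            )
            payload["beta_original_scale"] = raw_beta
            payload["intercept_original_scale"] = raw_b0
        return json.dumps(payload, indent=2)


def _prepare(X, y, groups):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa.reshape(-1, 1)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if not np.isfinite(Xa).all() or not np.isfinite(ya).all():
        raise ValueError("non-finite values in X or y")
    if groups is None:
        labels = np.zeros(len(ya), dtype=object)
    else:
        labels = np.asarray(groups)
        if labels.shape[0] != ya.shape[0]:
            raise ValueError("groups length does not match y")
    uniq, gidx = np.unique(labels, return_inverse=True)
    gsize = np.bincount(gidx).astype(np.float64)
    return Xa, ya, names, list(uniq), gidx.astype(np.int64), gsize


def fit_enet_lmm(
    X,
    y,
    groups=None,
    penalty: PenaltySpec = PenaltySpec(lam=0.0, alpha=0.5),
    tol: float = 1e-6,
    max_iter: int = 500,
    variance_components: tuple[float, float] | None = None,
    update_variances: bool = True,
) -> PenalizedLMMFit:
    """Fit the elastic-net penalized LMM.

    Parameters
    ----------
    X, y, groups:
        Aligned design matrix (standardized covariables), response, and site
        labels.  ``groups=None`` or a single distinct label disables the
        random intercept (``sigma2_site = 0``).
    penalty:
        :class:`PenaltySpec`; the intercept and site intercepts are never
        penalized.
    variance_components:
        Optional ``(sigma2_site, sigma2_res)`` starting values; combined
        with ``update_variances=False`` they are held fixed (useful for
        closed-form comparisons).

    Notes
    -----
    ``objective_trace`` records the penalized objective of the terminal
    fitting phase (variance weights frozen at their converged values); it is
    non-increasing by construction.  On non-convergence a warning is issued
    and the fit is returned with ``converged=False``.
    """
    Xa, ya, names, labels, gidx, gsize = _prepare(X, y, groups)
    n = len(ya)
    has_ranef = len(labels) >= 2
    if variance_components is not None:
        s2_site0, s2_res0 = map(float, variance_components)
        if s2_site0 < 0 or s2_res0 <= 0:
            raise ValueError("need sigma2_site >= 0 and sigma2_res > 0")
        if s2_site0 == 0:
            has_ranef = False
            s2_site0 = 1e-8
    else:
        vy = float(ya.var()) or 1.0
        s2_site0, s2_res0 = 0.4 * vy, 0.6 * vy
    Xf = np.asfortranarray(Xa)
    beta0 = np.zeros(Xa.shape[1])
    beta, b0, u, s2_site, s2_res, trace, _, n_iter, converged = _solver.fit_kernel(
        Xf, ya, gidx, gsize,
        penalty.lam_l1, penalty.lam_l2,
        tol, max_iter,
        s2_site0, s2_res0,
        update_variances, 1e-9, has_ranef,
        beta0, 0.0, False,
    )
    if not converged:
        warnings.warn(
            f"penalized LMM did not converge in {n_iter} iterations "
            f"(lam={penalty.lam:g}, alpha={penalty.alpha:g})",
            RuntimeWarning,
        )
    u_map = {lab: float(uv) for lab, uv in zip(labels, u)} if has_ranef else {
        lab: 0.0 for lab in labels
    }
    return PenalizedLMMFit(
        intercept=float(b0),
        beta=beta,
        feature_names=names,
        u=u_map,
        sigma2_site=float(max(s2_site, 0.0)) if has_ranef else 0.0,
        sigma2_res=float(s2_res),
        lam=penalty.lam,
        alpha=penalty.alpha,
        n_iter=int(n_iter),
        converged=bool(converged),
        objective_trace=np.asarray(trace),
    )


def _collinear_columns(Xa: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that do not increase the rank of the preceding ones."""
    bad = []
    rank = 0
    for j in range(Xa.shape[1]):
        r = np.linalg.matrix_rank(Xa[:, : j + 1])
        if r == rank:
            bad.append(names[j])
        rank = r
    return bad


def fit_ml_lmm(X, y, groups=None, tol: float = 1e-8, max_iter: int = 5000) -> PenalizedLMMFit:
    """Unpenalized maximum-likelihood mixed-model fit (``lam = 0``).

    Raises on a rank-deficient design, listing the collinear columns.
    """
    Xa, ya, names, *_ = _prepare(X, y, groups)
    if Xa.shape[1] > 0:
        Xc = np.column_stack([np.ones(len(ya)), Xa])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            bad = _collinear_columns(Xc, ["(intercept)"] + list(names))
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return fit_enet_lmm(
        X, y, groups, PenaltySpec(lam=0.0), tol=tol, max_iter=max_iter
    )


def fit_null(y, groups, tol: float = 1e-8, max_iter: int = 5000) -> PenalizedLMMFit:
    """Intercept-plus-random-intercept model (no covariables).

    Its variance components give the site/residual partition against which
    the full model is compared.  Requires at least two groups.
    """
    ya = np.asarray(y, dtype=float)
    if groups is None or len(np.unique(np.asarray(groups))) < 2:
        raise ValueError("null model needs >= 2 groups to separate the site variance")
    return fit_enet_lmm(
        np.empty((len(ya), 0)), ya, groups, PenaltySpec(lam=0.0),
        tol=tol, max_iter=max_iter,
    )


def predict(fit: PenalizedLMMFit, X_new, groups_new=None, mode: str = "marginal") -> np.ndarray:
    """Predict responses for new rows.

    ``marginal`` returns ``intercept + X beta``; ``conditional`` adds each
    row's site BLUP, falling back to 0 (with a logged notice) for sites not
    seen in training.  ``X_new`` must be on the training standardization.
    """
    if mode not in ("marginal", "conditional"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    if isinstance(X_new, pd.DataFrame):
        Xa = X_new[fit.feature_names].to_numpy(dtype=float)
    else:
        Xa = np.asarray(X_new, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa.reshape(1, -1)
    pred = fit.intercept + Xa @ fit.beta
    if mode == "conditional":
        if groups_new is None:
            raise ValueError("conditional prediction needs group labels")
        labels = np.asarray(groups_new)
        blup = np.zeros(len(labels))
        unseen = set()
        for i, lab in enumerate(labels):
            if lab in fit.u:
                blup[i] = fit.u[lab]
            else:
                unseen.add(lab)
        if unseen:
            log.info("unseen groups in conditional prediction, BLUP=0: %s",
                     sorted(map(str, unseen)))
        pred = pred + blup
    return pred
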