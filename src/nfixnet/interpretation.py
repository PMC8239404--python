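"""Coefficient-importance clustering, reduced model, and partial dependence.

The cross-validated coefficient paths are summarized per covariable by the
median |coefficient| across outer folds and grouped into four magnitude
clusters (high, medium-high, medium-low, low) by one-dimensional k-means;
the reduced model refits the high and medium-high covariables without
penalty under the same outer-CV protocol.  Partial dependence here is the
observed-value profile of the paper's figures: model predictions for the
observed rows, averaged within equal-width intervals of one covariable's
range, with empty intervals flagged rather than interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import FeatureTable
from .model_selection import CVConfig, CVResult, nested_cv
from .penlmm import PenalizedLMMFit, fit_ml_lmm, predict

__all__ = [
    "CLUSTER_LABELS",
    "ImportanceClusters",
    "PDPResult",
    "cluster_coefficients",
    "select_reduced",
    "refit_reduced",
    "partial_dependence",
]

log = logging.getLogger(__name__)

CLUSTER_LABELS = ("high", "medium-high", "medium-low", "low")


@dataclass
class ImportanceClusters:
    """Per-covariable importance summary: median |coefficient|, magnitude
    cluster, zero-shrinkage flag, and sign of the median coefficient."""

    table: pd.DataFrame  # index: covariable; columns: abs_median, cluster, zero_flag, sign
    centroids: dict[str, float]

    def members(self, label: str) -> list[str]:
        if label not in CLUSTER_LABELS:
            raise ValueError(f"unknown cluster label {label!r}")
        return list(self.table.index[self.table["cluster"] == label])


def cluster_coefficients(
    coef_summary: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 50,
) -> ImportanceClusters:
    """Group covariables into ``k`` magnitude clusters by 1-D k-means.

    ``coef_summary`` is the per-covariable frame from
    :attr:`~nfixnet.model_selection.CVResult.coef_summary` (needs columns
    ``abs_median``, ``zero_flag``, ``sign``).  Labels are assigned by
    descending centroid, so ``high`` always holds the largest magnitudes.
    Requires at least ``k`` distinct magnitude values.
    """
    mags = coef_summary["abs_median"].to_numpy(dtype=float)
    if len(np.unique(mags)) < k:
        raise ValueError(
            f"need at least {k} distinct coefficient magnitudes for {k} "
            f"clusters; got {len(np.unique(mags))} — use a smaller k"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(mags.reshape(-1, 1))
    order = np.argsort(-km.cluster_centers_.ravel())  # descending magnitude
    relabel = {int(old): CLUSTER_LABELS[rank] for rank, old in enumerate(order)}
    out = pd.DataFrame(
        {
            "abs_median": mags,
            "cluster": [relabel[int(c)] for c in raw],
            "zero_flag": coef_summary["zero_flag"].to_numpy(),
            "sign": coef_summary["sign"].to_numpy(),
        },
        index=coef_summary.index,
    )
    centroids = {
        CLUSTER_LABELS[rank]: float(km.cluster_centers_.ravel()[old])
        for rank, old in enumerate(order)
    }
    return ImportanceClusters(table=out, centroids=centroids)


def select_reduced(clusters: ImportanceClusters) -> list[str]:
    """Covariables of the high and medium-high clusters, order preserved.

    A zero-flagged covariable landing in a top cluster is excluded with a
    logged warning (a coefficient that is zero in most folds has no
    business in the reduced model, whatever its median magnitude).
    """
    chosen = []
    for name, row in clusters.table.iterrows():
        if row["cluster"] in ("high", "medium-high"):
            if row["zero_flag"]:
                log.warning(
                    "covariable %s is in cluster %s but zero-flagged; "
                    "excluded from the reduced model", name, row["cluster"],
                )
                continue
            chosen.append(name)
    if not chosen:
        raise ValueError("reduced-model selection is empty")
    return chosen


def refit_reduced(
    table: FeatureTable,
    y,
    groups,
    subset: Sequence[str],
    config: CVConfig | None = None,
) -> tuple[PenalizedLMMFit, CVResult]:
    """Unpenalized mixed-model refit on the selected covariables, plus the
    same outer-CV protocol (penalty off) for comparable metrics.

    The subset is frozen before refitting: it is not re-selected inside the
    outer folds, mirroring the two-stage full-then-reduced procedure (the
    selection-bias caveat that implies is documented, not hidden).
    """
    subset = list(subset)
    if not subset:
        raise ValueError("reduced-model subset is empty")
    missing = [c for c in subset if c not in table.columns]
    if missing:
        raise ValueError(f"subset names absent from the table: {missing}")
    cfg = config or CVConfig()
    cfg = CVConfig(**{**cfg.__dict__, "penalized": False})
    from .features import standardize

    std = standardize(table.copy_with(table.df[subset]))
    fit = fit_ml_lmm(std.df, np.asarray(y, dtype=float), groups)
    cv = nested_cv(table, y, groups, cfg, columns=subset)
    return fit, cv


@dataclass
class PDPResult:
    """Segmented-mean partial dependence of one covariable."""

    covariable: str
    edges: np.ndarray            # n_intervals + 1 boundaries over [min, max]
    mean_prediction: np.ndarray  # NaN where empty
    counts: np.ndarray
    empty: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariable": self.covariable,
                "interval_left": self.edges[:-1],
                "interval_right": self.edges[1:],
                "mean_prediction": self.mean_prediction,
                "n_obs": self.counts,
                "empty": self.empty,
            }
        )


def partial_dependence(
    fits: PenalizedLMMFit | Sequence[PenalizedLMMFit],
    table: FeatureTable,
    covariable: str,
    n_intervals: int = 7,
) -> PDPResult:
    """Mean (marginal) prediction within equal-width intervals of one
    covariable's observed range.

    ``fits`` may be a single fit or the per-fold fits of a CV run, whose
    predictions for the observed rows are averaged.  ``table`` must be on
    the standardization the fits were trained with.  Intervals partition
    [min, max]; empty ones are flagged.  A constant covariable has no range
    to segment and raises ``ValueError``.
    """
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    if covariable not in table.columns:
        raise ValueError(f"{covariable!r} is not a model covariable")
    fit_list = [fits] if isinstance(fits, PenalizedLMMFit) else list(fits)
    X = table.df[fit_list[0].feature_names]
    pred = np.mean([predict(f, X, mode="marginal") for f in fit_list], axis=0)
    x = table.df[covariable].to_numpy(dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        raise ValueError(f"covariable {covariable!r} is constant")
    edges = np.linspace(lo, hi, n_intervals + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_intervals - 1)
    means = np.full(n_intervals, np.nan)
    counts = np.zeros(n_intervals, dtype=int)
    for b in range(n_intervals):
        m = idx == b
        counts[b] = int(m.sum())
        if counts[b]:
            means[b] = float(pred[m].mean())
    return PDPResult(
        covariable=covariable,
        edges=edges,
        mean_prediction=means,
        counts=counts,
        empty=counts == 0,
    )
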