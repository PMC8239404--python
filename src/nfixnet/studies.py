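"""Replicate studies over the synthetic trial generator.

These drive the package's own validation: across many independently
generated trials with known ground truth, how often does the nested-CV
elastic-net pipeline recover the active covariables, beat the intercept-only
null model out of bag, absorb the site variance, and how close does the
reduced (top-two-cluster, unpenalized) model track the full model?

Scoring conventions
-------------------
The *estimated important set* of a replicate is the union of the high and
medium-high magnitude clusters (zero-flagged covariables excluded).  Sign
recovery is the fraction of true actives inside that set whose median
coefficient has the true sign; the false-positive rate is the fraction of
truly-inactive retained covariables inside it.  An active covariable
removed by the correlation pre-filter counts as a miss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as feat
from . import interpretation as interp
from . import model_selection as ms
from . import synthetic_data as sd

__all__ = ["replicate_seed", "run_replicate", "recovery_study", "summarize_recovery"]


def replicate_seed(base_seed: int, r: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return int((base_seed * 1_000_003 + 7919 * r + 1) % (2**31))


def run_replicate(seed: int, response: str = "rau",
                  cv: ms.CVConfig | None = None) -> dict:
    """Generate one trial, run the full protocol, and score it."""
    trial = sd.gen_trial(seed=seed)
    table = feat.correlation_filter(
        trial.feature_table,
        keep_preference=feat.default_keep_preference(trial.feature_table.columns),
    )
    y = trial.observations[
        {"rau": "rau", "yield": "yield_mg_ha", "protein": "protein_g_kg"}[response]
    ].to_numpy()
    groups = trial.observations["site_id"].to_numpy()
    cfg = cv or ms.CVConfig(seed=seed)

    full = ms.nested_cv(table, y, groups, cfg)
    null = ms.nested_cv(None, y, groups, cfg)
    clusters = interp.cluster_coefficients(full.coef_summary, seed=seed)
    important = set(interp.select_reduced(clusters))
    _, reduced = interp.refit_reduced(table, y, groups, sorted(important), cfg)

    truth = trial.truth[response]
    actives = set(truth.active_set)
    retained = set(table.columns)
    cs = full.coef_summary
    hits = [
        a in retained
        and a in important
        and np.sign(cs.loc[a, "median"]) == np.sign(truth.beta[a])
        for a in actives
    ]
    inactive = retained - actives
    fm = full.metric_summary.loc["median"]
    nm = null.metric_summary.loc["median"]
    rm = reduced.metric_summary.loc["median"]
    return {
        "seed": seed,
        "p_retained": len(retained),
        "n_important": len(important),
        "sign_recovery": float(np.mean(hits)),
        "false_positive_rate": len(important - actives) / len(inactive),
        "actives_in_top_clusters": actives <= important,
        "rmse_full": fm["RMSE"],
        "rmse_null": nm["RMSE"],
        "rmse_reduced": rm["RMSE"],
        "r2_full": fm["R2"],
        "rrmse_full": fm["RRMSE"],
        "mae_full": fm["MAE"],
        "sigma2_site_full": fm["sigma2_site"],
        "sigma2_site_null": nm["sigma2_site"],
        "sigma2_res_full": fm["sigma2_res"],
        "sigma2_res_null": nm["sigma2_res"],
    }


def recovery_study(n_replicates: int = 100, base_seed: int = 0,
                   response: str = "rau") -> pd.DataFrame:
    """Run ``n_replicates`` independent trials of the full protocol."""
    rows = [
        run_replicate(replicate_seed(base_seed, r), response=response)
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows)


def summarize_recovery(df: pd.DataFrame) -> dict[str, float]:
    """Aggregate rates of a :func:`recovery_study` frame."""
    return {
        "sign_recovery_rate": float(df["sign_recovery"].mean()),
        "false_positive_rate": float(df["false_positive_rate"].mean()),
        "actives_in_top_clusters_rate": float(df["actives_in_top_clusters"].mean()),
        "full_beats_null_rate": float((df["rmse_full"] < df["rmse_null"]).mean()),
        "site_variance_reduced_rate": float(
            (df["sigma2_site_full"] <= df["sigma2_site_null"]).mean()
        ),
        "median_rmse_full": float(df["rmse_full"].median()),
        "median_rmse_null": float(df["rmse_null"].median()),
        "median_rmse_reduced": float(df["rmse_reduced"].median()),
        "reduced_vs_full_rmse_ratio": float(
            (df["rmse_reduced"] / df["rmse_full"]).median()
        ),
        "median_r2_full": float(df["r2_full"].median()),
    }
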