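"""Importance clustering (against an exact 1-D k-means dynamic-programming
oracle), reduced-model selection and refit, and partial dependence."""

import numpy as np
import pandas as pd
import pytest

from nfixnet import features as feat
from nfixnet import interpretation as interp
from nfixnet import model_selection as ms
from nfixnet.containers import FeatureTable
from nfixnet.penlmm import PenalizedLMMFit, fit_ml_lmm


# ---------------------------------------------------------------------------
# exact 1-D k-means by dynamic programming (independent oracle)
# ---------------------------------------------------------------------------

def exact_1d_kmeans(values, k):
    """Optimal 1-D k-means partition (contiguous on sorted values) by DP;
    returns (optimal within-cluster sum of squares, labels)."""
    order = np.argsort(values)
    x = np.asarray(values, dtype=float)[order]
    n = len(x)
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # cost of cluster x[i:j]
        s = pre[j] - pre[i]
        return pre2[j] - pre2[i] - s * s / (j - i)

    dp = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                cost = dp[c - 1, i] + sse(i, j)
                if cost < dp[c, j] - 1e-15:
                    dp[c, j] = cost
                    back[c, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = back[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return dp[k, n], labels


def _summary(mags, zero_flag=None, sign=None):
    mags = np.asarray(mags, dtype=float)
    return pd.DataFrame(
        {
            "abs_median": mags,
            "zero_flag": zero_flag if zero_flag is not None else mags == 0,
            "sign": sign if sign is not None else np.sign(mags),
        },
        index=[f"c{i}" for i in range(len(mags))],
    )


def test_four_separated_bands_recovered():
    mags = [10, 9, 9.5, 5, 5.2, 1, 1.1, 0, 0.05]
    cl = interp.cluster_coefficients(_summary(mags), seed=0)
    t = cl.table
    assert set(t.loc[t.abs_median >= 9, "cluster"]) == {"high"}
    assert set(t.loc[(t.abs_median >= 5) & (t.abs_median < 9), "cluster"]) == {
        "medium-high"
    }
    assert set(t.loc[(t.abs_median >= 1) & (t.abs_median < 5), "cluster"]) == {
        "medium-low"
    }
    assert set(t.loc[t.abs_median < 1, "cluster"]) == {"low"}
    # k-means reaches the DP optimum here
    opt_sse, opt_labels = exact_1d_kmeans(mags, 4)
    got = pd.Categorical(
        t["cluster"], categories=["low", "medium-low", "medium-high", "high"]
    ).codes
    # same partition up to label names
    assert len(set(zip(got, opt_labels))) == 4


def test_kmeans_matches_dp_optimum_on_random_instances():
    rng = np.random.default_rng(1)
    for trial in range(25):
        n = int(rng.integers(6, 40))
        mags = np.abs(np.concatenate([
            rng.normal(0, 0.2, n // 2),
            rng.normal(3, 1.0, n - n // 2),
        ]))
        if len(np.unique(mags)) < 4:
            continue
        cl = interp.cluster_coefficients(_summary(mags), seed=int(trial))
        got_sse = 0.0
        for label in interp.CLUSTER_LABELS:
            members = cl.table.loc[cl.table.cluster == label, "abs_median"]
            if len(members):
                got_sse += float(((members - members.mean()) ** 2).sum())
        opt_sse, _ = exact_1d_kmeans(mags, 4)
        assert got_sse == pytest.approx(opt_sse, rel=1e-9, abs=1e-9)


def test_degenerate_magnitudes_error():
    with pytest.raises(ValueError, match="smaller k"):
        interp.cluster_coefficients(_summary([1.0] * 8), seed=0)


def test_permutation_and_sign_invariance():
    rng = np.random.default_rng(2)
    mags = np.abs(rng.normal(2, 1.5, 20))
    base = interp.cluster_coefficients(_summary(mags), seed=3)
    perm = rng.permutation(20)
    permuted = interp.cluster_coefficients(
        _summary(mags[perm]), seed=3
    )
    for i, j in enumerate(perm):
        assert permuted.table.iloc[i]["cluster"] == base.table.iloc[j]["cluster"]
    # clustering consumes |median|: flipping signs upstream changes nothing
    flipped = interp.cluster_coefficients(
        _summary(mags, sign=-np.sign(mags)), seed=3
    )
    assert list(flipped.table["cluster"]) == list(base.table["cluster"])


# ---------------------------------------------------------------------------
# reduced-model selection
# ---------------------------------------------------------------------------

def _clusters_from(table):
    return interp.ImportanceClusters(table=table, centroids={})


def test_select_reduced_takes_top_two_clusters():
    t = pd.DataFrame(
        {
            "abs_median": [5, 4, 3, 2, 1, 0.5],
            "cluster": ["high", "high", "medium-high", "medium-low", "low", "low"],
            "zero_flag": [False] * 6,
            "sign": [1, -1, 1, 1, -1, 1],
        },
        index=list("abcdef"),
    )
    assert interp.select_reduced(_clusters_from(t)) == ["a", "b", "c"]


def test_select_reduced_excludes_zero_flagged_with_warning(caplog):
    t = pd.DataFrame(
        {
            "abs_median": [5, 4, 1],
            "cluster": ["high", "high", "low"],
            "zero_flag": [False, True, False],
            "sign": [1, 0, 1],
        },
        index=list("abc"),
    )
    import logging

    with caplog.at_level(logging.WARNING, logger="nfixnet.interpretation"):
        out = interp.select_reduced(_clusters_from(t))
    assert out == ["a"]
    assert any("zero-flagged" in r.message for r in caplog.records)


def test_select_reduced_empty_errors():
    t = pd.DataFrame(
        {
            "abs_median": [1.0],
            "cluster": ["low"],
            "zero_flag": [False],
            "sign": [1],
        },
        index=["a"],
    )
    with pytest.raises(ValueError, match="empty"):
        interp.select_reduced(_clusters_from(t))


# ---------------------------------------------------------------------------
# reduced refit
# ---------------------------------------------------------------------------

def test_refit_with_all_columns_equals_ml_fit():
    rng = np.random.default_rng(4)
    n = 60
    X = rng.normal(size=(n, 3))
    groups = np.arange(n) % 6
    y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(scale=0.5, size=n)
    table = FeatureTable(pd.DataFrame(X, columns=["a", "b", "c"]))
    cfg = ms.CVConfig(outer_k=6, inner_k=4, n_lambda=10, seed=0)
    fit, cv = interp.refit_reduced(table, y, groups, ["a", "b", "c"], cfg)
    std = feat.standardize(table)
    ref = fit_ml_lmm(std.df, y, groups)
    assert fit.beta == pytest.approx(ref.beta, abs=1e-8)
    assert fit.lam == 0.0
    assert (cv.fold_records["lam"] == 0).all()


def test_refit_pure_noise_subset_has_low_r2():
    rng = np.random.default_rng(5)
    n = 80
    X = rng.normal(size=(n, 4))
    y = rng.normal(size=n)  # no relation to X
    table = FeatureTable(pd.DataFrame(X, columns=list("abcd")))
    cfg = ms.CVConfig(outer_k=8, inner_k=4, n_lambda=10, seed=1)
    _, cv = interp.refit_reduced(table, y, np.arange(n) % 8, ["a", "b"], cfg)
    assert cv.metric_summary.loc["median", "R2"] < 0.35


def test_refit_requires_nonempty_known_subset():
    table = FeatureTable(pd.DataFrame({"a": np.arange(10.0)}))
    with pytest.raises(ValueError, match="empty"):
        interp.refit_reduced(table, np.arange(10.0), np.zeros(10), [])
    with pytest.raises(ValueError, match="absent"):
        interp.refit_reduced(table, np.arange(10.0), np.zeros(10), ["zz"])


# ---------------------------------------------------------------------------
# partial dependence
# ---------------------------------------------------------------------------

def _linear_fit(names, beta, intercept=0.0):
    return PenalizedLMMFit(
        intercept=intercept,
        beta=np.asarray(beta, dtype=float),
        feature_names=list(names),
        u={},
        sigma2_site=0.0,
        sigma2_res=1.0,
        lam=0.0,
        alpha=0.5,
        n_iter=1,
        converged=True,
    )


def test_pdp_toy_line():
    """y = 2x on x = 0.5, 1.5, ..., 6.5 with 7 unit intervals."""
    x = np.arange(0.5, 7.0, 1.0)
    table = FeatureTable(pd.DataFrame({"x": x}))
    fit = _linear_fit(["x"], [2.0])
    pdp = interp.partial_dependence(fit, table, "x", n_intervals=7)
    assert pdp.mean_prediction == pytest.approx([1, 3, 5, 7, 9, 11, 13])
    assert pdp.counts.sum() == len(x)
    assert not pdp.empty.any()


def test_pdp_monotone_for_positive_slope():
    rng = np.random.default_rng(6)
    x = rng.uniform(-2, 2, 200)
    table = FeatureTable(pd.DataFrame({"x": x}))
    pdp = interp.partial_dependence(_linear_fit(["x"], [1.7]), table, "x")
    vals = pdp.mean_prediction[~pdp.empty]
    assert np.all(np.diff(vals) > 0)
    assert pdp.counts.sum() == 200


def test_pdp_empty_interval_flagged():
    x = np.concatenate([np.linspace(0, 1, 10), np.linspace(6, 7, 10)])
    table = FeatureTable(pd.DataFrame({"x": x}))
    pdp = interp.partial_dependence(_linear_fit(["x"], [1.0]), table, "x")
    assert pdp.empty.any()
    assert np.isnan(pdp.mean_prediction[pdp.empty]).all()


def test_pdp_constant_covariable_errors():
    table = FeatureTable(pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)}))
    with pytest.raises(ValueError, match="constant"):
        interp.partial_dependence(_linear_fit(["x", "y"], [1, 1]), table, "x")


def test_pdp_average_over_fold_fits():
    x = np.linspace(0, 7, 14)
    table = FeatureTable(pd.DataFrame({"x": x}))
    fits = [_linear_fit(["x"], [2.0]), _linear_fit(["x"], [4.0])]
    pdp = interp.partial_dependence(fits, table, "x")
    single = interp.partial_dependence(_linear_fit(["x"], [3.0]), table, "x")
    assert pdp.mean_prediction == pytest.approx(single.mean_prediction)
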