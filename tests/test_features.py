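"""Covariable-formula tests: RAU, SDI, VPD, the drought bucket, window
aggregation, the correlation pre-filter, and standardization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nfixnet import features as feat
from nfixnet.containers import (
    DailyWeatherSeries,
    FeatureTable,
    PhenologyWindows,
)


# ---------------------------------------------------------------------------
# RAU
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ureide, nitrate, expected",
    [
        (20.0, 0.0, 100.0),   # nitrate-free limit
        (0.0, 5.0, 0.0),      # ureide-free limit
        (10.0, 10.0, 80.0),   # 4*10 / (4*10 + 10) = 40/50
    ],
)
def test_rau_values(ureide, nitrate, expected):
    assert feat.compute_rau(ureide, nitrate) == pytest.approx(expected)


def test_rau_errors():
    with pytest.raises(ValueError, match="both zero"):
        feat.compute_rau(0.0, 0.0)
    with pytest.raises(ValueError, match=">= 0"):
        feat.compute_rau(-1.0, 5.0)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    u=st.floats(0.01, 50.0),
    n=st.floats(0.01, 50.0),
    du=st.floats(0.1, 10.0),
)
def test_rau_bounds_and_monotonicity(u, n, du):
    """RAU stays in [0, 100], increases in ureide, decreases in nitrate."""
    r = feat.compute_rau(u, n)
    assert 0.0 <= r <= 100.0
    assert feat.compute_rau(u + du, n) > r
    assert feat.compute_rau(u, n + du) < r


# ---------------------------------------------------------------------------
# SDI
# ---------------------------------------------------------------------------

def test_sdi_uniform_is_one():
    assert feat.compute_sdi([3.0] * 17) == pytest.approx(1.0)


def test_sdi_single_day_is_zero():
    assert feat.compute_sdi([0, 0, 7.5, 0]) == pytest.approx(0.0)


def test_sdi_half_even():
    # two equal wet days among four: H = ln 2, normalized by ln 4
    assert feat.compute_sdi([5, 5, 0, 0]) == pytest.approx(0.5)


def test_sdi_errors():
    with pytest.raises(ValueError, match="zero total"):
        feat.compute_sdi([0.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="at least 2"):
        feat.compute_sdi([1.0])
    with pytest.raises(ValueError, match=">= 0"):
        feat.compute_sdi([1.0, -0.5])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    data=st.lists(st.floats(0, 50), min_size=2, max_size=40),
    c=st.floats(0.01, 100),
    seed=st.integers(0, 10_000),
)
def test_sdi_invariances(data, c, seed):
    """SDI is scale-invariant and permutation-invariant, and lies in [0, 1]."""
    x = np.asarray(data)
    if x.sum() <= 1e-6:
        x = x.copy()
        x[0] = 1.0
    s = feat.compute_sdi(x)
    assert 0.0 <= s <= 1.0 + 1e-12
    assert feat.compute_sdi(c * x) == pytest.approx(s, abs=1e-9)
    perm = np.random.default_rng(seed).permutation(x)
    assert feat.compute_sdi(perm) == pytest.approx(s, abs=1e-9)


# ---------------------------------------------------------------------------
# VPD
# ---------------------------------------------------------------------------

def test_vpd_saturated_air_is_zero():
    assert feat.compute_vpd(10.0, 30.0, 100.0) == pytest.approx(0.0)


def test_vpd_half_saturation_at_constant_temp():
    es25 = 0.6108 * math.exp(17.27 * 25 / (25 + 237.3))
    assert feat.compute_vpd(25.0, 25.0, 50.0) == pytest.approx(0.5 * es25)


def test_vpd_dry_limit_is_mean_saturation_pressure():
    es = 0.5 * (
        feat.saturation_vapor_pressure(15.0) + feat.saturation_vapor_pressure(28.0)
    )
    assert feat.compute_vpd(15.0, 28.0, 0.0) == pytest.approx(es)


def test_vpd_domain_errors():
    with pytest.raises(ValueError, match="humidity"):
        feat.compute_vpd(10.0, 20.0, 105.0)
    with pytest.raises(ValueError, match="tmin"):
        feat.compute_vpd(25.0, 20.0, 50.0)


# ---------------------------------------------------------------------------
# drought bucket
# ---------------------------------------------------------------------------

def test_bucket_no_stress_when_rain_meets_demand(toy_weather, toy_windows):
    params = feat.BucketParams(capacity_mm=50.0, kc=0.2)  # demand 1 < rain 2
    red = feat.bucket_drought_stress(toy_weather, params, toy_windows)
    assert np.all(red == 0.0)


def test_bucket_depletion_gives_positive_nondecreasing_cumulative(toy_windows):
    n = 10
    dry = DailyWeatherSeries(
        pd.DataFrame(
            {
                "doy": np.arange(150, 160),
                "tmin": 15.0,
                "tmax": 25.0,
                "precip": np.zeros(n),
                "radiation": 20.0,
                "et0": np.full(n, 6.0),
                "rh_mean": 50.0,
            }
        )
    )
    params = feat.BucketParams(capacity_mm=10.0, initial_fraction=0.5, kc=1.0)
    red = feat.bucket_drought_stress(dry, params, toy_windows)
    assert red.sum() > 0
    assert np.all(np.diff(np.cumsum(red)) >= 0)
    assert np.all(red <= 6.0 + 1e-12)  # never exceeds the day's demand


def test_bucket_matches_hand_simulation(toy_weather, toy_windows):
    """Day-by-day hand run of the documented bucket recurrence."""
    params = feat.BucketParams(
        capacity_mm=20.0,
        initial_fraction=0.6,
        frac_thresh_low_et=0.5,
        frac_thresh_high_et=0.8,
        et_split_mm=4.0,
        kc=1.0,
        max_reduction_frac=0.6,
    )
    red = feat.bucket_drought_stress(toy_weather, params, toy_windows)
    content = 0.6 * 20.0
    expected = []
    for day in range(len(toy_weather)):
        demand = 5.0  # kc * et0
        thresh = 0.8  # demand 5 > et_split 4 -> high-ET threshold
        rel = content / 20.0
        if rel >= thresh:
            actual = demand
        else:
            actual = demand * max(rel / thresh, 1 - 0.6)
        expected.append(demand - actual)
        content = min(max(content + 2.0 - actual, 0.0), 20.0)
    assert red == pytest.approx(expected, abs=1e-12)


def test_bucket_requires_covering_calendar(toy_weather):
    windows = PhenologyWindows(VE=100, R1=120, R4=140, R5=150, R7=200)
    with pytest.raises(ValueError, match="does not cover"):
        feat.bucket_drought_stress(toy_weather, feat.BucketParams(), windows)


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def test_window_sums_and_means_toy():
    """9-day season split 3/3/3 with distinct values, all aggregates by hand."""
    df = pd.DataFrame(
        {
            "doy": np.arange(100, 109),
            "tmin": [10, 11, 12, 13, 14, 15, 16, 17, 18],
            "tmax": [20, 21, 22, 23, 24, 25, 26, 27, 28],
            "precip": [1, 2, 3, 4, 5, 6, 7, 8, 9],
            "radiation": [10.0] * 3 + [20.0] * 3 + [30.0] * 3,
            "et0": [2.0] * 9,
            "rh_mean": [50.0] * 9,
        }
    )
    weather = DailyWeatherSeries(df)
    win = PhenologyWindows(VE=100, R1=103, R4=105, R5=106, R7=108)
    out = feat.summarize_windows(weather, win)
    assert out["Prec.v"] == pytest.approx(6.0)    # 1+2+3
    assert out["Prec.r"] == pytest.approx(15.0)   # 4+5+6
    assert out["Prec.s"] == pytest.approx(24.0)   # 7+8+9
    assert out["Rad.v"] == pytest.approx(30.0)
    assert out["Rad.r"] == pytest.approx(60.0)
    assert out["Rad.s"] == pytest.approx(90.0)
    assert out["Tmean.v"] == pytest.approx(16.0)  # mean of 15,16,17
    assert out["Tmean.r"] == pytest.approx(19.0)
    assert out["Tmean.s"] == pytest.approx(22.0)
    assert out["T.Amp.v"] == pytest.approx(10.0)
    assert out["ET0.s"] == pytest.approx(6.0)
    assert out["SDI.v"] == pytest.approx(feat.compute_sdi([1, 2, 3]))


def test_single_window_reproduces_whole_season(toy_weather):
    win = PhenologyWindows(
        VE=150, R1=151, R4=152, R5=153, R7=159
    )
    full = feat.summarize_windows(
        toy_weather,
        PhenologyWindows(VE=150, R1=155, R4=156, R5=157, R7=159),
        window_tags=("v",),
    )
    # one window equal to the whole season: build it via bounds [VE, R1)
    whole = feat.summarize_windows(
        toy_weather,
        PhenologyWindows(VE=150, R1=160, R4=161, R5=162, R7=163),
        window_tags=("v",),
    )
    df = toy_weather.df
    assert whole["Prec.v"] == pytest.approx(df["precip"].sum())
    assert whole["Rad.v"] == pytest.approx(df["radiation"].sum())
    assert whole["Tmean.v"] == pytest.approx(
        (0.5 * (df["tmin"] + df["tmax"])).mean()
    )
    assert full["Prec.v"] == pytest.approx(df["precip"].iloc[:5].sum())


def test_window_outside_calendar_names_window(toy_weather):
    win = PhenologyWindows(VE=140, R1=153, R4=155, R5=156, R7=159)
    with pytest.raises(ValueError, match="'v'"):
        feat.summarize_windows(toy_weather, win)


# ---------------------------------------------------------------------------
# correlation filter
# ---------------------------------------------------------------------------

def _table_from_matrix(X, names, binary=()):
    return FeatureTable(pd.DataFrame(X, columns=names), binary_cols=binary)


def test_duplicated_column_dropped_once():
    rng = np.random.default_rng(0)
    x = rng.normal(size=60)
    tab = _table_from_matrix(np.column_stack([x, x, rng.normal(size=60)]),
                             ["a", "b", "c"])
    out = feat.correlation_filter(tab)
    assert out.columns == ["a", "c"]
    assert len(out.drop_log) == 1
    rec = out.drop_log[0]
    assert rec.dropped == "b" and rec.kept == "a"
    assert rec.r == pytest.approx(1.0)


def test_independent_columns_rarely_dropped():
    """Under the null (independent columns, n=95) drops are rare."""
    rng = np.random.default_rng(7)
    clean = 0
    n_rep = 40
    for _ in range(n_rep):
        tab = _table_from_matrix(rng.normal(size=(95, 8)),
                                 [f"x{j}" for j in range(8)])
        out = feat.correlation_filter(tab)
        clean += len(out.drop_log) == 0
    assert clean / n_rep >= 0.95


def test_paper_like_structure_retains_35_of_40():
    """Four collinear families (texture closure, SOM-OMM, RH-Tmean,
    ET0-VPD) among 40 covariables leave 35 after filtering."""
    rng = np.random.default_rng(11)
    n = 95
    cols = {}
    sand = rng.uniform(9, 50, n)
    clay = 35 - 0.35 * sand + rng.normal(0, 2.0, n)  # finer soils hold more clay
    silt = 100 - sand - clay
    cols["Sand"], cols["Clay"], cols["Silt"] = sand, clay, silt
    som = rng.uniform(6, 48, n)
    cols["SOM"] = som
    cols["OMM"] = 0.01 + 0.0015 * som + rng.normal(0, 0.002, n)
    tmean = rng.normal(23, 1, n)
    cols["Tmean"] = tmean
    cols["Hum"] = 0.09 * tmean + rng.normal(0, 0.02, n)
    vpd = rng.normal(0.8, 0.1, n)
    cols["VPD"] = vpd
    cols["ET0"] = 300 + 180 * vpd + rng.normal(0, 5, n)
    for j in range(31):
        cols[f"z{j}"] = rng.normal(size=n)
    tab = FeatureTable(pd.DataFrame(cols))
    # silt ~ -sand under closure: check the family is actually collinear
    out = feat.correlation_filter(
        tab, keep_preference=feat.default_keep_preference(tab.columns)
    )
    assert len(tab.columns) == 40
    assert len(out.columns) == 35
    assert set(d.dropped for d in out.drop_log) == {
        "Silt", "Clay", "OMM", "Hum", "ET0"
    }
    # no surviving flagged pair
    from scipy import stats
    cont = out.continuous_cols
    for i in range(len(cont)):
        for j in range(i + 1, len(cont)):
            r, p = stats.pearsonr(out.df[cont[i]], out.df[cont[j]])
            assert not (abs(r) > 0.75 and p < 0.05)


def test_explicit_preference_must_cover_flagged_pair():
    rng = np.random.default_rng(3)
    x = rng.normal(size=50)
    tab = _table_from_matrix(np.column_stack([x, x + 1e-6 * rng.normal(size=50)]),
                             ["a", "b"])
    with pytest.raises(ValueError, match="explicit"):
        feat.correlation_filter(tab, keep_preference=["a"])


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_population_convention():
    tab = _table_from_matrix(np.array([[1.0], [2.0], [3.0]]), ["x"])
    out = feat.standardize(tab)
    expected = np.array([-1.0, 0.0, 1.0]) * math.sqrt(3 / 2)
    assert out.df["x"].to_numpy() == pytest.approx(expected)
    assert out.scaling["x"] == pytest.approx((2.0, math.sqrt(2.0 / 3.0)))


def test_standardize_idempotent():
    rng = np.random.default_rng(0)
    tab = _table_from_matrix(rng.normal(2, 5, size=(40, 3)), ["a", "b", "c"])
    once = feat.standardize(tab)
    twice = feat.standardize(once)
    assert np.allclose(once.df.to_numpy(), twice.df.to_numpy(), atol=1e-12)


def test_standardize_uses_fit_rows_only():
    """Scaling from the training rows leaves the test rows off-center."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 2))
    X[40:, 0] += 5.0  # shifted test block
    tab = _table_from_matrix(X, ["a", "b"])
    out = feat.standardize(tab, fit_rows=np.arange(40))
    assert abs(out.df["a"].to_numpy()[:40].mean()) < 1e-9
    assert out.df["a"].to_numpy()[40:].mean() > 1.0


def test_standardize_binary_centered_not_scaled():
    X = np.column_stack([np.r_[np.ones(5), np.zeros(15)], np.arange(20.0)])
    tab = _table_from_matrix(X, ["treat", "x"], binary=["treat"])
    out = feat.standardize(tab)
    vals = np.unique(out.df["treat"].round(9))
    assert vals == pytest.approx([-0.25, 0.75])  # centered, still unit gap


def test_standardize_constant_column_errors():
    tab = _table_from_matrix(np.column_stack([np.ones(10), np.arange(10.0)]),
                             ["const", "x"])
    with pytest.raises(ValueError, match="const"):
        feat.standardize(tab)


def test_drop_constant_and_sparse_columns():
    n = 95
    X = np.column_stack([
        np.ones(n),                       # constant
        np.r_[np.ones(5), np.zeros(n - 5)],  # varies in 5% of rows
        np.arange(float(n)),              # fine
    ])
    tab = _table_from_matrix(X, ["const", "sparse", "x"])
    out, dropped = feat.drop_constant_columns(tab)
    assert dropped == ["const", "sparse"]
    assert out.columns == ["x"]


def test_destandardize_roundtrip():
    rng = np.random.default_rng(5)
    tab = _table_from_matrix(rng.normal(3, 2, size=(30, 2)), ["a", "b"])
    std = feat.standardize(tab)
    beta_std = {"a": 1.5, "b": -0.5}
    beta_raw, b0_raw = feat.destandardize_coefficients(beta_std, std.scaling, 10.0)
    row = tab.df.iloc[4]
    pred_std = 10.0 + sum(beta_std[c] * std.df.iloc[4][c] for c in ("a", "b"))
    pred_raw = b0_raw + sum(beta_raw[c] * row[c] for c in ("a", "b"))
    assert pred_raw == pytest.approx(pred_std)
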