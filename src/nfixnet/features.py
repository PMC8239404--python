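"""Covariable engineering for multi-environment soybean trials.

Turns raw trial/weather/soil inputs into the standardized covariable matrix
used by the penalized mixed model:

* :func:`compute_rau` — relative abundance of ureides (%), the proxy for the
  fraction of plant N derived from symbiotic fixation,
  ``RAU = 100 * 4u / (4u + n)`` with stem ureide ``u`` and nitrate ``n``
  concentrations (umol g-1).
* :func:`compute_sdi` — Shannon evenness of within-window precipitation,
  normalized to [0, 1] (1 = the same rain every day, 0 = all rain on one day).
* :func:`compute_vpd` — daily mean vapor pressure deficit from the FAO-56
  saturation curve ``es(T) = 0.6108 * exp(17.27 T / (T + 237.3))`` kPa:
  ``vpd = mean(es(tmin), es(tmax)) * (1 - rh/100)``.
* :func:`bucket_drought_stress` — a single-bucket soil-water balance whose
  output is the daily reduction in crop transpiration, triggered when
  relative plant-available water falls below a demand-dependent threshold
  (the wetter threshold applies on high-demand days, mirroring the -50 kPa /
  -80 kPa dual trigger of full soil-water models).
* :func:`summarize_windows` — per-phenology-window aggregates (cumulative
  for water/energy fluxes, means for temperature/VPD/humidity).
* :func:`correlation_filter` — drops one member of each significantly,
  highly correlated covariable pair (|r| > 0.75, p < 0.05 by default).
* :func:`standardize` — center/scale on a fitting subset only, keeping the
  pairs for back-transformation; binary indicators are centered, not scaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DailyWeatherSeries, DropRecord, FeatureTable, PhenologyWindows

__all__ = [
    "compute_rau",
    "compute_sdi",
    "compute_vpd",
    "saturation_vapor_pressure",
    "BucketParams",
    "bucket_drought_stress",
    "summarize_windows",
    "correlation_filter",
    "standardize",
    "destandardize_coefficients",
    "build_feature_table",
    "WEATHER_VAR_STATS",
    "SOIL_COLUMNS",
    "CROP_COLUMNS",
]


# ---------------------------------------------------------------------------
# scalar / vector covariable formulas
# ---------------------------------------------------------------------------

def compute_rau(ureide, nitrate):
    """Relative abundance of ureides, in percent.

    ``RAU = 100 * 4u / (4u + n)``; the factor 4 counts the four N atoms
    carried per ureide molecule against the single N of nitrate.

    Accepts scalars or arrays (broadcast).  Raises ``ValueError`` on any
    negative input or on a pair where both concentrations are zero.
    """
    u = np.asarray(ureide, dtype=float)
    n = np.asarray(nitrate, dtype=float)
    if (u < 0).any() or (n < 0).any():
        raise ValueError("ureide and nitrate concentrations must be >= 0")
    denom = 4.0 * u + n
    if (denom == 0).any():
        raise ValueError("RAU undefined: ureide and nitrate both zero")
    out = 100.0 * 4.0 * u / denom
    return float(out) if out.ndim == 0 else out


def compute_sdi(daily_precip) -> float:
    """Shannon evenness index of a daily precipitation vector.

    ``SDI = -sum(p_i ln p_i) / ln(n)`` with ``p_i = day_i / total`` and the
    convention ``0 ln 0 = 0``.  Lies in [0, 1]: 1 for perfectly even rain,
    0 when all rain falls on a single day.
    """
    x = np.asarray(daily_precip, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("SDI needs a 1-D vector of at least 2 days")
    if (x < 0).any():
        raise ValueError("precipitation must be >= 0")
    total = x.sum()
    if total <= 0:
        raise ValueError("SDI undefined for zero total precipitation")
    p = x / total
    p = p[p > 0]
    h = -(p * np.log(p)).sum()
    return float(h / math.log(len(x)))


def saturation_vapor_pressure(temp_c):
    """FAO-56 saturation vapor pressure (kPa) at air temperature ``temp_c`` (C)."""
    t = np.asarray(temp_c, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if out.ndim == 0 else out


def compute_vpd(tmin, tmax, rh_mean):
    """Daily mean vapor pressure deficit (kPa).

    ``vpd = mean(es(tmin), es(tmax)) * (1 - rh/100)`` — zero exactly at
    saturation (rh = 100).  Raises on rh outside [0, 100] or tmin > tmax.
    """
    tn = np.asarray(tmin, dtype=float)
    tx = np.asarray(tmax, dtype=float)
    rh = np.asarray(rh_mean, dtype=float)
    if (tn > tx + 1e-12).any():
        raise ValueError("tmin must not exceed tmax")
    if (rh < 0).any() or (rh > 100).any():
        raise ValueError("relative humidity must lie in [0, 100]")
    es = 0.5 * (saturation_vapor_pressure(tn) + saturation_vapor_pressure(tx))
    out = es * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# soil-water bucket
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BucketParams:
    """Water-holding parameters of the single-bucket drought model.

    ``capacity_mm`` is plant-available water in the root zone; stress begins
    when relative content drops below ``frac_thresh_low_et`` on low-demand
    days or below the wetter ``frac_thresh_high_et`` on days with crop
    demand above ``et_split_mm`` (high atmospheric demand makes stress set
    in at higher soil-water content).  ``kc`` converts reference to crop
    evapotranspiration.  Below the threshold, actual transpiration ramps
    down linearly with relative content but never below
    ``1 - max_reduction_frac`` of demand (subsoil water keeps part of the
    demand supplied), so a day's reduction is at most
    ``max_reduction_frac * demand``.
    """

    capacity_mm: float = 150.0
    initial_fraction: float = 1.0
    frac_thresh_low_et: float = 0.80
    frac_thresh_high_et: float = 0.95
    et_split_mm: float = 4.0
    kc: float = 0.5
    max_reduction_frac: float = 0.3

    def __post_init__(self):
        if self.capacity_mm <= 0 or self.kc <= 0 or self.et_split_mm <= 0:
            raise ValueError("bucket parameters must be positive")
        if not (0 < self.frac_thresh_low_et <= self.frac_thresh_high_et <= 1):
            raise ValueError(
                "need 0 < frac_thresh_low_et <= frac_thresh_high_et <= 1"
            )
        if not (0 <= self.initial_fraction <= 1):
            raise ValueError("initial_fraction must lie in [0, 1]")
        if not (0 < self.max_reduction_frac <= 1):
            raise ValueError("max_reduction_frac must lie in (0, 1]")

    @classmethod
    def from_soil(cls, soil: Mapping[str, float], root_depth_mm: float = 1200.0,
                  **overrides) -> "BucketParams":
        """Derive capacity from texture: available-water fraction rises with
        clay and falls with sand (pedotransfer rule of thumb)."""
        clay = float(soil.get("Clay", 20.0))
        sand = float(soil.get("Sand", 30.0))
        awc = 0.12 + 0.0020 * clay - 0.0010 * sand  # m3 m-3
        awc = min(max(awc, 0.05), 0.22)
        return cls(capacity_mm=awc * root_depth_mm, **overrides)


def bucket_drought_stress(
    weather: DailyWeatherSeries,
    soil: BucketParams | Mapping[str, float],
    windows: PhenologyWindows,
) -> np.ndarray:
    """Daily transpiration reduction (mm) from a single-bucket water balance.

    The bucket starts at ``initial_fraction`` of capacity on the emergence
    day (VE) and is updated through R7: demand is ``kc * et0``; when relative
    content is below the demand-dependent threshold, actual transpiration is
    ramped down linearly with relative content and the shortfall is the
    day's reduction.  Days outside [VE, R7] get reduction 0.

    Returns an array aligned with ``weather.df`` rows.  Raises if the
    weather calendar does not cover the season.
    """
    if not isinstance(soil, BucketParams):
        soil = BucketParams.from_soil(soil)
    if windows.VE < weather.start_doy or windows.R7 > weather.end_doy:
        raise ValueError(
            f"weather calendar [{weather.start_doy}, {weather.end_doy}] does "
            f"not cover the season [{windows.VE}, {windows.R7}]"
        )
    doy = weather.df["doy"].to_numpy()
    precip = weather.df["precip"].to_numpy(dtype=float)
    et0 = weather.df["et0"].to_numpy(dtype=float)

    reduction = np.zeros(len(doy))
    content = soil.initial_fraction * soil.capacity_mm
    in_season = (doy >= windows.VE) & (doy <= windows.R7)
    for i in np.flatnonzero(in_season):
        demand = soil.kc * et0[i]
        thresh = (
            soil.frac_thresh_high_et
            if demand > soil.et_split_mm
            else soil.frac_thresh_low_et
        )
        rel = content / soil.capacity_mm
        if rel >= thresh:
            actual = demand
        else:
            # linear ramp below the threshold, floored: part of the demand
            # is always met from below the bucket (subsoil water access),
            # so the daily reduction never exceeds max_reduction_frac of
            # that day's demand
            actual = demand * max(rel / thresh, 1.0 - soil.max_reduction_frac)
        reduction[i] = demand - actual
        content = min(content + precip[i] - actual, soil.capacity_mm)
        content = max(content, 0.0)
    return reduction


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

#: statistic per weather covariable: cumulative for water/energy fluxes,
#: mean for state variables; SDI is an evenness index of the window's rain.
WEATHER_VAR_STATS: dict[str, str] = {
    "ET0": "sum",
    "Hum": "mean",
    "Prec": "sum",
    "Rad": "sum",
    "SDI": "sdi",
    "D.str": "sum",
    "T.Amp": "mean",
    "Tmean": "mean",
    "VPD": "mean",
}


def _daily_variables(weather: DailyWeatherSeries) -> pd.DataFrame:
    """Derive the daily series behind each weather covariable."""
    df = weather.df
    out = pd.DataFrame({"doy": df["doy"].to_numpy()})
    tmin = df["tmin"].to_numpy(dtype=float)
    tmax = df["tmax"].to_numpy(dtype=float)
    out["ET0"] = df["et0"].to_numpy(dtype=float)
    out["Prec"] = df["precip"].to_numpy(dtype=float)
    out["Rad"] = df["radiation"].to_numpy(dtype=float)
    out["T.Amp"] = tmax - tmin
    out["Tmean"] = 0.5 * (tmin + tmax)
    es = 0.5 * (saturation_vapor_pressure(tmin) + saturation_vapor_pressure(tmax))
    if "vpd" in df.columns:
        out["VPD"] = df["vpd"].to_numpy(dtype=float)
    else:
        out["VPD"] = compute_vpd(tmin, tmax, df["rh_mean"].to_numpy(dtype=float))
    # Hum: actual vapor pressure (kPa), es - vpd (equivalently es * rh/100)
    if "rh_mean" in df.columns:
        out["Hum"] = es * df["rh_mean"].to_numpy(dtype=float) / 100.0
    else:
        out["Hum"] = es - out["VPD"]
    if "transp_reduction" in df.columns:
        out["D.str"] = df["transp_reduction"].to_numpy(dtype=float)
    return out


def summarize_windows(
    weather: DailyWeatherSeries,
    windows: PhenologyWindows,
    var_stats: Mapping[str, str] | None = None,
    window_tags: Sequence[str] = ("v", "r", "s"),
) -> dict[str, float]:
    """Aggregate each weather covariable over each phenology window.

    Returns suffix-named values, e.g. ``Prec.r`` (cumulative pre-seed-filling
    precipitation, mm) or ``VPD.s`` (mean seed-filling VPD, kPa).  A window
    that falls outside the weather calendar raises ``ValueError`` naming it.
    A window with zero total rain gets SDI 0.0 (fully uneven by convention).
    """
    var_stats = dict(var_stats or WEATHER_VAR_STATS)
    daily = _daily_variables(weather)
    available = [
        v for v, s in var_stats.items()
        if v in daily.columns or (s == "sdi" and "Prec" in daily.columns)
    ]
    out: dict[str, float] = {}
    for tag in window_tags:
        lo, hi = windows.window_bounds(tag)
        if lo < weather.start_doy or hi > weather.end_doy:
            raise ValueError(
                f"window {tag!r} [{lo}, {hi}] outside weather calendar "
                f"[{weather.start_doy}, {weather.end_doy}]"
            )
        m = (daily["doy"] >= lo) & (daily["doy"] <= hi)
        sub = daily.loc[m]
        for var in available:
            stat = var_stats[var]
            series = sub["Prec" if stat == "sdi" else var].to_numpy(dtype=float)
            if stat == "sum":
                val = float(series.sum())
            elif stat == "mean":
                val = float(series.mean())
            elif stat == "sdi":
                val = compute_sdi(series) if series.sum() > 0 else 0.0
            else:
                raise ValueError(f"unknown statistic {stat!r} for {var!r}")
            out[f"{var}.{tag}"] = val
    return out


# ---------------------------------------------------------------------------
# correlation pre-filter and standardization
# ---------------------------------------------------------------------------

#: retention priority class per covariable family when a correlated pair is
#: flagged (lower = preferred).  Encodes the field conventions: keep sand
#: over the other texture fractions, SOM over its mineralization index,
#: mean temperature over humidity, and VPD over reference ET.
_KEEP_PRIORITY: dict[str, int] = {
    "Clay": 2, "Silt": 3, "OMM": 3, "Hum": 3, "ET0": 3,
}


def default_keep_preference(columns: Sequence[str]) -> list[str]:
    """Order columns for :func:`correlation_filter`: preferred members of
    known collinear families first, otherwise original order."""
    def key(item):
        i, c = item
        base = c.rsplit(".", 1)[0] if c[-2:] in (".v", ".r", ".s") else c
        return (_KEEP_PRIORITY.get(base, 1), i)

    return [c for _, c in sorted(enumerate(columns), key=lambda t: key(t))]


def correlation_filter(
    table: FeatureTable,
    r_threshold: float = 0.75,
    p_threshold: float = 0.05,
    keep_preference: Sequence[str] | None = None,
) -> FeatureTable:
    """Drop one member of each significantly, highly correlated pair.

    Pairs of *continuous* columns with ``|r| > r_threshold`` and a two-sided
    Pearson-correlation test ``p < p_threshold`` are processed in order of
    decreasing |r|; the member ranked later in ``keep_preference`` is
    dropped.  ``keep_preference`` defaults to the table's column order.  If
    an explicit preference list omits a column involved in a flagged pair,
    a ``ValueError`` demands an explicit choice.  Every drop is recorded as
    a :class:`~nfixnet.containers.DropRecord` on the returned table.
    """
    cont = table.continuous_cols
    if len(cont) < 2:
        raise ValueError("correlation filter needs at least 2 continuous columns")
    explicit_pref = keep_preference is not None
    pref = list(keep_preference) if explicit_pref else list(table.columns)
    rank = {c: i for i, c in enumerate(pref)}

    flagged: list[tuple[float, float, str, str]] = []
    for i in range(len(cont)):
        for j in range(i + 1, len(cont)):
            a, b = cont[i], cont[j]
            r, p = stats.pearsonr(table.df[a], table.df[b])
            if abs(r) > r_threshold and p < p_threshold:
                flagged.append((abs(r), p, a, b))
    flagged.sort(key=lambda t: (-t[0], t[2], t[3]))

    dropped: set[str] = set()
    log = list(table.drop_log)
    for absr, p, a, b in flagged:
        if a in dropped or b in dropped:
            continue
        for c in (a, b):
            if explicit_pref and c not in rank:
                raise ValueError(
                    f"flagged pair ({a!r}, {b!r}) needs an explicit keep "
                    f"preference for {c!r}"
                )
        ra = rank.get(a, len(pref))
        rb = rank.get(b, len(pref))
        keep, drop = (a, b) if ra <= rb else (b, a)
        r_signed, _ = stats.pearsonr(table.df[keep], table.df[drop])
        dropped.add(drop)
        log.append(DropRecord(dropped=drop, kept=keep, r=float(r_signed), p=float(p)))

    kept_cols = [c for c in table.columns if c not in dropped]
    return table.copy_with(table.df[kept_cols], drop_log=log)


def drop_constant_columns(
    table: FeatureTable, tol: float = 1e-10, min_varying_frac: float = 0.2
) -> tuple[FeatureTable, list[str]]:
    """Remove columns with (near-)zero variance, returning them by name.

    A covariable that does not vary across environments (e.g. early-season
    drought stress in a network where no vegetative-stage drought occurred)
    carries no signal and would break standardization; one varying in only
    a handful of rows (fewer than ``min_varying_frac``) can still go
    constant inside resampling folds and is screened out for the same
    reason.
    """
    sds = table.df.std(ddof=0)
    dropped = []
    for c in table.columns:
        if sds[c] <= tol:
            dropped.append(c)
            continue
        if c in table.binary_cols:
            continue  # indicators are centered, never scaled: folds are safe
        vals = table.df[c].to_numpy()
        mode = pd.Series(vals).mode().iloc[0]
        if np.mean(vals != mode) < min_varying_frac:
            dropped.append(c)
    if not dropped:
        return table, []
    kept = [c for c in table.columns if c not in dropped]
    return table.copy_with(table.df[kept]), dropped


def standardize(
    table: FeatureTable,
    fit_rows: Sequence[int] | np.ndarray | None = None,
    scale_binary: bool = False,
) -> FeatureTable:
    """Center and scale columns using statistics from ``fit_rows`` only.

    Continuous columns are centered and divided by their population standard
    deviation (ddof = 0) on the fitting rows; binary indicator columns are
    centered but left on the 0/1 scale unless ``scale_binary``.  The
    (center, scale) pairs are stored on the returned table so coefficients
    can be mapped back to original units.  A column constant on the fitting
    rows raises ``ValueError`` naming it.
    """
    idx = np.arange(len(table)) if fit_rows is None else np.asarray(fit_rows)
    if len(idx) == 0:
        raise ValueError("fit_rows must be nonempty")
    df = table.df.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in table.columns:
        vals = df[col].to_numpy(dtype=float)
        center = float(vals[idx].mean())
        if col in table.binary_cols and not scale_binary:
            scale = 1.0
        else:
            scale = float(vals[idx].std(ddof=0))
            if scale < 1e-12:
                raise ValueError(f"column {col!r} is constant on the fitting rows")
        df[col] = (vals - center) / scale
        scaling[col] = (center, scale)
    return table.copy_with(df, scaling=scaling)


def destandardize_coefficients(
    beta: Mapping[str, float], scaling: Mapping[str, tuple[float, float]],
    intercept: float,
) -> tuple[dict[str, float], float]:
    """Map coefficients from the standardized scale back to original units."""
    out: dict[str, float] = {}
    b0 = float(intercept)
    for col, b in beta.items():
        center, scale = scaling[col]
        out[col] = b / scale
        b0 -= b * center / scale
    return out, b0


# ---------------------------------------------------------------------------
# end-to-end table assembly
# ---------------------------------------------------------------------------

#: engineered column -> trial-table source column
CROP_COLUMNS: dict[str, str] = {
    "MG": "maturity_group",
    "S.Phe": "s_phe",
    "S.Length": "season_days",
    "Sowing": "sowing_doy",
}

SOIL_COLUMNS: tuple[str, ...] = (
    "CEC", "Clay", "N.NO3", "OMM", "pH", "Sand", "Silt", "S.SO4", "SOM",
)


def build_feature_table(
    trial: pd.DataFrame,
    weather: Mapping[tuple, DailyWeatherSeries],
    phenology: Mapping[str, PhenologyWindows],
    soil: pd.DataFrame,
    bucket: BucketParams | None = None,
    compute_drought: bool = True,
) -> FeatureTable:
    """Assemble the unstandardized covariable table, one row per trial row.

    ``weather`` is keyed by ``(site_id, year)``; ``phenology`` by ``env_id``;
    ``soil`` must carry ``site_id`` plus the nine soil covariables.  When
    ``compute_drought`` the transpiration-reduction series is computed per
    environment with :func:`bucket_drought_stress` (bucket capacity derived
    from each site's texture unless ``bucket`` is given).
    """
    soil = soil.set_index("site_id")
    rows: list[dict[str, float]] = []
    env_cache: dict[str, dict[str, float]] = {}
    for _, obs in trial.iterrows():
        env = obs["env_id"]
        if env not in env_cache:
            wx = weather[(obs["site_id"], obs["year"])]
            win = phenology[env]
            soil_row = soil.loc[obs["site_id"]]
            if compute_drought:
                bp = bucket or BucketParams.from_soil(soil_row)
                red = bucket_drought_stress(wx, bp, win)
                wx = wx.with_column("transp_reduction", red)
            env_cache[env] = summarize_windows(wx, win)
        row: dict[str, float] = {}
        for name, src in CROP_COLUMNS.items():
            row[name] = float(obs[src])
        for name in SOIL_COLUMNS:
            row[name] = float(soil.loc[obs["site_id"], name])
        row.update(env_cache[env])
        row["N.fert"] = 1.0 if obs["treatment"] == "n_fert" else 0.0
        row["Reinoc"] = 1.0 if obs["treatment"] == "reinoculation" else 0.0
        rows.append(row)

    df = pd.DataFrame(rows)
    groups: dict[str, str] = {}
    windows_tag: dict[str, str] = {}
    for c in df.columns:
        if c in CROP_COLUMNS:
            groups[c] = "Crop"
        elif c in SOIL_COLUMNS:
            groups[c] = "Soil"
        elif c in ("N.fert", "Reinoc"):
            groups[c] = "Management"
        else:
            groups[c] = "Weather"
        windows_tag[c] = c.rsplit(".", 1)[1] if c[-2:] in (".v", ".r", ".s") else "none"
    return FeatureTable(
        df,
        col_groups=groups,
        col_windows=windows_tag,
        binary_cols=("N.fert", "Reinoc"),
    )
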