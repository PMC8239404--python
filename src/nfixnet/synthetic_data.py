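"""Synthetic multi-environment soybean trial generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: ~11
sites x 2 years of environment x treatment observations (95 by default),
site-level random intercepts, environmental covariables spanning realistic
field envelopes, induced cross-correlations (texture fractions, SOM with
its mineralization index, humidity with temperature, ET0 with VPD) so the
correlation pre-filter has real work to do, sparse true coefficient
vectors on the standardized covariable scale, and Gaussian residual noise.

Stand-ins replace the external crop/soil models a field study would use:
phenology stage boundaries are fixed fractions of season length, the
weather generator is a first-order wet/dry precipitation chain plus
seasonal-sinusoid temperature and radiation with season totals drawn inside
the observed envelopes, and drought stress comes from the package's own
single-bucket water balance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .containers import DailyWeatherSeries, PhenologyWindows, FeatureTable

__all__ = [
    "SOIL_RANGES",
    "SiteProfile",
    "GroundTruth",
    "SyntheticTrial",
    "TrialConfig",
    "WeatherParams",
    "gen_sites",
    "gen_weather",
    "gen_phenology",
    "gen_trial",
    "default_truths",
    "write_inputs",
]

log = logging.getLogger(__name__)

#: Observed [min, max] envelopes of the soil covariables (units as in the
#: engineered table: CEC cmolc dm-3, N.NO3 and S.SO4 mg dm-3, texture %,
#: SOM g kg-1, OMM fraction).
SOIL_RANGES: dict[str, tuple[float, float]] = {
    "CEC": (3.0, 27.0),
    "Clay": (7.0, 31.0),
    "N.NO3": (1.0, 10.6),
    "OMM": (0.01, 0.07),
    "pH": (5.6, 7.1),
    "Sand": (9.0, 50.0),
    "Silt": (34.0, 63.0),
    "S.SO4": (0.9, 21.3),
    "SOM": (6.4, 48.0),
}


@dataclass(frozen=True)
class SiteProfile:
    """One research site: identifiers, soil chemistry/texture, and an
    ordinal latitude band that shifts the site's mean temperature."""

    site_id: str
    soil: dict[str, float]
    latitude_band: int


@dataclass(frozen=True)
class GroundTruth:
    """True generative parameters for one response.

    ``beta`` maps covariable name -> coefficient on the standardized scale
    (binary indicators keep their 0/1 presence scale); covariables absent
    from the mapping are exactly zero.  ``mu`` is the grand mean in response
    units.
    """

    beta: dict[str, float]
    sigma2_site: float
    sigma2_res: float
    mu: float

    def __post_init__(self):
        if self.sigma2_site < 0 or self.sigma2_res <= 0:
            raise ValueError("need sigma2_site >= 0 and sigma2_res > 0")

    @property
    def active_set(self) -> list[str]:
        return [k for k, v in self.beta.items() if v != 0.0]

    def vector(self, names: Sequence[str]) -> np.ndarray:
        missing = [k for k in self.beta if k not in names]
        if missing:
            raise ValueError(
                f"truth references covariables absent from the configured set: "
                f"{missing}; available: {list(names)}"
            )
        return np.array([self.beta.get(n, 0.0) for n in names])


@dataclass
class WeatherParams:
    """Tunable weather-generator parameters (defaults emulate the observed
    season envelopes of a US Midwest/Mid-South soybean network)."""

    tmean_base: float = 22.9        # C, network-mean season temperature
    tmean_site_spread: float = 1.0  # C, latitude-band half-range
    tmean_year_sd: float = 0.25     # C, year-to-year shift
    tmean_season_amp: float = 1.5   # C, within-season sinusoid amplitude
    tmean_daily_sd: float = 1.2     # C, AR(1) innovation sd
    tmean_ar: float = 0.6
    tamp_mean: float = 11.0         # C, diurnal amplitude
    tamp_season_sd: float = 0.3
    tamp_daily_sd: float = 0.7
    tmean_block_sd: float = 1.0     # C, ~12-day spell-scale variation
    vpd_mean: float = 0.84          # kPa, season target mean
    vpd_sd: float = 0.042
    rh_daily_sd: float = 3.0        # %, day-to-day humidity jitter
    rh_block_sd: float = 4.0        # %, spell-scale humidity variation
    block_days: int = 12
    p_wet_dry: float = 0.28         # P(wet | dry)
    p_wet_wet: float = 0.43         # P(wet | wet)
    rain_shape: float = 0.65        # gamma shape of wet-day amounts
    prec_total_mean: float = 438.0  # mm at the reference season length
    prec_total_sd: float = 90.0
    prec_total_range: tuple[float, float] = (190.0, 780.0)
    rad_total_mean: float = 2186.0  # MJ m-2 at the reference length
    rad_total_sd: float = 110.0
    rad_total_range: tuple[float, float] = (1700.0, 2580.0)
    et0_total_mean: float = 440.0   # mm at the reference length
    et0_total_sd: float = 25.0
    et0_total_range: tuple[float, float] = (345.0, 595.0)
    ref_season_days: int = 98


@dataclass
class TrialConfig:
    """Configuration of :func:`gen_trial` (defaults are the study design:
    11 sites x 2 years, 95 environment x treatment observations)."""

    n_sites: int = 11
    years: tuple[int, ...] = (2018, 2019)
    n_obs: int = 95
    soil_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SOIL_RANGES)
    )
    weather: WeatherParams = field(default_factory=WeatherParams)
    sowing_range: tuple[int, int] = (126, 177)
    mg_range: tuple[float, float] = (1.0, 4.6)
    s_phe_range: tuple[float, float] = (1.3, 1.9)
    season_days_range: tuple[int, int] = (75, 112)
    season_days_sd: float = 3.0
    reinoculation_every: int = 5   # every k-th environment also has reinoculation
    emergence_days: int = 8


def _check_ranges(config: Mapping[str, tuple[float, float]]) -> None:
    for name, (lo, hi) in config.items():
        if lo > hi:
            raise ValueError(f"invalid range for {name!r}: min {lo} > max {hi}")


def gen_sites(
    n_sites: int,
    config: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[SiteProfile]:
    """Draw site soil profiles inside the configured envelopes.

    Texture is drawn as (sand, clay) with silt the closure to 100%,
    rejection-sampled until silt is inside its own envelope, so the three
    fractions sum to 100 exactly and each stays within range.  The
    organic-matter mineralization index (OMM) is tied to SOM (plus noise) to
    induce the collinearity the correlation filter must resolve.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    ranges = dict(SOIL_RANGES)
    if config:
        ranges.update(config)
    _check_ranges(ranges)
    rng = np.random.default_rng(seed)
    sites = []
    for k in range(n_sites):
        soil: dict[str, float] = {}
        for name in ("CEC", "N.NO3", "pH", "S.SO4", "SOM"):
            lo, hi = ranges[name]
            soil[name] = float(rng.uniform(lo, hi))
        # OMM follows SOM with noise, clipped into its envelope
        lo_o, hi_o = ranges["OMM"]
        lo_s, hi_s = ranges["SOM"]
        frac = 0.0 if hi_s == lo_s else (soil["SOM"] - lo_s) / (hi_s - lo_s)
        omm = lo_o + frac * (hi_o - lo_o) + rng.normal(0.0, 0.05 * (hi_o - lo_o))
        soil["OMM"] = float(min(max(omm, lo_o), hi_o))
        # texture closure with rejection on silt
        lo_sa, hi_sa = ranges["Sand"]
        lo_cl, hi_cl = ranges["Clay"]
        lo_si, hi_si = ranges["Silt"]
        # clay concentrated near mid-range: the 100% closure then plays out
        # almost entirely as a sand-silt trade-off (strong negative r)
        clay_mid = 0.5 * (lo_cl + hi_cl)
        clay_sd = 0.15 * (hi_cl - lo_cl)
        for attempt in range(10000):
            sand = rng.uniform(lo_sa, hi_sa)
            clay = min(max(rng.normal(clay_mid, clay_sd), lo_cl), hi_cl)
            silt = 100.0 - sand - clay
            if lo_si - 1e-9 <= silt <= hi_si + 1e-9:
                break
        else:
            raise ValueError(
                "texture ranges admit no composition summing to 100 "
                f"(Sand {ranges['Sand']}, Silt {ranges['Silt']}, Clay {ranges['Clay']})"
            )
        soil["Sand"], soil["Silt"], soil["Clay"] = float(sand), float(silt), float(clay)
        sites.append(SiteProfile(site_id=f"S{k+1:02d}", soil=soil, latitude_band=k))
    return sites


def _site_temp_offset(site: SiteProfile, n_bands: int, spread: float) -> float:
    if n_bands <= 1:
        return 0.0
    mid = (n_bands - 1) / 2.0
    return spread * (mid - site.latitude_band) / mid


def _truncnorm(rng, mean, sd, lo, hi):
    return float(min(max(rng.normal(mean, sd), lo), hi))


def gen_weather(
    site: SiteProfile,
    season_days: int = 98,
    seed: int = 0,
    params: WeatherParams | None = None,
    start_doy: int | None = None,
    n_days: int | None = None,
    n_bands: int = 11,
) -> DailyWeatherSeries:
    """Generate one daily weather series.

    ``season_days`` is the calibration length: season totals of rain,
    radiation, and reference ET are drawn from envelope-truncated normals
    whose means scale with it, then the daily patterns (Markov wet/dry rain,
    sinusoid-plus-AR temperature and radiation) are rescaled to the drawn
    totals; relative humidity is set so the season-mean VPD matches a drawn
    target.  ``n_days`` (default ``season_days``) allows a longer series
    than the calibration season, at the same daily rates.
    """
    if season_days <= 0:
        raise ValueError("season_days must be positive")
    p = params or WeatherParams()
    rng = np.random.default_rng(seed)
    nd = int(n_days or season_days)
    doy0 = int(start_doy) if start_doy is not None else 140
    doy = np.arange(doy0, doy0 + nd)
    sfrac = nd / season_days  # totals scale for a longer-than-season series

    def block_noise(sd: float) -> np.ndarray:
        """Centered multi-day spell-scale variation: decorrelates phenology
        windows within a season without moving the season aggregate."""
        nb = max(1, math.ceil(nd / p.block_days))
        b = np.repeat(rng.normal(0.0, sd, nb), p.block_days)[:nd]
        return b - b.mean()

    # -- temperature
    base = (
        p.tmean_base
        + _site_temp_offset(site, n_bands, p.tmean_site_spread)
        + rng.normal(0.0, p.tmean_year_sd)
    )
    t = np.arange(nd)
    sinus = p.tmean_season_amp * np.sin(math.pi * (t + 0.5) / nd)
    ar = np.empty(nd)
    eps = rng.normal(0.0, p.tmean_daily_sd, nd)
    prev = 0.0
    for i in range(nd):
        prev = p.tmean_ar * prev + eps[i]
        ar[i] = prev
    ar -= ar.mean()
    tmean = base + sinus - sinus.mean() + ar + block_noise(p.tmean_block_sd)
    amp_level = rng.normal(p.tamp_mean, p.tamp_season_sd)
    amp = np.clip(rng.normal(amp_level, p.tamp_daily_sd, nd), 6.0, 16.0)
    tmax = tmean + amp / 2.0
    tmin = tmean - amp / 2.0

    # -- precipitation: first-order wet/dry chain conditioned on its wet-day
    #    count (keeps dry-spell clustering while stabilizing rain evenness),
    #    gamma amounts, season total rescaled to an envelope-truncated draw
    pw = p.p_wet_dry / max(p.p_wet_dry + (1.0 - p.p_wet_wet), 1e-12)
    k_target = pw * nd
    wet = np.zeros(nd, dtype=bool)
    for _ in range(60):
        wet[0] = rng.random() < pw
        for i in range(1, nd):
            pr = p.p_wet_wet if wet[i - 1] else p.p_wet_dry
            wet[i] = rng.random() < pr
        if abs(wet.sum() - k_target) <= 4 or pw == 0.0:
            break
    amounts = np.minimum(rng.gamma(p.rain_shape, 10.0, nd), 50.0)
    precip = np.where(wet, amounts, 0.0)
    raw_total = precip.sum()
    len_scale = 0.4 + 0.6 * season_days / p.ref_season_days
    if raw_total > 0:
        target = _truncnorm(
            rng, p.prec_total_mean * len_scale, p.prec_total_sd,
            *p.prec_total_range,
        ) * sfrac
        precip *= target / raw_total

    # -- radiation: seasonal sinusoid + noise, total rescale
    rad_shape = (
        1.0 + 0.15 * np.sin(math.pi * (t + 0.5) / nd)
        + rng.normal(0, 0.08, nd) + block_noise(0.10)
    )
    rad_shape = np.clip(rad_shape, 0.3, None)
    rad_scale = 0.60 + 0.40 * season_days / p.ref_season_days
    rad_target = _truncnorm(
        rng, p.rad_total_mean * rad_scale, p.rad_total_sd, *p.rad_total_range
    ) * sfrac
    radiation = rad_shape * rad_target / rad_shape.sum()

    # -- humidity set so season-mean VPD hits a drawn target
    es = 0.5 * (
        feat.saturation_vapor_pressure(tmin) + feat.saturation_vapor_pressure(tmax)
    )
    vpd_target = _truncnorm(rng, p.vpd_mean, p.vpd_sd, 0.66, 1.06)
    rh = (
        100.0 * (1.0 - vpd_target / es)
        + rng.normal(0.0, p.rh_daily_sd, nd)
        + block_noise(p.rh_block_sd)
    )
    rh = np.clip(rh, 20.0, 98.0)
    vpd = es * (1.0 - rh / 100.0)

    # -- reference ET: daily shape follows radiation and VPD; the season
    #    total tracks the drawn VPD and radiation levels, inducing the
    #    ET0-VPD collinearity seen in field data
    et_shape = np.clip(
        0.6 * radiation / max(radiation.mean(), 1e-9)
        + 0.4 * vpd / max(vpd.mean(), 1e-9)
        + rng.normal(0, 0.05, nd),
        0.05,
        None,
    )
    et_scale = 0.60 + 0.40 * season_days / p.ref_season_days
    vpd_season = float(vpd.mean())
    et_mean = (
        p.et0_total_mean
        * et_scale
        * (vpd_season / p.vpd_mean) ** 0.8
        * (rad_target / sfrac / (p.rad_total_mean * rad_scale)) ** 0.5
    )
    et_target = _truncnorm(rng, et_mean, p.et0_total_sd, *p.et0_total_range) * sfrac
    et0 = et_shape * et_target / et_shape.sum()

    return DailyWeatherSeries(
        pd.DataFrame(
            {
                "doy": doy,
                "tmin": tmin,
                "tmax": tmax,
                "precip": precip,
                "radiation": radiation,
                "et0": et0,
                "rh_mean": rh,
            }
        )
    )


#: default stage-boundary fractions of season length (VE -> R7)
STAGE_FRACTIONS = {"R1": 0.40, "R4": 0.60, "R5": 0.65}


def mg_season_days(maturity_group: float) -> int:
    """Stand-in season length (days VE to R7) as a linear map of maturity
    group onto the observed 75-112 day envelope."""
    return int(round(min(max(70.0 + 9.2 * maturity_group, 75), 112)))


def gen_phenology(
    sowing_doy: int,
    maturity_group: float,
    season_days: int | None = None,
    fractions: Mapping[str, float] | None = None,
    emergence_days: int = 8,
) -> PhenologyWindows:
    """Stage boundaries as fixed fractions of season length.

    ``season_days=None`` derives the length from the maturity group, so a
    longer-maturing cultivar reaches R7 later from the same sowing day.
    """
    if not (1 <= sowing_doy <= 365):
        raise ValueError("sowing_doy must lie in [1, 365]")
    if not (1.0 <= maturity_group <= 4.6):
        raise ValueError("maturity_group must lie in [1.0, 4.6]")
    fr = dict(STAGE_FRACTIONS)
    if fractions:
        fr.update(fractions)
    if not (0 < fr["R1"] < fr["R4"] <= fr["R5"] < 1):
        raise ValueError("stage fractions must satisfy 0 < R1 < R4 <= R5 < 1")
    S = int(season_days) if season_days is not None else mg_season_days(maturity_group)
    if S < 4:
        raise ValueError("season_days must be at least 4")
    VE = int(sowing_doy) + int(emergence_days)
    R7 = VE + S
    R1 = VE + max(1, round(fr["R1"] * S))
    R4 = max(R1 + 1, VE + round(fr["R4"] * S))
    R5 = max(R4, VE + round(fr["R5"] * S))
    R5 = min(R5, R7 - 1)
    R4 = min(R4, R5)
    return PhenologyWindows(VE=VE, R1=R1, R4=R4, R5=R5, R7=R7)


def default_truths() -> dict[str, GroundTruth]:
    """Ground truth of the default study conditions, one per response.

    RAU (%): an N-fertilization penalty of ~4 points plus drivers of a
    common effect-size scale (about one residual sd each) spread across the
    design strata — management (N.fert), sowing window (Sowing), soil
    fertility (CEC, the only site-level active: with 11 sites, several
    correlated site-level actives would not be separately estimable), and
    early-reproductive weather (VPD.r negative, Prec.r negative); site
    variance 4, residual sd 3.
    """
    return {
        "rau": GroundTruth(
            beta={
                "N.fert": -4.0,
                "VPD.r": -3.2,
                "Prec.r": -2.8,
                "CEC": 3.2,
                "Sowing": 2.8,
            },
            sigma2_site=4.0,
            sigma2_res=9.0,
            mu=84.0,
        ),
        "yield": GroundTruth(
            beta={
                "Sowing": -0.25,
                "VPD.r": -0.15,
                "S.SO4": 0.12,
                "N.fert": 0.15,
                "Rad.s": 0.15,
            },
            sigma2_site=0.04,
            sigma2_res=0.0625,
            mu=4.0,
        ),
        "protein": GroundTruth(
            beta={
                "S.SO4": 6.0,
                "S.Length": 5.0,
                "VPD.r": -4.0,
                "N.fert": 4.0,
                "Tmean.s": 3.0,
            },
            sigma2_site=16.0,
            sigma2_res=25.0,
            mu=398.0,
        ),
    }


@dataclass
class SyntheticTrial:
    """A generated dataset plus everything needed to score recovery."""

    observations: pd.DataFrame
    weather: dict[tuple, DailyWeatherSeries]
    phenology: dict[str, PhenologyWindows]
    truth: dict[str, GroundTruth]
    seed: int
    feature_table: FeatureTable
    sites: list[SiteProfile]
    clip_log: list[dict] = field(default_factory=list)

    @property
    def soil_table(self) -> pd.DataFrame:
        rows = [{"site_id": s.site_id, **s.soil} for s in self.sites]
        return pd.DataFrame(rows)


def gen_trial(
    config: TrialConfig | None = None,
    truth: GroundTruth | Mapping[str, GroundTruth] | None = None,
    seed: int = 0,
) -> SyntheticTrial:
    """Generate a full multi-environment trial with known ground truth.

    Responses are built as ``y = mu + X_std beta_true + u_site + eps`` with
    ``X_std`` the standardized engineered features (binary indicators
    centered only), ``u_site ~ N(0, sigma2_site)`` and
    ``eps ~ N(0, sigma2_res)``.  RAU is clipped to [0, 100]; every clip is
    recorded in ``clip_log`` (and logged), not silently absorbed.
    """
    cfg = config or TrialConfig()
    truths = dict(default_truths())
    if isinstance(truth, GroundTruth):
        truths["rau"] = truth
    elif truth is not None:
        truths.update(truth)
    rng = np.random.default_rng(seed)

    sites = gen_sites(cfg.n_sites, cfg.soil_ranges, seed=int(rng.integers(2**31)))
    site_years = [(s, y) for s in sites for y in cfg.years]

    # -- environment x treatment plan (deterministic given config)
    plan: list[dict] = []
    env_meta: dict[str, dict] = {}
    e = 0
    while len(plan) < cfg.n_obs:
        site, year = site_years[e % len(site_years)]
        env_id = f"{site.site_id}-{year}-E{e:03d}"
        sowing = int(rng.integers(cfg.sowing_range[0], cfg.sowing_range[1] + 1))
        mg = float(np.round(rng.uniform(*cfg.mg_range), 1))
        S = int(
            np.clip(
                round(mg_season_days(mg) + rng.normal(0, cfg.season_days_sd)),
                cfg.season_days_range[0],
                cfg.season_days_range[1],
            )
        )
        s_phe = float(np.round(rng.uniform(*cfg.s_phe_range), 2))
        windows = gen_phenology(sowing, mg, S, emergence_days=cfg.emergence_days)
        env_meta[env_id] = {
            "site": site,
            "year": year,
            "sowing": sowing,
            "mg": mg,
            "season_days": S,
            "s_phe": s_phe,
            "windows": windows,
        }
        treatments = ["control", "n_fert"]
        if cfg.reinoculation_every and e % cfg.reinoculation_every == 0:
            treatments.append("reinoculation")
        for tr in treatments:
            if len(plan) < cfg.n_obs:
                plan.append({"env_id": env_id, "treatment": tr})
        e += 1

    used_envs = {row["env_id"] for row in plan}
    env_meta = {k: v for k, v in env_meta.items() if k in used_envs}

    # -- one weather series per site-year spanning its environments
    weather: dict[tuple, DailyWeatherSeries] = {}
    by_sy: dict[tuple, list[dict]] = {}
    for m in env_meta.values():
        by_sy.setdefault((m["site"].site_id, m["year"]), []).append(m)
    for (sid, year), metas in by_sy.items():
        start = min(m["windows"].VE for m in metas) - 2
        end = max(m["windows"].R7 for m in metas) + 2
        calib = int(round(np.mean([m["season_days"] for m in metas])))
        site = metas[0]["site"]
        weather[(sid, year)] = gen_weather(
            site,
            season_days=calib,
            seed=int(rng.integers(2**31)),
            params=cfg.weather,
            start_doy=start,
            n_days=end - start + 1,
            n_bands=cfg.n_sites,
        )

    # -- raw trial table (responses filled after feature engineering)
    rows = []
    for row in plan:
        m = env_meta[row["env_id"]]
        rows.append(
            {
                "env_id": row["env_id"],
                "site_id": m["site"].site_id,
                "year": m["year"],
                "sowing_doy": m["sowing"],
                "maturity_group": m["mg"],
                "season_days": m["season_days"],
                "s_phe": m["s_phe"],
                "treatment": row["treatment"],
                "ureide": np.nan,
                "nitrate": np.nan,
                "rau": np.nan,
                "yield_mg_ha": np.nan,
                "protein_g_kg": np.nan,
            }
        )
    trial = pd.DataFrame(rows)
    soil_df = pd.DataFrame([{"site_id": s.site_id, **s.soil} for s in sites])
    phen = {k: v["windows"] for k, v in env_meta.items()}

    table = feat.build_feature_table(trial, weather, phen, soil_df)
    table, constant = feat.drop_constant_columns(table)
    if constant:
        log.info("dropped constant covariables: %s", constant)
    table_std = feat.standardize(table)
    names = table_std.columns
    X = table_std.matrix()

    site_codes = trial["site_id"].to_numpy()
    uniq_sites = [s.site_id for s in sites if s.site_id in set(site_codes)]
    clip_log: list[dict] = []
    for resp, gt in truths.items():
        beta = gt.vector(names)
        u = {s: rng.normal(0.0, math.sqrt(gt.sigma2_site)) for s in uniq_sites}
        eps = rng.normal(0.0, math.sqrt(gt.sigma2_res), len(trial))
        y = gt.mu + X @ beta + np.array([u[s] for s in site_codes]) + eps
        if resp == "rau":
            n_hi = int((y > 100).sum())
            n_lo = int((y < 0).sum())
            if n_hi or n_lo:
                clip_log.append({"response": resp, "below_0": n_lo, "above_100": n_hi})
                log.info("RAU clipped: %d above 100, %d below 0", n_hi, n_lo)
            y = np.clip(y, 0.0, 100.0)
            trial["rau"] = y
            # back out assay concentrations consistent with RAU
            nitrate = rng.lognormal(math.log(5.0), 0.4, len(trial))
            safe = np.clip(y, 1e-6, 99.9)
            ureide = nitrate * safe / (4.0 * (100.0 - safe))
            at_top = y >= 99.95
            nitrate[at_top] = 0.0
            ureide[at_top] = 20.0
            trial["nitrate"] = nitrate
            trial["ureide"] = ureide
        elif resp == "yield":
            trial["yield_mg_ha"] = y
        elif resp == "protein":
            trial["protein_g_kg"] = y

    return SyntheticTrial(
        observations=trial,
        weather=weather,
        phenology=phen,
        truth=truths,
        seed=seed,
        feature_table=table,
        sites=sites,
        clip_log=clip_log,
    )


_DATA_DICTIONARY = """\
# Data dictionary

## trial.csv (one row per environment x treatment observation)
- env_id: environment identifier (site-year-variant)
- site_id: research-site identifier (random-intercept group)
- year: growing season
- sowing_doy: sowing date, day of year
- maturity_group: cultivar maturity group (1.0-4.6)
- season_days: emergence (VE) to physiological maturity (R7), days
- s_phe: relative phenological stage at stem sampling (1.3-1.9)
- treatment: control | n_fert | reinoculation
- ureide, nitrate: stem concentrations, umol g-1
- rau: relative abundance of ureides, % (response)
- yield_mg_ha: seed yield, Mg ha-1 at 130 g kg-1 moisture (response)
- protein_g_kg: seed protein, g kg-1 dry basis (response)

## weather.csv (one row per site-year-day)
- site_id, year, doy
- tmin, tmax: daily air temperature, C
- precip: daily precipitation, mm
- radiation: daily solar radiation, MJ m-2
- et0: daily reference evapotranspiration, mm
- rh_mean: daily mean relative humidity, %

## soil.csv (one row per site; 0-0.15 m depth)
- CEC: cation exchange capacity, cmolc dm-3
- Clay, Sand, Silt: texture fractions, % (sum to 100)
- N.NO3: pre-sowing nitrate-N, mg dm-3
- S.SO4: pre-sowing sulfate-S, mg dm-3
- OMM: organic-matter mineralization index, fraction
- pH: soil pH
- SOM: soil organic matter, g kg-1

## truth.json
Per response: mu (grand mean), beta (nonzero standardized-scale
coefficients), sigma2_site, sigma2_res.
"""


def write_inputs(trial: SyntheticTrial, outdir) -> dict[str, str]:
    """Write the three input CSVs, the ground-truth JSON, the data
    dictionary, and a YAML seed/config stamp.  Returns the path map."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    trial.observations.to_csv(out / "trial.csv", index=False)
    paths["trial"] = str(out / "trial.csv")
    wx_rows = []
    for (sid, year), series in trial.weather.items():
        df = series.df.copy()
        df.insert(0, "site_id", sid)
        df.insert(1, "year", year)
        wx_rows.append(df)
    pd.concat(wx_rows, ignore_index=True).to_csv(out / "weather.csv", index=False)
    paths["weather"] = str(out / "weather.csv")
    trial.soil_table.to_csv(out / "soil.csv", index=False)
    paths["soil"] = str(out / "soil.csv")
    truth_payload = {
        resp: {
            "mu": gt.mu,
            "beta": gt.beta,
            "sigma2_site": gt.sigma2_site,
            "sigma2_res": gt.sigma2_res,
        }
        for resp, gt in trial.truth.items()
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    paths["truth"] = str(out / "truth.json")
    (out / "data_dictionary.md").write_text(_DATA_DICTIONARY)
    paths["data_dictionary"] = str(out / "data_dictionary.md")
    phen_payload = {
        env: dataclasses.asdict(w) for env, w in trial.phenology.items()
    }
    (out / "phenology.json").write_text(json.dumps(phen_payload, indent=2))
    paths["phenology"] = str(out / "phenology.json")
    (out / "config.yaml").write_text(
        yaml.safe_dump({"seed": trial.seed, "n_obs": len(trial.observations)})
    )
    paths["config"] = str(out / "config.yaml")
    return paths
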