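"""End-to-end orchestration: simulate -> features -> fit -> CV -> interpret.

For each requested response (RAU %, seed yield Mg ha-1, seed protein
g kg-1) the pipeline produces the null/full/reduced model summaries (metric
and variance-component medians with CV spreads), the coefficient-importance
cluster table, the reduced-model coefficients, and segmented-mean partial-
dependence tables — all as CSV, plus a machine-readable run manifest.  RAU
enters the yield and protein models as a covariable; its own model uses
environmental covariables only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import features as feat
from . import interpretation as interp
from . import model_selection as ms
from . import synthetic_data as sd
from .containers import DailyWeatherSeries, FeatureTable, PhenologyWindows, TRIAL_COLUMNS
from .penlmm import PenaltySpec, fit_enet_lmm

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "load_inputs",
           "run_full_analysis"]

log = logging.getLogger(__name__)

RESPONSE_COLUMNS = {"rau": "rau", "yield": "yield_mg_ha", "protein": "protein_g_kg"}


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    responses: tuple[str, ...] = ("rau", "yield", "protein")
    outdir: str = "runs/latest"
    seed: int = 0
    # either paths to the three input CSVs (+ phenology json) ...
    trial_csv: str | None = None
    weather_csv: str | None = None
    soil_csv: str | None = None
    phenology_json: str | None = None
    # ... or a synthetic-trial configuration
    synthetic: bool = True
    trial_config: sd.TrialConfig = field(default_factory=sd.TrialConfig)
    cv: ms.CVConfig = field(default_factory=ms.CVConfig)
    n_pdp_intervals: int = 7
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = [r for r in self.responses if r not in RESPONSE_COLUMNS]
        if unknown:
            raise ValueError(f"unknown responses {unknown}; "
                             f"choose from {sorted(RESPONSE_COLUMNS)}")
        if not self.synthetic:
            for name in ("trial_csv", "weather_csv", "soil_csv", "phenology_json"):
                p = getattr(self, name)
                if p is None or not pathlib.Path(p).exists():
                    raise ValueError(f"input path {name} missing or nonexistent: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        if "cv" in raw:
            raw["cv"] = ms.CVConfig(**raw["cv"])
        if "trial_config" in raw:
            raw["trial_config"] = sd.TrialConfig(**raw["trial_config"])
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    trial: pd.DataFrame, weather_long: pd.DataFrame, soil: pd.DataFrame
) -> ValidationReport:
    """Schema, range, and calendar checks on the three input tables.

    Hard errors: missing mandatory columns, RAU outside [0, 100],
    ``tmin > tmax``, negative fluxes, calendar gaps.  Warnings: texture sums
    off 100 by up to 0.5 (auto-renormalized downstream).
    """
    rep = ValidationReport()
    for col in TRIAL_COLUMNS:
        if col not in trial.columns:
            rep.errors.append(f"trial table is missing column {col!r}")
    if "rau" in trial.columns:
        bad = trial["rau"].dropna()
        bad = bad[(bad < 0) | (bad > 100)]
        if len(bad):
            rep.errors.append(
                f"RAU outside [0, 100] for {len(bad)} rows (e.g. {bad.iloc[0]:.2f})"
            )
    for col in ("site_id", "year", "doy", "tmin", "tmax", "precip", "radiation", "et0"):
        if col not in weather_long.columns:
            rep.errors.append(f"weather table is missing column {col!r}")
    if rep.errors:
        return rep
    bad = weather_long[weather_long["tmin"] > weather_long["tmax"] + 1e-9]
    if len(bad):
        row = bad.iloc[0]
        rep.errors.append(
            f"tmin > tmax on doy {int(row['doy'])} "
            f"({row['site_id']}, {int(row['year'])})"
        )
    for col in ("precip", "radiation", "et0"):
        if (weather_long[col] < -1e-9).any():
            rep.errors.append(f"negative values in weather column {col!r}")
    for (sid, year), g in weather_long.groupby(["site_id", "year"]):
        doy = np.sort(g["doy"].to_numpy())
        if not np.all(np.diff(doy) == 1):
            rep.errors.append(f"weather calendar gap for site {sid}, year {year}")
    for col in ("Sand", "Silt", "Clay", "site_id"):
        if col not in soil.columns:
            rep.errors.append(f"soil table is missing column {col!r}")
    if not rep.errors:
        total = soil["Sand"] + soil["Silt"] + soil["Clay"]
        off = (total - 100).abs()
        if (off > 0.5).any():
            rep.errors.append(
                "texture fractions deviate from 100% by more than 0.5 for sites "
                f"{list(soil.loc[off > 0.5, 'site_id'])}"
            )
        elif (off > 1e-9).any():
            rep.warnings.append(
                "texture fractions off 100% by <= 0.5; renormalized"
            )
    return rep


def load_inputs(cfg: RunConfig):
    """Read (or simulate) the trial/weather/soil/phenology inputs."""
    if cfg.synthetic:
        trial_obj = sd.gen_trial(cfg.trial_config, seed=cfg.seed)
        weather_long = []
        for (sid, year), series in trial_obj.weather.items():
            df = series.df.copy()
            df.insert(0, "site_id", sid)
            df.insert(1, "year", year)
            weather_long.append(df)
        return (
            trial_obj.observations,
            pd.concat(weather_long, ignore_index=True),
            trial_obj.soil_table,
            trial_obj.phenology,
            trial_obj,
        )
    trial = pd.read_csv(cfg.trial_csv)
    weather_long = pd.read_csv(cfg.weather_csv)
    soil = pd.read_csv(cfg.soil_csv)
    phen_raw = json.loads(pathlib.Path(cfg.phenology_json).read_text())
    phen = {k: PhenologyWindows(**v) for k, v in phen_raw.items()}
    return trial, weather_long, soil, phen, None


def _weather_map(weather_long: pd.DataFrame) -> dict[tuple, DailyWeatherSeries]:
    out = {}
    for (sid, year), g in weather_long.groupby(["site_id", "year"]):
        out[(sid, year)] = DailyWeatherSeries(
            g.drop(columns=["site_id", "year"]).sort_values("doy")
        )
    return out


def _renormalize_texture(soil: pd.DataFrame) -> pd.DataFrame:
    soil = soil.copy()
    total = soil["Sand"] + soil["Silt"] + soil["Clay"]
    for col in ("Sand", "Silt", "Clay"):
        soil[col] = soil[col] * 100.0 / total
    return soil


def _table2_frame(results: Mapping[str, ms.CVResult]) -> pd.DataFrame:
    """Stack metric/variance medians (sd) for the null/full/reduced models."""
    rows = []
    for model, res in results.items():
        s = res.metric_summary
        row = {"model": model}
        for metric in ("MAE", "RMSE", "RRMSE", "R2", "sigma2_site", "sigma2_res"):
            row[metric] = s.loc["median", metric]
            row[f"{metric}_sd"] = s.loc["sd", metric]
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of output paths and objects."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = pathlib.Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    trial, weather_long, soil, phen, trial_obj = load_inputs(cfg)
    report = validate_inputs(trial, weather_long, soil)
    for w in report.warnings:
        log.warning("input validation: %s", w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))
    soil = _renormalize_texture(soil)
    weather = _weather_map(weather_long)

    stage = "feature engineering"
    try:
        table = feat.build_feature_table(trial, weather, phen, soil)
        table, constant = feat.drop_constant_columns(table)
        if constant:
            log.info("dropped constant covariables: %s", constant)
        table = feat.correlation_filter(
            table, keep_preference=feat.default_keep_preference(table.columns)
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    table.to_csv(out / "features.csv")
    (out / "feature_metadata.json").write_text(json.dumps(table.metadata(), indent=2))

    groups = trial["site_id"].to_numpy()
    artifacts: dict = {"features": table, "outdir": str(out), "responses": {}}
    for resp in cfg.responses:
        stage = f"response {resp}"
        y = trial[RESPONSE_COLUMNS[resp]].to_numpy(dtype=float)
        resp_table = table
        if resp in ("yield", "protein"):
            df = table.df.copy()
            df["RAU"] = trial["rau"].to_numpy(dtype=float)
            resp_table = table.copy_with(df)
            resp_table.col_groups["RAU"] = "Crop"
            resp_table.col_windows["RAU"] = "none"
        cv_cfg = ms.CVConfig(**{**cfg.cv.__dict__, "seed": cfg.seed})
        try:
            full = ms.nested_cv(resp_table, y, groups, cv_cfg)
            null = ms.nested_cv(None, y, groups, cv_cfg)
            clusters = interp.cluster_coefficients(full.coef_summary, seed=cfg.seed)
            subset = interp.select_reduced(clusters)
            red_fit, red_cv = interp.refit_reduced(
                resp_table, y, groups, subset, cv_cfg
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # "null" alone would round-trip as NaN through CSV readers
        table2 = _table2_frame(
            {"null_model": null, "full_model": full, "reduced_model": red_cv}
        )
        table2.insert(0, "response", resp)
        table2.to_csv(out / f"{resp}_model_summary.csv", index=False)

        fig3 = full.coef_summary.join(clusters.table[["cluster"]])
        fig3.index.name = "covariable"
        fig3.to_csv(out / f"{resp}_coefficient_clusters.csv")

        red_coefs = pd.DataFrame(
            {
                "covariable": red_fit.feature_names,
                "coefficient": red_fit.beta,
                "median_cv": red_cv.coef_summary["median"].reindex(
                    red_fit.feature_names
                ).to_numpy(),
                "min_cv": red_cv.coef_summary["min"].reindex(
                    red_fit.feature_names
                ).to_numpy(),
                "max_cv": red_cv.coef_summary["max"].reindex(
                    red_fit.feature_names
                ).to_numpy(),
            }
        )
        red_coefs.to_csv(out / f"{resp}_reduced_coefficients.csv", index=False)

        std_red = feat.standardize(resp_table.copy_with(resp_table.df[subset]))
        pdp_frames = []
        for cov in subset:
            try:
                pdp = interp.partial_dependence(
                    red_fit, std_red, cov, cfg.n_pdp_intervals
                )
            except ValueError as exc:
                log.warning("PDP skipped for %s: %s", cov, exc)
                continue
            frame = pdp.to_frame()
            center, scale = std_red.scaling[cov]
            frame["interval_left"] = frame["interval_left"] * scale + center
            frame["interval_right"] = frame["interval_right"] * scale + center
            pdp_frames.append(frame)
        if pdp_frames:
            pd.concat(pdp_frames, ignore_index=True).to_csv(
                out / f"{resp}_partial_dependence.csv", index=False
            )

        artifacts["responses"][resp] = {
            "full": full,
            "null": null,
            "clusters": clusters,
            "reduced_subset": subset,
            "reduced_fit": red_fit,
            "reduced_cv": red_cv,
        }

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "responses": list(cfg.responses),
        "synthetic": cfg.synthetic,
        "cv": cfg.cv.__dict__,
        "n_obs": int(len(trial)),
        "n_covariables": len(table.columns),
        "dropped_by_filter": [d.dropped for d in table.drop_log],
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "responses": list(cfg.responses),
                    "seed": cfg.seed,
                    "cv": cfg.cv.__dict__,
                    "trial": dataclasses.asdict(cfg.trial_config)
                    if cfg.synthetic
                    else None,
                },
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if cfg.synthetic and trial_obj is not None:
        sd.write_inputs(trial_obj, out / "inputs")
    artifacts["manifest"] = manifest
    return artifacts
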