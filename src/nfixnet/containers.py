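"""Shared data containers for trial, weather, phenology, and feature data.

The analysis moves between three tabular inputs (plot/environment trial
records, daily weather per site-year, and a soil table) and one derived
object, the :class:`FeatureTable`, which carries the standardized covariable
matrix together with the metadata needed to interpret penalized coefficients
(group/window tags, centering/scaling pairs, and the provenance of any
column dropped by the correlation pre-filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WEATHER_COLUMNS",
    "DailyWeatherSeries",
    "PhenologyWindows",
    "DropRecord",
    "FeatureTable",
    "TRIAL_COLUMNS",
    "TREATMENT_CLASSES",
]

#: Required columns of a daily weather frame. ``rh_mean`` (relative humidity,
#: %) and ``vpd`` (kPa) are alternatives: at least one must be present.
WEATHER_COLUMNS = ("doy", "tmin", "tmax", "precip", "radiation", "et0")

TREATMENT_CLASSES = ("control", "n_fert", "reinoculation")

#: Columns of the environment x treatment trial table.
TRIAL_COLUMNS = (
    "env_id",
    "site_id",
    "year",
    "sowing_doy",
    "maturity_group",
    "season_days",
    "s_phe",
    "treatment",
    "ureide",
    "nitrate",
    "rau",
    "yield_mg_ha",
    "protein_g_kg",
)


class DailyWeatherSeries:
    """Contiguous daily meteorology for one site-year (or one season).

    Parameters
    ----------
    df:
        Frame with columns ``doy, tmin, tmax, precip, radiation, et0`` and
        at least one of ``rh_mean`` (%) or ``vpd`` (kPa).  ``transp_reduction``
        (mm d-1, from the soil-water bucket) may be attached later.

    Raises
    ------
    ValueError
        on a missing column, a calendar gap, ``tmin > tmax``, or a negative
        flux value.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        for col in WEATHER_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"weather series is missing column {col!r}")
        if "rh_mean" not in df.columns and "vpd" not in df.columns:
            raise ValueError("weather series needs 'rh_mean' or 'vpd'")
        doy = df["doy"].to_numpy()
        if len(doy) == 0:
            raise ValueError("weather series is empty")
        if not np.all(np.diff(doy) == 1):
            raise ValueError("weather calendar is not contiguous daily")
        bad = df["tmin"].to_numpy() > df["tmax"].to_numpy() + 1e-12
        if bad.any():
            day = int(doy[np.argmax(bad)])
            raise ValueError(f"tmin > tmax on doy {day}")
        for col in ("precip", "radiation", "et0"):
            if (df[col].to_numpy() < -1e-12).any():
                raise ValueError(f"negative values in weather column {col!r}")
        if "transp_reduction" in df.columns:
            if (df["transp_reduction"].to_numpy() < -1e-12).any():
                raise ValueError("negative transp_reduction")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def start_doy(self) -> int:
        return int(self.df["doy"].iloc[0])

    @property
    def end_doy(self) -> int:
        return int(self.df["doy"].iloc[-1])

    def slice(self, start_doy: int, end_doy: int) -> "DailyWeatherSeries":
        """Sub-series for ``[start_doy, end_doy]`` (inclusive)."""
        if start_doy < self.start_doy or end_doy > self.end_doy:
            raise ValueError(
                f"requested window [{start_doy}, {end_doy}] outside weather "
                f"calendar [{self.start_doy}, {self.end_doy}]"
            )
        m = (self.df["doy"] >= start_doy) & (self.df["doy"] <= end_doy)
        return DailyWeatherSeries(self.df.loc[m])

    def with_column(self, name: str, values: np.ndarray) -> "DailyWeatherSeries":
        df = self.df.copy()
        df[name] = np.asarray(values, dtype=float)
        return DailyWeatherSeries(df)


@dataclass(frozen=True)
class PhenologyWindows:
    """Stage boundary dates (day-of-year) delimiting aggregation windows.

    VE = emergence, R1 = first flower, R4 = full pod, R5 = seed-filling
    onset, R7 = physiological maturity.  The three windows consumed by
    :func:`nfixnet.features.summarize_windows` are vegetative
    ``v = [VE, R1)``, pre-seed-filling ``r = [R1, R5)`` (days between R4 and
    R5 are assigned to ``r``), and seed filling ``s = [R5, R7]``.
    """

    VE: int
    R1: int
    R4: int
    R5: int
    R7: int

    def __post_init__(self):
        if not (self.VE < self.R1 < self.R4 <= self.R5 < self.R7):
            raise ValueError(
                "phenology stages must satisfy VE < R1 < R4 <= R5 < R7, got "
                f"{(self.VE, self.R1, self.R4, self.R5, self.R7)}"
            )

    @property
    def season_days(self) -> int:
        return self.R7 - self.VE

    def window_bounds(self, window: str) -> tuple[int, int]:
        """Inclusive day range of a window tag ``v``/``r``/``s``."""
        if window == "v":
            return self.VE, self.R1 - 1
        if window == "r":
            return self.R1, self.R5 - 1
        if window == "s":
            return self.R5, self.R7
        raise ValueError(f"unknown window tag {window!r}")


@dataclass(frozen=True)
class DropRecord:
    """One correlation-filter drop: ``dropped`` removed in favour of ``kept``."""

    dropped: str
    kept: str
    r: float
    p: float


class FeatureTable:
    """Covariable matrix plus column metadata, scaling, and drop provenance.

    ``col_groups`` maps column -> group tag (``Crop``/``Soil``/``Weather``/
    ``Management``), ``col_windows`` maps column -> window tag (``v``/``r``/
    ``s``/``none``).  ``binary_cols`` are presence/absence indicators
    (treatment dummies): they are centered but not variance-scaled by
    :func:`nfixnet.features.standardize` unless explicitly requested, so a
    coefficient keeps its "effect of presence" reading.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        col_groups: Mapping[str, str] | None = None,
        col_windows: Mapping[str, str] | None = None,
        binary_cols: Iterable[str] = (),
        scaling: Mapping[str, tuple[float, float]] | None = None,
        drop_log: Sequence[DropRecord] = (),
    ):
        self.df = df.reset_index(drop=True).copy()
        self.col_groups = dict(col_groups or {c: "Weather" for c in df.columns})
        self.col_windows = dict(col_windows or {c: "none" for c in df.columns})
        self.binary_cols = [c for c in binary_cols if c in self.df.columns]
        self.scaling = dict(scaling or {})
        self.drop_log = list(drop_log)

    # -- basic protocol ----------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def continuous_cols(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.binary_cols]

    def __len__(self) -> int:
        return len(self.df)

    def copy_with(self, df: pd.DataFrame, **overrides) -> "FeatureTable":
        kw = dict(
            col_groups={c: self.col_groups.get(c, "Weather") for c in df.columns},
            col_windows={c: self.col_windows.get(c, "none") for c in df.columns},
            binary_cols=[c for c in self.binary_cols if c in df.columns],
            scaling=self.scaling,
            drop_log=self.drop_log,
        )
        kw.update(overrides)
        return FeatureTable(df, **kw)

    def matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.columns
        return self.df[cols].to_numpy(dtype=float)

    # -- persistence -------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def metadata(self) -> dict:
        """JSON-serializable column metadata, scaling pairs, and drop log."""
        return {
            "col_groups": self.col_groups,
            "col_windows": self.col_windows,
            "binary_cols": list(self.binary_cols),
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "drop_log": [
                {"dropped": d.dropped, "kept": d.kept, "r": d.r, "p": d.p}
                for d in self.drop_log
            ],
        }
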