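"""Environmental covariates on a thermal-time grid.

Daily weather for one year-location ("environment") is cut into
consecutive growth stages of 100 growing degree-days (GDD), and within
each stage 17 climatic covariates describing temperature, radiation,
water balance and frost exposure are computed.  Together with
depth-resolved soil descriptors these form the environmental covariate
(EC) matrix ``W`` whose cross-product ``Omega = W W' / q`` acts as an
environmental relationship kernel between field plots: plots grown
under similar thermal-time weather trajectories receive high covariance
regardless of calendar alignment, which is what lets a reaction-norm
model borrow genotype-by-environment signal across years and sites.

GDD is the cumulative sum of daily average temperature truncated at
0 degrees C from the sowing date; it is the standard thermal-time proxy
for wheat development, so a 100-GDD window covers roughly the same
developmental span in an early warm spring and a late cold one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLIMATIC_EC_CODES",
    "SOIL_EC_CODES",
    "SOIL_DEPTHS",
    "LOW_RADIATION_MJ",
    "WeatherSeries",
    "compute_gdd",
    "assign_stages",
    "climatic_ec_values",
    "compute_stage_ecs",
    "compute_soil_ecs",
    "environment_covariates",
    "qc_ecs",
    "build_W",
    "build_omega",
]

#: The 17 per-stage climatic covariates, in canonical order.
CLIMATIC_EC_CODES = (
    "ave.glorad",   # mean daily global radiation (MJ/m2)
    "ave.temp",     # mean daily average temperature (degC)
    "ave.vpd",      # mean daily vapour pressure deficit (kPa)
    "cumglorad",    # accumulated global radiation (MJ/m2)
    "ratrdtmp",     # accumulated radiation per unit thermal time (MJ/m2 per degC day)
    "cumpospetp",   # accumulated positive daily precipitation - evaporation (mm)
    "cumnegpetp",   # accumulated negative daily precipitation - evaporation (mm)
    "cumpetp",      # accumulated total precipitation - evaporation (mm)
    "cumntdryd",    # number of dry days (precipitation <= evaporation)
    "cumnsti4",     # accumulated minimum temperature below -4 degC
    "cumndt0",      # number of days with minimum temperature below 0 degC
    "cumsti0",      # accumulated minimum temperature below 0 degC
    "cumprec",      # accumulated precipitation (mm)
    "cumvpd",       # accumulated vapour pressure deficit (kPa)
    "GDD",          # thermal sum of daily average temperature over 0 degC
    "ndi10m",       # number of low-radiation days (< 10.45 MJ/m2)
    "sri10m",       # accumulated radiation on low-radiation days (MJ/m2)
)

#: Depth-resolved soil covariates (7 variables x 4 depth layers = 28 columns).
SOIL_EC_CODES = (
    "pvt",       # plant available water (%)
    "claynor",   # clay content (%)
    "fsandno",   # fine sand content (%)
    "gsandno",   # coarse sand content (%)
    "siltnor",   # silt content (%)
    "kulstof",   # carbon content (%)
    "Ks_250",    # saturated hydraulic conductivity (%)
)

#: Soil depth layers in cm (top, bottom).
SOIL_DEPTHS = ((0, 30), (30, 60), (60, 100), (100, 200))

#: Low-radiation day threshold: 1,045 J/cm2 expressed in MJ/m2.
LOW_RADIATION_MJ = 10.45

_WEATHER_COLS = ("tmin", "tavg", "tmax", "precip", "evap", "glorad", "vpd")


@dataclass
class WeatherSeries:
    """Daily climate records for one year-location.

    Parameters
    ----------
    env_id : str
        Year-location label, e.g. ``"Skive_2014"``.
    records : pandas.DataFrame
        Indexed by daily ``DatetimeIndex``; columns among ``tmin``,
        ``tavg``, ``tmax`` (degC), ``precip``, ``evap`` (mm),
        ``glorad`` (MJ/m2), ``vpd`` (kPa).  Missing columns simply make
        the dependent ECs missing.
    sowing_date, season_end : datetime-like
        The thermal-time clock starts at sowing; the season is closed at
        a fixed calendar date (mid-August for Danish winter wheat)
        rather than a simulated maturity date.
    """

    env_id: str
    records: pd.DataFrame
    sowing_date: pd.Timestamp
    season_end: pd.Timestamp

    def __post_init__(self) -> None:
        self.sowing_date = pd.Timestamp(self.sowing_date)
        self.season_end = pd.Timestamp(self.season_end)
        self.records = self.records.sort_index()

    def validate(self) -> None:
        """Raise ``ValueError`` on violated invariants."""
        idx = self.records.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError(f"{self.env_id}: records must be indexed by date")
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError(f"{self.env_id}: dates must be strictly increasing and daily")
        if self.sowing_date >= self.season_end:
            raise ValueError(f"{self.env_id}: sowing_date must precede season_end")
        r = self.records
        if {"tmin", "tavg", "tmax"} <= set(r.columns):
            full = r[["tmin", "tavg", "tmax"]].dropna()
            if ((full["tmin"] > full["tavg"]) | (full["tavg"] > full["tmax"])).any():
                raise ValueError(f"{self.env_id}: tmin <= tavg <= tmax violated")
        for col in ("precip", "glorad"):
            if col in r.columns and (r[col].dropna() < 0).any():
                raise ValueError(f"{self.env_id}: {col} must be non-negative")


def compute_gdd(series: WeatherSeries) -> pd.Series:
    """Cumulative growing degree-days per day from sowing to season end.

    The daily increment is ``max(tavg, 0)``: days below freezing
    contribute nothing rather than subtracting thermal time.

    Raises
    ------
    ValueError
        If any day in the window is absent or has missing ``tavg``
        (the error names the first offending date).
    """
    series.validate()
    window = pd.date_range(series.sowing_date, series.season_end, freq="D")
    if "tavg" not in series.records.columns:
        raise ValueError(f"{series.env_id}: no tavg column")
    tavg = series.records["tavg"].reindex(window)
    missing = tavg.index[tavg.isna()]
    if len(missing):
        raise ValueError(
            f"{series.env_id}: missing tavg on {missing[0].date()} inside the season window"
        )
    gdd = tavg.clip(lower=0.0).cumsum()
    gdd.name = "gdd"
    return gdd


def assign_stages(gdd: pd.Series, stage_size: float = 100.0) -> pd.DataFrame:
    """Partition a cumulative GDD series into consecutive thermal stages.

    A stage closes on the first day whose within-stage accumulated GDD
    reaches ``stage_size``, so every complete stage accumulates at least
    ``stage_size`` and at most ``stage_size`` plus one day's increment.
    A trailing stage still open at season end is emitted with
    ``complete = False``.

    Returns
    -------
    pandas.DataFrame
        Columns ``stage`` (1-based), ``start_date``, ``end_date``,
        ``gdd_start``, ``gdd_end``, ``n_days``, ``complete``.
    """
    if len(gdd) == 0:
        raise ValueError("empty GDD series")
    if stage_size <= 0:
        raise ValueError("stage_size must be positive")
    values = np.asarray(gdd, dtype=float)
    if np.any(np.diff(values) < 0):
        raise ValueError("cumulative GDD must be non-decreasing")
    rows = []
    start = 0
    gdd_prev = 0.0
    stage = 1
    n = len(values)
    while start < n:
        # first day at which this stage's own accumulation reaches stage_size
        rel = values[start:] - gdd_prev
        hit = np.searchsorted(rel, stage_size, side="left")
        if hit == n - start:  # never reached: trailing incomplete stage
            end = n - 1
            complete = False
        else:
            end = start + hit
            complete = True
        rows.append(
            {
                "stage": stage,
                "start_date": gdd.index[start],
                "end_date": gdd.index[end],
                "gdd_start": gdd_prev,
                "gdd_end": values[end],
                "n_days": end - start + 1,
                "complete": complete,
            }
        )
        gdd_prev = values[end]
        start = end + 1
        stage += 1
    return pd.DataFrame(rows)


def _sum_strict(s: pd.Series) -> float:
    """Sum propagating NaN (a missing day makes the stage value missing)."""
    arr = np.asarray(s, dtype=float)
    if np.isnan(arr).any():
        return np.nan
    return float(arr.sum())


def _mean_strict(s: pd.Series) -> float:
    arr = np.asarray(s, dtype=float)
    if np.isnan(arr).any() or len(arr) == 0:
        return np.nan
    return float(arr.mean())


def climatic_ec_values(days: pd.DataFrame) -> dict[str, float]:
    """The 17 climatic ECs for one stage's window of daily records.

    Missing input *columns* yield ``NaN`` for the dependent codes;
    missing individual days likewise propagate to ``NaN`` rather than
    being treated as zero.  Quality control downstream decides whether
    a covariate survives.
    """
    if len(days) == 0:
        raise ValueError("stage with zero days")
    out: dict[str, float] = {code: np.nan for code in CLIMATIC_EC_CODES}

    def col(name: str) -> pd.Series | None:
        return days[name] if name in days.columns else None

    tavg, glorad, vpd = col("tavg"), col("glorad"), col("vpd")
    precip, evap = col("precip"), col("evap")
    tmin = col("tmin")
    if tmin is None:  # fall back on tavg for the frost covariates
        tmin = tavg

    if tavg is not None:
        out["ave.temp"] = _mean_strict(tavg)
        out["GDD"] = _sum_strict(tavg.clip(lower=0.0))
    if glorad is not None:
        out["ave.glorad"] = _mean_strict(glorad)
        out["cumglorad"] = _sum_strict(glorad)
        arr = np.asarray(glorad, dtype=float)
        if not np.isnan(arr).any():
            mask = arr < LOW_RADIATION_MJ
            out["ndi10m"] = float(mask.sum())
            out["sri10m"] = float(arr[mask].sum())
    if glorad is not None and tavg is not None:
        gdd = out["GDD"]
        if np.isfinite(gdd) and gdd > 0 and np.isfinite(out["cumglorad"]):
            out["ratrdtmp"] = out["cumglorad"] / gdd
    if vpd is not None:
        out["ave.vpd"] = _mean_strict(vpd)
        out["cumvpd"] = _sum_strict(vpd)
    if precip is not None:
        out["cumprec"] = _sum_strict(precip)
    if precip is not None and evap is not None:
        pe = np.asarray(precip, dtype=float) - np.asarray(evap, dtype=float)
        if not np.isnan(pe).any():
            out["cumpospetp"] = float(pe[pe > 0].sum())
            out["cumnegpetp"] = float(pe[pe < 0].sum())
            out["cumpetp"] = float(pe.sum())
            out["cumntdryd"] = float((pe <= 0).sum())  # ties count as dry
    if tmin is not None:
        arr = np.asarray(tmin, dtype=float)
        if not np.isnan(arr).any():
            out["cumnsti4"] = float(arr[arr < -4.0].sum())
            out["cumndt0"] = float((arr < 0.0).sum())
            out["cumsti0"] = float(arr[arr < 0.0].sum())
    return out


def compute_stage_ecs(
    series: WeatherSeries,
    stages: pd.DataFrame,
    include_incomplete: bool = False,
) -> pd.DataFrame:
    """One row (the environment) of per-stage climatic ECs.

    Columns are named ``<code>_s<stage>``; only complete stages are
    emitted unless ``include_incomplete``.
    """
    values: dict[str, float] = {}
    kept = stages if include_incomplete else stages[stages["complete"]]
    for _, st in kept.iterrows():
        days = series.records.loc[st["start_date"]: st["end_date"]]
        if len(days) == 0:
            raise ValueError(f"{series.env_id}: stage {st['stage']} has zero days")
        ecs = climatic_ec_values(days)
        for code, val in ecs.items():
            values[f"{code}_s{int(st['stage'])}"] = val
    return pd.DataFrame([values], index=pd.Index([series.env_id], name="env_id"))


def compute_soil_ecs(soil: pd.DataFrame) -> pd.DataFrame:
    """Depth-resolved soil ECs per location (7 variables x 4 depths).

    ``soil`` holds one row per location x depth layer with columns
    ``location``, ``depth_top_cm``, ``depth_bottom_cm`` and the
    variables in :data:`SOIL_EC_CODES`.  Output columns are named
    ``<code>_d<k>`` for depth layer k = 1..4; values are constant
    across years within a location by construction.
    """
    missing_cols = [c for c in SOIL_EC_CODES if c not in soil.columns]
    if missing_cols:
        raise ValueError(f"soil table lacks columns: {missing_cols}")
    rows = {}
    for loc, grp in soil.groupby("location"):
        row: dict[str, float] = {}
        for k, (top, bottom) in enumerate(SOIL_DEPTHS, start=1):
            layer = grp[(grp["depth_top_cm"] == top) & (grp["depth_bottom_cm"] == bottom)]
            if len(layer) != 1:
                raise ValueError(f"location {loc}: missing soil layer {top}-{bottom} cm")
            for code in SOIL_EC_CODES:
                row[f"{code}_d{k}"] = float(layer.iloc[0][code])
        rows[loc] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("location")


def environment_covariates(
    weather: dict[str, WeatherSeries] | list[WeatherSeries],
    soil: pd.DataFrame | None = None,
    env_location: dict[str, str] | None = None,
    stage_size: float = 100.0,
) -> pd.DataFrame:
    """Raw environment-level EC matrix: climatic per-stage + soil columns.

    Environments reaching different numbers of complete stages produce
    ragged stage coverage; stages missing for an environment are NaN and
    are left to :func:`qc_ecs` to resolve.
    """
    if isinstance(weather, dict):
        series_list = list(weather.values())
    else:
        series_list = list(weather)
    frames = []
    for series in series_list:
        gdd = compute_gdd(series)
        stages = assign_stages(gdd, stage_size=stage_size)
        frames.append(compute_stage_ecs(series, stages))
    clim = pd.concat(frames, axis=0)
    clim = clim.sort_index()
    if soil is None:
        return clim
    soil_ecs = compute_soil_ecs(soil)
    if env_location is None:
        raise ValueError("env_location mapping required when soil is given")
    unknown = [e for e in clim.index if e not in env_location]
    if unknown:
        raise ValueError(f"environments without a location mapping: {unknown}")
    broadcast = soil_ecs.loc[[env_location[e] for e in clim.index]]
    broadcast.index = clim.index
    return pd.concat([clim, broadcast], axis=1)


def qc_ecs(
    raw: pd.DataFrame,
    na_frac: float = 0.10,
    repeat_frac: float = 0.30,
) -> pd.DataFrame:
    """Drop EC columns with too many missing or too many repeated values.

    A column is dropped when its missing fraction exceeds ``na_frac``
    (strictly) or its most frequent non-missing value accounts for more
    than ``repeat_frac`` of the rows (strictly).  Dropped columns and
    reasons are recorded in ``result.attrs["qc_dropped"]``.  Idempotent.
    """
    if len(raw) < 2:
        raise ValueError("qc_ecs needs at least 2 environment rows")
    n = len(raw)
    dropped: dict[str, str] = {}
    keep = []
    for colname in raw.columns:
        col = raw[colname]
        na = col.isna().sum() / n
        if na > na_frac:
            dropped[colname] = f"missing fraction {na:.3f} > {na_frac}"
            continue
        nonmiss = col.dropna()
        if len(nonmiss):
            top = nonmiss.value_counts().iloc[0] / n
            if top > repeat_frac:
                dropped[colname] = f"repeated-value fraction {top:.3f} > {repeat_frac}"
                continue
        keep.append(colname)
    if not keep:
        raise ValueError(
            "quality control removed every EC column; review na_frac/repeat_frac thresholds"
        )
    out = raw[keep].copy()
    out.attrs["qc_dropped"] = dropped
    return out


def build_W(
    ec: pd.DataFrame,
    obs_env: pd.Series,
    scale: str = "environment",
) -> pd.DataFrame:
    """Observation-level centered and scaled EC matrix ``W``.

    Parameters
    ----------
    ec : pandas.DataFrame
        Environment-level EC matrix (after QC), one row per env_id.
    obs_env : pandas.Series
        Maps observation id (index) to env_id (values); the output has
        one row per observation.
    scale : {"environment", "observation"}
        Level at which columns are centered to mean 0 and scaled to
        unit *sample* standard deviation.  Environment-level scaling
        (default) weighs every environment equally and guarantees the
        derived Omega kernel is constant within environment.

    Residual missing values are imputed to 0 after centering.  Columns
    with zero variance at the chosen level are dropped with a warning.
    """
    unknown = sorted(set(obs_env) - set(ec.index))
    if unknown:
        raise ValueError(f"observations map to unknown environments: {unknown}")
    if scale == "environment":
        mu = ec.mean(axis=0)
        sd = ec.std(axis=0, ddof=1)
        scaled = (ec - mu) / sd
        W = scaled.loc[obs_env.values]
    elif scale == "observation":
        expanded = ec.loc[obs_env.values]
        mu = expanded.mean(axis=0)
        sd = expanded.std(axis=0, ddof=1)
        scaled = (expanded - mu) / sd
        W = scaled
    else:
        raise ValueError("scale must be 'environment' or 'observation'")
    # columns where sd was 0 or NaN become all-NaN / inf: drop them
    bad = [c for c in W.columns if not np.isfinite(W[c].fillna(0.0)).all() or W[c].isna().all()]
    if bad:
        warnings.warn(f"dropping zero-variance EC columns: {bad}")
        W = W.drop(columns=bad)
    W = W.fillna(0.0)
    W.index = pd.Index(obs_env.index, name=obs_env.index.name or "obs_id")
    W.attrs["centered_scaled"] = True
    W.attrs["q"] = W.shape[1]
    W.attrs["scale_level"] = scale
    return W


def build_omega(W: pd.DataFrame) -> pd.DataFrame:
    """Environmental relationship kernel ``Omega = W W' / q``.

    Symmetric and positive semidefinite by construction; rows are
    identical for observations sharing an environment when ``W`` was
    scaled at environment level.
    """
    q = W.shape[1]
    if q == 0:
        raise ValueError("W has no EC columns (q = 0)")
    vals = W.to_numpy(dtype=float)
    omega = vals @ vals.T / q
    out = pd.DataFrame(omega, index=W.index, columns=W.index)
    out.attrs["q"] = q
    out.attrs["ec_columns"] = list(W.columns)
    return out
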