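"""Derived phenology, growth and energy traits from chamber logs.

Thermal time accumulates degree-days above a 2 °C base from the logged
chamber temperature; photothermal units weight each thermal-time increment
by the logged PAR.  Developmental traits (growth rates, phyllochron) come
from repeated Huan growth-stage scores; growth efficiencies relate biomass
at ear emergence to the climate accumulations; energy-use efficiencies
relate growth measures to dark respiration and quantum yield.  Broad-sense
heritability of any replicated trait is estimated by a REML random-intercept
model.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "BASE_TEMP_C",
    "thermal_time",
    "photothermal_units",
    "growth_rates",
    "phyllochron",
    "growth_efficiencies",
    "energy_use_efficiency",
    "broad_sense_heritability",
    "genotype_means",
    "derive_traits",
]

#: Base temperature (°C) below which no thermal time accumulates.
BASE_TEMP_C = 2.0


# ----------------------------------------------------------------------
def _intervals(series: pd.DataFrame, t_start: float, t_end: float) -> tuple[np.ndarray, ...]:
    """Clip the series' piecewise-constant intervals to [t_start, t_end].

    Each record holds from its own time to the next record's time (the last
    record extends by the trailing cadence).  Returns (duration_days, temp,
    par) for the clipped intervals.
    """
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    t = series["day"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("climate series needs at least two records")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError("climate timestamps must be strictly increasing")
    cadence = np.median(steps)
    gaps = np.flatnonzero(steps > 2 * cadence)
    if len(gaps):
        g = gaps[0]
        warnings.warn(
            f"gap in climate series between day {t[g]:.3f} and {t[g + 1]:.3f}",
            stacklevel=3,
        )
    starts = t
    ends = np.append(t[1:], t[-1] + steps[-1])
    if t_start < starts[0] - 1e-9 or t_end > ends[-1] + 1e-9:
        raise ValueError("requested span outside the climate series")
    lo = np.maximum(starts, t_start)
    hi = np.minimum(ends, t_end)
    dur = np.clip(hi - lo, 0.0, None)
    return dur, series["temp_C"].to_numpy(dtype=float), series["par"].to_numpy(dtype=float)


def thermal_time(series: pd.DataFrame, t_start: float, t_end: float) -> float:
    """Accumulated thermal time (°C·d) above the 2 °C base.

    Each logging interval contributes ``(temp - 2) * dt`` when its starting
    temperature exceeds 2 °C, else nothing; increments are never negative.
    """
    dur, temp, _ = _intervals(series, t_start, t_end)
    inc = np.where(temp > BASE_TEMP_C, (temp - BASE_TEMP_C) * dur, 0.0)
    return float(inc.sum())


def photothermal_units(
    series: pd.DataFrame, t_start: float, t_end: float, mode: str = "incremental"
) -> float:
    """Accumulated photothermal units over [t_start, t_end].

    ``incremental`` (default) accumulates ``dTT * PAR`` per logging
    interval; ``cumulative`` is the literal product of the running thermal
    time with the instantaneous PAR, summed over intervals (dimensionally
    awkward, provided for comparison).
    """
    dur, temp, par = _intervals(series, t_start, t_end)
    d_tt = np.where(temp > BASE_TEMP_C, (temp - BASE_TEMP_C) * dur, 0.0)
    if mode == "incremental":
        return float((d_tt * par).sum())
    if mode == "cumulative":
        return float((np.cumsum(d_tt) * par).sum())
    raise ValueError("mode must be 'incremental' or 'cumulative'")


# ----------------------------------------------------------------------
def _nearest_obs(stages: pd.DataFrame, target: float) -> pd.Series:
    """Observation whose growth stage is closest to ``target`` (tie: the
    earlier time)."""
    d = (stages["gs"] - target).abs().to_numpy()
    order = np.lexsort((stages["day"].to_numpy(), d))
    return stages.iloc[order[0]]


def growth_rates(stages: pd.DataFrame) -> tuple[float, float]:
    """Stage-progression rates (Huan stage per day) for one plant.

    GR1 runs between the observations nearest stage 1 and stage 3, GR2
    between stages 3 and 5.  ``stages`` needs columns ``day`` and ``gs``.
    Windows the observations cannot span give NaN.
    """
    if len(stages) < 2:
        return np.nan, np.nan
    out = []
    for lo, hi in ((1.0, 3.0), (3.0, 5.0)):
        a, b = _nearest_obs(stages, lo), _nearest_obs(stages, hi)
        dt = float(b["day"] - a["day"])
        dgs = float(b["gs"] - a["gs"])
        out.append(dgs / dt if dt > 0 and dgs > 0 else np.nan)
    return out[0], out[1]


def phyllochron(stages: pd.DataFrame, emergence_day: float) -> float:
    """Days per leaf: ``(T2 - Te) / GS2`` at the ~three-leaf observation."""
    if len(stages) == 0 or not np.isfinite(emergence_day):
        return np.nan
    obs = _nearest_obs(stages, 3.0)
    if obs["gs"] <= 0:
        return np.nan
    dt = float(obs["day"] - emergence_day)
    if dt == 0:
        warnings.warn("three-leaf observation coincides with emergence", stacklevel=2)
        return 0.0
    return dt / float(obs["gs"])


def growth_efficiencies(
    biomass_g: float,
    series: pd.DataFrame,
    emergence_day: float,
    ear_day: float,
) -> tuple[float, float]:
    """Biomass at ear emergence per unit thermal time / photothermal units,
    both accumulated from seedling emergence to ear emergence.  Plants that
    never reached ear emergence get NaN for both."""
    if not (np.isfinite(biomass_g) and np.isfinite(emergence_day) and np.isfinite(ear_day)):
        return np.nan, np.nan
    tt = thermal_time(series, emergence_day, ear_day)
    ptu = photothermal_units(series, emergence_day, ear_day)
    eff1 = biomass_g / tt if tt > 0 else np.nan
    eff2 = biomass_g / ptu if ptu > 0 else np.nan
    if tt <= 0 or ptu <= 0:
        logger.warning("zero climate accumulation between emergence and ear")
    return eff1, eff2


def energy_use_efficiency(
    resp_area: float,
    resp_dm: float,
    avg_qy: float,
    height_mm: float,
    leaf3_length_mm: float,
) -> tuple[float, float, float, float]:
    """The four energy-use efficiency ratios.

    EUE1 = 1 - respiration-per-area / average quantum yield;
    EUE2 = seedling height / respiration-per-dry-mass;
    EUE3 = leaf-3 length / respiration-per-dry-mass;
    EUE4 = seedling height / respiration-per-area.
    Zero denominators give NaN.
    """
    eue1 = 1.0 - resp_area / avg_qy if avg_qy else np.nan
    eue2 = height_mm / resp_dm if resp_dm else np.nan
    eue3 = leaf3_length_mm / resp_dm if resp_dm else np.nan
    eue4 = height_mm / resp_area if resp_area else np.nan
    return eue1, eue2, eue3, eue4


# ----------------------------------------------------------------------
def broad_sense_heritability(values: pd.DataFrame) -> float:
    """Broad-sense heritability H² = sigma²_G / (sigma²_G + sigma²_E).

    Variance components come from a REML random-intercept model (genotype
    as the grouping factor) on columns ``genotype`` and ``value``; the
    estimate is clipped to [0, 1].  Needs at least two genotypes and
    replication within at least one genotype.
    """
    df = values.dropna(subset=["value"])
    counts = df.groupby("genotype").size()
    if len(counts) < 2:
        raise ValueError("need at least two genotypes")
    if (counts < 2).all():
        raise ValueError("no genotype has replicate observations")
    within = df.groupby("genotype")["value"].var(ddof=1).dropna()
    between = df.groupby("genotype")["value"].mean().var(ddof=1)
    if np.allclose(within, 0.0):
        return 1.0 if between > 0 else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            endog=df["value"].to_numpy(dtype=float),
            exog=np.ones((len(df), 1)),
            groups=df["genotype"].to_numpy(),
        )
        fit = model.fit(reml=True)
    var_g = float(np.asarray(fit.cov_re)[0, 0])
    var_e = float(fit.scale)
    if var_g + var_e <= 0:
        return 0.0
    return float(np.clip(var_g / (var_g + var_e), 0.0, 1.0))


def genotype_means(traits: pd.DataFrame, trait_columns: list[str]) -> pd.DataFrame:
    """Mean over non-missing replicates per genotype x environment, with the
    replicate count per trait recorded in ``<trait>_n`` columns."""
    grouped = traits.groupby(["genotype", "environment"], sort=True)
    means = grouped[trait_columns].mean()
    counts = grouped[trait_columns].count().add_suffix("_n")
    return means.join(counts).reset_index()


def derive_traits(
    plants: pd.DataFrame,
    stages: pd.DataFrame,
    climate_by_env: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-plant derived trait table.

    ``plants`` has one row per plant with identity columns (``plant``,
    ``genotype``, ``environment``, ``replicate``) and raw measurements
    (``emergence_day``, ``ear_day``, ``biomass_g``, ``height_mm``,
    ``leaf3_length_mm``, ``leaf3_width_mm``, ``resp_area``, ``resp_dm``,
    ``avg_qy``); ``stages`` is long-format (``plant``, ``day``, ``gs``).
    """
    rows = []
    stage_groups = dict(tuple(stages.groupby("plant"))) if len(stages) else {}
    for rec in plants.itertuples(index=False):
        series = climate_by_env[rec.environment]
        plant_stages = stage_groups.get(
            rec.plant, pd.DataFrame(columns=["day", "gs"])
        )
        gr1, gr2 = growth_rates(plant_stages)
        phyll = phyllochron(plant_stages, rec.emergence_day)
        eff1, eff2 = growth_efficiencies(
            rec.biomass_g, series, rec.emergence_day, rec.ear_day
        )
        eue = energy_use_efficiency(
            rec.resp_area, rec.resp_dm, rec.avg_qy, rec.height_mm, rec.leaf3_length_mm
        )
        flowered = np.isfinite(rec.ear_day)
        rows.append(
            {
                "plant": rec.plant,
                "genotype": rec.genotype,
                "environment": rec.environment,
                "replicate": rec.replicate,
                "days_to_ear": rec.ear_day - rec.emergence_day if flowered else np.nan,
                "tt_to_ear": thermal_time(series, rec.emergence_day, rec.ear_day)
                if flowered
                else np.nan,
                "ptu_to_ear": photothermal_units(series, rec.emergence_day, rec.ear_day)
                if flowered
                else np.nan,
                "gr1": gr1,
                "gr2": gr2,
                "phyllochron": phyll,
                "growth_eff1": eff1,
                "growth_eff2": eff2,
                "eue1": eue[0],
                "eue2": eue[1],
                "eue3": eue[2],
                "eue4": eue[3],
                "leaf3_length_mm": rec.leaf3_length_mm,
                "leaf3_width_mm": rec.leaf3_width_mm,
            }
        )
    return pd.DataFrame(rows)
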