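"""Project welfare losses forward under explicit trend assumptions.

Each location-cause DALY series gets a trend model fitted to history
(default: OLS of log count on year => a constant exponential growth rate;
alternatives: linear-in-count, flat carry-forward). Burden is then rolled
forward year by year and re-valued with the valuation core under an economic
scenario: *static* (GDP and VSLY frozen at baseline — so the share trajectory
is exactly proportional to the VLW trajectory) or *dynamic* (GDP grows at a
configured rate and the VSLY is re-derived each year).

Point estimates are projected by default; UI bounds can optionally be scaled
by the same factor as the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import Hierarchy, ValuationParams, ValidationError, validate_burden
from .valuation import run_valuation

TREND_MODELS = ("log", "linear", "flat")


@dataclass(frozen=True)
class TrendConfig:
    """DALY trend-fit settings: model family and inclusive fit window."""

    model: str = "log"
    window: tuple[int, int] = (2000, 2021)
    min_years: int = 5

    def __post_init__(self) -> None:
        if self.model not in TREND_MODELS:
            raise ValidationError(f"unknown trend model {self.model!r}")


@dataclass(frozen=True)
class EconScenario:
    """Economic assumptions for the projection horizon.

    mode='static' freezes GDP and VSLY at their baseline-year values;
    mode='dynamic' grows gdp_pc and gdp_total at ``gdp_growth_rate`` per
    year and re-derives the VSLY annually. ``scale_ui`` propagates the DALY
    UI bounds by the same growth factor as the point estimate.
    """

    mode: str = "static"
    gdp_growth_rate: float = 0.0
    scale_ui: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("static", "dynamic"):
            raise ValidationError(f"unknown econ mode {self.mode!r}")


def fit_daly_trend(
    history: pd.DataFrame, config: TrendConfig | None = None
) -> pd.DataFrame:
    """Fit a growth model per (location, cause) from a burden history.

    Returns one row per location-cause with columns ``model``, ``rate``
    (per-year log growth for the log model; per-year count increment for the
    linear model; 0 for flat), ``rate_se`` and ``baseline_year``. Requires
    at least ``min_years`` historical years inside the window.
    """
    cfg = config or TrendConfig()
    validate_burden(history)
    lo, hi = cfg.window
    rows = []
    for (loc, cause), grp in history.groupby(["location_id", "cause"]):
        obs = grp[(grp["year"] >= lo) & (grp["year"] <= hi)].sort_values("year")
        if len(obs) < cfg.min_years:
            raise ValidationError(
                f"{loc}/{cause}: {len(obs)} year(s) in window, need >= {cfg.min_years}"
            )
        years = obs["year"].to_numpy(dtype=float)
        counts = obs["dalys_val"].to_numpy(dtype=float)
        if cfg.model == "flat":
            rate, se = 0.0, 0.0
        elif cfg.model == "log":
            if (counts <= 0).any():
                raise ValidationError(
                    f"{loc}/{cause}: non-positive DALY counts; use the linear model"
                )
            fit = sm.OLS(np.log(counts), sm.add_constant(years)).fit()
            rate, se = float(fit.params[1]), float(fit.bse[1])
        else:  # linear-in-count
            fit = sm.OLS(counts, sm.add_constant(years)).fit()
            rate, se = float(fit.params[1]), float(fit.bse[1])
        rows.append(
            {
                "location_id": loc,
                "cause": cause,
                "model": cfg.model,
                "rate": rate,
                "rate_se": se,
                "baseline_year": int(obs["year"].max()),
            }
        )
    return pd.DataFrame(rows)


def project_burden(
    baseline_burden: pd.DataFrame,
    econ: pd.DataFrame,
    hierarchy: Hierarchy | None,
    params: ValuationParams,
    trends: pd.DataFrame,
    scenario: EconScenario | None = None,
    horizon: int = 2050,
    baseline_year: int = 2021,
) -> pd.DataFrame:
    """Yearly valuation results from ``baseline_year`` through ``horizon``.

    DALYs_t = DALYs_baseline * exp(rate * (t - baseline)) under the log
    model (linear model adds rate * (t - baseline) counts, floored at 0;
    flat carries the baseline forward). Each year is re-valued with the
    valuation core under the scenario economics. ``horizon == baseline_year``
    returns the baseline valuation unchanged.
    """
    scenario = scenario or EconScenario()
    if horizon < baseline_year:
        raise ValidationError(
            f"horizon {horizon} precedes baseline year {baseline_year}"
        )
    base = baseline_burden[baseline_burden["year"] == baseline_year]
    if base.empty:
        raise ValidationError(f"no baseline burden for year {baseline_year}")
    validate_burden(base)
    base_econ = econ[econ["year"] == baseline_year]
    if base_econ.empty:
        raise ValidationError(f"no macro data for baseline year {baseline_year}")

    keyed = base.merge(
        trends[["location_id", "cause", "model", "rate"]],
        on=["location_id", "cause"],
        how="left",
    )
    if keyed["rate"].isna().any():
        missing = keyed.loc[keyed["rate"].isna(), ["location_id", "cause"]]
        raise ValidationError(f"no trend model for:\n{missing.head(10)}")

    frames = []
    for year in range(baseline_year, horizon + 1):
        dt = year - baseline_year
        burden_t = keyed.copy()
        model = burden_t["model"].to_numpy()
        rate = burden_t["rate"].to_numpy(dtype=float)
        factor = np.where(model == "log", np.exp(rate * dt), 1.0)
        shift = np.where(model == "linear", rate * dt, 0.0)
        for col in ("dalys_val", "dalys_lower", "dalys_upper"):
            scaled = burden_t[col].to_numpy(dtype=float) * factor + shift
            if col == "dalys_val" or scenario.scale_ui:
                burden_t[col] = np.maximum(scaled, 0.0)
        if not scenario.scale_ui:
            # point-estimate projection: collapse the UI onto the point
            burden_t["dalys_lower"] = burden_t["dalys_val"]
            burden_t["dalys_upper"] = burden_t["dalys_val"]
        burden_t["year"] = year
        burden_t = burden_t[list(base.columns)]

        econ_t = base_econ.copy()
        if scenario.mode == "dynamic":
            growth = np.exp(scenario.gdp_growth_rate * dt)
            econ_t["gdp_pc"] = econ_t["gdp_pc"] * growth
            econ_t["gdp_total"] = econ_t["gdp_total"] * growth
        econ_t["year"] = year
        frames.append(run_valuation(burden_t, econ_t, hierarchy, params))
    return pd.concat(frames, ignore_index=True)
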