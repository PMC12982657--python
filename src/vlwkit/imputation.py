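"""Fill missing macroeconomic values by per-location regression on year.

GDP-like series grow multiplicatively, so the default model regresses
log(value) on calendar year with OLS and predicts missing years on that
scale; a linear-in-level alternative is selectable. Locations with too few
observed points fall back to extending their last observation with the
median log-growth of their region. Every imputed cell is flagged and logged
so runs can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ECON_COLUMNS, Hierarchy, ValidationError, validate_econ

logger = logging.getLogger("vlwkit")


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for macro imputation.

    min_points: observed values required for a per-location fit (else the
    regional-growth fallback is used). scale: 'log' (default, multiplicative
    growth) or 'linear'. window: inclusive year range used for fitting.
    """

    min_points: int = 3
    scale: str = "log"
    window: tuple[int, int] = (2000, 2021)

    def __post_init__(self) -> None:
        if self.scale not in ("log", "linear"):
            raise ValidationError(f"unknown imputation scale {self.scale!r}")
        if self.min_points < 2:
            raise ValidationError("min_points must be at least 2")


def impute_series(
    series: pd.Series, config: ImputationConfig | None = None
) -> tuple[pd.Series, pd.Series]:
    """Fill gaps in one (year -> value) series by OLS on year.

    Returns ``(completed, imputed_flags)`` indexed like the input. Observed
    values are never touched; a complete series is returned unchanged
    (idempotence). Raises if fewer than ``min_points`` observations exist.
    """
    cfg = config or ImputationConfig()
    values = series.astype(float)
    observed = values.dropna()
    flags = values.isna()
    if not flags.any():
        return values, flags

    lo, hi = cfg.window
    fit = observed[(observed.index >= lo) & (observed.index <= hi)]
    if len(fit) < cfg.min_points:
        fit = observed  # fall back to everything we have
    if len(fit) < cfg.min_points:
        raise ValidationError(
            f"only {len(fit)} observed value(s); need >= {cfg.min_points}"
        )
    if cfg.scale == "log" and (fit <= 0).any():
        raise ValidationError("non-positive values under log-scale imputation")

    y = np.log(fit.to_numpy()) if cfg.scale == "log" else fit.to_numpy()
    X = sm.add_constant(fit.index.to_numpy(dtype=float))
    model = sm.OLS(y, X).fit()
    missing_years = values.index[flags].to_numpy(dtype=float)
    pred = model.predict(sm.add_constant(missing_years, has_constant="add"))
    if cfg.scale == "log":
        pred = np.exp(pred)
    completed = values.copy()
    completed.loc[values.index[flags]] = pred
    return completed, flags


def fallback_regional_growth(
    location: str, hierarchy: Hierarchy, econ: pd.DataFrame, variable: str = "gdp_pc"
) -> float:
    """Median per-year log-growth of the location's region, for short series.

    Each same-region country contributes the OLS slope of log(value) on year
    over its observed points (>= 2 needed); the median of those slopes is
    returned. Raises if the region has no usable history.
    """
    region = hierarchy.get(location).parent_region
    if region is None:
        raise ValidationError(f"{location!r} has no parent region")
    members = hierarchy.members(region)
    growths: list[float] = []
    for country in members:
        obs = (
            econ.loc[econ["location_id"] == country, ["year", variable]]
            .dropna()
            .sort_values("year")
        )
        if len(obs) < 2:
            continue
        X = sm.add_constant(obs["year"].to_numpy(dtype=float))
        slope = sm.OLS(np.log(obs[variable].to_numpy()), X).fit().params[1]
        growths.append(float(slope))
    if not growths:
        raise ValidationError(f"region {region!r} has no usable {variable} history")
    return float(np.median(growths))


def impute_econ_table(
    econ: pd.DataFrame,
    hierarchy: Hierarchy | None = None,
    config: ImputationConfig | None = None,
    variables: tuple[str, ...] = ("gdp_pc", "gdp_total", "hale"),
) -> pd.DataFrame:
    """Impute missing cells of the econ table, per location and variable.

    Per-location OLS on year where enough points exist; otherwise, when a
    hierarchy is supplied, the last observation is extended by the region's
    median log-growth (for HALE the nearest observation is carried over).
    A table with no gaps is returned unchanged.
    """
    cfg = config or ImputationConfig()
    validate_econ(econ)
    out = econ.copy()
    n_imputed = 0
    for location, grp in econ.groupby("location_id"):
        for var in variables:
            series = grp.set_index("year")[var]
            if not series.isna().any():
                continue
            observed = series.dropna()
            try:
                if len(observed) >= cfg.min_points:
                    completed, flags = impute_series(series, cfg)
                elif hierarchy is not None and len(observed) >= 1:
                    completed, flags = _extend_by_growth(
                        series, location, hierarchy, econ, var
                    )
                else:
                    raise ValidationError("too few points and no fallback donor")
            except ValidationError as exc:
                raise ValidationError(
                    f"cannot impute {var} for {location!r}: {exc}"
                ) from exc
            mask = out["location_id"] == location
            out.loc[mask, var] = out.loc[mask, "year"].map(completed)
            if f"{var}_imputed" in out.columns:
                out.loc[mask, f"{var}_imputed"] = out.loc[mask, "year"].map(flags)
            n_filled = int(flags.sum())
            n_imputed += n_filled
            logger.info(
                "imputed %d %s cell(s) for %s (years %s)",
                n_filled, var, location, sorted(series.index[flags]),
            )
    if n_imputed:
        logger.info("imputation complete: %d cell(s) filled", n_imputed)
    return validate_econ(out)


def _extend_by_growth(
    series: pd.Series,
    location: str,
    hierarchy: Hierarchy,
    econ: pd.DataFrame,
    variable: str,
) -> tuple[pd.Series, pd.Series]:
    """Extend a short series from its nearest observation.

    GDP-like variables grow at the region's median log-growth; HALE (slowly
    varying) carries the nearest observed value forward/backward.
    """
    flags = series.isna()
    observed = series.dropna()
    growth = (
        0.0
        if variable == "hale"
        else fallback_regional_growth(location, hierarchy, econ, variable)
    )
    completed = series.astype(float).copy()
    for year in series.index[flags]:
        anchor_year = observed.index[np.argmin(np.abs(observed.index - year))]
        completed.loc[year] = observed.loc[anchor_year] * np.exp(
            growth * (year - anchor_year)
        )
    return completed, flags
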