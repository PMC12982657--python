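"""Synthetic GBD-like / WDI-like worlds with known ground truth.

The generator emulates the structure of the real inputs without calibrating
to their magnitudes: country incomes are lognormal; HALE rises with log
income; DALY *rates* decline with a country's income rank (the SDI
gradient), so absolute burden concentrates where populations and incomes
are large while the GDP share concentrates in poor countries — the
rich-pay-more / poor-hurt-more pattern. Subtype burdens are generated so
T1DM + T2DM equals the overall cause exactly, and every country-year series
carries exponential trends for fitting.

Ground truth (each country's VSL, VSLY, VLW and GDP share) is computed here
by a standalone closed-form path that shares no code with the valuation
module, so truth-vs-pipeline equality is a genuine oracle test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import (
    AGE_BAND_LABEL,
    CAUSE_OVERALL,
    CAUSE_T1DM,
    CAUSE_T2DM,
    Hierarchy,
    ValidationError,
    ValuationParams,
    hierarchy_from_frame,
    validate_burden,
    validate_econ,
)

SDI_ORDER = ("low", "low-middle", "middle", "high-middle", "high")


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world.

    Income is lognormal: ``log gdp_pc ~ N(gdp_pc_log_mean, gdp_pc_log_sd)``
    (defaults give a median near Int$13,000 with a realistic cross-country
    spread). HALE = hale_intercept + hale_slope * log(gdp_pc) + noise.
    Overall DALY rates per 100k population-15-39 start at ``daly_rate_base``
    and are multiplied by ``exp(sdi_gradient * income_rank)`` with rank in
    [0, 1] (negative gradient => poorer countries carry higher rates);
    ``t1_share`` of the overall rate is type 1. GDP and DALYs carry
    exponential per-year trends; 95% UIs are symmetric with relative
    half-width ``ui_halfwidth_frac``. Identical seed => bit-identical world.
    """

    n_countries: int = 30
    n_regions: int = 6
    years: tuple[int, int] = (2000, 2021)
    seed: int = 42
    gdp_pc_log_mean: float = 9.5
    gdp_pc_log_sd: float = 1.0
    hale_intercept: float = 25.0
    hale_slope: float = 4.0
    daly_rate_base: float = 400.0
    t1_share: float = 0.2
    sdi_gradient: float = -0.8
    ui_halfwidth_frac: float = 0.25
    growth_rate_daly: float = 0.02
    growth_rate_gdp: float = 0.03
    gdp_noise_sd: float = 0.0
    hale_noise_sd: float = 0.0
    daly_noise_sd: float = 0.0
    vsl_ref: float = 11.8e6

    def __post_init__(self) -> None:
        if self.n_regions > self.n_countries:
            raise ValidationError("n_regions must not exceed n_countries")
        for name in ("gdp_pc_log_sd", "ui_halfwidth_frac", "gdp_noise_sd",
                     "hale_noise_sd", "daly_noise_sd", "daly_rate_base"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0.0 <= self.t1_share <= 1.0:
            raise ValidationError("t1_share must lie in [0, 1]")


class World(NamedTuple):
    """Everything the pipeline needs, plus independently computed truth."""

    burden: pd.DataFrame
    econ: pd.DataFrame
    hierarchy: Hierarchy
    truth: pd.DataFrame
    params: ValuationParams
    reference_location: str


def generate_world(spec: WorldSpec | None = None) -> World:
    """Generate burden, econ and hierarchy tables plus a truth record.

    The truth frame holds, for the final year and every country x cause,
    the VSL, FLE, VSLY, VLW (point and UI bounds) and GDP share computed by
    closed-form arithmetic inside this function — deliberately not by the
    valuation module. The richest country is designated the benefit-transfer
    reference, and the returned :class:`ValuationParams` use its income.
    """
    spec = spec or WorldSpec()
    rng = np.random.default_rng(spec.seed)
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    n = spec.n_countries

    countries = [f"Country_{i:02d}" for i in range(n)]
    regions = [f"Region_{i}" for i in range(spec.n_regions)]

    gdp_pc_final = np.exp(
        rng.normal(spec.gdp_pc_log_mean, spec.gdp_pc_log_sd, size=n)
    )
    population = np.exp(rng.normal(16.0, 1.0, size=n))  # total persons
    pop_young = 0.35 * population  # ages 15-39
    # income rank in [0, 1]: 0 = poorest
    rank = (np.argsort(np.argsort(gdp_pc_final)) / max(n - 1, 1)).astype(float)
    hale = (
        spec.hale_intercept
        + spec.hale_slope * np.log(gdp_pc_final)
        + rng.normal(0.0, spec.hale_noise_sd, size=n)
    )
    hale = np.clip(hale, 5.0, 119.0)

    rate_overall = spec.daly_rate_base * np.exp(spec.sdi_gradient * rank)
    dalys_final = {
        CAUSE_T1DM: pop_young * rate_overall * spec.t1_share / 1e5,
        CAUSE_T2DM: pop_young * rate_overall * (1.0 - spec.t1_share) / 1e5,
    }

    # hierarchy: regions round-robin; SDI quintiles by income rank
    region_of = {c: regions[i % spec.n_regions] for i, c in enumerate(countries)}
    quint = np.minimum((rank * 5).astype(int), 4)
    sdi_of = {c: SDI_ORDER[quint[i]] for i, c in enumerate(countries)}
    hierarchy = hierarchy_from_frame(
        pd.DataFrame(
            {
                "country": countries,
                "gbd_region": [region_of[c] for c in countries],
                "sdi_quintile": [sdi_of[c] for c in countries],
            }
        )
    )

    # panel tables with exponential trends back from the final year
    econ_rows, burden_rows = [], []
    for i, c in enumerate(countries):
        gdp_noise = np.exp(rng.normal(0.0, spec.gdp_noise_sd, size=len(years)))
        daly_noise = {
            cause: np.exp(rng.normal(0.0, spec.daly_noise_sd, size=len(years)))
            for cause in (CAUSE_T1DM, CAUSE_T2DM)
        }
        for j, year in enumerate(years):
            back = float(year - y1)
            gdp_pc = gdp_pc_final[i] * math.exp(spec.growth_rate_gdp * back)
            gdp_pc *= gdp_noise[j] if year != y1 else 1.0
            econ_rows.append(
                {
                    "location_id": c,
                    "year": int(year),
                    "gdp_pc": gdp_pc,
                    "gdp_total": gdp_pc * population[i],
                    "hale": float(hale[i]),
                    "population": float(population[i]),
                    "gdp_pc_imputed": False,
                    "gdp_total_imputed": False,
                    "hale_imputed": False,
                }
            )
            sub = {}
            for cause in (CAUSE_T1DM, CAUSE_T2DM):
                val = dalys_final[cause][i] * math.exp(spec.growth_rate_daly * back)
                val *= daly_noise[cause][j] if year != y1 else 1.0
                sub[cause] = val
            sub[CAUSE_OVERALL] = sub[CAUSE_T1DM] + sub[CAUSE_T2DM]
            for cause, val in sub.items():
                burden_rows.append(
                    {
                        "location_id": c,
                        "year": int(year),
                        "cause": cause,
                        "age_band": AGE_BAND_LABEL,
                        "dalys_val": val,
                        "dalys_lower": val * (1.0 - spec.ui_halfwidth_frac),
                        "dalys_upper": val * (1.0 + spec.ui_halfwidth_frac),
                    }
                )

    econ = validate_econ(
        pd.DataFrame(econ_rows).sort_values(
            ["location_id", "year"], ignore_index=True
        )
    )
    burden = validate_burden(
        pd.DataFrame(burden_rows).sort_values(
            ["location_id", "year", "cause"], ignore_index=True
        )
    )

    ref_idx = int(np.argmax(gdp_pc_final))
    reference = countries[ref_idx]
    gdp_pc_ref = float(gdp_pc_final[ref_idx])
    params = ValuationParams(vsl_ref=spec.vsl_ref, gdp_pc_ref=gdp_pc_ref)

    truth = _closed_form_truth(
        countries, gdp_pc_final, population, hale,
        {c: dalys_final[c] for c in (CAUSE_T1DM, CAUSE_T2DM)},
        spec, gdp_pc_ref, int(y1),
    )
    return World(burden, econ, hierarchy, truth, params, reference)


def _closed_form_truth(
    countries, gdp_pc, population, hale, dalys_by_cause, spec, gdp_pc_ref, year
) -> pd.DataFrame:
    """Final-year per-country truth, written out formula by formula.

    Independent of the valuation module on purpose: plain ``math`` arithmetic
    per country so pipeline-vs-truth equality is a real cross-check.
    """
    rows = []
    ie = 1.0
    for i, c in enumerate(countries):
        vsl = spec.vsl_ref * math.pow(gdp_pc[i] / gdp_pc_ref, ie)
        fle = 0.5 * hale[i]
        vsly = vsl / fle
        gdp_total = gdp_pc[i] * population[i]
        causes = dict(dalys_by_cause)
        all_causes = {
            CAUSE_T1DM: causes[CAUSE_T1DM][i],
            CAUSE_T2DM: causes[CAUSE_T2DM][i],
        }
        all_causes[CAUSE_OVERALL] = all_causes[CAUSE_T1DM] + all_causes[CAUSE_T2DM]
        for cause, dalys in all_causes.items():
            vlw = dalys * vsly
            rows.append(
                {
                    "location_id": c,
                    "cause": cause,
                    "year": year,
                    "gdp_pc": float(gdp_pc[i]),
                    "vsl": vsl,
                    "fle": fle,
                    "vsly": vsly,
                    "dalys_val": dalys,
                    "vlw_val": vlw,
                    "vlw_lower": dalys * (1.0 - spec.ui_halfwidth_frac) * vsly,
                    "vlw_upper": dalys * (1.0 + spec.ui_halfwidth_frac) * vsly,
                    "gdp_total": gdp_total,
                    "gdp_share_val": 100.0 * vlw / gdp_total,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["location_id", "cause"], ignore_index=True
    )


def mask_econ(
    econ: pd.DataFrame,
    frac: float,
    seed: int,
    variable: str = "gdp_pc",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hide exactly ``ceil(frac * n)`` observed cells of one econ variable.

    Returns the masked table and a mask index recording (location, year,
    true value) for recovery scoring. Masking is reproducible by seed.
    """
    if not 0.0 < frac < 1.0:
        raise ValidationError("mask fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    observed = econ.index[econ[variable].notna()].to_numpy()
    n_hide = math.ceil(frac * len(observed))
    hidden = np.sort(rng.choice(observed, size=n_hide, replace=False))
    masked = econ.copy()
    mask_index = econ.loc[hidden, ["location_id", "year"]].copy()
    mask_index["variable"] = variable
    mask_index["true_value"] = econ.loc[hidden, variable].to_numpy()
    masked.loc[hidden, variable] = np.nan
    return masked, mask_index.reset_index(drop=True)


def write_gbd_style_csv(burden: pd.DataFrame, path: str | Path) -> None:
    """Emit a burden table in the results-export dialect the reader consumes."""
    out = pd.DataFrame(
        {
            "measure_name": "DALYs (Disability-Adjusted Life Years)",
            "location_name": burden["location_id"],
            "sex_name": "Both",
            "age_name": burden["age_band"],
            "cause_name": burden["cause"].map(
                {
                    CAUSE_OVERALL: "Diabetes mellitus",
                    CAUSE_T1DM: "Diabetes mellitus type 1",
                    CAUSE_T2DM: "Diabetes mellitus type 2",
                }
            ),
            "metric_name": "Number",
            "year": burden["year"],
            "val": burden["dalys_val"],
            "upper": burden["dalys_upper"],
            "lower": burden["dalys_lower"],
        }
    )
    out.to_csv(path, index=False)
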