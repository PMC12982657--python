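"""Benefit-transfer valuation: DALYs -> value of lost welfare (VLW).

The chain of four equations, applied per country *i*:

1. Benefit transfer of the reference VSL by relative income,
   ``VSL_i = VSL_ref * (gdp_pc_i / gdp_pc_ref) ** IE``;
2. annualization over future life expectancy, ``FLE_i = f * HALE_i``
   (default f = 1/2) and ``VSLY_i = VSL_i / FLE_i``;
3. monetization, ``VLW_i = DALYs_i * VSLY_i`` (point and both UI bounds
   scaled by the same VSLY, so interval ordering is preserved);
4. normalization, ``share_i = 100 * VLW_i / GDP_i`` (percent of total GDP).

Uncertainty is propagated multiplicatively through a fixed VSLY: the UI of
the monetized burden comes entirely from the DALY interval.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import (
    ECON_COLUMNS,
    Hierarchy,
    ValuationParams,
    ValidationError,
    validate_burden,
    validate_econ,
)

RESULT_COLUMNS = (
    "location_id",
    "cause",
    "year",
    "vsl",
    "fle",
    "vsly",
    "vlw_val",
    "vlw_lower",
    "vlw_upper",
    "gdp_total",
    "gdp_share_val",
    "gdp_share_lower",
    "gdp_share_upper",
)


def benefit_transfer_vsl(gdp_pc_i, params: ValuationParams):
    """Country VSL by benefit transfer from the reference VSL.

    Accepts scalars or arrays; strictly increasing in ``gdp_pc_i``.
    """
    gdp_pc_i = np.asarray(gdp_pc_i, dtype=float)
    if np.any(gdp_pc_i <= 0):
        raise ValidationError("per-capita GDP must be strictly positive")
    out = params.vsl_ref * (gdp_pc_i / params.gdp_pc_ref) ** params.income_elasticity
    return float(out) if out.ndim == 0 else out


def annualize_vsl(vsl_i, hale_i, params: ValuationParams):
    """Annualize a VSL over future life expectancy.

    Returns ``(fle, vsly)`` with ``fle = fle_fraction * hale`` and
    ``vsly = vsl / fle``. A non-positive HALE signals missing or corrupt
    life-expectancy data and raises.
    """
    hale_i = np.asarray(hale_i, dtype=float)
    if np.any(~np.isfinite(hale_i)) or np.any(hale_i <= 0):
        raise ValidationError("HALE must be positive and finite")
    fle = params.fle_fraction * hale_i
    vsly = np.asarray(vsl_i, dtype=float) / fle
    if fle.ndim == 0:
        return float(fle), float(vsly)
    return fle, vsly


def monetize(dalys_val, dalys_lower, dalys_upper, vsly):
    """Multiply a DALY estimate and its UI bounds by a (positive) VSLY."""
    vsly = np.asarray(vsly, dtype=float)
    if np.any(vsly <= 0):
        raise ValidationError("VSLY must be strictly positive")
    return (
        np.asarray(dalys_val, dtype=float) * vsly,
        np.asarray(dalys_lower, dtype=float) * vsly,
        np.asarray(dalys_upper, dtype=float) * vsly,
    )


def gdp_share(vlw, gdp_total):
    """Welfare loss as a percentage of total GDP."""
    gdp_total = np.asarray(gdp_total, dtype=float)
    if np.any(gdp_total <= 0):
        raise ValidationError("total GDP must be strictly positive")
    out = 100.0 * np.asarray(vlw, dtype=float) / gdp_total
    return float(out) if out.ndim == 0 else out


def run_valuation(
    burden: pd.DataFrame,
    econ: pd.DataFrame,
    hierarchy: Hierarchy | None,
    params: ValuationParams,
) -> pd.DataFrame:
    """Apply the valuation chain to every (location, year, cause) record.

    Every burden location-year must have a complete econ record (gdp_pc,
    gdp_total, hale) — run imputation first if the macro table has gaps.
    Unmatched locations raise, listing them, rather than silently truncating
    the world total. Deterministic given inputs and invariant to row order.
    """
    validate_burden(burden)
    validate_econ(econ)
    if hierarchy is not None:
        missing = sorted(set(burden["location_id"]) - set(hierarchy.countries()))
        if missing:
            raise ValidationError(
                f"burden locations absent from hierarchy: {missing}"
            )

    econ_keyed = econ.set_index(["location_id", "year"])
    merged = burden.merge(
        econ[["location_id", "year", "gdp_pc", "gdp_total", "hale"]],
        on=["location_id", "year"],
        how="left",
    )
    unmatched = merged[merged[["gdp_pc", "gdp_total", "hale"]].isna().any(axis=1)]
    if len(unmatched):
        locs = sorted(unmatched["location_id"].unique())
        raise ValidationError(
            f"{len(locs)} location-year(s) lack complete macro data "
            f"(impute first): {locs[:10]}"
        )
    del econ_keyed

    vsl = benefit_transfer_vsl(merged["gdp_pc"].to_numpy(), params)
    fle, vsly = annualize_vsl(vsl, merged["hale"].to_numpy(), params)
    vlw_val, vlw_lo, vlw_up = monetize(
        merged["dalys_val"].to_numpy(),
        merged["dalys_lower"].to_numpy(),
        merged["dalys_upper"].to_numpy(),
        vsly,
    )
    gdp_total = merged["gdp_total"].to_numpy()
    out = pd.DataFrame(
        {
            "location_id": merged["location_id"],
            "cause": merged["cause"],
            "year": merged["year"],
            "vsl": vsl,
            "fle": fle,
            "vsly": vsly,
            "vlw_val": vlw_val,
            "vlw_lower": vlw_lo,
            "vlw_upper": vlw_up,
            "gdp_total": gdp_total,
            "gdp_share_val": gdp_share(vlw_val, gdp_total),
            "gdp_share_lower": gdp_share(vlw_lo, gdp_total),
            "gdp_share_upper": gdp_share(vlw_up, gdp_total),
        }
    )
    return out[list(RESULT_COLUMNS)].sort_values(
        ["location_id", "year", "cause"], ignore_index=True
    )


def sensitivity_sweep(
    burden: pd.DataFrame,
    econ: pd.DataFrame,
    hierarchy: Hierarchy | None,
    params: ValuationParams,
    ie_values: Iterable[float] = (0.55, 1.0, 1.5),
) -> Mapping[float, pd.DataFrame]:
    """Re-run the valuation for each income elasticity in ``ie_values``.

    For a country with per-capita income below the reference, VLW decreases
    in IE; above the reference it increases; at the reference it is flat.
    """
    ie_values = list(ie_values)
    if not ie_values:
        raise ValidationError("ie_values must be non-empty")
    return {
        ie: run_valuation(burden, econ, hierarchy, params.with_elasticity(ie))
        for ie in ie_values
    }
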