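"""Roll country-level welfare losses up the location hierarchy.

Aggregate VLW is the bound-wise sum of member-country VLW (no independence
assumption between country UIs — conservative), and the aggregate GDP share
is recomputed as 100 * (sum VLW) / (sum GDP), i.e. GDP-weighted, the only
definition consistent with "share of GDP" at every level. The same rule
applied to the regional partition, the SDI partition, or all countries at
once yields mutually consistent totals (sum conservation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import (
    CAUSE_OVERALL,
    CAUSE_T1DM,
    CAUSE_T2DM,
    GLOBAL_ID,
    LEVEL_GLOBAL,
    LEVEL_REGION,
    LEVEL_SDI,
    Hierarchy,
    ValidationError,
)
from .valuation import RESULT_COLUMNS


def aggregate_vlw(
    results: pd.DataFrame, hierarchy: Hierarchy, level: str
) -> pd.DataFrame:
    """Aggregate country-level results to regions, SDI quintiles, or global.

    ``results`` must be country-level (one row per country-year-cause);
    a country absent from the hierarchy is an error. The returned frame has
    the same shape as the input with ``location_id`` set to the aggregate
    node id; per-country VSL/FLE/VSLY are not aggregate quantities and are
    reported as NaN.
    """
    if level not in (LEVEL_REGION, LEVEL_SDI, LEVEL_GLOBAL):
        raise ValidationError(f"unknown aggregation level {level!r}")
    known = set(hierarchy.countries())
    missing = sorted(set(results["location_id"]) - known)
    if missing:
        raise ValidationError(f"countries absent from hierarchy: {missing}")

    group = results["location_id"].map(
        {c: hierarchy.parent(c, level) for c in known if c in set(results["location_id"])}
    )
    agg = (
        results.assign(location_id=group)
        .groupby(["location_id", "year", "cause"], as_index=False)
        .agg(
            vlw_val=("vlw_val", "sum"),
            vlw_lower=("vlw_lower", "sum"),
            vlw_upper=("vlw_upper", "sum"),
            gdp_total=("gdp_total", "sum"),
        )
    )
    for bound in ("val", "lower", "upper"):
        agg[f"gdp_share_{bound}"] = 100.0 * agg[f"vlw_{bound}"] / agg["gdp_total"]
    for col in ("vsl", "fle", "vsly"):
        agg[col] = np.nan
    return agg[list(RESULT_COLUMNS)].sort_values(
        ["location_id", "year", "cause"], ignore_index=True
    )


def aggregate_all_levels(results: pd.DataFrame, hierarchy: Hierarchy) -> pd.DataFrame:
    """Global + SDI quintiles + regions, stacked, with a ``level`` column."""
    frames = []
    for level in (LEVEL_GLOBAL, LEVEL_SDI, LEVEL_REGION):
        frame = aggregate_vlw(results, hierarchy, level)
        frame.insert(1, "level", level)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def to_regional_table(
    results: pd.DataFrame,
    hierarchy: Hierarchy,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Report aggregates as a wide table: one row per aggregate location,
    VLW in Int$ millions and VLW/GDP in percent for overall/T2DM/T1DM,
    rounded to ``ndigits`` decimals (internal computation is full precision).
    """
    agg = aggregate_all_levels(results, hierarchy)
    rows = []
    for (loc, level), grp in agg.groupby(["location_id", "level"], sort=False):
        row: dict[str, object] = {"location": loc, "level": level}
        for cause, tag in (
            (CAUSE_OVERALL, "overall"),
            (CAUSE_T2DM, "t2dm"),
            (CAUSE_T1DM, "t1dm"),
        ):
            sub = grp[grp["cause"] == cause]
            if len(sub):
                row[f"vlw_{tag}"] = round(float(sub["vlw_val"].iloc[0]) / 1e6, ndigits)
                row[f"share_{tag}"] = round(float(sub["gdp_share_val"].iloc[0]), ndigits)
        rows.append(row)
    out = pd.DataFrame(rows)
    order = (
        [GLOBAL_ID]
        + [f"{s} SDI" for s in ("high", "high-middle", "middle", "low-middle", "low")]
        + hierarchy.regions()
    )
    out["__ord"] = out["location"].map({loc: i for i, loc in enumerate(order)})
    return out.sort_values("__ord", ignore_index=True).drop(columns="__ord")


def consistency_report(
    table: pd.DataFrame,
    vlw_tolerance: float = 0.02,
    share_tolerance: float = 0.02,
) -> pd.DataFrame:
    """Check cause additivity of a wide report table, row by row.

    ``table`` must carry ``location``, ``vlw_overall/vlw_t2dm/vlw_t1dm``
    (Int$ millions) and ``share_overall/share_t2dm/share_t1dm`` (percent).
    Reports |overall - T1 - T2| for VLW and share; tolerances default to
    0.02 (million / percentage points), twice the 0.01 slack introduced by
    rounding components to two decimals independently. The headline
    ``within_tolerance`` flag tracks the VLW discrepancy; the share analogue
    gets its own flag, since published share columns are rounded much more
    coarsely relative to their magnitude.
    """
    required = [
        "location",
        "vlw_overall", "vlw_t2dm", "vlw_t1dm",
        "share_overall", "share_t2dm", "share_t1dm",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"report table missing column(s): {missing}")
    out = table[["location"]].copy()
    out["vlw_discrepancy"] = (
        table["vlw_overall"] - table["vlw_t2dm"] - table["vlw_t1dm"]
    ).abs()
    out["share_discrepancy"] = (
        table["share_overall"] - table["share_t2dm"] - table["share_t1dm"]
    ).abs()
    out["within_tolerance"] = out["vlw_discrepancy"] <= vlw_tolerance
    out["share_within_tolerance"] = out["share_discrepancy"] <= share_tolerance
    return out


def consistency_report_from_results(
    results: pd.DataFrame, hierarchy: Hierarchy, **kwargs
) -> pd.DataFrame:
    """Cause-additivity report computed from country-level results."""
    return consistency_report(to_regional_table(results, hierarchy, ndigits=12), **kwargs)
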