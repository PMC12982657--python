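"""Domain types and tabular I/O for burden, macroeconomic and hierarchy data.

The package consumes three kinds of tables:

* **burden tables** — DALY counts with 95% uncertainty intervals (UIs) per
  location, year and diabetes cause, in the column dialect of public
  burden-of-disease results exports;
* **econ tables** — per-country macroeconomic series (GDP per capita and
  total GDP in PPP constant 2021 Int$, health-adjusted life expectancy,
  population), in wide (years as columns) or long layout;
* **hierarchy tables** — the country -> region -> SDI-quintile -> global
  location tree used for aggregation.

All tables are carried in memory as :class:`pandas.DataFrame` objects with
fixed column schemas (module-level ``*_COLUMNS`` constants). Money is carried
in plain Int$ throughout; conversion to millions happens only at reporting.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("vlwkit")

# ---------------------------------------------------------------------------
# Canonical vocabularies
# ---------------------------------------------------------------------------

#: Canonical cause codes used throughout the package.
CAUSE_OVERALL = "dm_overall"
CAUSE_T1DM = "t1dm"
CAUSE_T2DM = "t2dm"
CAUSES = (CAUSE_OVERALL, CAUSE_T1DM, CAUSE_T2DM)

#: Mapping from source cause labels to canonical codes (case-insensitive).
DEFAULT_CAUSE_MAP: Mapping[str, str] = {
    "diabetes mellitus": CAUSE_OVERALL,
    "diabetes mellitus type 1": CAUSE_T1DM,
    "diabetes mellitus type 2": CAUSE_T2DM,
    "dm_overall": CAUSE_OVERALL,
    "t1dm": CAUSE_T1DM,
    "t2dm": CAUSE_T2DM,
}

#: The five 5-year age bands spanning ages 15-39, plus the direct label.
AGE_BAND_LABEL = "15-39 years"
FIVE_YEAR_BANDS = (
    "15-19 years",
    "20-24 years",
    "25-29 years",
    "30-34 years",
    "35-39 years",
)

SDI_GROUPS = ("high", "high-middle", "middle", "low-middle", "low")

LEVEL_COUNTRY = "country"
LEVEL_REGION = "gbd_region"
LEVEL_SDI = "sdi_quintile"
LEVEL_GLOBAL = "global"
GLOBAL_ID = "Global"

BURDEN_COLUMNS = (
    "location_id",
    "year",
    "cause",
    "age_band",
    "dalys_val",
    "dalys_lower",
    "dalys_upper",
)

ECON_VARIABLES = ("gdp_pc", "gdp_total", "hale", "population")
ECON_COLUMNS = (
    "location_id",
    "year",
    "gdp_pc",
    "gdp_total",
    "hale",
    "population",
    "gdp_pc_imputed",
    "gdp_total_imputed",
    "hale_imputed",
)


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class ValidationError(ValueError):
    """Parsed rows violate a domain invariant (e.g. val outside its UI)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocationNode:
    """One node of the location tree.

    ``level`` is one of ``country``, ``gbd_region``, ``sdi_quintile`` or
    ``global``. Countries carry both a parent region and an SDI group;
    aggregate nodes carry neither.
    """

    location_id: str
    name: str
    level: str
    parent_region: str | None = None
    sdi_group: str | None = None

    def __post_init__(self) -> None:
        if self.level not in (LEVEL_COUNTRY, LEVEL_REGION, LEVEL_SDI, LEVEL_GLOBAL):
            raise ValidationError(f"unknown hierarchy level {self.level!r}")
        if self.level == LEVEL_COUNTRY:
            if not self.parent_region:
                raise ValidationError(f"country {self.location_id!r} lacks a region")
            if self.sdi_group not in SDI_GROUPS:
                raise ValidationError(
                    f"country {self.location_id!r} has invalid SDI group "
                    f"{self.sdi_group!r}"
                )


class Hierarchy:
    """Country -> region -> SDI-quintile -> global location tree.

    Supports lookup by id and by name (ids double as names here), membership
    queries per aggregate node, and emission of the canonical hierarchy CSV.
    """

    def __init__(self, nodes: Iterable[LocationNode]):
        self._nodes: dict[str, LocationNode] = {}
        for node in nodes:
            if node.location_id in self._nodes:
                raise ValidationError(f"duplicate location {node.location_id!r}")
            self._nodes[node.location_id] = node
        if GLOBAL_ID not in self._nodes:
            self._nodes[GLOBAL_ID] = LocationNode(GLOBAL_ID, GLOBAL_ID, LEVEL_GLOBAL)
        for region in self.regions():
            if not self.members(region):
                logger.warning("region %r has no member countries", region)

    def __contains__(self, location_id: str) -> bool:
        return location_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def get(self, location_id: str) -> LocationNode:
        try:
            return self._nodes[location_id]
        except KeyError:
            raise KeyError(f"unknown location {location_id!r}") from None

    def by_name(self, name: str) -> LocationNode:
        for node in self._nodes.values():
            if node.name == name:
                return node
        raise KeyError(f"no location named {name!r}")

    def countries(self) -> list[str]:
        return sorted(
            n.location_id for n in self._nodes.values() if n.level == LEVEL_COUNTRY
        )

    def regions(self) -> list[str]:
        return sorted(
            n.location_id for n in self._nodes.values() if n.level == LEVEL_REGION
        )

    def sdi_quintiles(self) -> list[str]:
        return sorted(
            n.location_id for n in self._nodes.values() if n.level == LEVEL_SDI
        )

    def members(self, aggregate_id: str) -> list[str]:
        """Country ids belonging to a region, SDI quintile, or the globe."""
        agg = self.get(aggregate_id)
        if agg.level == LEVEL_GLOBAL:
            return self.countries()
        if agg.level == LEVEL_REGION:
            return sorted(
                n.location_id
                for n in self._nodes.values()
                if n.level == LEVEL_COUNTRY and n.parent_region == aggregate_id
            )
        if agg.level == LEVEL_SDI:
            return sorted(
                n.location_id
                for n in self._nodes.values()
                if n.level == LEVEL_COUNTRY and n.sdi_group == agg.sdi_group
            )
        raise ValidationError(f"{aggregate_id!r} is a country, not an aggregate")

    def parent(self, country_id: str, level: str) -> str:
        """Aggregate id containing ``country_id`` at the requested level."""
        node = self.get(country_id)
        if node.level != LEVEL_COUNTRY:
            raise ValidationError(f"{country_id!r} is not a country")
        if level == LEVEL_REGION:
            return node.parent_region  # type: ignore[return-value]
        if level == LEVEL_SDI:
            return f"{node.sdi_group} SDI"
        if level == LEVEL_GLOBAL:
            return GLOBAL_ID
        raise ValidationError(f"unknown aggregation level {level!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "country": n.location_id,
                "gbd_region": n.parent_region,
                "sdi_quintile": n.sdi_group,
            }
            for n in self._nodes.values()
            if n.level == LEVEL_COUNTRY
        ]
        return pd.DataFrame(rows).sort_values("country").reset_index(drop=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ValuationParams:
    """Parameters of the benefit-transfer valuation.

    vsl_ref
        Reference value of a statistical life (default US 2021 estimate,
        11.8 million, in 2021 Int$).
    gdp_pc_ref
        Per-capita GDP of the reference country (PPP constant 2021 Int$).
    income_elasticity
        Exponent of the income ratio in the benefit transfer (1.0 =>
        VSL proportional to per-capita income). Sensitivity set: 0.55/1.0/1.5.
    fle_fraction
        Future life expectancy as a fraction of HALE (default one half).
    """

    vsl_ref: float = 11.8e6
    gdp_pc_ref: float = 1.0
    income_elasticity: float = 1.0
    fle_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (self.vsl_ref > 0 and self.gdp_pc_ref > 0 and self.fle_fraction > 0):
            raise ValidationError("valuation parameters must be strictly positive")
        if not (0.1 <= self.income_elasticity <= 3.0):
            raise ValidationError(
                f"income elasticity {self.income_elasticity} outside [0.1, 3.0]"
            )

    def with_elasticity(self, ie: float) -> "ValuationParams":
        return replace(self, income_elasticity=ie)


# ---------------------------------------------------------------------------
# Dialect configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GbdDialect:
    """Column dialect of a burden-of-disease results export.

    Defaults follow the public results-tool CSV header; exports vary, so
    every column name is configurable. ``measure_col`` may be absent from
    the file, in which case all rows are assumed to be DALY measures.
    """

    location_col: str = "location_name"
    year_col: str = "year"
    cause_col: str = "cause_name"
    metric_col: str = "metric_name"
    measure_col: str = "measure_name"
    age_col: str = "age_name"
    sex_col: str = "sex_name"
    val_col: str = "val"
    upper_col: str = "upper"
    lower_col: str = "lower"
    metric_keep: str = "Number"
    cause_map: Mapping[str, str] = field(default_factory=lambda: DEFAULT_CAUSE_MAP)
    age_bands: Sequence[str] = (AGE_BAND_LABEL,) + FIVE_YEAR_BANDS


@dataclass(frozen=True)
class WdiDialect:
    """Layout of a macroeconomic table.

    ``layout='long'`` expects columns location/year/variable/value;
    ``layout='wide'`` expects one row per location x variable with year
    columns, as development-indicator exports are shaped. Variable labels
    are mapped to the canonical names via ``variable_map``.
    """

    layout: str = "long"
    location_col: str = "location_name"
    year_col: str = "year"
    variable_col: str = "variable"
    value_col: str = "value"
    variable_map: Mapping[str, str] = field(
        default_factory=lambda: {v: v for v in ECON_VARIABLES}
    )

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide"):
            raise SchemaError(f"unknown econ layout {self.layout!r}")


def _normalize_age(label: str) -> str:
    # exports use hyphen, en-dash or "15 to 19"; fold them together
    s = str(label).strip().lower()
    s = s.replace("–", "-").replace("‐", "-").replace(" to ", "-")
    s = re.sub(r"\s+", " ", s)
    if not s.endswith("years"):
        s = f"{s} years"
    return s


_CANON_BANDS = {_normalize_age(b): b for b in (AGE_BAND_LABEL,) + FIVE_YEAR_BANDS}


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Burden reader / writer
# ---------------------------------------------------------------------------


def read_burden_table(
    path: str | Path, dialect: GbdDialect | None = None
) -> pd.DataFrame:
    """Read a burden CSV and return the canonical burden table.

    Keeps only rows with the configured count metric, the three diabetes
    causes and age bands inside 15-39; sums 5-year bands (and sexes, unless
    a combined-sex stratum is present) per (location, year, cause), with UI
    bounds summed bound-wise. Every dropped row is counted in the log.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If any point estimate lies outside its own uncertainty interval.
    """
    d = dialect or GbdDialect()
    raw = pd.read_csv(path)
    required = [d.location_col, d.year_col, d.cause_col, d.metric_col, d.age_col,
                d.val_col, d.upper_col, d.lower_col]
    _require_columns(raw, required, path)

    n0 = len(raw)
    if d.measure_col in raw.columns:
        keep = raw[d.measure_col].astype(str).str.contains("DALY", case=False)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("burden reader: dropped %d non-DALY measure rows", dropped)
        raw = raw[keep]

    keep = raw[d.metric_col].astype(str).str.strip() == d.metric_keep
    if (~keep).any():
        logger.info(
            "burden reader: dropped %d rows with metric != %r",
            int((~keep).sum()), d.metric_keep,
        )
    raw = raw[keep]

    cause_map = {k.lower(): v for k, v in d.cause_map.items()}
    cause = raw[d.cause_col].astype(str).str.strip().str.lower().map(cause_map)
    if cause.isna().any():
        unknown = raw.loc[cause.isna(), d.cause_col].unique()
        logger.info(
            "burden reader: ignored %d rows with unknown cause(s): %s",
            int(cause.isna().sum()), ", ".join(map(str, unknown[:5])),
        )
    raw = raw.assign(cause=cause).dropna(subset=["cause"])

    allowed = {_normalize_age(b) for b in d.age_bands}
    age = raw[d.age_col].map(_normalize_age)
    keep = age.isin(allowed)
    if (~keep).any():
        logger.info(
            "burden reader: dropped %d rows outside configured age bands",
            int((~keep).sum()),
        )
    raw = raw[keep].assign(age_band=age[keep].map(_CANON_BANDS))

    # sexes: prefer a combined stratum when present, else sum male + female
    if d.sex_col in raw.columns:
        sex = raw[d.sex_col].astype(str).str.strip().str.lower()
        if (sex == "both").any():
            n_dropped = int((sex != "both").sum())
            if n_dropped:
                logger.info(
                    "burden reader: dropped %d sex-specific rows in favour of "
                    "the combined stratum", n_dropped,
                )
            raw = raw[(sex == "both").to_numpy()]

    for col in (d.val_col, d.upper_col, d.lower_col):
        raw[col] = pd.to_numeric(raw[col], errors="raise")

    bad = raw[(raw[d.val_col] < raw[d.lower_col]) | (raw[d.val_col] > raw[d.upper_col])]
    if len(bad):
        detail = bad[[d.location_col, d.year_col, d.cause_col, d.age_col]].head(10)
        raise ValidationError(
            f"{len(bad)} row(s) with val outside [lower, upper]:\n{detail}"
        )
    if (raw[[d.val_col, d.lower_col, d.upper_col]] < 0).any().any():
        raise ValidationError("negative DALY counts in burden table")

    out = (
        raw.groupby([d.location_col, d.year_col, "cause"], as_index=False)
        .agg(
            dalys_val=(d.val_col, "sum"),
            dalys_lower=(d.lower_col, "sum"),
            dalys_upper=(d.upper_col, "sum"),
        )
        .rename(columns={d.location_col: "location_id", d.year_col: "year"})
    )
    out["year"] = out["year"].astype(int)
    out["age_band"] = AGE_BAND_LABEL
    out = out[list(BURDEN_COLUMNS)].sort_values(
        ["location_id", "year", "cause"], ignore_index=True
    )
    logger.info("burden reader: %d/%d raw rows -> %d records", len(raw), n0, len(out))
    return validate_burden(out)


def validate_burden(df: pd.DataFrame) -> pd.DataFrame:
    """Check burden-table invariants; returns the frame unchanged."""
    _require_columns(df, BURDEN_COLUMNS, "<burden table>")
    if df.duplicated(["location_id", "year", "cause"]).any():
        raise ValidationError("duplicate (location, year, cause) in burden table")
    if ((df["dalys_lower"] > df["dalys_val"]) | (df["dalys_val"] > df["dalys_upper"])).any():
        raise ValidationError("burden UI ordering violated (lower <= val <= upper)")
    if (df[["dalys_val", "dalys_lower", "dalys_upper"]] < 0).any().any():
        raise ValidationError("negative DALY counts")
    return df


def write_burden_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical long burden CSV (UTF-8, period decimals)."""
    validate_burden(df)[list(BURDEN_COLUMNS)].to_csv(path, index=False)


def read_canonical_burden(path: str | Path) -> pd.DataFrame:
    """Re-read a CSV produced by :func:`write_burden_table`."""
    df = pd.read_csv(path)
    _require_columns(df, BURDEN_COLUMNS, path)
    df["year"] = df["year"].astype(int)
    return validate_burden(df[list(BURDEN_COLUMNS)])


# ---------------------------------------------------------------------------
# Econ reader / writer
# ---------------------------------------------------------------------------


def read_econ_table(path: str | Path, dialect: WdiDialect | None = None) -> pd.DataFrame:
    """Read a macroeconomic CSV, wide or long, into the canonical econ table.

    Missing cells are preserved as NaN for downstream imputation; all
    ``*_imputed`` flags start False. Duplicate (location, year, variable)
    observations and non-numeric cells are errors.
    """
    d = dialect or WdiDialect()
    raw = pd.read_csv(path)

    if d.layout == "long":
        _require_columns(raw, [d.location_col, d.year_col, d.variable_col, d.value_col], path)
        long = raw.rename(
            columns={
                d.location_col: "location_id",
                d.year_col: "year",
                d.variable_col: "variable",
                d.value_col: "value",
            }
        )[["location_id", "year", "variable", "value"]]
    else:  # wide: one row per location x variable, year columns
        _require_columns(raw, [d.location_col, d.variable_col], path)
        year_cols = [c for c in raw.columns if re.fullmatch(r"\d{4}", str(c))]
        if not year_cols:
            raise SchemaError(f"{path}: wide layout but no 4-digit year columns found")
        long = raw.melt(
            id_vars=[d.location_col, d.variable_col],
            value_vars=year_cols,
            var_name="year",
            value_name="value",
        ).rename(columns={d.location_col: "location_id", d.variable_col: "variable"})

    vmap = {str(k).strip().lower(): v for k, v in d.variable_map.items()}
    var = long["variable"].astype(str).str.strip().str.lower().map(vmap)
    if var.isna().any():
        unknown = long.loc[var.isna(), "variable"].unique()
        logger.info(
            "econ reader: ignored %d rows with unknown variable(s): %s",
            int(var.isna().sum()), ", ".join(map(str, unknown[:5])),
        )
    long = long.assign(variable=var).dropna(subset=["variable"])
    long["year"] = long["year"].astype(int)

    blank = long["value"].astype(str).str.strip().isin(["", "..", "nan", "None"])
    long.loc[blank, "value"] = np.nan
    try:
        long["value"] = pd.to_numeric(long["value"], errors="raise")
    except (ValueError, TypeError):
        coerced = pd.to_numeric(long["value"], errors="coerce")
        bad = long[coerced.isna() & ~long["value"].isna()]
        row = bad.iloc[0]
        raise SchemaError(
            f"{path}: non-numeric cell {row['value']!r} at "
            f"location={row['location_id']!r} year={row['year']} "
            f"variable={row['variable']!r}"
        ) from None

    dup = long.duplicated(["location_id", "year", "variable"])
    if dup.any():
        rows = long[dup][["location_id", "year", "variable"]].head(5)
        raise ValidationError(f"duplicate location-year observations:\n{rows}")

    wide = (
        long.pivot(index=["location_id", "year"], columns="variable", values="value")
        .reset_index()
        .rename_axis(columns=None)
    )
    for v in ECON_VARIABLES:
        if v not in wide.columns:
            wide[v] = np.nan
    for v in ("gdp_pc", "gdp_total", "hale"):
        wide[f"{v}_imputed"] = False
    out = wide[list(ECON_COLUMNS)].sort_values(["location_id", "year"], ignore_index=True)
    return validate_econ(out)


def validate_econ(df: pd.DataFrame) -> pd.DataFrame:
    """Check econ-table invariants on observed (non-missing) cells."""
    _require_columns(df, ECON_COLUMNS, "<econ table>")
    if df.duplicated(["location_id", "year"]).any():
        raise ValidationError("duplicate location-year in econ table")
    for col in ("gdp_pc", "gdp_total"):
        vals = df[col].dropna()
        if (vals <= 0).any():
            raise ValidationError(f"non-positive {col} in econ table")
    hale = df["hale"].dropna()
    if ((hale <= 0) | (hale >= 120)).any():
        raise ValidationError("HALE outside (0, 120) years")
    have = df.dropna(subset=["gdp_pc", "gdp_total", "population"])
    # regression-imputed cells need not satisfy the accounting identity
    have = have[~(have["gdp_pc_imputed"] | have["gdp_total_imputed"])]
    if len(have):
        ratio = have["gdp_total"] / (have["gdp_pc"] * have["population"])
        if ((ratio - 1.0).abs() > 0.01).any():
            raise ValidationError(
                "gdp_total inconsistent with gdp_pc x population (>1% off)"
            )
    return df


def write_econ_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical long econ CSV (one row per location-year)."""
    validate_econ(df)[list(ECON_COLUMNS)].to_csv(path, index=False)


def read_canonical_econ(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ECON_COLUMNS, path)
    df["year"] = df["year"].astype(int)
    for col in ("gdp_pc_imputed", "gdp_total_imputed", "hale_imputed"):
        df[col] = df[col].astype(bool)
    return validate_econ(df[list(ECON_COLUMNS)])


def write_econ_long(df: pd.DataFrame, path: str | Path) -> None:
    """Write the econ table in the long (location/year/variable/value) reader
    dialect; missing cells are omitted (the reader restores them as NaN)."""
    validate_econ(df)
    long = df.melt(
        id_vars=["location_id", "year"],
        value_vars=list(ECON_VARIABLES),
        var_name="variable",
        value_name="value",
    ).dropna(subset=["value"])
    long = long.rename(columns={"location_id": "location_name"})
    long.sort_values(["location_name", "year", "variable"]).to_csv(path, index=False)


def write_econ_wide(df: pd.DataFrame, path: str | Path) -> None:
    """Write the econ table in the wide (years-as-columns) reader dialect."""
    validate_econ(df)
    long = df.melt(
        id_vars=["location_id"],
        value_vars=list(ECON_VARIABLES),
        var_name="variable",
        value_name="value",
        ignore_index=False,
    )
    long["year"] = df.loc[long.index, "year"]
    wide = long.pivot_table(
        index=["location_id", "variable"], columns="year", values="value",
        dropna=False,
    ).reset_index()
    wide.columns = [str(c) for c in wide.columns]
    wide = wide.rename(columns={"location_id": "location_name"})
    wide.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Hierarchy reader
# ---------------------------------------------------------------------------


def read_hierarchy(path: str | Path) -> Hierarchy:
    """Read a hierarchy CSV (columns country, gbd_region, sdi_quintile).

    Rows with a blank country but a named region declare an empty region
    (retained with a warning). A country with a missing region or SDI group,
    or listed twice, is an error.
    """
    raw = pd.read_csv(path)
    _require_columns(raw, ["country", "gbd_region", "sdi_quintile"], path)
    nodes: list[LocationNode] = []
    region_ids: set[str] = set()
    seen: set[str] = set()
    for _, row in raw.iterrows():
        country = row["country"]
        region = row["gbd_region"]
        sdi = row["sdi_quintile"]
        if pd.isna(country) or str(country).strip() == "":
            if not pd.isna(region):
                region_ids.add(str(region))
            continue
        country = str(country).strip()
        if country in seen:
            raise ValidationError(f"country {country!r} listed twice in {path}")
        seen.add(country)
        if pd.isna(region) or pd.isna(sdi):
            raise ValidationError(
                f"country {country!r} has missing region or SDI group"
            )
        sdi = str(sdi).strip().lower().replace(" sdi", "")
        if sdi not in SDI_GROUPS:
            raise ValidationError(f"country {country!r}: unknown SDI group {sdi!r}")
        region = str(region).strip()
        region_ids.add(region)
        nodes.append(LocationNode(country, country, LEVEL_COUNTRY, region, sdi))

    for region in sorted(region_ids):
        nodes.append(LocationNode(region, region, LEVEL_REGION))
    for sdi in SDI_GROUPS:
        nodes.append(LocationNode(f"{sdi} SDI", f"{sdi} SDI", LEVEL_SDI, None, sdi))
    nodes.append(LocationNode(GLOBAL_ID, GLOBAL_ID, LEVEL_GLOBAL))
    return Hierarchy(nodes)


def hierarchy_from_frame(df: pd.DataFrame) -> Hierarchy:
    """Build a :class:`Hierarchy` from an in-memory country table."""
    nodes = [
        LocationNode(
            str(r["country"]), str(r["country"]), LEVEL_COUNTRY,
            str(r["gbd_region"]), str(r["sdi_quintile"]),
        )
        for _, r in df.iterrows()
    ]
    regions = sorted({n.parent_region for n in nodes})  # type: ignore[arg-type]
    nodes += [LocationNode(r, r, LEVEL_REGION) for r in regions]
    nodes += [
        LocationNode(f"{s} SDI", f"{s} SDI", LEVEL_SDI, None, s) for s in SDI_GROUPS
    ]
    nodes.append(LocationNode(GLOBAL_ID, GLOBAL_ID, LEVEL_GLOBAL))
    return Hierarchy(nodes)


def _isclose(a: float, b: float, rel: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=rel, abs_tol=1e-12)
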