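"""Reading, validation and grouping of the three input tables.

Inputs are plain CSVs:

* a long country-year **panel** of smoker counts and population in two age
  bands (10-24 for initiation outcomes; 45-59, with former/ever counts,
  for cessation);
* a country **meta** table carrying the treaty ratification year, World
  Bank income group, the tobacco tax share of the most-sold cigarette
  brand in 2008 with its 2008-2012 percentage-point change, and a count of
  survey years (a data-quality proxy);
* groupings derived from the meta table: world (with configurable
  exclusions), the four income classes, or a high/low tax-change split.

Column names are configurable through a schema map because public exports
of the underlying prevalence data vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_YOUNG",
    "AGE_OLD",
    "INCOME_GROUPS",
    "DEFAULT_PANEL_SCHEMA",
    "DEFAULT_META_SCHEMA",
    "PanelValidationError",
    "CountryMeta",
    "GroupingScheme",
    "read_panel",
    "validate_panel",
    "read_meta",
    "classify_tax_change",
    "filter_quality",
    "build_grouping",
    "write_panel",
]

log = logging.getLogger("smokeitsa")

AGE_YOUNG = "10-24"
AGE_OLD = "45-59"
INCOME_GROUPS = ("high", "upper-middle", "lower-middle", "low")

DEFAULT_PANEL_SCHEMA = {
    "country_id": "country",
    "year": "year",
    "age_band": "age_band",
    "current_smokers": "smokers",
    "population": "population",
    "former_smokers": "former",
    "ever_smokers": "ever",
}

DEFAULT_META_SCHEMA = {
    "country_id": "country",
    "ratification_year": "ratification_year",
    "income_group": "income_group",
    "tax_share_2008": "tax_share_2008",
    "tax_change_pp": "tax_change_pp",
    "survey_years_count": "survey_years_count",
}


class PanelValidationError(ValueError):
    """Input rows violate the panel invariants; message lists offending rows."""


@dataclass(frozen=True)
class CountryMeta:
    """Per-country metadata required for grouping and filtering."""

    country_id: str
    ratification_year: int | None
    income_group: str
    tax_share_2008: float | None = None
    tax_change_pp: float | None = None
    survey_years_count: int = 0

    def __post_init__(self):
        if self.income_group not in INCOME_GROUPS:
            raise ValueError(
                f"{self.country_id}: income_group {self.income_group!r} not in {INCOME_GROUPS}"
            )


@dataclass
class GroupingScheme:
    """A named, fixed set of member countries (constant across event time)."""

    name: str
    members: frozenset[str]
    exclusions: dict[str, str] = field(default_factory=dict)


def _rename(df: pd.DataFrame, schema: dict[str, str], required: list[str]) -> pd.DataFrame:
    inverse = {v: k for k, v in schema.items()}
    missing = [schema[k] for k in required if schema[k] not in df.columns]
    if missing:
        raise PanelValidationError(f"missing required column(s): {missing}")
    return df.rename(columns=inverse)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the panel invariants, reporting offending row numbers.

    Invariants: counts non-negative; smokers <= population;
    former <= ever (45-59 rows); (country, year, age_band) unique.
    """
    df = panel.copy()
    problems: list[str] = []

    bad_band = df[~df["age_band"].isin([AGE_YOUNG, AGE_OLD])]
    if len(bad_band):
        problems.append(
            f"unknown age_band at rows {bad_band.index.tolist()[:10]} "
            f"(expected {AGE_YOUNG!r} or {AGE_OLD!r})"
        )

    for col in ("current_smokers", "population", "former_smokers", "ever_smokers"):
        vals = pd.to_numeric(df[col], errors="coerce") if col in df else None
        if vals is None:
            continue
        bad = df.index[(vals < 0)].tolist()
        if bad:
            problems.append(f"negative {col} at rows {bad[:10]}")
        df[col] = vals

    over = df.index[df["current_smokers"] > df["population"]].tolist()
    if over:
        problems.append(f"current_smokers > population at rows {over[:10]}")

    old = df[df["age_band"] == AGE_OLD]
    fe = old.index[old["former_smokers"] > old["ever_smokers"]].tolist()
    if fe:
        problems.append(f"former_smokers > ever_smokers at rows {fe[:10]}")

    dup = df.index[df.duplicated(subset=["country_id", "year", "age_band"], keep=False)].tolist()
    if dup:
        problems.append(f"duplicate (country, year, age_band) at rows {dup[:10]}")

    if problems:
        raise PanelValidationError("; ".join(problems))
    return df


def read_panel(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a long country-year panel CSV.

    Returns a frame with canonical column names (country_id, year, age_band,
    current_smokers, population, former_smokers, ever_smokers).
    """
    schema = {**DEFAULT_PANEL_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path)
    df = _rename(raw, schema, ["country_id", "year", "age_band", "current_smokers", "population"])
    for col in ("former_smokers", "ever_smokers"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(DEFAULT_PANEL_SCHEMA)]
    # former/ever are only defined for the older band; fill young rows with 0
    young = df["age_band"] == AGE_YOUNG
    df.loc[young, ["former_smokers", "ever_smokers"]] = (
        df.loc[young, ["former_smokers", "ever_smokers"]].fillna(0.0)
    )
    return validate_panel(df)


def write_panel(panel: pd.DataFrame, path, schema: dict[str, str] | None = None) -> None:
    """Write a validated panel back to CSV under the given schema's names."""
    schema = {**DEFAULT_PANEL_SCHEMA, **(schema or {})}
    panel.rename(columns=schema).to_csv(path, index=False)


def read_meta(path, schema: dict[str, str] | None = None) -> dict[str, CountryMeta]:
    """Read the country meta table (ratification year, income, tax, surveys)."""
    schema = {**DEFAULT_META_SCHEMA, **(schema or {})}
    df = _rename(pd.read_csv(path), schema, ["country_id", "income_group"])
    metas = {}
    for _, row in df.iterrows():
        ry = row.get("ratification_year")
        metas[row["country_id"]] = CountryMeta(
            country_id=row["country_id"],
            ratification_year=int(ry) if pd.notna(ry) else None,
            income_group=row["income_group"],
            tax_share_2008=float(row["tax_share_2008"])
            if pd.notna(row.get("tax_share_2008"))
            else None,
            tax_change_pp=float(row["tax_change_pp"])
            if pd.notna(row.get("tax_change_pp"))
            else None,
            survey_years_count=int(row.get("survey_years_count", 0) or 0),
        )
    return metas


def classify_tax_change(meta: CountryMeta, threshold_pp: float = 10.0) -> str:
    """'high' iff the tax share rose >= 10 percentage points (2008-2012).

    Decreases and sub-threshold increases are 'low'; countries without tax
    data are 'unclassified'.
    """
    if meta.tax_change_pp is None:
        return "unclassified"
    return "high" if meta.tax_change_pp >= threshold_pp else "low"


def filter_quality(metas: dict[str, CountryMeta], min_surveys: int = 10) -> set[str]:
    """Countries with strictly more than ``min_surveys`` survey years."""
    if min_surveys < 0:
        raise ValueError("min_surveys must be >= 0")
    return {c for c, m in metas.items() if m.survey_years_count > min_surveys}


def build_grouping(
    metas: dict[str, CountryMeta],
    scheme: str,
    *,
    exclude: tuple[str, ...] = ("CHN",),
    last_data_year: int = 2020,
    post_window: int = 10,
    tax_threshold_pp: float = 10.0,
    quality_only: bool = False,
    min_surveys: int = 10,
) -> list[GroupingScheme]:
    """Build fixed country groups under one of the grouping schemes.

    Schemes: ``world`` (all ratifiers minus ``exclude``), ``income`` (the
    four World Bank classes), ``tax`` (high/low tax change among classified
    countries), ``single`` (one group per country, for per-country runs).
    Countries without a ratification year, or ratifying too late for a full
    ``post_window`` within the data (year > last_data_year - post_window),
    are excluded with a recorded reason.
    """
    if scheme not in ("world", "income", "tax", "single"):
        raise ValueError(f"unknown grouping scheme {scheme!r}")

    exclusions: dict[str, str] = {}
    eligible: list[CountryMeta] = []
    cutoff = last_data_year - post_window
    quality = filter_quality(metas, min_surveys) if quality_only else None
    for country, m in sorted(metas.items()):
        if m.ratification_year is None:
            exclusions[country] = "no ratification year"
        elif m.ratification_year > cutoff:
            exclusions[country] = (
                f"ratified {m.ratification_year}, after {cutoff} "
                f"(no full {post_window}-year post period by {last_data_year})"
            )
        elif country in exclude:
            exclusions[country] = "configured exclusion"
        elif quality is not None and country not in quality:
            exclusions[country] = f"fewer than {min_surveys + 1} survey years"
        else:
            eligible.append(m)
    for country, reason in exclusions.items():
        log.info("excluded %s: %s", country, reason)

    def make(name: str, members) -> GroupingScheme:
        g = GroupingScheme(name=name, members=frozenset(members), exclusions=dict(exclusions))
        if not g.members:
            raise ValueError(f"grouping scheme {scheme!r}: group '{name}' is empty")
        return g

    if scheme == "world":
        return [make("world", (m.country_id for m in eligible))]
    if scheme == "income":
        return [
            make(inc, (m.country_id for m in eligible if m.income_group == inc))
            for inc in INCOME_GROUPS
        ]
    if scheme == "tax":
        groups = []
        for label in ("high", "low"):
            members = [
                m.country_id
                for m in eligible
                if classify_tax_change(m, tax_threshold_pp) == label
            ]
            groups.append(make(f"{label}-tax-change", members))
        return groups
    return [make(m.country_id, [m.country_id]) for m in eligible]
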