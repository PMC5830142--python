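"""Canonical city-table schema.

One row per prefecture-level city.  Outcomes are health-workforce densities
(licensed/assistant doctors and registered nurses per 10,000 residents),
the living-standards ranking variable is per-capita GDP, and the covariates
are the city's socio-economic characteristics plus categorical attributes
of its two leading officials (party secretary and mayor).  Mainland China
is conventionally split into seven geographical regions, which enter the
models as a 7-level categorical with East China as the reference.
"""

from __future__ import annotations

OUTCOME_COLUMNS: tuple[str, ...] = ("doctors_per_10k", "nurses_per_10k")

#: The living-standards variable used to rank cities.
RANKING_VARIABLE = "pergdp"

#: Continuous covariates, in canonical column order.  Units: persons/km^2,
#: km^2, 10^4 persons, yuan per capita, million yuan, %, %.
CONTINUOUS_COLUMNS: tuple[str, ...] = (
    "population_density",
    "geographical_size",
    "population_size",
    "pergdp",
    "revenue",
    "health_exp_share",
    "urbanization",
)

REGIONS: tuple[str, ...] = (
    "East China",
    "North China",
    "Central China",
    "South China",
    "Southwest China",
    "Northwest China",
    "Northeast China",
)

AGE_LEVELS: tuple[str, ...] = ("<=54", "55-59", ">=60")
SERVICE_LEVELS: tuple[str, ...] = ("<=30", "31-37", ">=38")
SEX_LEVELS: tuple[str, ...] = ("Men", "Women")
NATION_LEVELS: tuple[str, ...] = ("Han", "Minority")
EDUCATION_LEVELS: tuple[str, ...] = ("College and below", "Bachelor", "Master", "PhD")

#: Categorical columns and their fixed level sets (level order is the
#: reporting order; the first level is the conventional reference).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "region": REGIONS,
    "secretary_age": AGE_LEVELS,
    "secretary_service": SERVICE_LEVELS,
    "secretary_sex": SEX_LEVELS,
    "secretary_nation": NATION_LEVELS,
    "secretary_education": EDUCATION_LEVELS,
    "mayor_age": AGE_LEVELS,
    "mayor_service": SERVICE_LEVELS,
    "mayor_sex": SEX_LEVELS,
    "mayor_nation": NATION_LEVELS,
    "mayor_education": EDUCATION_LEVELS,
}

CATEGORICAL_COLUMNS: tuple[str, ...] = tuple(CATEGORICAL_LEVELS)

#: Full documented CSV column order.
CITY_COLUMNS: tuple[str, ...] = (
    ("city_id",) + OUTCOME_COLUMNS + CONTINUOUS_COLUMNS + CATEGORICAL_COLUMNS
)

#: Columns that must be strictly positive.
POSITIVE_COLUMNS: tuple[str, ...] = OUTCOME_COLUMNS + (RANKING_VARIABLE,)

#: Columns bounded to [0, 100] (percentages).
PERCENT_COLUMNS: tuple[str, ...] = ("health_exp_share", "urbanization")

NUMERIC_COLUMNS: tuple[str, ...] = OUTCOME_COLUMNS + CONTINUOUS_COLUMNS


def indicator_name(column: str, level: str) -> str:
    """Design-column name for the dummy marking ``column == level``."""
    return f"{column}={level}"


def parse_indicator(term: str) -> tuple[str, str] | None:
    """Inverse of :func:`indicator_name`; ``None`` if ``term`` is not a dummy."""
    if "=" not in term:
        return None
    column, level = term.split("=", 1)
    return column, level
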