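"""Data coverage index (DCI) over a binary availability matrix.

The matrix is indexed by country x entity (cause or risk) x period x
age-restriction flag.  ``dci_by_entity`` is the percentage of countries with
any input data per entity; ``dci_by_country`` the percentage of entities
with any data per country; ``dci_gap`` contrasts all-ages coverage with
coverage restricted to ages >= 70.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

AGE_FLAG_ALL = "all-ages"
AGE_FLAG_70PLUS = "aged-70-plus"

REQUIRED_COLUMNS = ("country", "entity", "entity_type", "period", "age_flag", "has_data")


@dataclass
class CoverageMatrix:
    data: pd.DataFrame
    countries: list[str] = field(init=False)
    entities: list[str] = field(init=False)
    periods: list[str] = field(init=False)
    age_flags: list[str] = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"coverage frame missing columns: {missing}")
        vals = set(self.data["has_data"].unique())
        if not vals <= {0, 1}:
            raise ValueError(f"has_data must be binary 0/1, found {sorted(vals - {0, 1})}")
        self.countries = sorted(self.data["country"].unique())
        self.entities = sorted(self.data["entity"].unique())
        self.periods = sorted(self.data["period"].unique())
        self.age_flags = sorted(self.data["age_flag"].unique())
        for name, axis in (
            ("country", self.countries),
            ("entity", self.entities),
            ("period", self.periods),
            ("age_flag", self.age_flags),
        ):
            if not axis:
                raise ValueError(f"axis {name} is empty")

    def _slice(self, period: str, age_flag: str) -> pd.DataFrame:
        sub = self.data[(self.data["period"] == period) & (self.data["age_flag"] == age_flag)]
        if sub.empty:
            raise ValueError(f"empty slice for period={period!r}, age_flag={age_flag!r}")
        # full country x entity grid; absent cells count as no data
        grid = (
            sub.pivot_table(index="country", columns="entity", values="has_data",
                            aggfunc="max", fill_value=0)
            .reindex(index=self.countries, columns=self.entities, fill_value=0)
        )
        return grid.astype(int)

    def transposed(self) -> "CoverageMatrix":
        swapped = self.data.rename(columns={"country": "entity", "entity": "country"})
        return CoverageMatrix(swapped)


def dci_by_entity(m: CoverageMatrix, period: str, age_flag: str) -> pd.Series:
    """Per-entity (cause or risk) percentage of countries with any input data."""
    grid = m._slice(period, age_flag)
    return (100.0 * grid.mean(axis=0)).rename("dci")


# cause/risk is the entity axis
dci_by_cause = dci_by_entity


def dci_by_country(m: CoverageMatrix, period: str, age_flag: str) -> pd.Series:
    """Per-country percentage of entities with any input data."""
    grid = m._slice(period, age_flag)
    return (100.0 * grid.mean(axis=1)).rename("dci")


def dci_gap(m: CoverageMatrix, period: str, by: str = "entity") -> pd.Series:
    """All-ages DCI minus aged-70-plus DCI, per entity or per country.

    Positive values flag entities (or countries) whose older-age data are
    scarcer than their all-ages data.
    """
    if AGE_FLAG_ALL not in m.age_flags or AGE_FLAG_70PLUS not in m.age_flags:
        raise ValueError(
            f"both age flags {AGE_FLAG_ALL!r} and {AGE_FLAG_70PLUS!r} are required"
        )
    fn = {"entity": dci_by_entity, "cause": dci_by_entity, "country": dci_by_country}.get(by)
    if fn is None:
        raise ValueError(f"by must be 'entity'/'cause' or 'country', got {by!r}")
    all_ages = fn(m, period, AGE_FLAG_ALL)
    older = fn(m, period, AGE_FLAG_70PLUS)
    return (all_ages - older).rename("dci_gap")
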