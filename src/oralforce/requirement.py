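"""FTE provider requirement from need rates, population counts and service times.

Per planning year the model multiplies each stratum's per-capita visit
rates (held constant over the horizon) by the stratum's population to get
total visits by type, weights visits by an assumed chair time per visit
type, sums to total service minutes, and divides by the annual clinical
minutes of one full-time practitioner to express the requirement in FTE
practitioners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .need import AGE_BANDS, SEXES, VISIT_TYPES, NeedRates

logger = logging.getLogger(__name__)

POPULATION_COLUMNS = ("year", "sex", "age_band", "persons")


@dataclass(frozen=True)
class ServiceTimes:
    """Assumed chair time per visit, minutes, by visit type."""

    minutes_checkup: float = 20.0
    minutes_routine: float = 30.0
    minutes_emergency: float = 40.0

    def __post_init__(self) -> None:
        for name in ("minutes_checkup", "minutes_routine", "minutes_emergency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.minutes_checkup, self.minutes_routine, self.minutes_emergency],
            index=list(VISIT_TYPES),
            name="minutes_per_visit",
        )


@dataclass(frozen=True)
class CapacityParams:
    """Annual clinical capacity of one full-time practitioner.

    ``weeks_per_year`` working weeks of ``hours_per_week`` hours, of which
    ``clinical_time_fraction`` is spent with patients.  ``adult_care_share``
    discounts the capacity available to the modelled adult population when
    part of a practitioner's time goes to patients outside it (children);
    1.0 means all clinical time serves the modelled population.
    """

    weeks_per_year: float = 45.0
    hours_per_week: float = 39.0
    clinical_time_fraction: float = 0.90
    adult_care_share: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.weeks_per_year <= 52:
            raise ValueError(f"weeks_per_year must be in (0, 52], got {self.weeks_per_year!r}")
        if self.hours_per_week <= 0:
            raise ValueError(f"hours_per_week must be > 0, got {self.hours_per_week!r}")
        for name in ("clinical_time_fraction", "adult_care_share"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")


def annual_capacity_minutes(params: CapacityParams) -> float:
    """Clinical minutes one FTE practitioner devotes to the modelled
    population per year; full precision, no intermediate rounding."""
    return (
        params.weeks_per_year
        * params.hours_per_week
        * params.clinical_time_fraction
        * params.adult_care_share
        * 60.0
    )


def validate_population(population: pd.DataFrame) -> pd.DataFrame:
    """Check a population table (year, sex, age_band, persons) is complete:
    every year covers all eight sex x age-band strata with counts >= 0."""
    missing = [c for c in POPULATION_COLUMNS if c not in population.columns]
    if missing:
        raise ConfigurationError(f"population table lacks column(s) {missing}")
    df = population.copy()
    bad_band = ~df["age_band"].isin(AGE_BANDS)
    if bad_band.any():
        raise ConfigurationError(
            f"unknown age band label(s) {sorted(df.loc[bad_band, 'age_band'].unique())}; "
            f"expected {list(AGE_BANDS)}"
        )
    if ~df["sex"].isin(SEXES).all():
        raise ConfigurationError("population sex codes must be 'female'/'male'")
    if (df["persons"] < 0).any():
        raise ConfigurationError("population counts must be >= 0")
    counts = df.groupby("year").size()
    short = counts[counts != len(SEXES) * len(AGE_BANDS)]
    if not short.empty:
        raise ConfigurationError(
            f"population years {list(short.index)} do not cover all "
            f"{len(SEXES) * len(AGE_BANDS)} sex x age-band strata"
        )
    return df


def population_for_year(population: pd.DataFrame, year: int) -> pd.Series:
    """Persons per (sex, age_band) stratum in ``year``.

    Years between provided table years are linearly interpolated per
    stratum; years outside the provided range raise, because silent
    extrapolation of projections is never safe.
    """
    df = validate_population(population)
    years = np.sort(df["year"].unique())
    if year < years[0] or year > years[-1]:
        raise ConfigurationError(
            f"year {year} outside the population table range {years[0]}-{years[-1]}; "
            "extrapolation is not supported"
        )
    wide = df.pivot_table(index=["sex", "age_band"], columns="year", values="persons")
    if year in wide.columns:
        out = wide[year]
    else:
        y0 = years[years < year].max()
        y1 = years[years > year].min()
        t = (year - y0) / (y1 - y0)
        out = wide[y0] * (1 - t) + wide[y1] * t
    out.name = "persons"
    return out


def total_visits(rates: NeedRates, population: pd.DataFrame, year: int) -> pd.DataFrame:
    """Annual visits by stratum and visit type: persons x per-capita rate.

    Rates are held constant across years; a populated stratum without a
    defined rate is a configuration error (pool or zero-fill explicitly
    upstream).
    """
    persons = population_for_year(population, year)
    table = rates.table.reindex(persons.index)
    populated = persons > 0
    undefined = populated & ~table["defined"].fillna(False).astype(bool)
    if undefined.any():
        raise ConfigurationError(
            f"populated strata without a defined need rate: "
            f"{list(persons.index[undefined])}; pool or zero-fill explicitly"
        )
    visits = table[list(VISIT_TYPES)].multiply(persons, axis=0).fillna(0.0)
    visits.index = persons.index
    return visits


def service_minutes(visits: pd.DataFrame | pd.Series, times: ServiceTimes) -> float:
    """Total service minutes for a visit table (or per-type visit vector)."""
    per_type = visits.sum(axis=0) if isinstance(visits, pd.DataFrame) else visits
    per_type = pd.Series(per_type).reindex(list(VISIT_TYPES))
    if per_type.isna().any():
        raise ValueError(f"visits must cover visit types {list(VISIT_TYPES)}")
    if (per_type < 0).any():
        raise ValueError("visit counts must be >= 0")
    return float((per_type * times.as_series()).sum())


def fte_requirement(total_minutes: float, capacity_minutes: float) -> float:
    """FTE practitioners needed to deliver ``total_minutes`` in a year."""
    if capacity_minutes <= 0:
        raise ValueError(f"capacity must be > 0 minutes/FTE/yr, got {capacity_minutes!r}")
    if total_minutes < 0:
        raise ValueError(f"total_minutes must be >= 0, got {total_minutes!r}")
    return total_minutes / capacity_minutes


def requirement_for_year(
    rates: NeedRates,
    population: pd.DataFrame,
    year: int,
    times: ServiceTimes,
    capacity: CapacityParams,
) -> float:
    """FTE requirement in one year: visits -> minutes -> FTE."""
    visits = total_visits(rates, population, year)
    minutes = service_minutes(visits, times)
    return fte_requirement(minutes, annual_capacity_minutes(capacity))
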