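"""Provider-supply side of the workforce planning model.

The supply component tracks the headcount *stock* of licensed practitioners
through an annual stock-flow recursion:

    stock(t) = stock(t-1) + inflows(t) + graduates(t) - outflows(t)

where inflows cover foreign-trained entrants, nationals returning from
abroad and returns from a career break; outflows cover emigration, career
breaks/absence and retirement or death in service; and graduates(t) is the
domestically trained cohort becoming available for work in year t.

Headcount is then converted to full-time-equivalent (FTE) supply with two
multipliers: a *participation rate* (the share of registrants actively
delivering clinical care — registers include academics and the retired) and
an *activity rate* (the average fraction of full-time hours worked across
the active workforce, reflecting part-time practice).

Flow assumptions for future years can be approximated by diffing two
consecutive annual register snapshots: registrants present only in the
later snapshot are inflows (classified by qualification origin and year),
registrants present only in the earlier one are outflows.

All headcounts are carried as floats at full precision; rounding to whole
practitioners happens only in the reporting layer.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

QUALIFICATION_ORIGINS = ("domestic", "foreign")
PRACTICE_STATUSES = ("general_practice", "excluded")

#: Years since qualification beyond which a de-registered practitioner is
#: presumed retired (a practitioner qualifying at ~24 is then >= 65).
RETIREMENT_YEARS_SINCE_QUALIFICATION = 41


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# parameter types


@dataclass(frozen=True)
class SupplyParams:
    """Participation and part-time profile converting stock to FTE supply.

    ``participation_rate`` is the fraction of registrants actively treating
    patients.  ``part_time_share`` of the active workforce works
    ``part_time_hours_fraction`` of full-time hours; together they imply the
    activity rate ``(1 - share) + share * hours_fraction``.
    """

    participation_rate: float = 0.95
    part_time_share: float = 0.30
    part_time_hours_fraction: float = 0.50

    def __post_init__(self) -> None:
        _check_fraction("participation_rate", self.participation_rate)
        _check_fraction("part_time_share", self.part_time_share)
        _check_fraction("part_time_hours_fraction", self.part_time_hours_fraction)

    @property
    def activity_rate(self) -> float:
        return activity_rate(self.part_time_share, self.part_time_hours_fraction)


@dataclass(frozen=True)
class GraduatePipeline:
    """Undergraduate training pipeline producing the yearly graduate inflow.

    ``intake_places`` first-year places are discounted for non-progression
    into year 2 and attrition thereafter, then for the share of graduates
    taking up domestic employment.  The cohort entering in year ``y``
    arrives in the stock at the end of year ``y + course_length``.
    """

    intake_places: float
    nonprogression_y2: float = 0.0
    attrition_rate: float = 0.0
    domestic_employment_share: float = 1.0
    course_length: int = 5

    def __post_init__(self) -> None:
        if self.intake_places < 0:
            raise ValueError(f"intake_places must be >= 0, got {self.intake_places!r}")
        _check_fraction("nonprogression_y2", self.nonprogression_y2)
        _check_fraction("attrition_rate", self.attrition_rate)
        _check_fraction("domestic_employment_share", self.domestic_employment_share)
        if self.course_length < 1:
            raise ValueError(f"course_length must be >= 1, got {self.course_length!r}")


@dataclass(frozen=True)
class FlowAssumptions:
    """Annual headcount flows, all components non-negative.

    A single instance describes one calendar year; :func:`project_stock`
    accepts a per-year mapping with carry-forward of the last specified
    year's values.
    """

    inflow_foreign_trained: float = 0.0
    inflow_returning_domestic: float = 0.0
    inflow_return_from_absence: float = 0.0
    outflow_emigration: float = 0.0
    outflow_absence: float = 0.0
    outflow_retirement_death: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "inflow_foreign_trained",
            "inflow_returning_domestic",
            "inflow_return_from_absence",
            "outflow_emigration",
            "outflow_absence",
            "outflow_retirement_death",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")

    @property
    def total_inflow(self) -> float:
        return (
            self.inflow_foreign_trained
            + self.inflow_returning_domestic
            + self.inflow_return_from_absence
        )

    @property
    def total_outflow(self) -> float:
        return (
            self.outflow_emigration + self.outflow_absence + self.outflow_retirement_death
        )

    @property
    def net(self) -> float:
        return self.total_inflow - self.total_outflow


# ---------------------------------------------------------------------------
# register snapshots


@dataclass(frozen=True)
class RegisterEntry:
    """One row of an annual practitioner register."""

    registrant_id: str
    date_registered: datetime.date
    year_qualified: int
    qualification_origin: str = "domestic"
    practice_status: str = "general_practice"

    def __post_init__(self) -> None:
        if self.qualification_origin not in QUALIFICATION_ORIGINS:
            raise ValueError(
                f"qualification_origin must be one of {QUALIFICATION_ORIGINS}, "
                f"got {self.qualification_origin!r}"
            )
        if self.practice_status not in PRACTICE_STATUSES:
            raise ValueError(
                f"practice_status must be one of {PRACTICE_STATUSES}, "
                f"got {self.practice_status!r}"
            )
        if self.year_qualified > self.date_registered.year:
            raise ValueError(
                f"year_qualified {self.year_qualified} is after registration year "
                f"{self.date_registered.year} for {self.registrant_id!r}"
            )


@dataclass(frozen=True)
class RegisterSnapshot:
    """The register as of the end of ``as_of_year``; registrant ids unique."""

    as_of_year: int
    entries: tuple[RegisterEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.registrant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate registrant_id(s) in snapshot: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def by_id(self) -> dict[str, RegisterEntry]:
        return {e.registrant_id: e for e in self.entries}


@dataclass(frozen=True)
class FlowEstimate:
    """Flows inferred from diffing two register snapshots.

    Inflows are classified from register attributes; outflow subtypes
    (emigration vs absence vs retirement) are not identifiable from the
    register alone, so removals are reported as a single unclassified count,
    optionally with a years-since-qualification retirement estimate split
    out of it.
    """

    earlier_year: int
    later_year: int
    n_earlier: int
    n_later: int
    inflow_new_graduates: int
    inflow_foreign_trained: int
    inflow_returning_domestic: int
    outflow_unclassified: int
    outflow_retirement_estimate: int = 0

    @property
    def total_inflow(self) -> int:
        return (
            self.inflow_new_graduates
            + self.inflow_foreign_trained
            + self.inflow_returning_domestic
        )

    @property
    def total_outflow(self) -> int:
        return self.outflow_unclassified + self.outflow_retirement_estimate

    def to_flow_assumptions(self) -> FlowAssumptions:
        """Non-graduate flows as projection assumptions (graduates come from
        the pipeline; unclassified outflow is booked under absence)."""
        return FlowAssumptions(
            inflow_foreign_trained=self.inflow_foreign_trained,
            inflow_returning_domestic=self.inflow_returning_domestic,
            outflow_absence=self.outflow_unclassified,
            outflow_retirement_death=self.outflow_retirement_estimate,
        )


# ---------------------------------------------------------------------------
# operations


def activity_rate(part_time_share: float, part_time_hours_fraction: float) -> float:
    """Average fraction of full-time hours worked across the workforce.

    With a share ``s`` of practitioners working ``f`` of full-time hours and
    the rest full-time, the activity rate is ``(1 - s) + s * f``.

    >>> activity_rate(0.30, 0.50)
    0.85
    """
    _check_fraction("part_time_share", part_time_share)
    _check_fraction("part_time_hours_fraction", part_time_hours_fraction)
    return (1.0 - part_time_share) + part_time_share * part_time_hours_fraction


def new_graduates(pipeline: GraduatePipeline) -> float:
    """Graduates available for domestic work from one entry cohort.

    ``intake x (1 - nonprogression_y2) x (1 - attrition) x domestic_share``;
    fractional headcounts are kept.
    """
    return (
        pipeline.intake_places
        * (1.0 - pipeline.nonprogression_y2)
        * (1.0 - pipeline.attrition_rate)
        * pipeline.domestic_employment_share
    )


def graduate_arrival_year(pipeline: GraduatePipeline, cohort_year: int) -> int:
    """Year in which the cohort entering in ``cohort_year`` joins the stock."""
    return cohort_year + pipeline.course_length


def diff_registers(
    earlier: RegisterSnapshot,
    later: RegisterSnapshot,
    retirement_heuristic: bool = False,
) -> FlowEstimate:
    """Estimate annual flows by comparing two register snapshots.

    Entries only in ``later`` are inflows: foreign-qualified registrants are
    foreign-trained inflow; domestically qualified registrants whose
    qualification year falls after the earlier snapshot are the new-graduate
    inflow; the remainder are returning domestic registrants.  Entries only
    in ``earlier`` are outflows, unclassifiable from the register alone;
    with ``retirement_heuristic`` those qualified at least
    ``RETIREMENT_YEARS_SINCE_QUALIFICATION`` years before the later snapshot
    are counted as presumed retirements.

    Conservation holds by construction:
    ``n_later == n_earlier + total_inflow - total_outflow``.
    """
    if earlier.as_of_year >= later.as_of_year:
        raise ValueError(
            f"earlier snapshot year {earlier.as_of_year} must precede "
            f"later snapshot year {later.as_of_year}"
        )
    earlier_ids = earlier.by_id()
    later_ids = later.by_id()

    grads = foreign = returning = 0
    for rid in later_ids.keys() - earlier_ids.keys():
        entry = later_ids[rid]
        if entry.qualification_origin == "foreign":
            foreign += 1
        elif entry.year_qualified > earlier.as_of_year:
            grads += 1
        else:
            returning += 1

    removed = [earlier_ids[rid] for rid in earlier_ids.keys() - later_ids.keys()]
    retired = 0
    if retirement_heuristic:
        retired = sum(
            1
            for e in removed
            if later.as_of_year - e.year_qualified >= RETIREMENT_YEARS_SINCE_QUALIFICATION
        )
    return FlowEstimate(
        earlier_year=earlier.as_of_year,
        later_year=later.as_of_year,
        n_earlier=len(earlier),
        n_later=len(later),
        inflow_new_graduates=grads,
        inflow_foreign_trained=foreign,
        inflow_returning_domestic=returning,
        outflow_unclassified=len(removed) - retired,
        outflow_retirement_estimate=retired,
    )


def resolve_flows(
    flows: Mapping[int, FlowAssumptions] | FlowAssumptions | None, year: int
) -> FlowAssumptions:
    """Flow assumptions applying in ``year``, carrying the last specified
    year's values forward when ``year`` itself is not listed."""
    if flows is None or (not isinstance(flows, FlowAssumptions) and len(flows) == 0):
        return FlowAssumptions()
    if isinstance(flows, FlowAssumptions):
        return flows
    specified = sorted(y for y in flows if y <= year)
    if not specified:
        raise ConfigurationError(
            f"no flow assumptions specified for year {year} or any earlier year; "
            "carry-forward needs at least one year at or before the horizon start"
        )
    return flows[specified[-1]]


def project_stock(
    initial_stock: float,
    flows: Mapping[int, FlowAssumptions] | FlowAssumptions | None,
    pipeline: GraduatePipeline | None,
    horizon: Iterable[int],
) -> pd.Series:
    """Project the end-of-year practitioner stock over a planning horizon.

    ``initial_stock`` is the stock at the end of the year preceding the
    first horizon year.  Each horizon year applies the stock-flow recursion;
    under a constant pipeline a full graduate cohort arrives every year.
    The stock is floored at zero (with a logged warning) if outflows exceed
    it.  Returns a series of end-of-year stock indexed by year.
    """
    years = list(horizon)
    if not years:
        raise ValueError("horizon must be non-empty")
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("horizon years must be contiguous and ascending")
    if initial_stock < 0:
        raise ValueError(f"initial_stock must be >= 0, got {initial_stock!r}")

    graduates = new_graduates(pipeline) if pipeline is not None else 0.0
    stock = float(initial_stock)
    out = []
    for year in years:
        f = resolve_flows(flows, year)
        stock = stock + f.total_inflow + graduates - f.total_outflow
        if stock < 0:
            logger.warning(
                "projected stock fell below zero in %d (%.2f); flooring at 0", year, stock
            )
            stock = 0.0
        out.append(stock)
    return pd.Series(out, index=pd.Index(years, name="year"), name="end_of_year_stock")


def fte_supply(stock: float, params: SupplyParams) -> float:
    """FTE provider supply: stock x participation rate x activity rate."""
    if stock < 0:
        raise ValueError(f"stock must be >= 0, got {stock!r}")
    return stock * params.participation_rate * params.activity_rate
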