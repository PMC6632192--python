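"""Supply-vs-requirement projection over the planning horizon, with scenarios.

A projection run composes the other modules year by year: the stock-flow
recursion gives the end-of-year practitioner stock, participation and
activity rates give FTE supply, and the need rates applied to the year's
population give FTE requirement; the headline output is the ratio of FTE
supply to FTE requirement per year.

Scenario analyses re-run the projection under named partial parameter
overrides (dotted paths into the baseline parameter set) without ever
mutating the baseline, so a baseline re-run after any number of scenarios
is bit-for-bit identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .need import NeedRates
from .requirement import (
    CapacityParams,
    ServiceTimes,
    annual_capacity_minutes,
    fte_requirement,
    service_minutes,
    total_visits,
)
from .supply import FlowAssumptions, GraduatePipeline, SupplyParams, fte_supply, project_stock

DEFAULT_HORIZON = (2017, 2050)

RESULT_COLUMNS = ("year", "stock", "fte_supply", "fte_requirement", "ratio")


@dataclass(frozen=True)
class ModelParams:
    """Complete baseline parameter set for one projection run."""

    service_times: ServiceTimes = field(default_factory=ServiceTimes)
    capacity: CapacityParams = field(default_factory=CapacityParams)
    supply: SupplyParams = field(default_factory=SupplyParams)
    pipeline: GraduatePipeline | None = None
    flows: Mapping[int, FlowAssumptions] = field(default_factory=dict)
    initial_stock: float = 3053.0
    horizon: tuple[int, int] = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        start, end = self.horizon
        if end < start:
            raise ConfigurationError(f"horizon end {end} precedes start {start}")
        object.__setattr__(self, "flows", dict(self.flows))

    @property
    def years(self) -> range:
        return range(self.horizon[0], self.horizon[1] + 1)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named set of parameter overrides applied to a baseline run.

    Override keys are dotted paths into :class:`ModelParams`, e.g.
    ``service_times.minutes_emergency`` or ``capacity.adult_care_share``;
    per-year flow components use ``flows.<year>.<component>``.
    """

    name: str
    overrides: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("scenario name must be non-empty")
        object.__setattr__(self, "overrides", dict(self.overrides))


def _replace_field(obj, field_name: str, value, path: str):
    if obj is None or field_name not in {f.name for f in dataclasses.fields(obj)}:
        raise ConfigurationError(f"unknown override path {path!r}")
    return replace(obj, **{field_name: value})


def apply_overrides(baseline: ModelParams, spec: ScenarioSpec) -> ModelParams:
    """Baseline with the scenario's overrides applied; baseline untouched.

    Unknown paths are rejected by name so a typo never silently runs the
    baseline under a scenario label.
    """
    params = replace(baseline, flows=dict(baseline.flows))
    top_fields = {f.name for f in dataclasses.fields(ModelParams)}
    for path, value in spec.overrides.items():
        parts = path.split(".")
        if parts[0] not in top_fields:
            raise ConfigurationError(f"unknown override path {path!r}")
        if len(parts) == 1:
            if parts[0] == "horizon":
                value = tuple(value)  # type: ignore[arg-type]
            params = replace(params, **{parts[0]: value})
        elif parts[0] == "flows":
            if len(parts) != 3:
                raise ConfigurationError(
                    f"flow overrides use 'flows.<year>.<component>', got {path!r}"
                )
            year = int(parts[1])
            flows = dict(params.flows)
            base_flow = flows.get(year, FlowAssumptions())
            flows[year] = _replace_field(base_flow, parts[2], value, path)
            params = replace(params, flows=flows)
        elif len(parts) == 2:
            sub = getattr(params, parts[0])
            params = replace(params, **{parts[0]: _replace_field(sub, parts[1], value, path)})
        else:
            raise ConfigurationError(f"unknown override path {path!r}")
    return params


def run_projection(
    params: ModelParams,
    rates: NeedRates,
    population: pd.DataFrame,
) -> pd.DataFrame:
    """Run the full comparison for every year of the horizon.

    Returns a frame with columns year, stock, fte_supply, fte_requirement
    and ratio.  The ratio is computed from the unrounded FTE figures and is
    NaN (flagged, not zero) in any year with zero requirement.
    """
    years = list(params.years)
    stock = project_stock(params.initial_stock, params.flows, params.pipeline, years)
    capacity = annual_capacity_minutes(params.capacity)

    rows = []
    for year in years:
        try:
            visits = total_visits(rates, population, year)
            minutes = service_minutes(visits, params.service_times)
            req = fte_requirement(minutes, capacity)
        except (ConfigurationError, ValueError) as exc:
            raise ConfigurationError(f"requirement failed for year {year}: {exc}") from exc
        sup = fte_supply(float(stock.loc[year]), params.supply)
        ratio = sup / req if req > 0 else float("nan")
        rows.append((year, float(stock.loc[year]), sup, req, ratio))
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def compare_scenarios(
    params: ModelParams,
    specs: Sequence[ScenarioSpec],
    rates: NeedRates,
    population: pd.DataFrame,
    baseline_name: str = "baseline",
) -> pd.DataFrame:
    """Baseline plus each scenario as one tidy long table.

    Scenarios are independent: each starts from the untouched baseline, so
    the table content does not depend on their order.
    """
    names = [baseline_name] + [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate scenario name(s): {dupes}")
    frames = []
    for name, run_params in [(baseline_name, params)] + [
        (s.name, apply_overrides(params, s)) for s in specs
    ]:
        result = run_projection(run_params, rates, population)
        result.insert(0, "scenario", name)
        frames.append(result)
    return pd.concat(frames, ignore_index=True)


def reference_scenarios() -> list[ScenarioSpec]:
    """The three standard sensitivity scenarios around the baseline:
    longer chair times (30/40/60 min), a 20% child-care time share
    (capacity scaled to 80%), and both combined."""
    times = {
        "service_times.minutes_checkup": 30.0,
        "service_times.minutes_routine": 40.0,
        "service_times.minutes_emergency": 60.0,
    }
    hours = {"capacity.adult_care_share": 0.8}
    return [
        ScenarioSpec("adjusted_service_times", times),
        ScenarioSpec("reduced_adult_hours", hours),
        ScenarioSpec("combined", {**times, **hours}),
    ]
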