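"""Run configuration: one YAML/JSON file describing a full model run.

Every parameter defaults to the reference baseline (service times 20/30/40
minutes; 45 working weeks of 39 hours with 90% clinical time; participation
95%; 30% part-time at 50% hours; horizon 2017-2050), so an empty config is
a valid baseline run.  Loading validates every value against the type
invariants of the parameter classes and names the offending key on failure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError
from .need import DEFAULT_FREQUENCY_MAPPING
from .projection import DEFAULT_HORIZON, ModelParams, ScenarioSpec
from .requirement import CapacityParams, ServiceTimes
from .supply import FlowAssumptions, GraduatePipeline, SupplyParams

_TOP_LEVEL_KEYS = {
    "inputs",
    "frequency_mapping",
    "use_weights",
    "service_times",
    "capacity",
    "supply",
    "pipeline",
    "flows",
    "initial_stock",
    "horizon",
    "scenarios",
    "seed",
    "output_dir",
    "synth",
}

_INPUT_KEYS = {"survey", "population", "register_earlier", "register_later", "need_rates"}
_SYNTH_KEYS = {"n_survey", "register_size"}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    params: ModelParams = field(default_factory=ModelParams)
    frequency_mapping: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_MAPPING)
    )
    use_weights: bool = False
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    inputs: dict[str, Path] = field(default_factory=dict)
    seed: int = 0
    output_dir: Path = Path("oralforce_out")
    n_survey: int = 5000
    register_size: int = 3053

    def to_dict(self) -> dict:
        p = self.params
        return {
            "inputs": {k: str(v) for k, v in sorted(self.inputs.items())},
            "frequency_mapping": dict(self.frequency_mapping),
            "use_weights": self.use_weights,
            "service_times": dataclasses.asdict(p.service_times),
            "capacity": dataclasses.asdict(p.capacity),
            "supply": dataclasses.asdict(p.supply),
            "pipeline": dataclasses.asdict(p.pipeline) if p.pipeline else None,
            "flows": {y: dataclasses.asdict(f) for y, f in sorted(p.flows.items())},
            "initial_stock": p.initial_stock,
            "horizon": list(p.horizon),
            "scenarios": [
                {"name": s.name, "overrides": dict(s.overrides)} for s in self.scenarios
            ],
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "synth": {"n_survey": self.n_survey, "register_size": self.register_size},
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def _build(section: str, cls, data: Mapping | None, default=None):
    if data is None:
        return default if default is not None else cls()
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config section {section!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except ValueError as exc:
        raise ConfigurationError(f"invalid value in {section!r}: {exc}") from exc


def load_config(source: str | Path | Mapping | None = None) -> RunConfig:
    """Load and validate a run configuration from YAML/JSON (or a mapping).

    ``None`` or an empty file yields the pure baseline defaults.  Unknown
    keys and invariant breaches raise :class:`ConfigurationError` naming the
    offending key.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text(encoding="utf-8")
        raw = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)) or {}
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"config root of {path} must be a mapping")
        raw = dict(raw)

    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")

    inputs_raw = raw.get("inputs") or {}
    bad = set(inputs_raw) - _INPUT_KEYS
    if bad:
        raise ConfigurationError(f"unknown key(s) in 'inputs': {sorted(bad)}")
    inputs = {k: Path(v) for k, v in inputs_raw.items() if v is not None}

    service_times = _build("service_times", ServiceTimes, raw.get("service_times"))
    capacity = _build("capacity", CapacityParams, raw.get("capacity"))
    supply = _build("supply", SupplyParams, raw.get("supply"))
    pipeline = (
        _build("pipeline", GraduatePipeline, raw["pipeline"])
        if raw.get("pipeline")
        else None
    )
    flows = {
        int(year): _build(f"flows.{year}", FlowAssumptions, spec)
        for year, spec in (raw.get("flows") or {}).items()
    }

    horizon = raw.get("horizon", list(DEFAULT_HORIZON))
    if not (isinstance(horizon, (list, tuple)) and len(horizon) == 2):
        raise ConfigurationError("'horizon' must be a [start_year, end_year] pair")
    params = ModelParams(
        service_times=service_times,
        capacity=capacity,
        supply=supply,
        pipeline=pipeline,
        flows=flows,
        initial_stock=float(raw.get("initial_stock", 3053.0)),
        horizon=(int(horizon[0]), int(horizon[1])),
    )

    scenarios = []
    for i, spec in enumerate(raw.get("scenarios") or []):
        if not isinstance(spec, Mapping) or "name" not in spec:
            raise ConfigurationError(f"scenarios[{i}] must be a mapping with a 'name'")
        extra = set(spec) - {"name", "overrides"}
        if extra:
            raise ConfigurationError(f"unknown key(s) in scenarios[{i}]: {sorted(extra)}")
        scenarios.append(ScenarioSpec(str(spec["name"]), dict(spec.get("overrides") or {})))

    mapping = raw.get("frequency_mapping") or dict(DEFAULT_FREQUENCY_MAPPING)

    synth_raw = raw.get("synth") or {}
    bad = set(synth_raw) - _SYNTH_KEYS
    if bad:
        raise ConfigurationError(f"unknown key(s) in 'synth': {sorted(bad)}")

    return RunConfig(
        params=params,
        frequency_mapping={str(k): float(v) for k, v in mapping.items()},
        use_weights=bool(raw.get("use_weights", False)),
        scenarios=scenarios,
        inputs=inputs,
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", "oralforce_out")),
        n_survey=int(synth_raw.get("n_survey", 5000)),
        register_size=int(synth_raw.get("register_size", 3053)),
    )
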