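"""Synthetic survey, population and register data with known ground truth.

Every stage of the planning model can be exercised without external
downloads: this module draws survey microdata (Bernoulli visit
participation, categorical visit frequency and last-visit type per
stratum), compound-growth population tables, and register snapshot pairs
with planted inflows/outflows, all from a single :class:`SyntheticTruth`
record that also carries the analytically implied need rates.

All generators are pure functions of (truth, size, seed): one integer seed
drives independent derived streams per artefact, so regenerating the survey
never perturbs the register pair.

The default truth is loosely themed on a small European country's adult
population and a register of ~3000 dentists, but its numbers are synthetic:
they are chosen for plausible magnitudes, not to match any real dataset.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .need import (
    AGE_BANDS,
    DEFAULT_FREQUENCY_MAPPING,
    SEXES,
    VISIT_TYPES,
    NeedRates,
)
from .supply import RegisterEntry, RegisterSnapshot

FREQUENCY_CATEGORIES = tuple(DEFAULT_FREQUENCY_MAPPING)
TEETH_CATEGORIES = ("all_natural", "some_missing", "none_natural")

# stream tags deriving independent child RNGs from the run seed
_STREAMS = {"survey": 1, "population": 2, "register": 3}


def derived_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one artefact stream of a run seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _check_dist(name: str, dist: Mapping[str, float], categories: tuple[str, ...]) -> None:
    unknown = set(dist) - set(categories)
    if unknown:
        raise ConfigurationError(f"{name} has unknown categories {sorted(unknown)}")
    probs = np.array([dist.get(c, 0.0) for c in categories], float)
    if (probs < 0).any():
        raise ConfigurationError(f"{name} has negative probabilities")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} probabilities sum to {probs.sum()}, not 1")


@dataclass(frozen=True)
class StratumTruth:
    """True data-generating parameters for one sex x age-band stratum."""

    participation: float  # P(visited a dentist in the last 12 months)
    frequency_dist: Mapping[str, float]  # over FREQUENCY_CATEGORIES, visitors
    type_dist: Mapping[str, float]  # over VISIT_TYPES, visitors
    base_population: float  # persons in the base year
    growth_rate: float  # annual compound growth

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation <= 1.0:
            raise ConfigurationError(
                f"participation must be in [0, 1], got {self.participation!r}"
            )
        _check_dist("frequency_dist", self.frequency_dist, FREQUENCY_CATEGORIES)
        _check_dist("type_dist", self.type_dist, VISIT_TYPES)
        if self.base_population < 0:
            raise ConfigurationError("base_population must be >= 0")
        if not np.isfinite(self.growth_rate):
            raise ConfigurationError("growth_rate must be finite")


@dataclass(frozen=True)
class PlantedFlows:
    """Register flows planted between two consecutive snapshots."""

    inflow_new_graduates: int = 35
    inflow_foreign_trained: int = 40
    inflow_returning_domestic: int = 10
    outflows: int = 60

    def __post_init__(self) -> None:
        for name in (
            "inflow_new_graduates",
            "inflow_foreign_trained",
            "inflow_returning_domestic",
            "outflows",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Full ground-truth record emitted alongside every generated dataset."""

    strata: Mapping[tuple[str, str], StratumTruth]
    planted_flows: PlantedFlows = field(default_factory=PlantedFlows)
    base_year: int = 2017
    seed: int = 0

    def __post_init__(self) -> None:
        for key in self.strata:
            sex, band = key
            if sex not in SEXES or band not in AGE_BANDS:
                raise ConfigurationError(f"unknown stratum key {key!r}")

    def stratum_shares(self) -> pd.Series:
        pops = pd.Series(
            {k: s.base_population for k, s in self.strata.items()}, name="share"
        )
        return pops / pops.sum()

    def expected_need_rates(
        self, mapping: Mapping[str, float] | None = None
    ) -> NeedRates:
        """Analytic need rates implied by the truth under a frequency mapping:
        total = participation x E[mapped visits | visitor]; per-type rates
        split the total by the true last-visit-type distribution."""
        mapping = dict(mapping or DEFAULT_FREQUENCY_MAPPING)
        rows = {}
        for key, s in self.strata.items():
            mean_visits = sum(
                s.frequency_dist.get(c, 0.0) * mapping[c] for c in FREQUENCY_CATEGORIES
            )
            total = s.participation * mean_visits
            row = {vt: total * s.type_dist.get(vt, 0.0) for vt in VISIT_TYPES}
            row["total"] = total
            row["n_respondents"] = 0
            row["effective_n"] = 0.0
            row["defined"] = True
            rows[key] = row
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index = pd.MultiIndex.from_tuples(table.index, names=["sex", "age_band"])
        table = table.sort_index()
        return NeedRates(table=table, frequency_mapping=mapping)

    def to_dict(self) -> dict:
        return {
            "base_year": self.base_year,
            "seed": self.seed,
            "planted_flows": asdict(self.planted_flows),
            "strata": {
                f"{sex}|{band}": {
                    "participation": s.participation,
                    "frequency_dist": dict(s.frequency_dist),
                    "type_dist": dict(s.type_dist),
                    "base_population": s.base_population,
                    "growth_rate": s.growth_rate,
                }
                for (sex, band), s in self.strata.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        strata = {}
        for key, s in d["strata"].items():
            sex, band = key.split("|")
            strata[(sex, band)] = StratumTruth(
                participation=s["participation"],
                frequency_dist=s["frequency_dist"],
                type_dist=s["type_dist"],
                base_population=s["base_population"],
                growth_rate=s["growth_rate"],
            )
        return cls(
            strata=strata,
            planted_flows=PlantedFlows(**d.get("planted_flows", {})),
            base_year=d.get("base_year", 2017),
            seed=d.get("seed", 0),
        )


def default_truth(seed: int = 0) -> SyntheticTruth:
    """Reference synthetic truth: eight sex x age-band strata with
    participation between 0.42 and 0.68, a check-up-heavy visit-type mix
    that shifts toward routine/emergency care with age, adult population
    ~3.8M with band-specific growth, and planted register flows sized for a
    register of ~3000 practitioners."""
    base_pop = {
        ("female", "15-44"): 980_000.0,
        ("female", "45-64"): 590_000.0,
        ("female", "65-74"): 190_000.0,
        ("female", "75+"): 140_000.0,
        ("male", "15-44"): 990_000.0,
        ("male", "45-64"): 580_000.0,
        ("male", "65-74"): 185_000.0,
        ("male", "75+"): 105_000.0,
    }
    growth = {"15-44": 0.002, "45-64": 0.008, "65-74": 0.011, "75+": 0.011}
    participation = {
        ("female", "15-44"): 0.62,
        ("female", "45-64"): 0.68,
        ("female", "65-74"): 0.58,
        ("female", "75+"): 0.46,
        ("male", "15-44"): 0.52,
        ("male", "45-64"): 0.60,
        ("male", "65-74"): 0.52,
        ("male", "75+"): 0.42,
    }
    type_by_band = {
        "15-44": {"checkup_exam_cleaning": 0.62, "routine_treatment": 0.28, "emergency_treatment": 0.10},
        "45-64": {"checkup_exam_cleaning": 0.55, "routine_treatment": 0.33, "emergency_treatment": 0.12},
        "65-74": {"checkup_exam_cleaning": 0.50, "routine_treatment": 0.36, "emergency_treatment": 0.14},
        "75+": {"checkup_exam_cleaning": 0.45, "routine_treatment": 0.38, "emergency_treatment": 0.17},
    }
    freq = {"once": 0.48, "twice": 0.34, "three_or_more": 0.18}
    strata = {
        key: StratumTruth(
            participation=participation[key],
            frequency_dist=freq,
            type_dist=type_by_band[key[1]],
            base_population=base_pop[key],
            growth_rate=growth[key[1]],
        )
        for key in base_pop
    }
    return SyntheticTruth(strata=strata, seed=seed)


# ---------------------------------------------------------------------------
# generators

_AGE_RANGE = {"15-44": (15, 44), "45-64": (45, 64), "65-74": (65, 74), "75+": (75, 92)}


def gen_survey(truth: SyntheticTruth, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` survey respondents from the truth's stratum mix.

    Stratum membership is multinomial in the base-population shares; within
    a stratum, visiting is Bernoulli in the participation probability and
    visitors draw a frequency category and a last-visit type from the
    stated categoricals.  Ages are uniform within band; the health-status
    variables are drawn independently of service use.  Byte-identical
    output for identical (truth, n, seed).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = derived_rng(seed, "survey")
    keys = sorted(truth.strata)
    shares = truth.stratum_shares().loc[keys].to_numpy()
    stratum_idx = rng.choice(len(keys), size=n, p=shares)

    sex = np.empty(n, dtype=object)
    age = np.empty(n, dtype=int)
    visited = np.zeros(n, dtype=bool)
    freq = np.full(n, None, dtype=object)
    vtype = np.full(n, None, dtype=object)
    for i, key in enumerate(keys):
        mask = stratum_idx == i
        m = int(mask.sum())
        if m == 0:
            continue
        s = truth.strata[key]
        lo, hi = _AGE_RANGE[key[1]]
        sex[mask] = key[0]
        age[mask] = rng.integers(lo, hi + 1, size=m)
        vis = rng.random(m) < s.participation
        visited[mask] = vis
        fprobs = np.array([s.frequency_dist.get(c, 0.0) for c in FREQUENCY_CATEGORIES])
        tprobs = np.array([s.type_dist.get(c, 0.0) for c in VISIT_TYPES])
        fdraw = rng.choice(len(FREQUENCY_CATEGORIES), size=m, p=fprobs)
        tdraw = rng.choice(len(VISIT_TYPES), size=m, p=tprobs)
        sub_freq = np.where(vis, np.array(FREQUENCY_CATEGORIES, object)[fdraw], None)
        sub_type = np.where(vis, np.array(VISIT_TYPES, object)[tdraw], None)
        freq[mask] = sub_freq
        vtype[mask] = sub_type

    teeth = np.array(TEETH_CATEGORIES, object)[
        rng.choice(len(TEETH_CATEGORIES), size=n, p=[0.55, 0.35, 0.10])
    ]
    food_pain = rng.random(n) < 0.22
    return pd.DataFrame(
        {
            "sex": sex,
            "age_years": age,
            "natural_teeth_category": teeth,
            "food_pain_problem": food_pain,
            "visited_12m": visited,
            "frequency_category": freq,
            "last_visit_type": vtype,
        }
    )


def gen_population(
    truth: SyntheticTruth, horizon: tuple[int, int], base_year: int | None = None
) -> pd.DataFrame:
    """Population table over the horizon by compound growth per stratum:
    persons(s, t) = base(s) x (1 + growth(s))^(t - base_year), floored at 0."""
    base_year = truth.base_year if base_year is None else base_year
    rows = []
    for year in range(horizon[0], horizon[1] + 1):
        for (sex, band), s in sorted(truth.strata.items()):
            persons = s.base_population * (1.0 + s.growth_rate) ** (year - base_year)
            rows.append((year, sex, band, max(persons, 0.0)))
    return pd.DataFrame(rows, columns=["year", "sex", "age_band", "persons"])


def gen_register_pair(
    truth: SyntheticTruth, n0: int, seed: int
) -> tuple[RegisterSnapshot, RegisterSnapshot, PlantedFlows]:
    """Two consecutive register snapshots with planted flows.

    The earlier snapshot holds ``n0`` practitioners; the later one removes
    the planted number of randomly chosen registrants (outflows) and adds
    planted new graduates (domestic, qualified in the later year),
    foreign-trained entrants and returning domestic registrants (domestic,
    qualified before the earlier year), so a register diff must recover the
    planted counts exactly.
    """
    planted = truth.planted_flows
    if planted.outflows > n0:
        raise ConfigurationError(
            f"planted outflows {planted.outflows} exceed register size {n0}"
        )
    rng = derived_rng(seed, "register")
    y_earlier = truth.base_year
    y_later = truth.base_year + 1

    def _entry(rid: int, year_qualified: int, origin: str, reg_year: int) -> RegisterEntry:
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        return RegisterEntry(
            registrant_id=f"R{rid:06d}",
            date_registered=datetime.date(reg_year, month, day),
            year_qualified=int(year_qualified),
            qualification_origin=origin,
        )

    entries = []
    for i in range(n0):
        yq = int(rng.integers(y_earlier - 45, y_earlier))
        origin = "foreign" if rng.random() < 0.15 else "domestic"
        reg_year = int(rng.integers(yq, y_earlier + 1))
        entries.append(_entry(i, yq, origin, reg_year))
    earlier = RegisterSnapshot(as_of_year=y_earlier, entries=tuple(entries))

    keep = set(rng.choice(n0, size=n0 - planted.outflows, replace=False).tolist())
    later_entries = [e for i, e in enumerate(entries) if i in keep]
    next_id = n0
    for _ in range(planted.inflow_new_graduates):
        later_entries.append(_entry(next_id, y_later, "domestic", y_later))
        next_id += 1
    for _ in range(planted.inflow_foreign_trained):
        yq = int(rng.integers(y_later - 25, y_later + 1))
        later_entries.append(_entry(next_id, yq, "foreign", y_later))
        next_id += 1
    for _ in range(planted.inflow_returning_domestic):
        yq = int(rng.integers(y_earlier - 30, y_earlier - 2))
        later_entries.append(_entry(next_id, yq, "domestic", y_later))
        next_id += 1
    later = RegisterSnapshot(as_of_year=y_later, entries=tuple(later_entries))
    return earlier, later, planted
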