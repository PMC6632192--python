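"""CSV readers/writers for the model's tabular interfaces.

All files are plain RFC-4180 CSV, UTF-8, '.' decimal point.  Writers
prepend a commented metadata header (lines starting '# key: value')
recording at minimum the producing command, the config hash and the seed,
so every artefact is traceable to the run that made it; readers skip these
lines transparently.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DataError
from .need import NeedRates
from .supply import FlowAssumptions, RegisterEntry, RegisterSnapshot

REGISTER_COLUMNS = (
    "registrant_id",
    "date_registered",
    "year_qualified",
    "qualification_origin",
    "practice_status",
)


def config_hash(config_dict: Mapping) -> str:
    """Stable sha256 of a JSON-serialisable run configuration."""
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def write_csv(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
    return path


def read_metadata(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


# ---------------------------------------------------------------------------
# survey


def write_survey_csv(df: pd.DataFrame, path, metadata=None) -> Path:
    return write_csv(df, path, metadata)


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    df = read_csv(path)
    for col in ("visited_12m", "food_pain_problem"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


# ---------------------------------------------------------------------------
# population and flows


def write_population_csv(df: pd.DataFrame, path, metadata=None) -> Path:
    return write_csv(df, path, metadata)


def read_population_csv(path: str | Path) -> pd.DataFrame:
    return read_csv(path)


def read_flows_csv(path: str | Path) -> dict[int, FlowAssumptions]:
    """Flow assumptions, one row per year; absent components default to 0.
    Missing years are resolved by carry-forward at projection time."""
    df = read_csv(path)
    if "year" not in df.columns:
        raise DataError("flow assumptions CSV needs a 'year' column")
    components = {f: f for f in FlowAssumptions().__dataclass_fields__}
    out = {}
    for _, row in df.iterrows():
        kwargs = {
            name: float(row[name]) for name in components if name in df.columns
        }
        out[int(row["year"])] = FlowAssumptions(**kwargs)
    return out


def write_flows_csv(flows: Mapping[int, FlowAssumptions], path, metadata=None) -> Path:
    rows = [{"year": year, **vars(f)} for year, f in sorted(flows.items())]
    return write_csv(pd.DataFrame(rows), path, metadata)


# ---------------------------------------------------------------------------
# register snapshots


def write_register_csv(snapshot: RegisterSnapshot, path, metadata=None) -> Path:
    rows = [
        {
            "registrant_id": e.registrant_id,
            "date_registered": e.date_registered.isoformat(),
            "year_qualified": e.year_qualified,
            "qualification_origin": e.qualification_origin,
            "practice_status": e.practice_status,
        }
        for e in snapshot.entries
    ]
    meta = {"as_of_year": snapshot.as_of_year, **(metadata or {})}
    return write_csv(pd.DataFrame(rows, columns=list(REGISTER_COLUMNS)), path, meta)


def read_register_csv(path: str | Path, as_of_year: int | None = None) -> RegisterSnapshot:
    """Read a register snapshot; the snapshot year comes from the metadata
    header unless given explicitly."""
    if as_of_year is None:
        meta = read_metadata(path)
        if "as_of_year" not in meta:
            raise DataError(f"{path}: no as_of_year metadata and none supplied")
        as_of_year = int(meta["as_of_year"])
    df = read_csv(path)
    missing = [c for c in REGISTER_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"register CSV lacks column(s) {missing}")
    entries = tuple(
        RegisterEntry(
            registrant_id=str(row.registrant_id),
            date_registered=datetime.date.fromisoformat(row.date_registered),
            year_qualified=int(row.year_qualified),
            qualification_origin=row.qualification_origin,
            practice_status=row.practice_status,
        )
        for row in df.itertuples()
    )
    return RegisterSnapshot(as_of_year=as_of_year, entries=entries)


# ---------------------------------------------------------------------------
# need rates


def write_need_rates_csv(rates: NeedRates, path, metadata=None) -> Path:
    meta = {
        "frequency_mapping": json.dumps(rates.frequency_mapping),
        "use_weights": rates.use_weights,
        "use_health_status": rates.use_health_status,
        "n_dropped_underage": rates.n_dropped_underage,
        "n_dropped_missing": rates.n_dropped_missing,
        **(metadata or {}),
    }
    return write_csv(rates.table.reset_index(), path, meta)


def read_need_rates_csv(path: str | Path) -> NeedRates:
    meta = read_metadata(path)
    df = read_csv(path)
    use_health = meta.get("use_health_status", "False") == "True"
    keys = ["sex", "age_band"] + (
        ["natural_teeth_category", "food_pain_problem"] if use_health else []
    )
    table = df.set_index(keys)
    if "defined" in table.columns and table["defined"].dtype == object:
        table["defined"] = table["defined"].map({"True": True, "False": False})
    mapping = json.loads(meta.get("frequency_mapping", "{}")) or None
    return NeedRates(
        table=table,
        frequency_mapping=mapping or {},
        use_weights=meta.get("use_weights", "False") == "True",
        use_health_status=use_health,
    )
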