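"""Stratified per-capita dental visit ("need") rates from survey microdata.

The requirement side of the model is driven by utilisation rates estimated
from an oral-health survey of the adult (15+) population, one row per
respondent, with the variables: sex; age in years; number of natural teeth
(ordinal category) and presence of a food/pain problem (the two health
status variables); whether the respondent visited a dentist in the past 12
months; how often (an ordinal frequency category); and the type of the most
recent visit (check-up/exam/cleaning, routine treatment, or emergency
treatment).

Respondents are stratified by sex and four age bands (15-44, 45-64, 65-74,
75+), optionally further by health status.  Per stratum the estimator
computes the per-capita annual number of visits — non-visitors contribute
zero, visitors contribute the visit count their frequency category maps to
— and splits it across the three visit types in proportion to the
distribution of last-visit type among the stratum's visitors.  The survey
only records the type of the *most recent* visit, so that distribution is
applied to all of a stratum's visits.

The mapping from frequency category to a visit count is a modelling choice
the survey does not pin down; it is an explicit, configurable input
(default: once -> 1, twice -> 2, three or more -> 3.5) and is echoed into
all output metadata because results are sensitive to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
AGE_BANDS = ("15-44", "45-64", "65-74", "75+")
VISIT_TYPES = ("checkup_exam_cleaning", "routine_treatment", "emergency_treatment")

DEFAULT_FREQUENCY_MAPPING: dict[str, float] = {
    "once": 1.0,
    "twice": 2.0,
    "three_or_more": 3.5,
}

#: Columns a survey record must carry to be usable at all.
CORE_COLUMNS = ("sex", "age_years", "visited_12m")

HEALTH_COLUMNS = ("natural_teeth_category", "food_pain_problem")


def age_band(age_years: float) -> str:
    """Age band for an adult respondent; bands are inclusive at 44/64/74."""
    if age_years < 15:
        raise ValueError(f"age {age_years} below the adult survey population (15+)")
    if age_years <= 44:
        return "15-44"
    if age_years <= 64:
        return "45-64"
    if age_years <= 74:
        return "65-74"
    return "75+"


def assign_stratum(record: Mapping, use_health_status: bool = False) -> tuple:
    """Stratum key (sex, age_band[, teeth_category, food_pain]) for a record."""
    sex = record["sex"]
    if sex not in SEXES:
        raise DataError(f"unknown sex code {sex!r}")
    key: tuple = (sex, age_band(record["age_years"]))
    if use_health_status:
        key = key + (record["natural_teeth_category"], bool(record["food_pain_problem"]))
    return key


def validate_frequency_mapping(mapping: Mapping[str, float]) -> dict[str, float]:
    if not mapping:
        raise ValueError("frequency mapping must not be empty")
    out = {}
    for category, visits in mapping.items():
        v = float(visits)
        if not np.isfinite(v) or v < 0:
            raise ValueError(
                f"frequency mapping for {category!r} must be a finite non-negative "
                f"visit count, got {visits!r}"
            )
        out[str(category)] = v
    return out


def visits_for_record(record: Mapping, mapping: Mapping[str, float] | None = None) -> float:
    """Annual visits implied by one respondent: 0 for non-visitors, else the
    visit count their frequency category maps to."""
    mapping = validate_frequency_mapping(mapping or DEFAULT_FREQUENCY_MAPPING)
    if not record["visited_12m"]:
        return 0.0
    category = record["frequency_category"]
    if category not in mapping:
        raise DataError(
            f"unknown frequency category {category!r}; mapping covers {sorted(mapping)}"
        )
    return mapping[category]


@dataclass
class NeedRates:
    """Per-stratum per-capita annual visit rates split by visit type.

    ``table`` is indexed by stratum (sex, age_band, optionally health
    status) with one column per visit type plus ``total``, the respondent
    count ``n_respondents``, the weighted effective sample size
    ``effective_n`` and a ``defined`` flag.  Strata with no respondents are
    flagged undefined (rates NaN), never silently zeroed; the caller decides
    whether to pool or zero-fill.
    """

    table: pd.DataFrame
    frequency_mapping: dict[str, float]
    use_weights: bool = False
    use_health_status: bool = False
    n_dropped_underage: int = 0
    n_dropped_missing: int = 0

    @property
    def strata(self) -> pd.Index:
        return self.table.index

    @property
    def undefined_strata(self) -> list:
        return list(self.table.index[~self.table["defined"]])

    def rate(self, sex: str, band: str, visit_type: str | None = None) -> float:
        row = self.table.loc[(sex, band)]
        return float(row["total"] if visit_type is None else row[visit_type])

    def zero_filled(self) -> "NeedRates":
        """Copy with undefined strata set to zero rates (explicit opt-in)."""
        table = self.table.copy()
        cols = list(VISIT_TYPES) + ["total"]
        table.loc[~table["defined"], cols] = 0.0
        return NeedRates(
            table,
            dict(self.frequency_mapping),
            self.use_weights,
            self.use_health_status,
            self.n_dropped_underage,
            self.n_dropped_missing,
        )


def _stratum_columns(use_health_status: bool) -> list[str]:
    cols = ["sex", "age_band"]
    if use_health_status:
        cols += list(HEALTH_COLUMNS)
    return cols


def _prepare_records(
    records: pd.DataFrame,
    mapping: dict[str, float],
    use_weights: bool,
    use_health_status: bool,
) -> tuple[pd.DataFrame, int, int]:
    """Filter to usable adult records and attach visits, weights, strata."""
    df = records.copy()
    missing_cols = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"survey data lacks required column(s) {missing_cols}")

    core = list(CORE_COLUMNS) + (list(HEALTH_COLUMNS) if use_health_status else [])
    n0 = len(df)
    df = df.dropna(subset=[c for c in core if c in df.columns])
    # a visitor without a frequency or visit type is unusable as well
    visited = df["visited_12m"].astype(bool)
    broken = visited & (df["frequency_category"].isna() | df["last_visit_type"].isna())
    df = df[~broken]
    n_missing = n0 - len(df)
    if n_missing:
        logger.info("dropped %d survey records with missing core fields", n_missing)

    underage = df["age_years"] < 15
    n_underage = int(underage.sum())
    if n_underage:
        logger.info("dropped %d survey records aged under 15", n_underage)
    df = df[~underage]

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise DataError(f"unknown sex code(s) {sorted(df.loc[bad_sex, 'sex'].unique())}")

    df["age_band"] = pd.cut(
        df["age_years"],
        bins=[15, 44, 64, 74, np.inf],
        labels=AGE_BANDS,
        include_lowest=True,
    ).astype(str)

    visited = df["visited_12m"].astype(bool)
    unknown_freq = visited & ~df["frequency_category"].isin(mapping)
    if unknown_freq.any():
        bad = sorted(df.loc[unknown_freq, "frequency_category"].unique())
        raise DataError(
            f"unknown frequency category(ies) {bad}; mapping covers {sorted(mapping)}"
        )
    unknown_type = visited & ~df["last_visit_type"].isin(VISIT_TYPES)
    if unknown_type.any():
        bad = sorted(df.loc[unknown_type, "last_visit_type"].unique())
        raise DataError(f"unknown visit type(s) {bad}; expected {list(VISIT_TYPES)}")

    df["visits"] = np.where(visited, df["frequency_category"].map(mapping), 0.0).astype(
        float
    )
    if use_weights and "weight" in df.columns:
        w = df["weight"].astype(float)
        if (w <= 0).any() or not np.isfinite(w).all():
            raise DataError("survey weights must be positive and finite")
        df["w"] = w
    else:
        if use_weights:
            logger.info("use_weights requested but no weight column found; unweighted")
        df["w"] = 1.0
    return df, n_underage, n_missing


def estimate_need_rates(
    records: pd.DataFrame,
    mapping: Mapping[str, float] | None = None,
    use_weights: bool = False,
    use_health_status: bool = False,
) -> NeedRates:
    """Estimate per-capita annual visit rates by stratum and visit type.

    Per stratum the total rate is the (weighted) mean of per-respondent
    visits, and the three type-specific rates split that total in proportion
    to the (weighted) last-visit-type distribution among the stratum's
    visitors; they sum to the total exactly.  Estimates are invariant to
    record order and to uniform rescaling of weights.
    """
    mapping = validate_frequency_mapping(mapping or DEFAULT_FREQUENCY_MAPPING)
    df, n_underage, n_missing = _prepare_records(
        records, mapping, use_weights, use_health_status
    )
    keys = _stratum_columns(use_health_status)

    grouped = df.groupby(keys, sort=True, observed=True)
    wsum = grouped["w"].sum()
    wsq = grouped["w"].apply(lambda s: float(np.sum(np.square(s))))
    wv = df.assign(wv=df["w"] * df["visits"]).groupby(keys, sort=True, observed=True)[
        "wv"
    ].sum()
    total = wv / wsum

    visitors = df[df["visited_12m"].astype(bool)]
    type_w = (
        visitors.groupby(keys + ["last_visit_type"], sort=True, observed=True)["w"]
        .sum()
        .unstack("last_visit_type", fill_value=0.0)
        .reindex(columns=list(VISIT_TYPES), fill_value=0.0)
    )
    shares = type_w.div(type_w.sum(axis=1), axis=0)

    table = pd.DataFrame(index=total.index)
    for vt in VISIT_TYPES:
        share_vt = shares[vt].reindex(total.index).fillna(0.0)
        table[vt] = total * share_vt
    table["total"] = total
    table["n_respondents"] = grouped.size()
    table["effective_n"] = (wsum**2) / wsq
    table["defined"] = True

    if not use_health_status:
        # complete 8-cell sex x age-band frame; empty strata flagged undefined
        full = pd.MultiIndex.from_product([SEXES, AGE_BANDS], names=["sex", "age_band"])
        table = table.reindex(full)
        empty = table["n_respondents"].isna()
        if empty.any():
            logger.warning(
                "strata with no survey respondents flagged undefined: %s",
                list(table.index[empty]),
            )
        table["n_respondents"] = table["n_respondents"].fillna(0).astype(int)
        table["effective_n"] = table["effective_n"].fillna(0.0)
        table["defined"] = ~empty
    else:
        table["n_respondents"] = table["n_respondents"].astype(int)

    return NeedRates(
        table=table,
        frequency_mapping=mapping,
        use_weights=use_weights,
        use_health_status=use_health_status,
        n_dropped_underage=n_underage,
        n_dropped_missing=n_missing,
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapIntervals:
    """Percentile intervals for per-stratum rates from B stratified resamples.

    ``lo``/``hi`` are DataFrames aligned with ``NeedRates.table`` on the
    stratum index, with columns for each visit type and ``total``.
    """

    lo: pd.DataFrame
    hi: pd.DataFrame
    B: int
    seed: int
    alpha: float = 0.05

    def covers(self, truth: pd.DataFrame, column: str = "total") -> pd.Series:
        """Whether each stratum's interval covers the given true rates."""
        t = truth[column].reindex(self.lo.index)
        return (self.lo[column] <= t) & (t <= self.hi[column])


def bootstrap_need_rates(
    records: pd.DataFrame,
    mapping: Mapping[str, float] | None = None,
    B: int = 500,
    seed: int = 0,
    use_weights: bool = False,
    use_health_status: bool = False,
    alpha: float = 0.05,
) -> BootstrapIntervals:
    """Percentile bootstrap intervals for the stratified need rates.

    Whole respondent records are resampled with replacement *within* each
    stratum (the strata are design cells, so their sizes are held fixed),
    the estimator is re-run on each resample, and per-stratum percentile
    intervals are formed.  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B!r}")
    mapping = validate_frequency_mapping(mapping or DEFAULT_FREQUENCY_MAPPING)
    df, _, _ = _prepare_records(records, mapping, use_weights, use_health_status)
    keys = _stratum_columns(use_health_status)
    rng = np.random.default_rng(seed)

    type_code = pd.Categorical(
        df["last_visit_type"], categories=list(VISIT_TYPES)
    ).codes  # -1 for non-visitors
    visits = df["visits"].to_numpy(float)
    w = df["w"].to_numpy(float)

    strata: list = []
    lo_rows: list[np.ndarray] = []
    hi_rows: list[np.ndarray] = []
    q = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    for key, idx in df.groupby(keys, sort=True, observed=True).indices.items():
        n_s = len(idx)
        draws = rng.integers(0, n_s, size=(B, n_s))
        pos = np.asarray(idx)[draws]  # B x n_s positional resamples
        wb = w[pos]
        totals = (wb * visits[pos]).sum(axis=1) / wb.sum(axis=1)
        tc = type_code[pos]
        visitor_w = np.where(tc >= 0, wb, 0.0).sum(axis=1)
        est = np.empty((B, len(VISIT_TYPES) + 1))
        for j in range(len(VISIT_TYPES)):
            tw = np.where(tc == j, wb, 0.0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                share = np.where(visitor_w > 0, tw / np.where(visitor_w > 0, visitor_w, 1), 0.0)
            est[:, j] = totals * share
        est[:, -1] = totals
        lo, hi = np.percentile(est, q, axis=0)
        strata.append(key)
        lo_rows.append(lo)
        hi_rows.append(hi)

    index = pd.MultiIndex.from_tuples(strata, names=keys)
    cols = list(VISIT_TYPES) + ["total"]
    return BootstrapIntervals(
        lo=pd.DataFrame(lo_rows, index=index, columns=cols),
        hi=pd.DataFrame(hi_rows, index=index, columns=cols),
        B=B,
        seed=seed,
        alpha=alpha,
    )
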