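"""Tabular containers and CSV readers/writers.

Everything is a pandas DataFrame with a validated schema; deaths counts are
stored as reals because redistribution produces fractional deaths.  Rounding
to whole deaths, when wanted, happens only at final export via the
largest-remainder method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import DEFAULT_AGE_GROUPS, STRATUM_COLS, check_age_groups

__all__ = [
    "MultiCauseRecord",
    "validate_deaths",
    "read_deaths",
    "write_deaths",
    "read_mcod",
    "write_mcod",
    "records_to_frame",
    "frame_to_records",
    "aggregate",
    "validate_covariates",
    "read_covariates",
    "validate_population",
    "read_population",
    "validate_ylds",
    "read_ylds",
    "integerise_deaths",
    "DEATHS_KEY",
]

DEATHS_KEY = STRATUM_COLS + ["code_or_cause"]

CHAIN_SEP = ";"


@dataclass(frozen=True)
class MultiCauseRecord:
    """One death certificate: underlying cause plus Part I chain and Part II.

    ``part1_codes`` is ordered certificate-style: first element is the
    immediate cause, the last the reported underlying cause.  ``part2_codes``
    are the contributing conditions outside the causal chain.
    """

    record_id: str
    location: str
    year: int
    age_group: str
    sex: str
    underlying_code: str
    part1_codes: tuple[str, ...] = ()
    part2_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.underlying_code:
            raise ValueError(f"record {self.record_id!r} has no underlying code")


# ---------------------------------------------------------------------------
# deaths tables


def validate_deaths(table: pd.DataFrame, age_groups=None) -> pd.DataFrame:
    missing = set(DEATHS_KEY + ["deaths"]) - set(table.columns)
    if missing:
        raise ValueError(f"deaths table missing column(s): {sorted(missing)}")
    if len(table) and (table["deaths"] < 0).any():
        raise ValueError("deaths must be non-negative")
    if table.duplicated(DEATHS_KEY).any():
        dup = table.loc[table.duplicated(DEATHS_KEY), DEATHS_KEY].iloc[0].tolist()
        raise ValueError(f"duplicated stratum key, first offender: {dup}")
    check_age_groups(table["age_group"].unique(), age_groups or DEFAULT_AGE_GROUPS)
    return table


def read_deaths(path, age_groups=None) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={"location": str, "age_group": str, "sex": str, "code_or_cause": str},
    )
    if len(table) == 0:
        table = pd.DataFrame(columns=DEATHS_KEY + ["deaths"])
    table["year"] = table["year"].astype(int) if len(table) else table.get("year", pd.Series(dtype=int))
    table["deaths"] = table["deaths"].astype(float) if len(table) else table.get("deaths", pd.Series(dtype=float))
    return validate_deaths(table.reset_index(drop=True), age_groups)


def write_deaths(table: pd.DataFrame, path) -> None:
    validate_deaths(table)
    table.to_csv(path, index=False, float_format="%.15g")


def aggregate(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Sum deaths over any subset of the key columns; totals are conserved."""
    bad = set(by) - set(DEATHS_KEY)
    if bad:
        raise ValueError(f"cannot aggregate by non-key column(s): {sorted(bad)}")
    return table.groupby(by, as_index=False, sort=True, observed=True)["deaths"].sum()


def integerise_deaths(table: pd.DataFrame) -> pd.DataFrame:
    """Round fractional deaths to integers by largest remainder, globally
    conserving the (rounded) total."""
    out = table.copy()
    deaths = out["deaths"].to_numpy(float)
    floors = np.floor(deaths)
    short = int(round(deaths.sum() - floors.sum()))
    order = np.argsort(-(deaths - floors), kind="stable")
    floors[order[:short]] += 1
    out["deaths"] = floors
    return out


# ---------------------------------------------------------------------------
# multiple-cause records


def read_mcod(path) -> list[MultiCauseRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for i, row in df.iterrows():
        if not row["underlying_code"].strip():
            raise ValueError(f"{path}: record at row {i + 2} has no underlying code")
        records.append(
            MultiCauseRecord(
                record_id=row["record_id"],
                location=row["location"],
                year=int(row["year"]),
                age_group=row["age_group"],
                sex=row["sex"],
                underlying_code=row["underlying_code"].strip(),
                part1_codes=tuple(c for c in row.get("part1_codes", "").split(CHAIN_SEP) if c),
                part2_codes=frozenset(c for c in row.get("part2_codes", "").split(CHAIN_SEP) if c),
            )
        )
    return records


def write_mcod(records, path) -> None:
    records_to_frame(records).assign(
        part1_codes=lambda d: d["part1_codes"].map(CHAIN_SEP.join),
        part2_codes=lambda d: d["part2_codes"].map(lambda s: CHAIN_SEP.join(sorted(s))),
    ).to_csv(path, index=False)


def records_to_frame(records) -> pd.DataFrame:
    """Columnar view of certificate records (chain cells hold tuples/sets)."""
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "location": [r.location for r in records],
            "year": [r.year for r in records],
            "age_group": [r.age_group for r in records],
            "sex": [r.sex for r in records],
            "underlying_code": [r.underlying_code for r in records],
            "part1_codes": [r.part1_codes for r in records],
            "part2_codes": [r.part2_codes for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[MultiCauseRecord]:
    return [
        MultiCauseRecord(
            record_id=str(r.record_id),
            location=str(r.location),
            year=int(r.year),
            age_group=str(r.age_group),
            sex=str(r.sex),
            underlying_code=str(r.underlying_code),
            part1_codes=tuple(r.part1_codes),
            part2_codes=frozenset(r.part2_codes),
        )
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# covariates / population / YLDs


def validate_covariates(table: pd.DataFrame, required=()) -> pd.DataFrame:
    if table.duplicated(["location", "year"]).any():
        raise ValueError("covariate table must have one row per (location, year)")
    for name in required:
        if name not in table.columns:
            raise ValueError(f"missing required covariate {name!r}")
        if table[name].isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
    return table


def read_covariates(path, required=()) -> pd.DataFrame:
    return validate_covariates(pd.read_csv(path, dtype={"location": str}), required)


def validate_population(pop: pd.DataFrame, weights: pd.DataFrame) -> None:
    if (pop["population"] <= 0).any():
        raise ValueError("population must be positive")
    w = weights["weight"].to_numpy(float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("age weights must be non-negative and sum to 1")


def read_population(pop_path, weights_path):
    pop = pd.read_csv(pop_path, dtype={"location": str, "age_group": str, "sex": str})
    weights = pd.read_csv(weights_path, dtype={"age_group": str})
    validate_population(pop, weights)
    return pop, weights


def validate_ylds(table: pd.DataFrame) -> pd.DataFrame:
    if (table["ylds"] < 0).any():
        raise ValueError("YLDs must be non-negative")
    return table


def read_ylds(path) -> pd.DataFrame:
    return validate_ylds(pd.read_csv(path, dtype={"location": str, "age_group": str, "sex": str}))
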