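"""Vital-registration quality scoring: completeness, major garbage, PWC, stars.

A location-year's "percent well certified" is

    PWC = completeness x (1 - major-garbage fraction)

where completeness is reported VR deaths over the estimated all-cause
envelope (capped at 1) and the major-garbage fraction is the share of deaths
coded to class-1/2 garbage, optionally age-standardised with a reference
weight vector.  Star grades (0-5) are assigned from PWC by a strictly
increasing threshold table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .causemap import CauseHierarchy, GarbageGroup, resolve_code

__all__ = [
    "StarRatingResult",
    "DEFAULT_STAR_THRESHOLDS",
    "completeness",
    "pwc",
    "assign_stars",
    "major_garbage_fraction",
    "star_rate",
]

#: Six equal-width PWC bins -> star grades 0..5.
DEFAULT_STAR_THRESHOLDS = tuple(np.arange(1, 6) / 6.0)


@dataclass(frozen=True)
class StarRatingResult:
    location: str
    period: str
    completeness: float
    major_garbage_fraction: float
    pwc: float
    stars: float
    age_standardised: bool


def completeness(vr_total: float, envelope_total: float) -> float:
    """Reported VR deaths over the all-cause envelope, capped at 1."""
    if envelope_total <= 0:
        raise ValueError("envelope total must be positive")
    if vr_total < 0:
        raise ValueError("VR total must be non-negative")
    return min(vr_total / envelope_total, 1.0)


def pwc(completeness_value: float, major_garbage: float) -> float:
    """Percent well certified: completeness x (1 - major-garbage fraction)."""
    for v in (completeness_value, major_garbage):
        if not 0.0 <= v <= 1.0:
            raise ValueError("inputs to pwc must lie in [0, 1]")
    return completeness_value * (1.0 - major_garbage)


def assign_stars(pwc_value: float, thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS) -> int:
    """Count of thresholds at or below the PWC value (closed lower bound)."""
    t = np.asarray(thresholds, float)
    if len(t) and (np.diff(t) <= 0).any():
        raise ValueError("star thresholds must be strictly increasing")
    if len(t) and ((t < 0).any() or (t > 1).any()):
        raise ValueError("star thresholds must lie in [0, 1]")
    return int(np.sum(t <= pwc_value))


def _is_major(code: str, hierarchy: CauseHierarchy, groups: Mapping[str, GarbageGroup]) -> bool:
    res = resolve_code(code, hierarchy, unknown="residual")
    return res.is_garbage and res.dest in groups and groups[res.dest].is_major


def major_garbage_fraction(
    deaths: pd.DataFrame,
    hierarchy: CauseHierarchy,
    groups: Mapping[str, GarbageGroup],
    weights: pd.DataFrame | None = None,
    age_standardise: bool = False,
) -> pd.DataFrame:
    """Fraction of deaths coded to class-1/2 garbage, per (location, year).

    Crude: total major-garbage deaths over total deaths.  Age-standardised:
    weighted mean of per-age-band fractions using the reference weight
    vector; bands with zero deaths are dropped and the weights renormalised
    over the remaining bands.
    """
    df = deaths.copy()
    codes = df["code_or_cause"].unique()
    major = {c: _is_major(c, hierarchy, groups) for c in codes}
    df["major_deaths"] = df["deaths"].where(df["code_or_cause"].map(major), 0.0)

    by_age = df.groupby(["location", "year", "age_group"], observed=True, as_index=False)[
        ["deaths", "major_deaths"]
    ].sum()

    if not age_standardise:
        tot = by_age.groupby(["location", "year"], as_index=False)[["deaths", "major_deaths"]].sum()
        tot["major_garbage_fraction"] = np.where(
            tot["deaths"] > 0, tot["major_deaths"] / tot["deaths"], np.nan
        )
        return tot[["location", "year", "major_garbage_fraction"]]

    if weights is None:
        raise ValueError("age standardisation requires a weight table")
    merged = by_age.merge(weights[["age_group", "weight"]], on="age_group", how="left")
    if merged["weight"].isna().any():
        missing = merged.loc[merged["weight"].isna(), "age_group"].unique()
        raise ValueError(f"no standard weight for age group(s): {sorted(missing)}")
    merged = merged[merged["deaths"] > 0].copy()
    merged["frac"] = merged["major_deaths"] / merged["deaths"]

    def _std(g: pd.DataFrame) -> float:
        w = g["weight"].to_numpy(float)
        return float(np.average(g["frac"], weights=w / w.sum()))

    out = (
        merged.groupby(["location", "year"])[["frac", "weight"]]
        .apply(lambda g: _std(g))
        .rename("major_garbage_fraction")
        .reset_index()
    )
    return out


def star_rate(
    deaths: pd.DataFrame,
    hierarchy: CauseHierarchy,
    groups: Mapping[str, GarbageGroup],
    envelope_totals: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
    age_standardise: bool = True,
) -> list[StarRatingResult]:
    """Score each (location, year): completeness, garbage fraction, PWC, stars.

    ``envelope_totals`` columns: location, year, envelope_deaths.
    """
    mg = major_garbage_fraction(deaths, hierarchy, groups, weights, age_standardise)
    vr = deaths.groupby(["location", "year"], as_index=False)["deaths"].sum()
    merged = vr.merge(mg, on=["location", "year"]).merge(envelope_totals, on=["location", "year"])
    results = []
    for row in merged.itertuples():
        comp = completeness(row.deaths, row.envelope_deaths)
        p = pwc(comp, row.major_garbage_fraction)
        results.append(
            StarRatingResult(
                location=row.location,
                period=str(row.year),
                completeness=comp,
                major_garbage_fraction=row.major_garbage_fraction,
                pwc=p,
                stars=assign_stars(p, thresholds),
                age_standardised=age_standardise,
            )
        )
    return results


def star_results_to_frame(results: Iterable[StarRatingResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
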