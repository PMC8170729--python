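"""Impairment redistribution from YLD shares.

Impairments (anaemia, pelvic inflammatory disease) are consequences of many
underlying causes and never themselves valid causes of death, and neither
multiple-cause data nor negative correlation applies.  Instead, the share
of years lived with disability (YLDs) each underlying cause contributes to
the impairment -- taken from non-fatal burden estimation -- stands in for
the share of impairment-coded deaths it should receive.  Targets are
restricted to causes that can actually kill (YLL-bearing causes).

Locations with a good vital-registration star rating (> 3 by default) use
their own YLD shares; lower-rated locations fall back to shares computed on
region-aggregated YLDs (summed before dividing, so large locations weigh
more, as pooled shares should).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd

from ._util import STRATUM_COLS
from .causemap import CauseHierarchy
from .proportions import ProportionPackage

__all__ = ["yld_proportions"]


def _shares(ylds: pd.DataFrame) -> pd.DataFrame:
    tot = ylds.groupby(STRATUM_COLS, observed=True)["ylds"].transform("sum")
    out = ylds[tot > 0].copy()
    out["proportion"] = out["ylds"] / tot[tot > 0]
    return out


def yld_proportions(
    ylds: pd.DataFrame,
    impairment_id: str,
    hierarchy: CauseHierarchy,
    stars: Mapping[str, float],
    region_map: Mapping[str, str],
    group_id: str | None = None,
    star_threshold: float = 3.0,
) -> ProportionPackage:
    """Redistribution proportions for one impairment from YLD shares.

    ``ylds`` columns: impairment_id, cause_id, location, year, age_group,
    sex, ylds.  ``stars`` maps location -> star rating; locations at or
    below ``star_threshold`` receive their region's pooled shares (regions
    from ``region_map``, a total function over the locations in use).
    Causes without YLLs attached are excluded before shares are formed, and
    strata with zero total YLDs are omitted with a warning.
    """
    df = ylds[ylds["impairment_id"] == impairment_id].copy()
    if len(df) == 0:
        raise ValueError(f"no YLD rows for impairment {impairment_id!r}")
    missing = set(df["location"]) - set(region_map)
    if missing:
        raise ValueError(f"region map does not cover location(s): {sorted(missing)}")
    yll_ok = df["cause_id"].map(lambda c: hierarchy.nodes[c].is_yll_cause)
    df = df[yll_ok]

    n_before = df[STRATUM_COLS].drop_duplicates().shape[0]
    country = _shares(df)
    n_after = country[STRATUM_COLS].drop_duplicates().shape[0]
    if n_after < n_before:
        warnings.warn(f"omitting {n_before - n_after} stratum/strata with zero total YLDs")

    # region pool: sum YLDs across the region's locations, shares by stratum
    pooled = df.copy()
    pooled["region"] = pooled["location"].map(region_map)
    regional = (
        pooled.groupby(["region", "year", "age_group", "sex", "cause_id"], as_index=False, observed=True)["ylds"].sum()
    )
    regional["location"] = regional.pop("region")
    regional = _shares(regional)

    parts = []
    for loc, star in ((l, stars[l]) for l in sorted(df["location"].unique())):
        if star > star_threshold:
            parts.append(country[country["location"] == loc])
        else:
            block = regional[regional["location"] == region_map[loc]].copy()
            block["location"] = loc
            parts.append(block)
    out = pd.concat(parts, ignore_index=True)
    return ProportionPackage(
        group_id or f"impairment_{impairment_id}",
        out[STRATUM_COLS + ["cause_id", "proportion"]],
    )
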