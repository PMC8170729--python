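"""Proportional redistribution.

The simplest method: within each (age, sex, location, year) stratum,
garbage deaths are allocated across plausible targets in proportion to the
observed non-garbage target deaths.  For class-1 groups the target set is
every valid underlying cause in the data; for class-3 groups it is the
group's a-priori target list.  The method assumes garbage coding is
independent of the underlying cause.

Strata whose targets hold no deaths fall back deterministically:
stratum -> same location-year pooled over ages/sexes -> global pool ->
uniform over targets.
"""

from __future__ import annotations

import pandas as pd

from ._util import STRATUM_COLS
from .causemap import CauseHierarchy, GarbageGroup, resolve_code
from .proportions import ProportionPackage

__all__ = ["proportional_proportions"]


def proportional_proportions(
    deaths: pd.DataFrame,
    group: GarbageGroup,
    hierarchy: CauseHierarchy,
    min_target_deaths: float = 0.0,
    strata: pd.DataFrame | None = None,
) -> ProportionPackage:
    """Observed non-garbage target distribution per stratum.

    ``strata`` optionally lists the strata the package must cover (defaults
    to every stratum present in ``deaths``).  ``min_target_deaths`` is the
    smallest informative target total; at or below it the fallback ladder
    triggers.
    """
    targets = sorted(group.target_causes) if group.target_causes else sorted(
        c for c in hierarchy.yll_causes()
    )
    if not targets:
        raise ValueError(f"group {group.group_id!r} has an empty target set")

    df = deaths.copy()
    res = {c: resolve_code(c, hierarchy, unknown="residual") for c in df["code_or_cause"].unique()}
    df["dest"] = df["code_or_cause"].map(lambda c: res[c].dest)
    df["kind"] = df["code_or_cause"].map(lambda c: res[c].kind)
    tgt = df[(df["kind"] == "cause") & df["dest"].isin(targets)]

    cell = (
        tgt.groupby(STRATUM_COLS + ["dest"], observed=True)["deaths"].sum().unstack("dest", fill_value=0.0)
    ).reindex(columns=targets, fill_value=0.0)
    locyear = cell.groupby(level=["location", "year"]).sum()
    global_pool = cell.sum(axis=0)

    if strata is None:
        strata = deaths[STRATUM_COLS].drop_duplicates()
    strata = strata.reset_index(drop=True)

    uniform = pd.Series(1.0 / len(targets), index=targets)

    def _pick(key: tuple) -> pd.Series:
        for pool in (
            cell.loc[key] if key in cell.index else None,
            locyear.loc[key[:2]] if key[:2] in locyear.index else None,
            global_pool,
        ):
            if pool is not None and pool.sum() > min_target_deaths:
                return pool / pool.sum()
        return uniform

    blocks = []
    for row in strata.itertuples(index=False):
        key = (row.location, row.year, row.age_group, row.sex)
        p = _pick(key)
        block = pd.DataFrame({"cause_id": p.index, "proportion": p.to_numpy()})
        for col, val in zip(STRATUM_COLS, key):
            block[col] = val
        blocks.append(block)
    out = pd.concat(blocks, ignore_index=True)
    return ProportionPackage(group.group_id, out[STRATUM_COLS + ["cause_id", "proportion"]])
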