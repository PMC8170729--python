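"""Redistribution engine: apply proportion packages and orchestrate methods.

``redistribute`` removes garbage rows from a deaths table and credits each
target cause with ``garbage_deaths x proportion`` inside every stratum, so
per-stratum and global totals are conserved exactly (up to float round-off).
``run_pipeline`` fits one package per garbage group with the method the
group declares -- multiple cause, negative correlation, impairment, or
proportional -- and applies them all in a single pass, returning the table
plus an accounting report of the death mass each method moved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._util import STRATUM_COLS
from .causemap import CauseHierarchy, GarbageGroup, resolve_code
from .datamodel import DEATHS_KEY, MultiCauseRecord
from .impairments import yld_proportions
from .mcod_injuries import NatureGroupMap, generalise_injury_fractions
from .mcod_intermediate import (
    IntermediateCauseSpec,
    build_proportions,
    fit_fraction_model,
    tag_and_aggregate,
    trim_targets,
)
from .negcorr import adjusted_proportions, build_subtype_dataset, fit_subtype_model, residual_adjustment
from .proportional import proportional_proportions
from .proportions import ProportionPackage

__all__ = ["redistribute", "run_pipeline", "PipelineConfig", "RunReport", "UncoveredStratumError"]


class UncoveredStratumError(ValueError):
    pass


def redistribute(
    deaths: pd.DataFrame,
    packages: Sequence[ProportionPackage],
    hierarchy: CauseHierarchy,
    strict: bool = True,
) -> pd.DataFrame:
    """Reallocate garbage-coded deaths onto valid causes.

    Garbage rows are matched to the package of their garbage group by
    stratum.  Under ``strict=True`` a garbage stratum with no matching
    package row raises :class:`UncoveredStratumError`; otherwise those
    deaths fall back to the stratum's observed non-garbage distribution
    (proportional fallback) with a warning.  Output codes are cause_ids.
    """
    by_group = {p.group_id: p for p in packages}
    df = deaths.copy()
    res = {c: resolve_code(c, hierarchy, unknown="residual") for c in df["code_or_cause"].unique()}
    df["dest"] = df["code_or_cause"].map(lambda c: res[c].dest)
    df["kind"] = df["code_or_cause"].map(lambda c: res[c].kind)

    valid = df[df["kind"] == "cause"][STRATUM_COLS + ["dest", "deaths"]].rename(
        columns={"dest": "cause_id"}
    )
    garbage = df[df["kind"] == "garbage"]
    pieces = [valid]

    uncovered: list[tuple] = []
    for gid, chunk in garbage.groupby("dest", observed=True):
        gsum = chunk.groupby(STRATUM_COLS, as_index=False, observed=True)["deaths"].sum()
        pkg = by_group.get(gid)
        if pkg is not None:
            merged = gsum.merge(pkg.data, on=STRATUM_COLS, how="left", indicator=True)
            hit = merged[merged["_merge"] == "both"]
            alloc = hit[STRATUM_COLS + ["cause_id"]].copy()
            alloc["deaths"] = hit["deaths"] * hit["proportion"]
            pieces.append(alloc[alloc["deaths"] != 0.0])
            miss = gsum.merge(
                merged.loc[merged["_merge"] == "left_only", STRATUM_COLS].drop_duplicates(),
                on=STRATUM_COLS,
            )
        else:
            miss = gsum
        if len(miss):
            miss = miss[miss["deaths"] > 0]
        if len(miss):
            if strict:
                uncovered.extend((gid, *row) for row in miss[STRATUM_COLS].itertuples(index=False))
                continue
            warnings.warn(
                f"group {gid!r}: {len(miss)} uncovered stratum/strata; using proportional fallback"
            )
            shares = valid.groupby(STRATUM_COLS + ["cause_id"], as_index=False, observed=True)["deaths"].sum()
            tot = shares.groupby(STRATUM_COLS, observed=True)["deaths"].transform("sum")
            shares["proportion"] = shares["deaths"] / tot
            fb = miss.merge(shares[STRATUM_COLS + ["cause_id", "proportion"]], on=STRATUM_COLS, how="inner")
            fb["deaths"] = fb["deaths"] * fb["proportion"]
            pieces.append(fb[STRATUM_COLS + ["cause_id", "deaths"]])
    if uncovered:
        raise UncoveredStratumError(
            f"{len(uncovered)} garbage stratum/strata without proportions, e.g. {uncovered[:3]}"
        )

    out = (
        pd.concat(pieces, ignore_index=True)
        .groupby(STRATUM_COLS + ["cause_id"], as_index=False, sort=True, observed=True)["deaths"]
        .sum()
        .rename(columns={"cause_id": "code_or_cause"})
    )
    return out[DEATHS_KEY + ["deaths"]]


@dataclass
class PipelineConfig:
    """Everything one redistribution run needs, in memory.

    Only the inputs required by the declared methods must be present;
    missing inputs for a declared method raise before any computation.
    """

    deaths: pd.DataFrame
    hierarchy: CauseHierarchy
    groups: Mapping[str, GarbageGroup]
    covariates: pd.DataFrame | None = None
    envelope: pd.DataFrame | None = None
    mcod_records: Sequence[MultiCauseRecord] | None = None
    intermediate_specs: Mapping[str, IntermediateCauseSpec] = field(default_factory=dict)
    nature_map: NatureGroupMap | None = None
    injury_causes: set[str] = field(default_factory=set)
    ylds: pd.DataFrame | None = None
    impairment_ids: Mapping[str, str] = field(default_factory=dict)  # group_id -> impairment
    stars: Mapping[str, float] = field(default_factory=dict)
    region_map: Mapping[str, str] = field(default_factory=dict)
    covariate_names: tuple[str, ...] = ("haq",)
    strict: bool = True
    lasso_folds: int = 10
    seed: int = 0

    def check(self, methods: set[str] | None = None) -> None:
        needs = {g.method for g in self.groups.values()} if methods is None else methods
        if "multiple_cause" in needs:
            if self.mcod_records is None or self.covariates is None or self.envelope is None:
                raise ValueError("multiple_cause groups need mcod_records, covariates and envelope")
        if "negative_correlation" in needs and self.covariates is None:
            raise ValueError("negative_correlation groups need covariates")
        if "impairment" in needs:
            if self.ylds is None or not self.stars or not self.region_map:
                raise ValueError("impairment groups need ylds, stars and region_map")


@dataclass
class RunReport:
    """Accounting of one pipeline run (Table-style tally by method)."""

    per_group: pd.DataFrame  # group_id, method, garbage_deaths
    total_garbage: float
    total_deaths_in: float
    total_deaths_out: float

    def by_method(self) -> pd.DataFrame:
        out = self.per_group.groupby("method", as_index=False)["garbage_deaths"].sum()
        out["share_of_garbage"] = (
            out["garbage_deaths"] / self.total_garbage if self.total_garbage > 0 else 0.0
        )
        return out


def _fit_group_package(cfg: PipelineConfig, group: GarbageGroup) -> ProportionPackage:
    if group.method == "proportional":
        return proportional_proportions(cfg.deaths, group, cfg.hierarchy)
    if group.method == "negative_correlation":
        data = build_subtype_dataset(cfg.deaths, group, cfg.hierarchy, cfg.covariates)
        model = fit_subtype_model(
            data, subtypes=tuple(sorted(group.target_causes)), covariate_names=cfg.covariate_names
        )
        adj = residual_adjustment(model)
        return adjusted_proportions(model, adj, group.group_id)
    if group.method == "impairment":
        impairment = cfg.impairment_ids.get(group.group_id, group.group_id)
        return yld_proportions(
            cfg.ylds, impairment, cfg.hierarchy, cfg.stars, cfg.region_map, group_id=group.group_id
        )
    # multiple_cause: injury-style when the group has a nature map context,
    # else intermediate-cause analysis
    if cfg.nature_map is not None and group.target_causes and group.target_causes <= set(
        cfg.injury_causes
    ):
        return generalise_injury_fractions(
            cfg.mcod_records,
            group.member_codes,
            set(cfg.injury_causes),
            cfg.nature_map,
            cfg.hierarchy,
            cfg.covariates,
            cfg.envelope,
            group.group_id,
            covariate_names=cfg.covariate_names,
        )
    spec = cfg.intermediate_specs.get(group.group_id) or IntermediateCauseSpec(
        name=group.group_id, code_set=frozenset(group.member_codes), covariates=cfg.covariate_names
    )
    agg = tag_and_aggregate(cfg.mcod_records, spec, cfg.hierarchy)
    targets = trim_targets(agg, lasso_folds=cfg.lasso_folds, seed=cfg.seed)
    model = fit_fraction_model(agg, cfg.covariates, covariate_names=spec.covariates, targets=targets)
    return build_proportions(model, cfg.covariates, cfg.envelope, group.group_id, targets=targets)


def run_pipeline(cfg: PipelineConfig) -> tuple[pd.DataFrame, RunReport]:
    """Fit every group's package by its declared method, redistribute once."""
    res = {
        c: resolve_code(c, cfg.hierarchy, unknown="residual")
        for c in cfg.deaths["code_or_cause"].unique()
    }
    garbage_by_group: dict[str, float] = {}
    for code, r in res.items():
        if r.is_garbage:
            mass = float(cfg.deaths.loc[cfg.deaths["code_or_cause"] == code, "deaths"].sum())
            garbage_by_group[r.dest] = garbage_by_group.get(r.dest, 0.0) + mass

    present = [gid for gid in sorted(garbage_by_group) if gid in cfg.groups]
    missing = set(garbage_by_group) - set(present)
    if missing and cfg.strict:
        raise ValueError(f"garbage group(s) present in deaths but not configured: {sorted(missing)}")
    # inputs for every method about to run must exist before any fitting
    cfg.check(methods={cfg.groups[gid].method for gid in present})

    packages = []
    tally_rows = []
    for gid in present:
        group = cfg.groups[gid]
        packages.append(_fit_group_package(cfg, group))
        tally_rows.append((gid, group.method, garbage_by_group[gid]))

    out = redistribute(cfg.deaths, packages, cfg.hierarchy, strict=cfg.strict)
    report = RunReport(
        per_group=pd.DataFrame(tally_rows, columns=["group_id", "method", "garbage_deaths"]),
        total_garbage=float(sum(garbage_by_group.values())),
        total_deaths_in=float(cfg.deaths["deaths"].sum()),
        total_deaths_out=float(out["deaths"].sum()),
    )
    return out, report
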