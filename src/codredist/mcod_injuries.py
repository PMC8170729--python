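"""Redistribution of unspecified-injury garbage (X59/Y34-style codes).

External-cause garbage codes say nothing about what caused an injury death,
but the certificate chain still records *nature-of-injury* diagnoses (head
injury, fracture, burn, ...).  Certificates with a valid injury underlying
cause reveal which nature-of-injury combinations each external cause tends
to produce, so the combination observed on a garbage-coded certificate
carries information about the true cause:

1. collapse the chain's nature-of-injury codes to a small set of custom
   diagnostic groups and form the (unordered) combination per certificate;
2. estimate P(combination | garbage code) from garbage-coded certificates
   (top 95% of combinations retained, renormalised) and
   P(injury cause | combination) from valid-cause certificates;
3. compose the two conditionals into preliminary redistribution
   proportions;
4. generalise beyond multiple-cause locations: apply the preliminary
   proportions to the garbage certificates, express the attributed deaths
   as a per-cause fraction of total injury deaths, model that fraction with
   the same binomial-logit model used for intermediate causes, and rescale
   by the external envelope.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import STRATUM_COLS
from .causemap import CauseHierarchy, normalize_code, resolve_code
from .datamodel import MultiCauseRecord
from .mcod_intermediate import build_proportions, fit_fraction_model
from .proportions import ProportionPackage

__all__ = [
    "NatureGroupMap",
    "CombinationStats",
    "collapse_chain",
    "combination_stats",
    "preliminary_proportions",
    "attribute_garbage_deaths",
    "generalise_injury_fractions",
    "load_nature_groups",
]


@dataclass(frozen=True)
class NatureGroupMap:
    """Raw nature-of-injury code -> custom diagnostic group (each code maps
    to exactly one group)."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(
            self, "mapping", {normalize_code(c): g for c, g in dict(self.mapping).items()}
        )

    def group_of(self, code: str) -> str | None:
        norm = normalize_code(code)
        g = self.mapping.get(norm)
        if g is None and len(norm) == 4:
            g = self.mapping.get(norm[:3])
        return g


def load_nature_groups(path) -> NatureGroupMap:
    df = pd.read_csv(path, dtype=str)
    if df["code"].duplicated().any():
        raise ValueError("nature-group map has duplicated codes")
    return NatureGroupMap(dict(zip(df["code"], df["group"])))


def collapse_chain(record: MultiCauseRecord, nmap: NatureGroupMap) -> frozenset[str] | None:
    """Distinct nature-of-injury groups in the Part I chain; None when no
    chain code maps to any group (such records are excluded upstream)."""
    groups = {g for c in record.part1_codes if (g := nmap.group_of(c)) is not None}
    return frozenset(groups) if groups else None


@dataclass
class CombinationStats:
    """Empirical conditionals over retained nature-group combinations."""

    p_comb_given_garbage: dict[frozenset[str], float]
    p_cause_given_comb: dict[frozenset[str], dict[str, float]]
    retained: set[frozenset[str]]
    n_garbage_records: int
    n_cause_records: int
    n_excluded_no_nature: int = 0

    def validate(self, tol: float = 1e-9) -> None:
        assert abs(sum(self.p_comb_given_garbage.values()) - 1.0) < tol
        for comb, dist in self.p_cause_given_comb.items():
            assert abs(sum(dist.values()) - 1.0) < tol, comb


def _top_prefix(counts: Counter, coverage: float) -> set:
    """Smallest most-frequent prefix reaching ``coverage`` of the total;
    items tied with the marginal one are all included."""
    items = sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    total = sum(counts.values())
    cum = 0
    marginal = None
    for key, n in items:
        cum += n
        marginal = n
        if cum >= coverage * total:
            break
    return {key for key, n in items if n >= marginal}


def combination_stats(
    records: Sequence[MultiCauseRecord],
    garbage_codes: set[str],
    injury_causes: set[str],
    nmap: NatureGroupMap,
    hierarchy: CauseHierarchy,
    coverage: float = 0.95,
) -> CombinationStats:
    """Empirical Eq.-style conditionals from a certificate collection.

    Certificates partition into garbage-coded (underlying code in
    ``garbage_codes``) and valid-injury-cause certificates; all others are
    ignored.  Combinations are ranked by garbage-conditioned frequency and
    the smallest prefix covering ``coverage`` retained, with probabilities
    renormalised over the retained support.
    """
    garbage_codes = {normalize_code(c) for c in garbage_codes}
    garbage_counts: Counter = Counter()
    cause_counts: dict[frozenset[str], Counter] = defaultdict(Counter)
    excluded = 0
    n_g = n_c = 0
    for r in records:
        comb = collapse_chain(r, nmap)
        ucod = normalize_code(r.underlying_code)
        if ucod in garbage_codes:
            if comb is None:
                excluded += 1
                continue
            garbage_counts[comb] += 1
            n_g += 1
        else:
            res = resolve_code(r.underlying_code, hierarchy, unknown="residual")
            if res.is_garbage or res.dest not in injury_causes:
                continue
            if comb is None:
                excluded += 1
                continue
            cause_counts[comb][res.dest] += 1
            n_c += 1
    if n_g == 0:
        raise ValueError("no garbage-coded certificates to build combination statistics from")

    retained = _top_prefix(garbage_counts, coverage)
    # a retained combination never seen with a valid cause has an undefined
    # cause conditional; drop it and renormalise
    orphan = {c for c in retained if not cause_counts.get(c)}
    if orphan:
        warnings.warn(
            f"{len(orphan)} retained combination(s) never observed with a valid "
            "injury cause; dropped from the support"
        )
        retained -= orphan
    if not retained:
        raise ValueError("no usable combinations after retention filtering")

    z = sum(garbage_counts[c] for c in retained)
    p_comb = {c: garbage_counts[c] / z for c in sorted(retained, key=sorted)}
    p_cause = {}
    for comb in p_comb:
        tot = sum(cause_counts[comb].values())
        p_cause[comb] = {k: v / tot for k, v in sorted(cause_counts[comb].items())}
    stats = CombinationStats(
        p_comb_given_garbage=p_comb,
        p_cause_given_comb=p_cause,
        retained=retained,
        n_garbage_records=n_g,
        n_cause_records=n_c,
        n_excluded_no_nature=excluded,
    )
    stats.validate()
    return stats


def preliminary_proportions(stats: CombinationStats) -> dict[str, float]:
    """Compose the two conditionals:
    proportion(cause) = sum_j P(combination_j | garbage) * P(cause | combination_j)."""
    out: dict[str, float] = defaultdict(float)
    for comb, p_c in stats.p_comb_given_garbage.items():
        for cause, p in stats.p_cause_given_comb[comb].items():
            out[cause] += p_c * p
    return dict(sorted(out.items()))


def _stratum_of(r: MultiCauseRecord) -> tuple:
    return (r.location, r.year, r.age_group, r.sex)


def attribute_garbage_deaths(
    records: Sequence[MultiCauseRecord],
    garbage_codes: set[str],
    injury_causes: set[str],
    nmap: NatureGroupMap,
    hierarchy: CauseHierarchy,
    coverage: float = 0.95,
    min_cell: int = 50,
) -> pd.DataFrame:
    """Attribute each garbage-coded certificate across injury causes.

    Preliminary proportions are computed within each demographic cell when
    it holds at least ``min_cell`` garbage certificates, falling back to the
    location pool and then the global pool (deterministic ladder).  Returns
    per (stratum, cause) attributed death counts (fractional).
    """
    garbage_norm = {normalize_code(c) for c in garbage_codes}

    global_stats = combination_stats(records, garbage_codes, injury_causes, nmap, hierarchy, coverage)
    global_props = preliminary_proportions(global_stats)

    by_cell: dict[tuple, list[MultiCauseRecord]] = defaultdict(list)
    by_loc: dict[str, list[MultiCauseRecord]] = defaultdict(list)
    for r in records:
        by_cell[_stratum_of(r)].append(r)
        by_loc[r.location].append(r)

    loc_cache: dict[str, dict[str, float] | None] = {}

    def _loc_props(loc: str) -> dict[str, float] | None:
        if loc not in loc_cache:
            loc_records = by_loc[loc]
            n_gc = sum(1 for r in loc_records if normalize_code(r.underlying_code) in garbage_norm)
            props = None
            if n_gc >= min_cell:
                try:
                    props = preliminary_proportions(
                        combination_stats(loc_records, garbage_codes, injury_causes, nmap, hierarchy, coverage)
                    )
                except ValueError:
                    props = None
            loc_cache[loc] = props
        return loc_cache[loc]

    def _props_for(cell: tuple) -> dict[str, float]:
        cell_records = by_cell[cell]
        n_gc_cell = sum(1 for r in cell_records if normalize_code(r.underlying_code) in garbage_norm)
        if n_gc_cell >= min_cell:
            try:
                return preliminary_proportions(
                    combination_stats(cell_records, garbage_codes, injury_causes, nmap, hierarchy, coverage)
                )
            except ValueError:
                pass
        return _loc_props(cell[0]) or global_props

    cache: dict[tuple, dict[str, float]] = {}
    tallies: dict[tuple, float] = defaultdict(float)
    for r in records:
        if normalize_code(r.underlying_code) not in garbage_norm:
            continue
        cell = _stratum_of(r)
        if cell not in cache:
            cache[cell] = _props_for(cell)
        for cause, p in cache[cell].items():
            tallies[cell + (cause,)] += p
    rows = [list(k) for k in tallies]
    out = pd.DataFrame(rows, columns=STRATUM_COLS + ["cause_id"])
    out["attributed_deaths"] = list(tallies.values())
    return out


def generalise_injury_fractions(
    records: Sequence[MultiCauseRecord],
    garbage_codes: set[str],
    injury_causes: set[str],
    nmap: NatureGroupMap,
    hierarchy: CauseHierarchy,
    covariates: pd.DataFrame,
    envelope: pd.DataFrame,
    group_id: str,
    covariate_names: Sequence[str] = ("haq",),
    coverage: float = 0.95,
    min_cell: int = 50,
) -> ProportionPackage:
    """End-to-end unspecified-injury proportions for one garbage code group.

    The attributed garbage deaths per cause are expressed as a binomial-style
    fraction of that cause's total injury deaths (attributed + correctly
    coded) per stratum, modelled with the shared fraction model, and the
    predictions rescaled by the injuries-only envelope so no mass leaves the
    injuries branch.
    """
    attributed = attribute_garbage_deaths(
        records, garbage_codes, injury_causes, nmap, hierarchy, coverage, min_cell
    )

    observed_rows = []
    for r in records:
        res = resolve_code(r.underlying_code, hierarchy, unknown="residual")
        if not res.is_garbage and res.dest in injury_causes:
            observed_rows.append(_stratum_of(r) + (res.dest,))
    observed = (
        pd.DataFrame(observed_rows, columns=STRATUM_COLS + ["cause_id"])
        .groupby(STRATUM_COLS + ["cause_id"], as_index=False)
        .size()
        .rename(columns={"size": "observed_deaths"})
    )

    merged = attributed.merge(observed, on=STRATUM_COLS + ["cause_id"], how="outer").fillna(0.0)
    merged["n_with_intermediate"] = merged["attributed_deaths"]
    merged["n_deaths"] = merged["attributed_deaths"] + merged["observed_deaths"]
    merged = merged[merged["n_deaths"] > 0].copy()
    merged["fraction"] = merged["n_with_intermediate"] / merged["n_deaths"]

    model = fit_fraction_model(
        merged[["cause_id"] + STRATUM_COLS + ["n_deaths", "n_with_intermediate", "fraction"]],
        covariates,
        covariate_names=covariate_names,
    )
    env = envelope[envelope["cause_id"].isin(injury_causes)]
    return build_proportions(model, covariates, env, group_id, targets=set(injury_causes))
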