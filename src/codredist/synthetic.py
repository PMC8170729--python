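"""Seed-deterministic synthetic worlds with known ground truth.

Every estimation method in the package is testable without external data:
this module builds a small (configurable) cause hierarchy with ICD-style
codes, location-year covariates, populations, cause-specific death
envelopes with known per-stratum cause distributions, tabulated deaths with
a controllable garbage-coding mechanism, and individual multiple-cause
certificates drawn from a known logistic tagging model.  All randomness
flows from one explicitly passed seed; identical seeds give identical
outputs.

The defaults emulate the statistical structure the estimation methods
assume -- stratified vital-registration counts, certificates with causal
chains, covariate-driven fractions -- not the code inventories or
demographic detail of any real registry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import DEFAULT_AGE_GROUPS, SEXES, STRATUM_COLS, expit, logit
from .causemap import CauseHierarchy, CauseNode, GarbageGroup
from .datamodel import MultiCauseRecord
from .mcod_injuries import NatureGroupMap

__all__ = [
    "WorldParams",
    "World",
    "IntermediateGenParams",
    "InjuryGenParams",
    "fixture_hierarchy",
    "fixture_garbage_groups",
    "fixture_nature_map",
    "make_world",
    "apply_garbage_mechanism",
    "make_mcod",
    "make_negcorr_scenario",
]


# ---------------------------------------------------------------------------
# fixture hierarchy (deterministic, no RNG)

_LEVEL1 = [("cmnn", "Communicable/maternal/neonatal/nutritional"), ("ncd", "Non-communicable"), ("inj", "Injuries")]

_LEVEL2 = {
    "infectious": "cmnn",
    "resp_infections": "cmnn",
    "maternal_neonatal": "cmnn",
    "cardio": "ncd",
    "neoplasms": "ncd",
    "diab_ckd": "ncd",
    "chronic_resp": "ncd",
    "unintentional": "inj",
    "intentional": "inj",
}

# leaf causes: cause_id -> (parent, level, primary ICD-style code)
_LEAVES = {
    "tuberculosis": ("infectious", 3, "A15"),
    "diarrheal": ("infectious", 3, "A09"),
    "malaria": ("infectious", 3, "B50"),
    "lri": ("resp_infections", 3, "J12"),
    "uri": ("resp_infections", 3, "J06"),
    "maternal": ("maternal_neonatal", 3, "O95"),
    "neonatal": ("maternal_neonatal", 3, "P07"),
    "ihd": ("cardio", 3, "I21"),
    "hypertensive_hd": ("cardio", 3, "I11"),
    "cardiomyopathy": ("cardio", 3, "I42"),
    "ischemic_stroke": ("stroke", 4, "I63"),
    "intracerebral_hem": ("stroke", 4, "I61"),
    "subarachnoid_hem": ("stroke", 4, "I60"),
    "lung_cancer": ("neoplasms", 3, "C34"),
    "liver_cancer": ("neoplasms", 3, "C22"),
    "stomach_cancer": ("neoplasms", 3, "C16"),
    "breast_cancer": ("neoplasms", 3, "C50"),
    "diabetes_t1": ("diabetes", 4, "E10"),
    "diabetes_t2": ("diabetes", 4, "E11"),
    "ckd": ("diab_ckd", 3, "N18"),
    "copd": ("chronic_resp", 3, "J44"),
    "asthma": ("chronic_resp", 3, "J45"),
    "road_injury": ("unintentional", 3, "V89"),
    "falls": ("unintentional", 3, "W19"),
    "drowning": ("unintentional", 3, "W74"),
    "poisoning": ("unintentional", 3, "X49"),
    "fire": ("unintentional", 3, "X09"),
    "self_harm": ("intentional", 3, "X84"),
    "violence": ("intentional", 3, "Y09"),
}

# intermediate (non-leaf, non-YLL) level-3 parents of level-4 subtype leaves
_SUBTYPE_PARENTS = {"stroke": "cardio", "diabetes": "diab_ckd"}

INJURY_CAUSES = frozenset(
    c for c, (p, _, _) in _LEAVES.items() if p in ("unintentional", "intentional")
)


def fixture_hierarchy() -> CauseHierarchy:
    """The standard test hierarchy: 3 level-1, 9 level-2, ~30 detailed causes."""
    nodes = {"all_cause": CauseNode("all_cause", "All causes", 0, None, False)}
    for cid, name in _LEVEL1:
        nodes[cid] = CauseNode(cid, name, 1, "all_cause", False)
    for cid, parent in _LEVEL2.items():
        nodes[cid] = CauseNode(cid, cid.replace("_", " "), 2, parent, False)
    for cid, parent in _SUBTYPE_PARENTS.items():
        nodes[cid] = CauseNode(cid, cid, 3, parent, False)
    for cid, (parent, level, _) in _LEAVES.items():
        nodes[cid] = CauseNode(cid, cid.replace("_", " "), level, parent, True)
    hier = CauseHierarchy(nodes)
    for cid, (_, _, code) in _LEAVES.items():
        hier.add_code(code, "cause", cid)
    for code, gid in _GARBAGE_CODES.items():
        hier.add_code(code, "garbage", gid)
    return hier


_GARBAGE_CODES = {
    "R99": "all_ill_defined",
    "R96": "all_ill_defined",
    "A419": "sepsis_like",
    "A40": "sepsis_like",
    "I50": "heart_failure_like",
    "X59": "unspec_injury_x59",
    "Y34": "undetermined_y34",
    "I64": "unspec_stroke",
    "E14": "unspec_diabetes",
    "D649": "anaemia_impairment",
    "J22": "unspec_resp_infection",
}


def fixture_garbage_groups(hierarchy: CauseHierarchy) -> dict[str, GarbageGroup]:
    leaves = set(hierarchy.yll_causes())
    groups = [
        GarbageGroup("all_ill_defined", {"R99", "R96"}, 1, "proportional", set()),
        GarbageGroup("sepsis_like", {"A419", "A40"}, 1, "multiple_cause", set()),
        GarbageGroup("heart_failure_like", {"I50"}, 1, "multiple_cause", set()),
        GarbageGroup("unspec_injury_x59", {"X59"}, 2, "multiple_cause", set(INJURY_CAUSES)),
        GarbageGroup("undetermined_y34", {"Y34"}, 2, "multiple_cause", set(INJURY_CAUSES)),
        GarbageGroup(
            "unspec_stroke",
            {"I64"},
            4,
            "negative_correlation",
            {"ischemic_stroke", "intracerebral_hem", "subarachnoid_hem"},
        ),
        GarbageGroup("unspec_diabetes", {"E14"}, 4, "negative_correlation", {"diabetes_t1", "diabetes_t2"}),
        GarbageGroup("anaemia_impairment", {"D649"}, 1, "impairment", {"ckd", "malaria", "maternal"}),
        GarbageGroup("unspec_resp_infection", {"J22"}, 3, "proportional", {"lri", "uri"}),
    ]
    assert leaves >= set().union(*(g.target_causes for g in groups))
    return {g.group_id: g for g in groups}


_NATURE_GROUPS = {
    "S06": "head_injury",
    "S09": "head_injury",
    "S27": "internal_injury",
    "S36": "internal_injury",
    "S42": "fracture",
    "S72": "fracture",
    "T08": "fracture",
    "T29": "burn",
    "T30": "burn",
    "T50": "toxic_effect",
    "T65": "toxic_effect",
    "T75A": "submersion",
    "T07": "multiple_injury",
    "T14": "other_injury",
}


def fixture_nature_map() -> NatureGroupMap:
    """8 custom nature-of-injury groups over ICD-style diagnosis codes."""
    return NatureGroupMap(dict(_NATURE_GROUPS))


# ---------------------------------------------------------------------------
# worlds


@dataclass(frozen=True)
class WorldParams:
    n_locations: int = 4
    years: tuple[int, ...] = (2011, 2012, 2013, 2014, 2015)
    age_groups: tuple[str, ...] = tuple(DEFAULT_AGE_GROUPS)
    total_deaths: float = 100_000.0
    covariate_effect: float = 0.0  # strength of the HAQ tilt on the cause mix
    locations_per_region: int = 2


@dataclass
class World:
    params: WorldParams
    hierarchy: CauseHierarchy
    groups: dict[str, GarbageGroup]
    nature_map: NatureGroupMap
    covariates: pd.DataFrame  # location, year, haq, sdi
    population: pd.DataFrame  # location, year, age_group, sex, population
    age_weights: pd.DataFrame  # age_group, weight
    envelope: pd.DataFrame  # stratum + cause_id, deaths (expected counts)
    true_distribution: pd.DataFrame  # stratum + cause_id, proportion
    region_map: dict[str, str]
    injury_causes: frozenset[str] = INJURY_CAUSES

    @property
    def causes(self) -> list[str]:
        return sorted(self.hierarchy.yll_causes())

    def code_of(self, cause_id: str) -> str:
        return _LEAVES[cause_id][2]


def make_world(params: WorldParams | None = None, seed: int = 0) -> World:
    """Build a deterministic synthetic world with stored ground truth."""
    params = params or WorldParams()
    rng = np.random.default_rng(seed)
    hier = fixture_hierarchy()
    groups = fixture_garbage_groups(hier)
    causes = sorted(hier.yll_causes())
    locations = [f"L{i + 1:02d}" for i in range(params.n_locations)]
    region_map = {
        loc: f"R{i // params.locations_per_region + 1}" for i, loc in enumerate(locations)
    }
    ages = list(params.age_groups)
    n_age = len(ages)

    # covariates: smooth location level + gentle year trend, clipped to (0, 1)
    cov_rows = []
    base_haq = rng.uniform(0.3, 0.85, len(locations))
    base_sdi = np.clip(base_haq + rng.normal(0, 0.08, len(locations)), 0.05, 0.95)
    for i, loc in enumerate(locations):
        for t, yr in enumerate(params.years):
            cov_rows.append(
                (loc, yr, float(np.clip(base_haq[i] + 0.01 * t, 0.02, 0.98)),
                 float(np.clip(base_sdi[i] + 0.008 * t, 0.02, 0.98)))
            )
    covariates = pd.DataFrame(cov_rows, columns=["location", "year", "haq", "sdi"])

    # population with a geometric-ish age profile; reference weights from it
    age_profile = np.exp(-0.06 * np.arange(n_age)) * (1 + 0.5 * (np.arange(n_age) == 0))
    pop_rows = []
    for loc in locations:
        scale = rng.uniform(0.6, 1.4) * 1e6
        for yr in params.years:
            for a, ag in enumerate(ages):
                for sex in SEXES:
                    pop_rows.append((loc, yr, ag, sex, scale * age_profile[a] / 2))
    population = pd.DataFrame(pop_rows, columns=["location", "year", "age_group", "sex", "population"])
    w = age_profile / age_profile.sum()
    age_weights = pd.DataFrame({"age_group": ages, "weight": w})

    # per-stratum cause distribution: global base mix x branch age tilt x
    # optional covariate tilt, normalised
    base_mix = rng.dirichlet(np.full(len(causes), 2.0))
    age_z = np.linspace(-1.0, 1.0, n_age)
    branch_slope = {"cmnn": -0.6, "ncd": 1.0, "inj": -1.2}
    slopes = np.array([branch_slope[hier.ancestor_at_level(c, 1)] for c in causes])
    cov_sign = rng.choice([-1.0, 1.0], len(causes))
    # mortality risk rises with age
    risk = 0.0005 * np.exp(0.12 * np.arange(n_age)) + 0.002 * (np.arange(n_age) == 0)

    env_rows = []
    dist_rows = []
    cov_idx = covariates.set_index(["location", "year"])
    pop_idx = population.set_index(["location", "year", "age_group", "sex"])
    for loc in locations:
        for yr in params.years:
            haq = cov_idx.loc[(loc, yr), "haq"]
            for a, ag in enumerate(ages):
                tilt = base_mix * np.exp(slopes * age_z[a])
                if params.covariate_effect:
                    tilt = tilt * np.exp(params.covariate_effect * cov_sign * haq)
                for sex in SEXES:
                    p = tilt.copy()
                    if sex == "male":
                        p = p * np.where(np.isin(causes, ["breast_cancer", "maternal"]), 0.02, 1.0)
                        p = p * np.where(slopes < -1.0, 1.5, 1.0)  # more injuries in males
                    p = p / p.sum()
                    pop = pop_idx.loc[(loc, yr, ag, sex), "population"]
                    total = pop * risk[a]
                    for c, pc in zip(causes, p):
                        env_rows.append((loc, yr, ag, sex, c, total * pc))
                        dist_rows.append((loc, yr, ag, sex, c, pc))
    envelope = pd.DataFrame(env_rows, columns=STRATUM_COLS + ["cause_id", "deaths"])
    scale = params.total_deaths / envelope["deaths"].sum()
    envelope["deaths"] *= scale
    true_distribution = pd.DataFrame(dist_rows, columns=STRATUM_COLS + ["cause_id", "proportion"])

    return World(
        params=params,
        hierarchy=hier,
        groups=groups,
        nature_map=fixture_nature_map(),
        covariates=covariates,
        population=population,
        age_weights=age_weights,
        envelope=envelope,
        true_distribution=true_distribution,
        region_map=region_map,
    )


# ---------------------------------------------------------------------------
# garbage mechanisms on tabulated deaths


def apply_garbage_mechanism(
    world: World,
    mechanism: str = "cause_independent",
    garbage_rate: float = 0.2,
    seed: int = 0,
    group_sources: dict[str, set[str]] | None = None,
    cause_rates: dict[str, float] | None = None,
    integer_counts: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulated deaths with garbage coding injected, plus the truth ledger.

    Counts are drawn Poisson around the envelope; each death is then
    independently recoded to its group's garbage code with probability
    ``garbage_rate`` (``cause_independent``) or a per-cause rate
    (``cause_biased``).  ``group_sources`` maps garbage group -> the causes
    it drains (default: ``all_ill_defined`` drains every cause).  The ledger
    records the true origin counts of every garbage-coded death.
    """
    if not 0.0 <= garbage_rate <= 1.0:
        raise ValueError("garbage_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if group_sources is None:
        group_sources = {"all_ill_defined": set(world.causes)}
    env = world.envelope.copy()
    counts = rng.poisson(env["deaths"].to_numpy()) if integer_counts else env["deaths"].to_numpy().copy()
    env["count"] = counts.astype(float)

    if mechanism == "cause_independent":
        rate_of = {c: garbage_rate for c in world.causes}
    elif mechanism == "cause_biased":
        if cause_rates is None:
            u = rng.uniform(0.2, 1.8, len(world.causes))
            cause_rates = {c: min(garbage_rate * ui, 1.0) for c, ui in zip(world.causes, u)}
        rate_of = {c: cause_rates.get(c, 0.0) for c in world.causes}
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    remaining = env["count"].to_numpy().copy()
    ledger_rows = []
    garbage_rows: dict[tuple, float] = {}
    for gid in sorted(group_sources):
        sources = group_sources[gid]
        code = sorted(world.groups[gid].member_codes)[0]
        mask = env["cause_id"].isin(sources).to_numpy()
        rates = env["cause_id"].map(rate_of).to_numpy() * mask
        moved = (
            rng.binomial(remaining.astype(int), rates).astype(float)
            if integer_counts
            else remaining * rates
        )
        remaining = remaining - moved
        moved_df = env.loc[moved > 0, STRATUM_COLS + ["cause_id"]].copy()
        moved_df["deaths_moved"] = moved[moved > 0]
        moved_df["group_id"] = gid
        ledger_rows.append(moved_df)
        for key, m in zip(env[STRATUM_COLS].itertuples(index=False), moved):
            if m > 0:
                k = tuple(key) + (code,)
                garbage_rows[k] = garbage_rows.get(k, 0.0) + m

    env["count"] = remaining
    kept = env[env["count"] > 0].copy()
    kept["code_or_cause"] = kept["cause_id"].map(world.code_of)
    deaths = kept[STRATUM_COLS + ["code_or_cause", "count"]].rename(columns={"count": "deaths"})
    if garbage_rows:
        gdf = pd.DataFrame(
            [list(k) + [v] for k, v in garbage_rows.items()],
            columns=STRATUM_COLS + ["code_or_cause", "deaths"],
        )
        deaths = pd.concat([deaths, gdf], ignore_index=True)
    deaths = deaths.groupby(STRATUM_COLS + ["code_or_cause"], as_index=False, sort=True)["deaths"].sum()
    ledger = (
        pd.concat(ledger_rows, ignore_index=True)
        if ledger_rows
        else pd.DataFrame(columns=STRATUM_COLS + ["cause_id", "deaths_moved", "group_id"])
    )
    return deaths, ledger


# ---------------------------------------------------------------------------
# multiple-cause certificates


@dataclass(frozen=True)
class IntermediateGenParams:
    """Known logistic tagging model for one intermediate cause."""

    code: str = "A419"
    beta0: float = -1.4
    beta_haq: float = 1.0
    beta_age_slope: float = 0.6  # linear trend over age index, reference age = 0
    beta_sex_male: float = 0.3
    gamma_scale: float = 0.8  # spread of per-cause effects (sum to zero)
    part2_share: float = 0.0  # tagged records carrying the code only in Part II
    miscode_rate: float = 0.3  # tagged records whose UCoD is replaced by the code
    filler_code: str = "I469"

    def age_effect(self, age_index: int, n_ages: int) -> float:
        if n_ages < 2:
            return 0.0
        return self.beta_age_slope * age_index / (n_ages - 1)


@dataclass(frozen=True)
class InjuryGenParams:
    garbage_code: str = "X59"
    garbage_share: float = 0.25  # injury certificates miscoded to the garbage code
    n_comb_per_cause: int = 3


def _draw_strata(world: World, n: int, rng) -> tuple[pd.DataFrame, np.ndarray]:
    strata = (
        world.envelope.groupby(STRATUM_COLS, as_index=False)["deaths"].sum().reset_index(drop=True)
    )
    p = strata["deaths"].to_numpy() / strata["deaths"].sum()
    idx = rng.choice(len(strata), size=n, p=p)
    return strata, idx


def _cause_sampler(world: World, causes: list[str]):
    dist = world.true_distribution[world.true_distribution["cause_id"].isin(causes)]
    wide = (
        dist.groupby(STRATUM_COLS + ["cause_id"], observed=True)["proportion"]
        .sum()
        .unstack("cause_id")
        .reindex(columns=causes, fill_value=0.0)
    )
    mats = wide.to_numpy()
    mats = mats / mats.sum(axis=1, keepdims=True)
    return wide.index, mats


def make_mcod(
    world: World,
    intermediate: IntermediateGenParams | None = None,
    injury: InjuryGenParams | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> tuple[list[MultiCauseRecord], dict]:
    """Simulate certificates; returns the records and a truth dictionary.

    Intermediate-cause presence follows the logistic model in
    ``intermediate``; a known share of tagged certificates is miscoded to
    the garbage code.  Injury certificates carry nature-group combinations
    drawn from stored per-cause conditionals; a known share is miscoded to
    the unspecified external-cause code.  The truth dictionary stores every
    generating parameter plus the realised garbage-origin tallies.
    """
    rng = np.random.default_rng(seed)
    ages = list(world.params.age_groups)
    cov = world.covariates.set_index(["location", "year"])
    records: list[MultiCauseRecord] = []
    truth: dict = {}
    rid = 0

    if intermediate is not None:
        ip = intermediate
        causes = world.causes
        gamma_raw = rng.normal(0.0, ip.gamma_scale, len(causes))
        gamma = dict(zip(causes, gamma_raw - gamma_raw.mean()))
        strata, idx = _draw_strata(world, n, rng)
        s_index, mats = _cause_sampler(world, causes)
        pos_of = {key: i for i, key in enumerate(s_index)}
        origin: dict[tuple, float] = {}
        for si in range(len(strata)):
            take = np.flatnonzero(idx == si)
            if take.size == 0:
                continue
            loc, yr, ag, sex = strata.loc[si, STRATUM_COLS]
            haq = float(cov.loc[(loc, yr), "haq"])
            p_cause = mats[pos_of[(loc, yr, ag, sex)]]
            cs = rng.choice(len(causes), size=take.size, p=p_cause)
            eta_base = (
                ip.beta0
                + ip.beta_haq * haq
                + ip.age_effect(ages.index(ag), len(ages))
                + (ip.beta_sex_male if sex == "male" else 0.0)
            )
            for ci in cs:
                cause = causes[ci]
                tagged = rng.random() < expit(eta_base + gamma[cause])
                ucod = world.code_of(cause)
                part1 = [ip.filler_code]
                part2: set[str] = set()
                if tagged:
                    if ip.part2_share > 0 and rng.random() < ip.part2_share:
                        part2.add(ip.code)
                    else:
                        part1.append(ip.code)
                miscoded = tagged and rng.random() < ip.miscode_rate
                if miscoded:
                    origin_key = (loc, yr, ag, sex, cause)
                    origin[origin_key] = origin.get(origin_key, 0.0) + 1.0
                records.append(
                    MultiCauseRecord(
                        record_id=f"r{rid}",
                        location=loc,
                        year=int(yr),
                        age_group=ag,
                        sex=sex,
                        underlying_code=ip.code if miscoded else ucod,
                        part1_codes=tuple(part1 + [ip.code if miscoded else ucod]),
                        part2_codes=frozenset(part2),
                    )
                )
                rid += 1
        truth["intermediate"] = {
            "params": ip,
            "gamma": gamma,
            "garbage_origin": pd.DataFrame(
                [list(k) + [v] for k, v in origin.items()],
                columns=STRATUM_COLS + ["cause_id", "deaths"],
            ),
        }

    if injury is not None:
        jp = injury
        inj_causes = sorted(world.injury_causes)
        groups_pool = sorted(set(_NATURE_GROUPS.values()))
        code_of_group = {}
        for code, g in _NATURE_GROUPS.items():
            code_of_group.setdefault(g, code)
        # stored per-cause combination conditionals: each cause favours a
        # signature group plus small random companion sets
        comb_support: dict[str, list[frozenset[str]]] = {}
        comb_probs: dict[str, np.ndarray] = {}
        for i, cause in enumerate(inj_causes):
            sig = groups_pool[i % len(groups_pool)]
            combos = [frozenset({sig})]
            for _ in range(jp.n_comb_per_cause - 1):
                extra = rng.choice([g for g in groups_pool if g != sig], size=1)[0]
                cand = frozenset({sig, extra})
                if cand not in combos:
                    combos.append(cand)
            probs = rng.dirichlet(np.full(len(combos), 2.0))
            comb_support[cause] = combos
            comb_probs[cause] = probs
        strata, idx = _draw_strata(world, n, rng)
        s_index, mats = _cause_sampler(world, inj_causes)
        pos_of = {key: i for i, key in enumerate(s_index)}
        origin = {}
        for si in range(len(strata)):
            take = np.flatnonzero(idx == si)
            if take.size == 0:
                continue
            loc, yr, ag, sex = strata.loc[si, STRATUM_COLS]
            p_cause = mats[pos_of[(loc, yr, ag, sex)]]
            cs = rng.choice(len(inj_causes), size=take.size, p=p_cause)
            for ci in cs:
                cause = inj_causes[ci]
                combos = comb_support[cause]
                comb = combos[rng.choice(len(combos), p=comb_probs[cause])]
                chain = [code_of_group[g] for g in sorted(comb)]
                miscoded = rng.random() < jp.garbage_share
                if miscoded:
                    key = (loc, yr, ag, sex, cause)
                    origin[key] = origin.get(key, 0.0) + 1.0
                ucod = jp.garbage_code if miscoded else world.code_of(cause)
                records.append(
                    MultiCauseRecord(
                        record_id=f"r{rid}",
                        location=loc,
                        year=int(yr),
                        age_group=ag,
                        sex=sex,
                        underlying_code=ucod,
                        part1_codes=tuple(chain + [ucod]),
                        part2_codes=frozenset(),
                    )
                )
                rid += 1
        truth["injury"] = {
            "params": jp,
            "comb_support": comb_support,
            "comb_probs": comb_probs,
            "garbage_origin": pd.DataFrame(
                [list(k) + [v] for k, v in origin.items()],
                columns=STRATUM_COLS + ["cause_id", "deaths"],
            ),
        }

    return records, truth


# ---------------------------------------------------------------------------
# negative-correlation scenario


def make_negcorr_scenario(
    world: World,
    group_id: str = "unspec_stroke",
    seed: int = 0,
    kappa: dict[str, float] | None = None,
    gc_intercept: float = -1.8,
    gc_sd: float = 0.8,
    noise_sd: float = 0.05,
    counterfactual_gc: float = 0.01,
    deaths_scale: float = 5_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtype deaths drained into a class-4 garbage code, with known truth.

    Per stratum the garbage fraction GC_i varies with an (unmodelled)
    coding-practice driver; the differential draining of subtypes is linear
    in logit(GC) relative to the counterfactual, i.e. the observed subtype
    mix in softmax form is
    ``w_c ~ p_true_c * exp(kappa_c * (logit(GC_i) - logit(GC0)))``,
    which matches the linearity the residual adjustment assumes.  True
    subtype shares follow a logit-linear trend in the HAQ covariate.

    Returns (deaths table for the group's strata, truth table of per-stratum
    true subtype shares).
    """
    rng = np.random.default_rng(seed)
    group = world.groups[group_id]
    subtypes = sorted(group.target_causes)
    k = len(subtypes)
    if kappa is None:
        kappa = {s: v for s, v in zip(subtypes, np.linspace(-0.4, 0.4, k))}
    strata = world.covariates[["location", "year"]].merge(
        pd.DataFrame(
            [(a, s) for a in world.params.age_groups for s in SEXES], columns=["age_group", "sex"]
        ),
        how="cross",
    ).merge(world.covariates, on=["location", "year"])
    b0 = rng.normal(0.0, 0.6, k)
    b1 = rng.normal(0.8, 0.3, k)
    haq = strata["haq"].to_numpy()
    w_true = np.exp(b0[None, :] + b1[None, :] * haq[:, None])
    p_true = w_true / w_true.sum(axis=1, keepdims=True)

    gc = expit(gc_intercept + gc_sd * rng.standard_normal(len(strata)))
    shift = (logit(gc) - logit(counterfactual_gc))[:, None]
    kap = np.array([kappa[s] for s in subtypes])
    w_obs = p_true * np.exp(kap[None, :] * shift + rng.normal(0, noise_sd, p_true.shape))
    p_obs = w_obs / w_obs.sum(axis=1, keepdims=True)

    total = deaths_scale * rng.uniform(0.5, 1.5, len(strata))
    specific = (1 - gc)[:, None] * total[:, None] * p_obs
    garbage = gc * total
    gcode = sorted(group.member_codes)[0]

    rows = []
    for j, s in enumerate(subtypes):
        block = strata[STRATUM_COLS].copy()
        block["code_or_cause"] = world.code_of(s)
        block["deaths"] = specific[:, j]
        rows.append(block)
    gblock = strata[STRATUM_COLS].copy()
    gblock["code_or_cause"] = gcode
    gblock["deaths"] = garbage
    rows.append(gblock)
    deaths = pd.concat(rows, ignore_index=True)

    truth_rows = []
    for j, s in enumerate(subtypes):
        block = strata[STRATUM_COLS].copy()
        block["cause_id"] = s
        block["proportion"] = p_true[:, j]
        truth_rows.append(block)
    truth = pd.concat(truth_rows, ignore_index=True)
    return deaths, truth
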