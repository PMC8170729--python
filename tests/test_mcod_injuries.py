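import numpy as np
import pytest

from codredist import synthetic as syn
from codredist._util import STRATUM_COLS
from codredist.datamodel import MultiCauseRecord
from codredist.mcod_injuries import (
    CombinationStats,
    NatureGroupMap,
    collapse_chain,
    combination_stats,
    generalise_injury_fractions,
    preliminary_proportions,
)

NMAP = NatureGroupMap({"S06": "head", "S09": "head", "S72": "fracture", "T30": "burn"})


def _rec(rid, ucod, chain, loc="L01", age="<1", sex="male"):
    return MultiCauseRecord(
        record_id=rid,
        location=loc,
        year=2014,
        age_group=age,
        sex=sex,
        underlying_code=ucod,
        part1_codes=tuple(chain),
    )


class TestCollapseChain:
    def test_groups_from_chain(self):
        r = _rec("r", "X59", ["S06", "S72", "X59"])
        assert collapse_chain(r, NMAP) == frozenset({"head", "fracture"})

    def test_duplicate_groups_become_one(self):
        r = _rec("r", "X59", ["S06", "S09"])
        assert collapse_chain(r, NMAP) == frozenset({"head"})

    def test_no_mappable_codes_returns_none(self):
        r = _rec("r", "X59", ["X59"])
        assert collapse_chain(r, NMAP) is None


def _mix(n_by_comb_ucod):
    """records from {(ucod, chain_codes): count}"""
    recs = []
    i = 0
    for (ucod, chain), n in n_by_comb_ucod.items():
        for _ in range(n):
            recs.append(_rec(f"r{i}", ucod, list(chain) + [ucod]))
            i += 1
    return recs


class TestCombinationStats:
    def test_garbage_conditional(self, hierarchy):
        recs = _mix(
            {
                ("X59", ("S06",)): 60,
                ("X59", ("S72",)): 40,
                ("W19", ("S06",)): 10,
                ("V89", ("S72",)): 10,
            }
        )
        stats = combination_stats(recs, {"X59"}, syn.INJURY_CAUSES, NMAP, hierarchy)
        assert stats.p_comb_given_garbage[frozenset({"head"})] == pytest.approx(0.6)
        assert stats.p_comb_given_garbage[frozenset({"fracture"})] == pytest.approx(0.4)

    def test_cause_conditional(self, hierarchy):
        recs = _mix(
            {
                ("X59", ("S06",)): 10,
                ("W19", ("S06",)): 80,  # falls
                ("V89", ("S06",)): 20,  # road injury
            }
        )
        stats = combination_stats(recs, {"X59"}, syn.INJURY_CAUSES, NMAP, hierarchy)
        assert stats.p_cause_given_comb[frozenset({"head"})]["falls"] == pytest.approx(0.8)

    def test_top95_prefix(self, hierarchy):
        recs = _mix(
            {
                ("X59", ("S06",)): 90,
                ("X59", ("S72",)): 5,
                ("X59", ("T30",)): 3,
                ("X59", ("S06", "S72")): 2,
                ("W19", ("S06",)): 5,
                ("W19", ("S72",)): 5,
            }
        )
        stats = combination_stats(recs, {"X59"}, syn.INJURY_CAUSES, NMAP, hierarchy)
        assert stats.retained == {frozenset({"head"}), frozenset({"fracture"})}
        # renormalisation preserves relative frequencies among the retained
        ratio = (
            stats.p_comb_given_garbage[frozenset({"head"})]
            / stats.p_comb_given_garbage[frozenset({"fracture"})]
        )
        assert ratio == pytest.approx(90 / 5)

    def test_no_garbage_records_rejected(self, hierarchy):
        recs = _mix({("W19", ("S06",)): 5})
        with pytest.raises(ValueError, match="no garbage"):
            combination_stats(recs, {"X59"}, syn.INJURY_CAUSES, NMAP, hierarchy)


class TestPreliminaryProportions:
    def test_worked_example(self):
        c1, c2 = frozenset({"head"}), frozenset({"fracture"})
        stats = CombinationStats(
            p_comb_given_garbage={c1: 0.6, c2: 0.4},
            p_cause_given_comb={
                c1: {"falls": 0.8, "road_injury": 0.2},
                c2: {"falls": 0.25, "road_injury": 0.75},
            },
            retained={c1, c2},
            n_garbage_records=100,
            n_cause_records=100,
        )
        props = preliminary_proportions(stats)
        assert props["falls"] == pytest.approx(0.6 * 0.8 + 0.4 * 0.25)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_single_combination_single_cause(self):
        c = frozenset({"burn"})
        stats = CombinationStats({c: 1.0}, {c: {"fire": 1.0}}, {c}, 10, 10)
        assert preliminary_proportions(stats) == {"fire": 1.0}

    def test_matches_brute_force_double_sum(self, hierarchy):
        rng = np.random.default_rng(5)
        combos = [frozenset({"head"}), frozenset({"fracture"}), frozenset({"head", "burn"})]
        causes = ["falls", "road_injury", "fire", "drowning"]
        p_comb = rng.dirichlet(np.ones(len(combos)))
        p_cause = {c: rng.dirichlet(np.ones(len(causes))) for c in combos}
        stats = CombinationStats(
            p_comb_given_garbage=dict(zip(combos, p_comb)),
            p_cause_given_comb={c: dict(zip(causes, p_cause[c])) for c in combos},
            retained=set(combos),
            n_garbage_records=1,
            n_cause_records=1,
        )
        props = preliminary_proportions(stats)
        for i, cause in enumerate(causes):
            brute = sum(p_comb[j] * p_cause[combos[j]][i] for j in range(len(combos)))
            assert props[cause] == pytest.approx(brute, abs=1e-12)

    def test_identifying_combinations_reproduce_empirical_distribution(self, hierarchy):
        # degenerate case: every combination identifies exactly one cause
        recs = _mix(
            {
                ("X59", ("S06",)): 30,
                ("X59", ("S72",)): 70,
                ("W19", ("S06",)): 10,
                ("V89", ("S72",)): 10,
            }
        )
        stats = combination_stats(recs, {"X59"}, syn.INJURY_CAUSES, NMAP, hierarchy)
        props = preliminary_proportions(stats)
        assert props == pytest.approx({"falls": 0.3, "road_injury": 0.7})


@pytest.fixture(scope="module")
def fitted(small_world):
    recs, truth = syn.make_mcod(small_world, injury=syn.InjuryGenParams(), n=20_000, seed=31)
    pkg = generalise_injury_fractions(
        recs,
        {"X59"},
        set(small_world.injury_causes),
        small_world.nature_map,
        small_world.hierarchy,
        small_world.covariates,
        small_world.envelope,
        "unspec_injury_x59",
    )
    return pkg, truth


class TestGeneralise:

    def test_only_injury_causes_receive_mass(self, fitted, small_world):
        pkg, _ = fitted
        assert set(pkg.targets()) <= set(small_world.injury_causes)

    def test_proportions_sum_to_one(self, fitted):
        pkg, _ = fitted
        sums = pkg.data.groupby(STRATUM_COLS)["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_recovers_garbage_origin_distribution(self, fitted):
        pkg, truth = fitted
        ledger = truth["injury"]["garbage_origin"]
        g = ledger.groupby(STRATUM_COLS, as_index=False)["deaths"].sum()
        alloc = g.merge(pkg.data, on=STRATUM_COLS, how="left")
        est = alloc.assign(d=alloc["deaths"] * alloc["proportion"]).groupby("cause_id")["d"].sum()
        true = ledger.groupby("cause_id")["deaths"].sum()
        idx = est.index.union(true.index)
        p = est.reindex(idx, fill_value=0.0)
        q = true.reindex(idx, fill_value=0.0)
        tv = 0.5 * float((p / p.sum() - q / q.sum()).abs().sum())
        assert tv < 0.1
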