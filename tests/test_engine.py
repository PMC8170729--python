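import pandas as pd
import pytest

from codredist import synthetic as syn
from codredist._util import STRATUM_COLS
from codredist.causemap import resolve_code
from codredist.engine import PipelineConfig, UncoveredStratumError, redistribute, run_pipeline
from codredist.proportional import proportional_proportions
from codredist.proportions import ProportionPackage


def _deaths(rows):
    return pd.DataFrame(
        rows, columns=["location", "year", "age_group", "sex", "code_or_cause", "deaths"]
    )


def _pkg(gid, rows):
    return ProportionPackage(
        gid, pd.DataFrame(rows, columns=STRATUM_COLS + ["cause_id", "proportion"])
    )


class TestRedistribute:
    def test_conservation_worked_example(self, hierarchy):
        d = _deaths(
            [
                ("L01", 2014, "<1", "male", "A15", 30.0),
                ("L01", 2014, "<1", "male", "C34", 50.0),
                ("L01", 2014, "<1", "male", "R99", 20.0),
            ]
        )
        pkg = _pkg(
            "all_ill_defined",
            [
                ("L01", 2014, "<1", "male", "tuberculosis", 0.3),
                ("L01", 2014, "<1", "male", "lung_cancer", 0.7),
            ],
        )
        out = redistribute(d, [pkg], hierarchy)
        assert out["deaths"].sum() == pytest.approx(100.0, abs=1e-12)
        got = out.set_index("code_or_cause")["deaths"]
        assert got["tuberculosis"] == pytest.approx(36.0)
        assert got["lung_cancer"] == pytest.approx(64.0)

    def test_zero_garbage_is_identity(self, hierarchy):
        d = _deaths([("L01", 2014, "<1", "male", "A15", 30.0)])
        out = redistribute(d, [], hierarchy)
        assert out["deaths"].iloc[0] == 30.0
        assert out["code_or_cause"].iloc[0] == "tuberculosis"  # codes mapped to cause ids

    def test_matches_brute_force_row_by_row(self, hierarchy, small_world):
        deaths, _ = syn.apply_garbage_mechanism(small_world, garbage_rate=0.2, seed=17)
        group = small_world.groups["all_ill_defined"]
        pkg = proportional_proportions(deaths, group, hierarchy)
        out = redistribute(deaths, [pkg], hierarchy)

        # brute force: walk every row, allocate garbage by the package
        tall = {}
        pidx = pkg.data.set_index(STRATUM_COLS + ["cause_id"])["proportion"]
        for row in deaths.itertuples(index=False):
            res = resolve_code(row.code_or_cause, hierarchy, unknown="residual")
            key = (row.location, row.year, row.age_group, row.sex)
            if res.is_garbage:
                for cause in pkg.targets():
                    p = pidx.get(key + (cause,), 0.0)
                    if p:
                        tall[key + (cause,)] = tall.get(key + (cause,), 0.0) + row.deaths * p
            else:
                tall[key + (res.dest,)] = tall.get(key + (res.dest,), 0.0) + row.deaths
        got = out.set_index(STRATUM_COLS + ["code_or_cause"])["deaths"]
        assert len(got) == len(tall)
        for k, v in tall.items():
            assert got[k] == pytest.approx(v, rel=1e-9)

    def test_idempotent(self, hierarchy, small_world):
        deaths, _ = syn.apply_garbage_mechanism(small_world, garbage_rate=0.2, seed=18)
        pkg = proportional_proportions(deaths, small_world.groups["all_ill_defined"], hierarchy)
        once = redistribute(deaths, [pkg], hierarchy)
        twice = redistribute(once, [pkg], hierarchy)
        pd.testing.assert_frame_equal(once, twice)

    def test_uncovered_stratum_strict_raises(self, hierarchy):
        d = _deaths([("L01", 2014, "<1", "male", "R99", 5.0),
                     ("L01", 2014, "<1", "male", "A15", 5.0)])
        with pytest.raises(UncoveredStratumError):
            redistribute(d, [], hierarchy, strict=True)

    def test_uncovered_stratum_lenient_falls_back(self, hierarchy):
        d = _deaths([("L01", 2014, "<1", "male", "R99", 6.0),
                     ("L01", 2014, "<1", "male", "A15", 2.0),
                     ("L01", 2014, "<1", "male", "C34", 2.0)])
        with pytest.warns(UserWarning, match="fallback"):
            out = redistribute(d, [], hierarchy, strict=False)
        got = out.set_index("code_or_cause")["deaths"]
        assert got["tuberculosis"] == pytest.approx(5.0)
        assert got["lung_cancer"] == pytest.approx(5.0)


class TestRunPipeline:
    def test_proportional_only_matches_direct(self, small_world):
        deaths, _ = syn.apply_garbage_mechanism(small_world, garbage_rate=0.15, seed=19)
        groups = {"all_ill_defined": small_world.groups["all_ill_defined"]}
        cfg = PipelineConfig(deaths=deaths, hierarchy=small_world.hierarchy, groups=groups)
        out, report = run_pipeline(cfg)
        pkg = proportional_proportions(deaths, groups["all_ill_defined"], small_world.hierarchy)
        direct = redistribute(deaths, [pkg], small_world.hierarchy)
        pd.testing.assert_frame_equal(out, direct)
        assert report.by_method()["method"].tolist() == ["proportional"]

    def test_tally_partitions_garbage(self, small_world):
        deaths, ledger = syn.apply_garbage_mechanism(
            small_world,
            garbage_rate=0.15,
            seed=20,
            group_sources={
                "all_ill_defined": set(small_world.causes),
                "unspec_resp_infection": {"lri", "uri"},
            },
        )
        cfg = PipelineConfig(
            deaths=deaths,
            hierarchy=small_world.hierarchy,
            groups={k: small_world.groups[k] for k in ["all_ill_defined", "unspec_resp_infection"]},
        )
        out, report = run_pipeline(cfg)
        assert report.per_group["garbage_deaths"].sum() == pytest.approx(report.total_garbage)
        assert report.total_garbage == pytest.approx(ledger["deaths_moved"].sum())
        assert report.total_deaths_out == pytest.approx(report.total_deaths_in, rel=1e-12)

    def test_empty_garbage_is_noop_with_empty_report(self, small_world):
        deaths, _ = syn.apply_garbage_mechanism(small_world, garbage_rate=0.0, seed=21)
        cfg = PipelineConfig(
            deaths=deaths, hierarchy=small_world.hierarchy, groups=small_world.groups
        )
        out, report = run_pipeline(cfg)
        assert report.total_garbage == 0.0
        assert len(report.per_group) == 0
        assert out["deaths"].sum() == pytest.approx(deaths["deaths"].sum())

    def test_missing_inputs_fail_before_computation(self, small_world):
        deaths, _ = syn.apply_garbage_mechanism(
            small_world, garbage_rate=0.1, seed=22,
            group_sources={"sepsis_like": set(small_world.causes)},
        )
        cfg = PipelineConfig(
            deaths=deaths,
            hierarchy=small_world.hierarchy,
            groups={"sepsis_like": small_world.groups["sepsis_like"]},
        )
        with pytest.raises(ValueError, match="multiple_cause"):
            run_pipeline(cfg)

    def test_all_four_methods_end_to_end(self, small_world):
        """Conservation and a complete method tally when every method runs."""
        w = small_world
        deaths, ledger = syn.apply_garbage_mechanism(
            w,
            garbage_rate=0.12,
            seed=23,
            group_sources={
                "all_ill_defined": set(w.causes),
                "sepsis_like": set(w.causes) - w.injury_causes,
                "anaemia_impairment": {"ckd", "malaria", "maternal"},
            },
        )
        # add a negative-correlation garbage group via the draining scenario
        nc_deaths, _ = syn.make_negcorr_scenario(w, seed=24, deaths_scale=50.0)
        stroke_codes = {"I60", "I61", "I63", "I64"}
        deaths = (
            pd.concat([deaths[~deaths["code_or_cause"].isin(stroke_codes)], nc_deaths])
            .groupby(deaths.columns[:-1].tolist(), as_index=False)["deaths"]
            .sum()
        )
        recs, _ = syn.make_mcod(w, intermediate=syn.IntermediateGenParams(), n=8_000, seed=25)
        ylds = w.envelope[w.envelope["cause_id"].isin(["ckd", "malaria", "maternal"])].rename(
            columns={"deaths": "ylds"}
        )
        ylds = ylds.assign(impairment_id="anaemia_impairment")
        cfg = PipelineConfig(
            deaths=deaths,
            hierarchy=w.hierarchy,
            groups={
                k: w.groups[k]
                for k in ["all_ill_defined", "sepsis_like", "unspec_stroke", "anaemia_impairment"]
            },
            covariates=w.covariates,
            envelope=w.envelope,
            mcod_records=recs,
            ylds=ylds,
            impairment_ids={"anaemia_impairment": "anaemia_impairment"},
            stars={loc: 4 for loc in deaths["location"].unique()},
            region_map=w.region_map,
            strict=False,
            lasso_folds=5,
        )
        out, report = run_pipeline(cfg)
        assert report.total_deaths_out == pytest.approx(report.total_deaths_in, rel=1e-9)
        tally = report.by_method()
        assert set(tally["method"]) == {
            "proportional", "multiple_cause", "negative_correlation", "impairment"
        }
        assert tally["garbage_deaths"].sum() == pytest.approx(report.total_garbage, rel=1e-12)
        # no garbage codes survive
        leftover = set(out["code_or_cause"]) & {"R99", "R96", "A419", "A40", "I64", "D649"}
        assert not leftover
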