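"""Biomass scenarios, hierarchical fallback, seasonal and scenario tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import otodiet as od
from otodiet.biomass import FallbackLevel, Scenario
from otodiet.types import GradeCategory, Season, Species

from conftest import make_prey, make_stomach


def _stomach(did, date, g02_weights=(), n_g35=0, species="croaker",
             unmeasured_g02=0):
    ots = [make_prey(did, species=species, grade="2", ol=9.0, sl=7.0, cl=3.0,
                     weight=w) for w in g02_weights]
    ots += [make_prey(did, species=species, grade="3-5", broken=True)
            for _ in range(n_g35)]
    ots += [make_prey(did, species=species, grade="2", ol=9.0, sl=7.0, cl=3.0)
            for _ in range(unmeasured_g02)]
    return make_stomach(did, date=date, otoliths=ots)


CR = Species.CROAKER


class TestStandardScenario:
    def test_direct_formula(self):
        st = _stomach("d1", "2005-07-01", g02_weights=(100, 200), n_g35=3)
        (r,) = od.scenario_standard([st])
        assert r.biomass_g == pytest.approx(300 + 3 * 150)
        assert (r.n_grade02, r.n_grade35) == (2, 3)
        assert r.fallback_level_used is FallbackLevel.STUDY

    def test_no_grade35_means_no_scaling(self):
        st = _stomach("d1", "2005-07-01", g02_weights=(100, 200))
        (r,) = od.scenario_standard([st])
        assert r.biomass_g == pytest.approx(300)
        assert r.fallback_level_used is FallbackLevel.NONE

    def test_global_mean_shared_across_stomachs_hand_oracle(self):
        sts = [_stomach("d1", "2005-07-01", g02_weights=(100, 200), n_g35=1),
               _stomach("d2", "2005-08-01", g02_weights=(400,), n_g35=2)]
        res = {r.dolphin_id: r.biomass_g for r in od.scenario_standard(sts)}
        mean = (100 + 200 + 400) / 3  # hand computation
        assert res["d1"] == pytest.approx(300 + mean)
        assert res["d2"] == pytest.approx(400 + 2 * mean)

    def test_undefined_mean_is_an_error(self):
        st = _stomach("d1", "2005-07-01", n_g35=2)
        with pytest.raises(ValueError):
            od.scenario_standard([st])


class TestIterativeScenario:
    def test_own_stomach_mean_used_first(self):
        sts = [_stomach("d1", "2005-07-01", g02_weights=(100,), n_g35=2),
               _stomach("d2", "2005-07-15", g02_weights=(900,))]
        res = {r.dolphin_id: r for r in od.scenario_iterative(sts)}
        assert res["d1"].biomass_g == pytest.approx(100 + 2 * 100)
        assert res["d1"].fallback_level_used is FallbackLevel.STOMACH

    def test_month_then_season_then_study_fallback(self):
        sts = [
            _stomach("d1", "2005-07-01", n_g35=1),                   # no G02
            _stomach("d2", "2006-07-20", g02_weights=(80,)),         # same month (pooled years)
            _stomach("d3", "2005-08-01", g02_weights=(300,)),        # same season
            _stomach("d4", "2005-01-01", g02_weights=(500,)),        # other season
        ]
        res = {r.dolphin_id: r for r in od.scenario_iterative(sts)}
        assert res["d1"].biomass_g == pytest.approx(80)
        assert res["d1"].fallback_level_used is FallbackLevel.MONTH

        res2 = {r.dolphin_id: r for r in od.scenario_iterative(sts[:1] + sts[2:])}
        assert res2["d1"].biomass_g == pytest.approx(300)
        assert res2["d1"].fallback_level_used is FallbackLevel.SEASON

        res3 = {r.dolphin_id: r
                for r in od.scenario_iterative([sts[0], sts[3]])}
        assert res3["d1"].biomass_g == pytest.approx(500)
        assert res3["d1"].fallback_level_used is FallbackLevel.STUDY
        # study-level fallback collapses to the Standard scenario
        std = {r.dolphin_id: r.biomass_g
               for r in od.scenario_standard([sts[0], sts[3]])}
        assert res3["d1"].biomass_g == pytest.approx(std["d1"])

    def test_month_within_year_option(self):
        sts = [_stomach("d1", "2005-07-01", n_g35=1),
               _stomach("d2", "2006-07-20", g02_weights=(80,)),
               _stomach("d3", "2005-08-01", g02_weights=(300,))]
        res = {r.dolphin_id: r
               for r in od.scenario_iterative(sts, month_within_year=True)}
        # 2006-07 is a different month-cell now; falls through to season
        assert res["d1"].fallback_level_used is FallbackLevel.SEASON

    def test_fallback_never_skips_a_level(self):
        sts = [_stomach("d1", "2005-07-01", g02_weights=(50,), n_g35=4),
               _stomach("d2", "2005-07-02", g02_weights=(99,))]
        res = {r.dolphin_id: r for r in od.scenario_iterative(sts)}
        assert res["d1"].fallback_level_used is FallbackLevel.STOMACH


class TestInclusiveScenario:
    def test_all_measured_is_plain_sum(self):
        ots = [make_prey("d1", grade="2", ol=9, sl=7, cl=3, weight=100),
               make_prey("d1", grade="3-5", ol=8, sl=6.5, cl=2.8, weight=40)]
        st = make_stomach("d1", otoliths=ots)
        (r,) = od.scenario_inclusive([st])
        assert r.biomass_g == pytest.approx(140)
        assert r.fallback_level_used is FallbackLevel.NONE

    def test_unmeasured_scaled_by_stomach_mean(self):
        ots = [make_prey("d1", grade="2", ol=9, sl=7, cl=3, weight=100),
               make_prey("d1", grade="2", ol=9, sl=7, cl=3, weight=300),
               make_prey("d1", grade="3-5", broken=True)]
        st = make_stomach("d1", otoliths=ots)
        (r,) = od.scenario_inclusive([st])
        assert r.biomass_g == pytest.approx(400 + 200)
        assert r.n_unmeasured == 1

    def test_error_when_nothing_measured_anywhere(self):
        st = make_stomach("d1", otoliths=[
            make_prey("d1", grade="3-5", broken=True)])
        with pytest.raises(ValueError):
            od.scenario_inclusive([st])


class TestScenarioInvariants:
    def _measured_g02_stomachs(self):
        rng = np.random.default_rng(5)
        sts = []
        for i, date in enumerate(["2005-02-01", "2005-05-10", "2005-09-20"]):
            ws = rng.uniform(50, 300, size=4)
            sts.append(_stomach(f"d{i}", date, g02_weights=tuple(ws)))
        return sts

    def test_scenario_equivalence_when_all_measured_grade02(self):
        """With only measured Grade 0-2 otoliths, all three scenarios agree
        exactly per stomach."""
        sts = self._measured_g02_stomachs()
        res = od.run_scenarios(sts)
        by = {sc: {r.dolphin_id: r.biomass_g for r in rs}
              for sc, rs in res.items()}
        for d in by[Scenario.STANDARD]:
            assert (by[Scenario.STANDARD][d] == by[Scenario.ITERATIVE][d]
                    == by[Scenario.INCLUSIVE][d])

    def test_adding_grade35_otolith_strictly_increases_biomass(self):
        sts = self._measured_g02_stomachs()
        base = {sc: {r.dolphin_id: r.biomass_g for r in rs}
                for sc, rs in od.run_scenarios(sts).items()}
        sts[0].otoliths.append(make_prey("d0", grade="3-5", broken=True))
        bumped = {sc: {r.dolphin_id: r.biomass_g for r in rs}
                  for sc, rs in od.run_scenarios(sts).items()}
        for sc in Scenario:
            assert bumped[sc]["d0"] > base[sc]["d0"]

    def test_total_biomass_invariant_to_stomach_order(self):
        sts = self._measured_g02_stomachs()
        sts[0].otoliths.append(make_prey("d0", grade="3-5", broken=True))
        t1 = sum(r.biomass_g for r in od.scenario_iterative(sts))
        t2 = sum(r.biomass_g for r in od.scenario_iterative(sts[::-1]))
        assert t1 == pytest.approx(t2, rel=1e-12)


def _seasonal_stomachs(values_by_season, species="croaker", grade="2"):
    dates = {Season.WINTER: "2005-01-15", Season.SPRING: "2005-04-15",
             Season.SUMMER: "2005-07-15", Season.FALL: "2005-10-15"}
    sts = []
    for i, (season, values) in enumerate(values_by_season.items()):
        ots = [make_prey(f"d{i}", species=species, grade=grade, ol=9.0,
                         sl=7.0, cl=3.0, weight=w) for w in values]
        sts.append(make_stomach(f"d{i}", date=dates[season], otoliths=ots))
    return sts


class TestSeasonalWeightComparison:
    def test_identical_distributions_not_flagged(self):
        vals = [100, 120, 140, 160, 180]
        sts = _seasonal_stomachs({Season.WINTER: vals, Season.SPRING: vals,
                                  Season.SUMMER: vals})
        s = od.seasonal_weight_comparison(sts, CR, GradeCategory.G02)
        assert s.p_value > 0.5

    def test_h_matches_hand_rank_oracle(self):
        """Tie-free 9-value table: H from the rank-sum formula directly."""
        groups = {Season.WINTER: [12.0, 15.0, 20.0],
                  Season.SPRING: [11.0, 16.0, 22.0],
                  Season.SUMMER: [30.0, 35.0, 40.0]}
        sts = _seasonal_stomachs(groups)
        s = od.seasonal_weight_comparison(sts, CR, GradeCategory.G02)
        allv = sorted(v for g in groups.values() for v in g)
        ranks = {v: i + 1 for i, v in enumerate(allv)}
        n = len(allv)
        h = (12.0 / (n * (n + 1))
             * sum(len(g) * (np.mean([ranks[v] for v in g])
                             - (n + 1) / 2) ** 2
                   for g in groups.values()))
        assert s.kruskal_h == pytest.approx(h, rel=1e-12)

    def test_shifted_season_flagged_in_contrasts(self):
        rng = np.random.default_rng(0)
        base = lambda: list(rng.normal(150, 10, size=12))
        shifted = list(rng.normal(150 + 3 * 10, 10, size=12))
        sts = _seasonal_stomachs({Season.WINTER: base(), Season.SPRING: base(),
                                  Season.FALL: shifted})
        s = od.seasonal_weight_comparison(sts, CR, GradeCategory.G02)
        assert s.p_value < 0.05
        fall_ps = [p for pair, p in s.pairwise.items() if Season.FALL in pair]
        assert all(p < 0.05 for p in fall_ps)

    def test_fewer_than_two_seasons_is_an_error(self):
        sts = _seasonal_stomachs({Season.WINTER: [100, 110, 120]})
        with pytest.raises(ValueError):
            od.seasonal_weight_comparison(sts, CR, GradeCategory.G02)


class TestCompareScenarios:
    def test_identical_biomass_gives_null(self):
        sts = TestScenarioInvariants()._measured_g02_stomachs()
        res = od.run_scenarios(sts)
        out = od.compare_scenarios(res, b=400, seed=0)
        t = out[CR]
        assert all(abs(d) < 1e-9 for d in t.pairwise_diff.values())
        assert t.global_p > 0.9

    def test_small_grade35_fish_pull_inclusive_below_standard(self):
        """When heavily eroded otoliths come from systematically smaller
        fish, using their measured weights (Inclusive) yields less biomass
        than scaling by the Grade 0-2 mean (Standard)."""
        rng = np.random.default_rng(1)
        sts = []
        for i in range(12):
            ots = [make_prey(f"d{i}", grade="2", ol=9, sl=7, cl=3,
                             weight=float(rng.uniform(200, 300)))
                   for _ in range(3)]
            ots += [make_prey(f"d{i}", grade="3-5", ol=7, sl=5.5, cl=2.5,
                              weight=float(rng.uniform(50, 100)))
                    for _ in range(3)]
            sts.append(make_stomach(f"d{i}", date="2005-06-01", otoliths=ots))
        out = od.compare_scenarios(od.run_scenarios(sts), b=800, seed=2)
        t = out[CR]
        assert t.means["inclusive"] < t.means["standard"]
        assert t.pairwise_p_holm[("standard", "inclusive")] < 0.05

    def test_permutation_matches_exact_enumeration_for_five_stomachs(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(100, 20, size=(5, 3)) + np.array([0, 5, -5])
        from otodiet._stats import within_unit_permutation

        mc = within_unit_permutation(mat, ["a", "b", "c"], b=20000, seed=4)
        pairs = [(0, 1), (0, 2), (1, 2)]
        obs = mat.mean(axis=0)
        obs_global = max(abs(obs[i] - obs[j]) for i, j in pairs)
        ge = total = 0
        for assign in itertools.product(
                itertools.permutations(range(3)), repeat=5):
            perm = np.stack([mat[i, list(assign[i])] for i in range(5)])
            mean = perm.mean(axis=0)
            ge += max(abs(mean[i] - mean[j]) for i, j in pairs) >= obs_global - 1e-12
            total += 1
        exact = ge / total
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert mc.global_p == pytest.approx(exact, abs=3 * se + 1e-3)

    def test_mismatched_stomach_sets_rejected(self):
        sts = TestScenarioInvariants()._measured_g02_stomachs()
        res = od.run_scenarios(sts)
        res[Scenario.INCLUSIVE] = res[Scenario.INCLUSIVE][:-1]
        with pytest.raises(ValueError):
            od.compare_scenarios(res, b=100, seed=0)


def test_estimate_weights_uses_species_default_predictor(packaged_models):
    # croaker -> SL; weakfish -> CL
    ots = [make_prey("d1", species="croaker", grade="2", ol=9, sl=7, cl=3),
           make_prey("d1", species="weakfish", grade="2", ol=9, sl=7, cl=3)]
    st = make_stomach("d1", otoliths=ots)
    n = od.estimate_weights([st], packaged_models)
    assert n == 2
    m_cr = od.packaged_model("croaker", "SL", "FW")
    m_wf = od.packaged_model("weakfish", "CL", "FW")
    assert ots[0].est_weight_g == pytest.approx(od.predict_size(m_cr, 7.0))
    assert ots[1].est_weight_g == pytest.approx(od.predict_size(m_wf, 3.0))
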