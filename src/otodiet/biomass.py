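"""Consumption-biomass reconstruction under three scaling scenarios.

For each stomach and prey species, consumed biomass is the summed estimated
fish weight over that species' otoliths. Weights are only estimable for
measured otoliths, so the lightly eroded (Grade 0-2) or measured otoliths
must be scaled up to cover the rest:

* **Standard** — the study-wide mean weight of Grade 0-2 otoliths is applied
  to every Grade 3-5 otolith:
  ``B_st = sum(W_G02,st) + N_G35,st * mean(W_G02, study)``.
* **Iterative** — the same formula, but the scaling mean comes from the first
  non-empty level of stomach -> same calendar month -> same season -> study.
* **Inclusive** — measured otoliths of *all* grades contribute their own
  weights; the iterative fallback mean of measured weights is applied only
  to unmeasured (broken or not-subsampled) otoliths.

Seasonal differences in estimated weight are screened with a Kruskal-Wallis
test (tie-corrected) and Holm-adjusted pairwise rank contrasts; scenario
differences with a within-stomach scenario-label permutation test.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from ._stats import WithinUnitTest, holm, within_unit_permutation
from .size_models import Predictor, Response, SizeModel, predict_size
from .types import (GradeCategory, PreyOtolith, Season, Species, StomachRecord)

__all__ = [
    "Scenario",
    "FallbackLevel",
    "ScenarioResult",
    "SeasonalWeightSummary",
    "DEFAULT_WEIGHT_PREDICTOR",
    "estimate_weights",
    "scenario_standard",
    "scenario_iterative",
    "scenario_inclusive",
    "run_scenarios",
    "seasonal_weight_comparison",
    "compare_scenarios",
]


class Scenario(str, enum.Enum):
    STANDARD = "standard"
    ITERATIVE = "iterative"
    INCLUSIVE = "inclusive"


class FallbackLevel(str, enum.Enum):
    STOMACH = "stomach"
    MONTH = "month"
    SEASON = "season"
    STUDY = "study"
    NONE = "none"


# least erosion-biased predictor per species: the croaker cauda is too
# variable, so its sulcus length is used; the other species use cauda length
DEFAULT_WEIGHT_PREDICTOR: dict[Species, Predictor] = {
    Species.CROAKER: Predictor.SL,
    Species.SPOT: Predictor.CL,
    Species.SPOTTED_SEATROUT: Predictor.CL,
    Species.WEAKFISH: Predictor.CL,
}

_FIELD = {Predictor.OL: "ol_mm", Predictor.SL: "sl_mm", Predictor.CL: "cl_mm"}


@dataclass
class ScenarioResult:
    dolphin_id: str
    species: Species
    scenario: Scenario
    biomass_g: float
    n_grade02: int
    n_grade35: int
    n_unmeasured: int
    fallback_level_used: FallbackLevel


def estimate_weights(stomachs: Sequence[StomachRecord],
                     models: Iterable[SizeModel],
                     predictor_override: dict | None = None) -> int:
    """Attach an estimated fish weight to every measurable prey otolith.

    For each species the default predictor (sulcus length for croaker, cauda
    length otherwise) is used when measured; otherwise the first measured
    predictor in the fallback order CL, SL, OL. Returns the number of
    otoliths that received a weight.
    """
    weight_models: dict[tuple[Species, Predictor], SizeModel] = {}
    for m in models:
        if m.response is Response.FW:
            weight_models[(m.species, m.predictor)] = m
    override = {Species(k): Predictor(v)
                for k, v in (predictor_override or {}).items()}
    count = 0
    for st in stomachs:
        for o in st.otoliths:
            if o.broken:
                continue
            sp = o.species
            pref = override.get(sp, DEFAULT_WEIGHT_PREDICTOR.get(sp))
            if pref is None:
                continue
            order = [pref] + [p for p in (Predictor.CL, Predictor.SL, Predictor.OL)
                              if p is not pref]
            for p in order:
                x = getattr(o, _FIELD[p])
                if x is not None and (sp, p) in weight_models:
                    o.est_weight_g = float(predict_size(weight_models[(sp, p)], x))
                    count += 1
                    break
    return count


def _species_present(stomachs: Sequence[StomachRecord]) -> list[Species]:
    seen = {o.species for st in stomachs for o in st.otoliths}
    return sorted(seen, key=lambda s: s.value)


def _otoliths(st: StomachRecord, species: Species) -> list[PreyOtolith]:
    return [o for o in st.otoliths if o.species is species]


def _counts(otoliths: Sequence[PreyOtolith]) -> tuple[int, int, int]:
    n02 = sum(o.grade_category is GradeCategory.G02 for o in otoliths)
    n35 = sum(o.grade_category is GradeCategory.G35 for o in otoliths)
    nun = sum(o.est_weight_g is None for o in otoliths)
    return n02, n35, nun


def _g02_weights(otoliths: Sequence[PreyOtolith]) -> list[float]:
    out = []
    for o in otoliths:
        if o.grade_category is GradeCategory.G02:
            if o.est_weight_g is None:
                raise ValueError(
                    f"Grade 0-2 otolith of {o.species.value} in stomach "
                    f"{o.dolphin_id} has no estimated weight")
            out.append(o.est_weight_g)
    return out


def scenario_standard(stomachs: Sequence[StomachRecord],
                      species: Sequence[Species] | None = None) -> list[ScenarioResult]:
    """Study-wide Grade 0-2 mean applied to every Grade 3-5 otolith."""
    species = list(species) if species else _species_present(stomachs)
    results = []
    for sp in species:
        all_w = [w for st in stomachs for w in _g02_weights(_otoliths(st, sp))]
        global_mean = float(np.mean(all_w)) if all_w else None
        for st in stomachs:
            ots = _otoliths(st, sp)
            if not ots:
                continue
            n02, n35, nun = _counts(ots)
            w02 = _g02_weights(ots)
            if n35 and global_mean is None:
                raise ValueError(
                    f"{sp.value}: Grade 3-5 otoliths present but no Grade 0-2 "
                    "otolith anywhere; the Standard-scenario mean is undefined")
            biomass = float(np.sum(w02)) + (n35 * global_mean if n35 else 0.0)
            results.append(ScenarioResult(
                dolphin_id=st.dolphin_id, species=sp, scenario=Scenario.STANDARD,
                biomass_g=biomass, n_grade02=n02, n_grade35=n35, n_unmeasured=nun,
                fallback_level_used=FallbackLevel.STUDY if n35 else FallbackLevel.NONE))
    return results


def _fallback_mean(st: StomachRecord, own: list[float],
                   by_month: dict, by_season: dict, study: list[float],
                   month_key) -> tuple[float | None, FallbackLevel]:
    """First non-empty mean along stomach -> month -> season -> study."""
    if own:
        return float(np.mean(own)), FallbackLevel.STOMACH
    m = by_month.get(month_key(st), [])
    if m:
        return float(np.mean(m)), FallbackLevel.MONTH
    s = by_season.get(st.season, [])
    if s:
        return float(np.mean(s)), FallbackLevel.SEASON
    if study:
        return float(np.mean(study)), FallbackLevel.STUDY
    return None, FallbackLevel.NONE


def scenario_iterative(stomachs: Sequence[StomachRecord],
                       species: Sequence[Species] | None = None, *,
                       month_within_year: bool = False) -> list[ScenarioResult]:
    """Grade 0-2 scaling mean resolved per stomach at the first non-empty
    level of stomach -> month -> season -> study.

    Months are pooled across years by default (mirroring the seasonal
    pooling); ``month_within_year=True`` keys months by (year, month).
    """
    month_key = ((lambda st: (st.stranding_date.year, st.month))
                 if month_within_year else (lambda st: st.month))
    species = list(species) if species else _species_present(stomachs)
    results = []
    for sp in species:
        by_month: dict = defaultdict(list)
        by_season: dict = defaultdict(list)
        study: list[float] = []
        per_stomach: dict[str, list[float]] = {}
        for st in stomachs:
            w = _g02_weights(_otoliths(st, sp))
            per_stomach[st.dolphin_id] = w
            by_month[month_key(st)].extend(w)
            by_season[st.season].extend(w)
            study.extend(w)
        for st in stomachs:
            ots = _otoliths(st, sp)
            if not ots:
                continue
            n02, n35, nun = _counts(ots)
            w02 = per_stomach[st.dolphin_id]
            biomass = float(np.sum(w02))
            level = FallbackLevel.NONE
            if n35:
                mean, level = _fallback_mean(st, w02, by_month, by_season,
                                             study, month_key)
                if mean is None:
                    raise ValueError(
                        f"{sp.value}: no Grade 0-2 otolith at any fallback level")
                biomass += n35 * mean
            results.append(ScenarioResult(
                dolphin_id=st.dolphin_id, species=sp, scenario=Scenario.ITERATIVE,
                biomass_g=biomass, n_grade02=n02, n_grade35=n35, n_unmeasured=nun,
                fallback_level_used=level))
    return results


def scenario_inclusive(stomachs: Sequence[StomachRecord],
                       species: Sequence[Species] | None = None, *,
                       month_within_year: bool = False) -> list[ScenarioResult]:
    """Measured otoliths of all grades contribute their own weights; the
    iterative fallback mean covers unmeasured (broken/not-subsampled) ones."""
    month_key = ((lambda st: (st.stranding_date.year, st.month))
                 if month_within_year else (lambda st: st.month))
    species = list(species) if species else _species_present(stomachs)
    results = []
    for sp in species:
        by_month: dict = defaultdict(list)
        by_season: dict = defaultdict(list)
        study: list[float] = []
        per_stomach: dict[str, list[float]] = {}
        for st in stomachs:
            w = [o.est_weight_g for o in _otoliths(st, sp)
                 if o.est_weight_g is not None]
            per_stomach[st.dolphin_id] = w
            by_month[month_key(st)].extend(w)
            by_season[st.season].extend(w)
            study.extend(w)
        for st in stomachs:
            ots = _otoliths(st, sp)
            if not ots:
                continue
            n02, n35, nun = _counts(ots)
            w_meas = per_stomach[st.dolphin_id]
            biomass = float(np.sum(w_meas))
            level = FallbackLevel.NONE
            if nun:
                mean, level = _fallback_mean(st, w_meas, by_month, by_season,
                                             study, month_key)
                if mean is None:
                    raise ValueError(
                        f"{sp.value}: unmeasured otoliths present but no measured "
                        "otolith at any fallback level")
                biomass += nun * mean
            results.append(ScenarioResult(
                dolphin_id=st.dolphin_id, species=sp, scenario=Scenario.INCLUSIVE,
                biomass_g=biomass, n_grade02=n02, n_grade35=n35, n_unmeasured=nun,
                fallback_level_used=level))
    return results


def run_scenarios(stomachs: Sequence[StomachRecord],
                  species: Sequence[Species] | None = None, *,
                  month_within_year: bool = False) -> dict[Scenario, list[ScenarioResult]]:
    return {
        Scenario.STANDARD: scenario_standard(stomachs, species),
        Scenario.ITERATIVE: scenario_iterative(stomachs, species,
                                               month_within_year=month_within_year),
        Scenario.INCLUSIVE: scenario_inclusive(stomachs, species,
                                               month_within_year=month_within_year),
    }


@dataclass
class SeasonalWeightSummary:
    species: Species
    grade_category: GradeCategory
    per_season: dict[Season, dict]    # mean_g, sd_g, n_otoliths, n_dolphins
    kruskal_h: float
    p_value: float
    pairwise: dict[tuple[Season, Season], float]  # Holm-adjusted rank-test p


def seasonal_weight_comparison(stomachs: Sequence[StomachRecord],
                               species: Species,
                               category: GradeCategory) -> SeasonalWeightSummary:
    """Kruskal-Wallis comparison of estimated weights across seasons within
    one species and grade category, with Holm-adjusted pairwise rank
    contrasts (two-sided Mann-Whitney)."""
    species = Species(species)
    weights: dict[Season, list[float]] = defaultdict(list)
    dolphins: dict[Season, set] = defaultdict(set)
    for st in stomachs:
        for o in _otoliths(st, species):
            if o.grade_category is category and o.est_weight_g is not None:
                weights[st.season].append(o.est_weight_g)
                dolphins[st.season].add(st.dolphin_id)
    seasons = [s for s in Season if weights[s]]
    if len(seasons) < 2:
        raise ValueError(
            f"{species.value}/{category.value}: need >= 2 seasons with data")
    h, p = sps.kruskal(*[weights[s] for s in seasons])
    pairs, raw = [], []
    for i in range(len(seasons)):
        for j in range(i + 1, len(seasons)):
            a, bvals = weights[seasons[i]], weights[seasons[j]]
            res = sps.mannwhitneyu(a, bvals, alternative="two-sided")
            pairs.append((seasons[i], seasons[j]))
            raw.append(res.pvalue)
    adj = holm(raw)
    per_season = {
        s: {"mean_g": float(np.mean(weights[s])),
            "sd_g": float(np.std(weights[s], ddof=1)) if len(weights[s]) > 1 else 0.0,
            "n_otoliths": len(weights[s]),
            "n_dolphins": len(dolphins[s])}
        for s in seasons
    }
    return SeasonalWeightSummary(species=species, grade_category=category,
                                 per_season=per_season, kruskal_h=float(h),
                                 p_value=float(p),
                                 pairwise=dict(zip(pairs, map(float, adj))))


def compare_scenarios(results: dict[Scenario, list[ScenarioResult]], *,
                      b: int = 2000, seed: int = 0) -> dict[Species, WithinUnitTest]:
    """Paired comparison of per-stomach biomass across the three scenarios.

    Requires the same (stomach, species) set under every scenario; the test
    permutes scenario labels within stomach and Holm-adjusts the three
    pairwise contrasts.
    """
    order = [Scenario.STANDARD, Scenario.ITERATIVE, Scenario.INCLUSIVE]
    keyed: dict[Scenario, dict] = {}
    for sc in order:
        keyed[sc] = {(r.dolphin_id, r.species): r.biomass_g for r in results[sc]}
    keys = set(keyed[order[0]])
    for sc in order[1:]:
        if set(keyed[sc]) != keys:
            raise ValueError("scenario results cover different stomach sets")
    out: dict[Species, WithinUnitTest] = {}
    for sp in sorted({k[1] for k in keys}, key=lambda s: s.value):
        rows = sorted(k for k in keys if k[1] is sp)
        mat = np.array([[keyed[sc][k] for sc in order] for k in rows])
        out[sp] = within_unit_permutation(mat, [sc.value for sc in order],
                                          b=b, seed=seed)
    return out
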