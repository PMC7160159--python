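"""Differential digestive-erosion assessment across OL, SL and CL.

Digestion abrades the otolith margin, so otolith length (OL) erodes faster
than the sulcus (SL) and cauda (CL), which lie within the margin. Because
pre-ingestion lengths are unknowable, erosion is detected indirectly:

1. Baseline pairwise regressions among the three features are fitted on
   pristine reference otoliths; prey otoliths are then compared against the
   baselines. The response of each pair is the faster-eroding feature
   (y = OL on x = CL, y = OL on x = SL, y = SL on x = CL), so a negative
   mean deviation of observed y from the baseline prediction means y eroded
   more than x predicts.
2. Fish sizes estimated from each of the three features are compared within
   otolith and between grade categories; if erosion were feature-neutral,
   the three estimates would agree.

Hypothesis tests are permutation analogs (within-otolith label permutation
for the predictor effect, group-label permutation for the grade-category
effect) with Holm correction over the pairwise predictor contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._stats import (WithinUnitTest, bootstrap_ci, group_label_permutation,
                     within_unit_permutation)
from .size_models import Predictor, SizeModel, predict_size
from .types import GradeCategory, PreyOtolith, ReferenceOtolith, Species

__all__ = [
    "BaselinePair",
    "DeviationReport",
    "PredictorComparison",
    "baseline_regressions",
    "deviation_assessment",
    "predictor_comparison",
    "plot_deviation_overlays",
]

# pair orientation: (x feature, y feature) with y the faster-eroding one
PAIRS: tuple[tuple[Predictor, Predictor], ...] = (
    (Predictor.CL, Predictor.OL),
    (Predictor.SL, Predictor.OL),
    (Predictor.CL, Predictor.SL),
)

_FIELD = {Predictor.OL: "ol_mm", Predictor.SL: "sl_mm", Predictor.CL: "cl_mm"}


@dataclass
class BaselinePair:
    """OLS line y = intercept + slope * x fitted on reference otoliths."""

    x_predictor: Predictor
    y_predictor: Predictor
    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class DeviationReport:
    """Deviation of prey otoliths from one baseline in one grade category."""

    pair: BaselinePair
    grade_category: GradeCategory
    n: int
    prey_slope: float | None
    prey_intercept: float | None
    mean_deviation: float | None     # mean(observed y - baseline prediction)
    ci_low: float | None
    ci_high: float | None
    insufficient: bool = False


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor variance in baseline regression")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else float(1 - np.sum(resid ** 2) / tss)
    return float(slope), float(intercept), r2


def baseline_regressions(reference: Sequence[ReferenceOtolith],
                         species: Species) -> dict[tuple[Predictor, Predictor], BaselinePair]:
    """Fit the three pairwise baseline regressions for one species."""
    species = Species(species)
    rows = [o for o in reference if o.species is species
            and o.ol_mm is not None and o.sl_mm is not None and o.cl_mm is not None]
    if len(rows) < 10:
        raise ValueError(f"{species.value}: need >= 10 complete reference rows, have {len(rows)}")
    out = {}
    for xp, yp in PAIRS:
        x = np.array([getattr(o, _FIELD[xp]) for o in rows])
        y = np.array([getattr(o, _FIELD[yp]) for o in rows])
        slope, intercept, r2 = _ols(x, y)
        out[(xp, yp)] = BaselinePair(x_predictor=xp, y_predictor=yp, slope=slope,
                                     intercept=intercept, r2=r2, n=len(rows))
    return out


def deviation_assessment(baselines: dict, prey: Sequence[PreyOtolith],
                         species: Species, *, b: int = 2000, seed: int = 0,
                         min_rows: int = 5) -> list[DeviationReport]:
    """Signed deviation of prey otoliths from each baseline, split by grade
    category, with a seeded bootstrap 95% CI of the mean deviation."""
    species = Species(species)
    reports = []
    for i, ((xp, yp), base) in enumerate(sorted(baselines.items(),
                                                key=lambda kv: (kv[0][0].value,
                                                                kv[0][1].value))):
        for j, cat in enumerate(GradeCategory):
            rows = [o for o in prey
                    if o.species is species and o.grade_category is cat
                    and getattr(o, _FIELD[xp]) is not None
                    and getattr(o, _FIELD[yp]) is not None]
            if len(rows) < min_rows:
                reports.append(DeviationReport(pair=base, grade_category=cat,
                                               n=len(rows), prey_slope=None,
                                               prey_intercept=None,
                                               mean_deviation=None, ci_low=None,
                                               ci_high=None, insufficient=True))
                continue
            x = np.array([getattr(o, _FIELD[xp]) for o in rows])
            y = np.array([getattr(o, _FIELD[yp]) for o in rows])
            dev = y - base.predict(x)
            try:
                slope, intercept, _ = _ols(x, y)
            except ValueError:
                slope = intercept = None
            lo, hi = bootstrap_ci(dev, b=b, seed=seed + 1000 * i + j)
            reports.append(DeviationReport(pair=base, grade_category=cat,
                                           n=len(rows), prey_slope=slope,
                                           prey_intercept=intercept,
                                           mean_deviation=float(dev.mean()),
                                           ci_low=lo, ci_high=hi))
    return reports


@dataclass
class PredictorComparison:
    """Estimated fish sizes per predictor nested in grade category."""

    species: Species
    response: str
    per_category: dict[GradeCategory, WithinUnitTest]
    category_test: dict | None         # grade-category effect on per-otolith means
    percent_diff_cl_vs_ol: dict[GradeCategory, float]
    n_excluded: int


def predictor_comparison(models: dict, prey: Sequence[PreyOtolith],
                         species: Species, *, b: int = 2000,
                         seed: int = 0) -> PredictorComparison:
    """Compare fish sizes estimated from OL, SL and CL on the same otoliths.

    Within each grade category, predictor labels are permuted within otolith
    (B permutations, Holm over the three pairwise contrasts); the
    grade-category effect is tested by permuting category labels over
    per-otolith mean estimates. The headline effect size is the percent
    difference 100 (CL-based - OL-based) / OL-based of mean estimates.
    """
    if b < 1:
        raise ValueError("number of permutations must be positive")
    species = Species(species)
    models = {Predictor(k): v for k, v in models.items()}
    if set(models) != set(Predictor):
        raise ValueError("need one model per predictor OL, SL, CL")
    responses = {m.response for m in models.values()}
    if len(responses) != 1:
        raise ValueError("models must share a response")

    per_cat_values: dict[GradeCategory, list[list[float]]] = {c: [] for c in GradeCategory}
    excluded = 0
    for o in prey:
        if o.species is not species:
            continue
        xs = {p: getattr(o, _FIELD[p]) for p in Predictor}
        if any(v is None for v in xs.values()):
            excluded += 1
            continue
        est = [float(predict_size(models[p], xs[p])) for p in Predictor]
        per_cat_values[o.grade_category].append(est)

    per_category: dict[GradeCategory, WithinUnitTest] = {}
    pct: dict[GradeCategory, float] = {}
    names = [p.value for p in Predictor]
    for idx, (cat, vals) in enumerate(per_cat_values.items()):
        if not vals:
            continue
        mat = np.asarray(vals)
        per_category[cat] = within_unit_permutation(mat, names, b=b,
                                                    seed=seed + idx)
        mean_ol = mat[:, 0].mean()
        mean_cl = mat[:, 2].mean()
        pct[cat] = float(100.0 * (mean_cl - mean_ol) / mean_ol)

    cat_test = None
    a = per_cat_values[GradeCategory.G02]
    g = per_cat_values[GradeCategory.G35]
    if a and g:
        cat_test = group_label_permutation(
            np.asarray(a).mean(axis=1), np.asarray(g).mean(axis=1),
            b=b, seed=seed + 97)

    return PredictorComparison(species=species, response=responses.pop().value,
                               per_category=per_category, category_test=cat_test,
                               percent_diff_cl_vs_ol=pct, n_excluded=excluded)


def plot_deviation_overlays(reports: Sequence[DeviationReport], path=None):
    """Baseline-vs-prey regression overlays (one panel per feature pair)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = sorted({(r.pair.x_predictor, r.pair.y_predictor) for r in reports},
                   key=lambda p: (p[0].value, p[1].value))
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5),
                             squeeze=False)
    for ax, pair in zip(axes[0], pairs):
        sub = [r for r in reports
               if (r.pair.x_predictor, r.pair.y_predictor) == pair]
        base = sub[0].pair
        x = np.linspace(1, 25, 50)
        ax.plot(x, base.predict(x), "k-", label="baseline")
        for r in sub:
            if r.insufficient or r.prey_slope is None:
                continue
            ax.plot(x, r.prey_intercept + r.prey_slope * x, "--",
                    label=f"prey {r.grade_category.value}")
        ax.set_xlabel(f"{pair[0].value} (mm)")
        ax.set_ylabel(f"{pair[1].value} (mm)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
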