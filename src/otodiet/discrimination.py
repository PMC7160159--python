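"""CL:SL discrimination between spotted seatrout and weakfish.

The cauda-to-sulcus length ratio separates the two *Cynoscion* species: the
spotted seatrout sulcus is relatively shorter-caudaed (ratio around 0.46)
than weakfish (around 0.53). A univariate recursive partition learns a
single optimal cut-point; a second, forced split brackets the ambiguous
ratio band where the two species overlap, and otoliths falling in that band
are apportioned between species by the band's class probabilities.

All threshold comparisons use the ratio rounded to two decimals, the
precision at which cut-points and the ambiguous band are reported; the raw
ratio is retained on every result.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._stats import largest_remainder
from .types import Nodules, PreyOtolith, ReferenceOtolith, Species

__all__ = [
    "SplitRule",
    "ClassificationResult",
    "ClassificationMethod",
    "compute_ratio",
    "learn_split",
    "classify_otolith",
    "classify_prey",
    "apportion_ambiguous",
    "nodule_summary",
]

PROB_FLOOR = 0.003  # leaf probabilities are never zero


class ClassificationMethod(str, enum.Enum):
    RATIO_RULE = "ratio_rule"
    BAND_APPORTION = "band_apportion"
    VISUAL_UNRESOLVABLE = "visual_unresolvable"


def compute_ratio(cl_mm: float, sl_mm: float) -> float:
    """Cauda:sulcus length ratio CL/SL (dimensionless)."""
    if sl_mm is None or cl_mm is None or sl_mm <= 0 or cl_mm <= 0:
        raise ValueError("CL and SL must both be positive")
    if cl_mm >= sl_mm:
        raise ValueError(f"CL ({cl_mm}) must be smaller than SL ({sl_mm})")
    return cl_mm / sl_mm


def band_ratio(ratio: float) -> float:
    """Ratio rounded to the 2-decimal resolution used for band comparison."""
    return round(float(ratio), 2)


@dataclass
class SplitRule:
    """Learned (or published) CL:SL cut-points with leaf class probabilities.

    ``cut_low <= cut_high`` bound the closed ambiguous band at 2-decimal
    resolution. ``outer_probs`` holds the class probabilities of the two
    outer leaves (keys ``below`` / ``above``); ``band_probs`` those of the
    middle leaf. Probabilities are floored (never zero) and each map sums
    to one.
    """

    cut_low: float
    cut_high: float
    band_probs: dict[Species, float]
    outer_probs: dict[str, dict[Species, float]]
    cv_r2: float | None = None
    accuracy: float | None = None
    n: int | None = None
    raw_primary_cut: float | None = None    # unrounded optimal single cut
    raw_secondary_cut: float | None = None  # unrounded forced second cut

    def __post_init__(self) -> None:
        if self.cut_low > self.cut_high:
            raise ValueError("cut_low must not exceed cut_high")
        self.band_probs = {Species(k): float(v) for k, v in self.band_probs.items()}
        self.outer_probs = {
            side: {Species(k): float(v) for k, v in probs.items()}
            for side, probs in self.outer_probs.items()
        }
        for name, probs in [("band", self.band_probs),
                            ("below", self.outer_probs["below"]),
                            ("above", self.outer_probs["above"])]:
            s = sum(probs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {s}, not 1")
            if any(not (0 < p < 1) for p in probs.values()):
                raise ValueError(f"{name} probabilities must lie strictly in (0,1)")

    @property
    def collapsed(self) -> bool:
        return self.cut_low == self.cut_high

    @property
    def species_below(self) -> Species:
        return max(self.outer_probs["below"], key=lambda s: self.outer_probs["below"][s])

    @property
    def species_above(self) -> Species:
        return max(self.outer_probs["above"], key=lambda s: self.outer_probs["above"][s])

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "cut_low": self.cut_low,
            "cut_high": self.cut_high,
            "band_probs": {s.value: p for s, p in self.band_probs.items()},
            "outer_probs": {side: {s.value: p for s, p in probs.items()}
                            for side, probs in self.outer_probs.items()},
            "cv_r2": self.cv_r2,
            "accuracy": self.accuracy,
            "n": self.n,
            "raw_primary_cut": self.raw_primary_cut,
            "raw_secondary_cut": self.raw_secondary_cut,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitRule":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def paper_rule() -> SplitRule:
    """The published cut-points (.49/.50) and leaf probabilities."""
    st, wf = Species.SPOTTED_SEATROUT, Species.WEAKFISH
    return SplitRule(
        cut_low=0.49, cut_high=0.50,
        band_probs={st: 0.202, wf: 0.798},
        outer_probs={"below": {st: 0.997, wf: 0.003},
                     "above": {st: 0.003, wf: 0.997}},
    )


@dataclass
class ClassificationResult:
    ratio: float
    assigned_species: Species | None
    probability: float
    method: ClassificationMethod
    band_probs: dict[Species, float] | None = None

    @property
    def ambiguous(self) -> bool:
        return self.assigned_species is None and self.method is ClassificationMethod.BAND_APPORTION


def _misclass_single(ratios: np.ndarray, labels: np.ndarray, cut: float) -> int:
    """Misclassifications of the two-leaf majority rule at ``cut``."""
    below = ratios < cut
    err = 0
    for mask in (below, ~below):
        if mask.any():
            counts = np.bincount(labels[mask], minlength=2)
            err += int(counts.sum() - counts.max())
    return err


def _misclass_double(ratios: np.ndarray, labels: np.ndarray,
                     lo: float, hi: float) -> int:
    err = 0
    for mask in (ratios < lo, (ratios >= lo) & (ratios < hi), ratios >= hi):
        if mask.any():
            counts = np.bincount(labels[mask], minlength=2)
            err += int(counts.sum() - counts.max())
    return err


def _smoothed_probs(counts: dict[Species, int]) -> dict[Species, float]:
    """Add-one (Laplace) smoothing, then a hard floor with renormalization."""
    total = sum(counts.values()) + len(counts)
    probs = {s: (c + 1) / total for s, c in counts.items()}
    probs = {s: max(p, PROB_FLOOR) for s, p in probs.items()}
    z = sum(probs.values())
    return {s: p / z for s, p in probs.items()}


def learn_split(reference: Sequence[ReferenceOtolith], *, folds: int = 10,
                seed: int = 0,
                include_nodules: bool = False) -> SplitRule:
    """Learn the CL:SL cut-points from labelled reference otoliths.

    Exhaustive search over candidate cuts (midpoints of sorted unique
    ratios) minimizing training misclassification gives the optimal single
    split; a second, forced split brackets the ambiguous band. Leaf class
    probabilities are Laplace-smoothed so no probability is ever zero.
    Resubstitution accuracy and a cross-validated fit statistic (fold
    assignment by seeded permutation, stratified by species) are attached.

    ``include_nodules`` additionally offers the nodule category as a split
    candidate; with the default ratio structure it never wins and is off by
    default, matching the published analysis.
    """
    rows = [o for o in reference
            if o.species in (Species.SPOTTED_SEATROUT, Species.WEAKFISH)
            and o.cl_mm is not None and o.sl_mm is not None]
    species = sorted({o.species for o in rows}, key=lambda s: s.value)
    if len(species) < 2:
        raise ValueError("both spotted seatrout and weakfish must be present")
    if len(rows) < folds:
        raise ValueError(f"{len(rows)} usable rows < {folds} folds")

    ratios = np.array([compute_ratio(o.cl_mm, o.sl_mm) for o in rows])
    labels = np.array([0 if o.species is Species.SPOTTED_SEATROUT else 1
                       for o in rows])

    order = np.argsort(ratios)
    uniq = np.unique(ratios)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    if cuts.size == 0:
        raise ValueError("all ratios identical; no candidate split")

    errs = np.array([_misclass_single(ratios, labels, c) for c in cuts])
    c1 = float(cuts[int(np.argmin(errs))])  # smallest minimizing midpoint

    if include_nodules:
        # a categorical split on nodules-present vs not, offered as an
        # alternative first split; kept only if strictly better
        nod = np.array([o.nodules is Nodules.PRESENT for o in rows])
        if nod.any() and (~nod).any():
            err_nod = 0
            for mask in (nod, ~nod):
                counts = np.bincount(labels[mask], minlength=2)
                err_nod += int(counts.sum() - counts.max())
            if err_nod < errs.min():
                raise NotImplementedError(
                    "nodule category won the optimal split; the packaged rule "
                    "only supports ratio cut-points")

    rest = cuts[cuts != c1]
    if rest.size:
        errs2 = np.array([_misclass_double(ratios, labels, min(c1, c), max(c1, c))
                          for c in rest])
        # ties go to the cut nearest the primary split so the ambiguous band
        # stays tight around the class boundary
        best = np.flatnonzero(errs2 == errs2.min())
        c2 = float(min((abs(rest[i] - c1), rest[i]) for i in best)[1])
    else:
        c2 = c1
    lo, hi = band_ratio(min(c1, c2)), band_ratio(max(c1, c2))

    r2dp = np.round(ratios, 2)
    st, wf = Species.SPOTTED_SEATROUT, Species.WEAKFISH

    def leaf_counts(mask: np.ndarray) -> dict[Species, int]:
        return {st: int((labels[mask] == 0).sum()), wf: int((labels[mask] == 1).sum())}

    rule = SplitRule(
        cut_low=lo, cut_high=hi,
        band_probs=_smoothed_probs(leaf_counts((r2dp >= lo) & (r2dp <= hi))),
        outer_probs={
            "below": _smoothed_probs(leaf_counts(r2dp < lo)),
            "above": _smoothed_probs(leaf_counts(r2dp > hi)),
        },
        n=len(rows),
        raw_primary_cut=c1,
        raw_secondary_cut=c2,
    )

    # resubstitution accuracy: ambiguous rows take the band-majority species
    band_major = 0 if rule.band_probs[st] >= rule.band_probs[wf] else 1
    pred = np.where(r2dp < lo, 0, np.where(r2dp > hi, 1, band_major))
    rule.accuracy = float((pred == labels).mean())
    rule.cv_r2 = _cv_pseudo_r2(ratios, labels, folds=folds, seed=seed)
    return rule


def _cv_pseudo_r2(ratios: np.ndarray, labels: np.ndarray, *, folds: int,
                  seed: int) -> float:
    """Cross-validated proportional reduction in classification error.

    1 - (held-out error of the learned single split) / (error of the
    majority-class baseline); clipped at 0. Folds are assigned by a seeded
    permutation stratified by species.
    """
    rng = np.random.default_rng(seed)
    fold_id = np.empty(len(ratios), dtype=int)
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        fold_id[idx] = np.arange(len(idx)) % folds
    errors = 0
    for f in range(folds):
        test = fold_id == f
        train = ~test
        if not test.any() or len(np.unique(labels[train])) < 2:
            continue
        tr_r, tr_l = ratios[train], labels[train]
        uniq = np.unique(tr_r)
        cuts = (uniq[:-1] + uniq[1:]) / 2.0
        if cuts.size == 0:
            continue
        errs = np.array([_misclass_single(tr_r, tr_l, c) for c in cuts])
        cut = float(cuts[int(np.argmin(errs))])
        below_major = _majority(tr_l[tr_r < cut])
        above_major = _majority(tr_l[tr_r >= cut])
        pred = np.where(ratios[test] < cut, below_major, above_major)
        errors += int((pred != labels[test]).sum())
    cv_err = errors / len(ratios)
    counts = np.bincount(labels, minlength=2)
    base_err = 1 - counts.max() / counts.sum()
    if base_err == 0:
        return 1.0
    return float(max(0.0, 1 - cv_err / base_err))


def _majority(labels: np.ndarray) -> int:
    if labels.size == 0:
        return 0
    counts = np.bincount(labels, minlength=2)
    return int(np.argmax(counts))


def classify_otolith(ratio: float, rule: SplitRule) -> ClassificationResult:
    """Assign a species (or the ambiguous band) to a CL:SL ratio."""
    r = band_ratio(ratio)
    if rule.collapsed:
        side = "below" if r < rule.cut_low else "above"
        sp = rule.species_below if side == "below" else rule.species_above
        return ClassificationResult(ratio=float(ratio), assigned_species=sp,
                                    probability=rule.outer_probs[side][sp],
                                    method=ClassificationMethod.RATIO_RULE)
    if r < rule.cut_low:
        sp = rule.species_below
        return ClassificationResult(ratio=float(ratio), assigned_species=sp,
                                    probability=rule.outer_probs["below"][sp],
                                    method=ClassificationMethod.RATIO_RULE)
    if r > rule.cut_high:
        sp = rule.species_above
        return ClassificationResult(ratio=float(ratio), assigned_species=sp,
                                    probability=rule.outer_probs["above"][sp],
                                    method=ClassificationMethod.RATIO_RULE)
    top = max(rule.band_probs.values())
    return ClassificationResult(ratio=float(ratio), assigned_species=None,
                                probability=top,
                                method=ClassificationMethod.BAND_APPORTION,
                                band_probs=dict(rule.band_probs))


def classify_prey(otoliths: Iterable[PreyOtolith], rule: SplitRule,
                  ) -> list[ClassificationResult | None]:
    """Apply the ratio rule to *Cynoscion* prey otoliths in place.

    Sets ``species_final`` for unambiguous unbroken otoliths; broken ones
    are flagged ``visual_unresolvable`` (their published resolution was by
    eye) and keep their initial identification. Non-*Cynoscion* otoliths get
    ``species_final = species_initial`` and a ``None`` result entry.
    """
    results: list[ClassificationResult | None] = []
    targets = (Species.SPOTTED_SEATROUT, Species.WEAKFISH)
    for o in otoliths:
        if o.species_initial not in targets:
            o.species_final = o.species_initial
            results.append(None)
            continue
        if o.broken or o.cl_mm is None or o.sl_mm is None:
            o.species_final = o.species_initial
            results.append(ClassificationResult(
                ratio=float("nan"), assigned_species=o.species_initial,
                probability=1.0, method=ClassificationMethod.VISUAL_UNRESOLVABLE))
            continue
        res = classify_otolith(compute_ratio(o.cl_mm, o.sl_mm), rule)
        if res.assigned_species is not None:
            o.species_final = res.assigned_species
        results.append(res)
    return results


def apportion_ambiguous(n_ambiguous: int, rule: SplitRule) -> dict[Species, int]:
    """Apportion band otoliths between species by expected counts n*p,
    largest-remainder rounded so the counts sum to ``n_ambiguous``."""
    if n_ambiguous < 0:
        raise ValueError("n_ambiguous must be non-negative")
    if n_ambiguous == 0:
        return {s: 0 for s in rule.band_probs}
    alloc = largest_remainder({s.value: p for s, p in rule.band_probs.items()},
                              n_ambiguous)
    return {Species(k): v for k, v in alloc.items()}


def nodule_summary(otoliths: Iterable) -> dict[Species, dict[Nodules, float]]:
    """Per-species proportions of nodule categories over recorded rows only."""
    counts: dict[Species, dict[Nodules, int]] = {}
    for o in otoliths:
        if o.nodules is Nodules.UNRECORDED:
            continue
        sp = o.species if isinstance(getattr(o, "species", None), Species) else o.species_initial
        counts.setdefault(sp, {n: 0 for n in
                               (Nodules.PRESENT, Nodules.REDUCED, Nodules.ABSENT)})
        counts[sp][o.nodules] += 1
    out: dict[Species, dict[Nodules, float]] = {}
    for sp, c in counts.items():
        total = sum(c.values())
        out[sp] = {n: v / total for n, v in c.items()}
    return out
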