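"""Prey enumeration and stratified measurement subsampling."""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from ._stats import largest_remainder
from .types import AgeClass, PreyOtolith, Side, StomachRecord

__all__ = ["enumerate_prey", "restrict_to_counted_side", "stratified_subsample"]


def enumerate_prey(otoliths: Sequence[PreyOtolith]) -> tuple[int, Side | None]:
    """Estimate the number of fish of one species in one stomach.

    Left and right otoliths are counted separately and the larger count is
    the prey number; downstream grading and measurement are restricted to
    that side. A tie goes to the right side (reference measurements were
    primarily of right otoliths). An empty collection yields (0, None).
    """
    if not otoliths:
        return 0, None
    ids = {o.dolphin_id for o in otoliths}
    if len(ids) > 1:
        raise ValueError(f"otoliths span multiple dolphins: {sorted(ids)}")
    species = {o.species for o in otoliths}
    if len(species) > 1:
        raise ValueError(f"otoliths span multiple species: {sorted(s.value for s in species)}")
    n_left = sum(o.side is Side.LEFT for o in otoliths)
    n_right = sum(o.side is Side.RIGHT for o in otoliths)
    side = Side.LEFT if n_left > n_right else Side.RIGHT
    return max(n_left, n_right), side


def restrict_to_counted_side(stomachs: Sequence[StomachRecord]) -> list[StomachRecord]:
    """Keep, per stomach and species, only otoliths from the counted side.

    The higher-count side estimates the number of fish consumed, and all
    downstream grading, measurement and biomass counting operate on that
    side only (each fish then contributes at most one otolith).
    """
    for st in stomachs:
        by_species: dict = defaultdict(list)
        for o in st.otoliths:
            by_species[o.species].append(o)
        kept: list[PreyOtolith] = []
        for ots in by_species.values():
            _, side = enumerate_prey(ots)
            kept.extend(o for o in ots if o.side is side)
        st.otoliths = kept
    return list(stomachs)


def stratified_subsample(
    otoliths: Sequence[PreyOtolith],
    strandings: Iterable[StomachRecord],
    target_n: int,
    seed: int,
) -> list[PreyOtolith]:
    """Choose a measurement subset proportional to dolphin age-class strata.

    Mirrors the measurement protocol for the abundant heavily eroded
    otoliths: allocation across age classes (unknown is its own stratum) is
    proportional to stratum size with largest-remainder rounding, then within
    each stratum dolphins and their otoliths are drawn uniformly at random
    under the given seed. Broken/compromised otoliths are excluded before
    anything is allocated.
    """
    age_by_dolphin = {s.dolphin_id: s.age_class for s in strandings}
    eligible = [o for o in otoliths if not o.broken]
    for o in eligible:
        if o.dolphin_id not in age_by_dolphin:
            raise KeyError(f"no stranding record for dolphin {o.dolphin_id!r}")
    if target_n > len(eligible):
        raise ValueError(
            f"target_n={target_n} exceeds the {len(eligible)} measurable otoliths")

    strata: dict[AgeClass, list[PreyOtolith]] = defaultdict(list)
    for o in eligible:
        strata[age_by_dolphin[o.dolphin_id]].append(o)

    sizes = {ac.value: len(v) for ac, v in strata.items()}
    alloc = largest_remainder(sizes, target_n)
    # largest-remainder can ask a small stratum for more than it holds only
    # if another stratum is undersubscribed; cap and redistribute greedily
    alloc = _cap_and_redistribute(alloc, sizes, target_n)

    rng = np.random.default_rng(seed)
    chosen: list[PreyOtolith] = []
    for ac in sorted(strata, key=lambda a: a.value):
        k = alloc[ac.value]
        if k == 0:
            continue
        members = strata[ac]
        by_dolphin: dict[str, list[PreyOtolith]] = defaultdict(list)
        for o in members:
            by_dolphin[o.dolphin_id].append(o)
        dolphin_order = list(rng.permutation(sorted(by_dolphin)))
        pool: list[PreyOtolith] = []
        for d in dolphin_order:
            olist = by_dolphin[d]
            pool.extend(olist[i] for i in rng.permutation(len(olist)))
        chosen.extend(pool[:k])
    return chosen


def _cap_and_redistribute(alloc: dict, sizes: dict, target_n: int) -> dict:
    alloc = dict(alloc)
    overflow = 0
    for k in alloc:
        if alloc[k] > sizes[k]:
            overflow += alloc[k] - sizes[k]
            alloc[k] = sizes[k]
    while overflow > 0:
        # give spare picks to the stratum with the most unused capacity
        k = max(alloc, key=lambda kk: (sizes[kk] - alloc[kk], kk))
        if sizes[k] == alloc[k]:
            raise ValueError("target_n exceeds available otoliths")
        alloc[k] += 1
        overflow -= 1
    return alloc
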