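"""Shared statistical helpers: apportionment, permutation tests, bootstrap.

The permutation tests here are the package's assumption-light analogs of
repeated-measures ANOVA: condition labels are permuted within each unit
(fish, otolith or stomach), which realizes the null of exchangeable
conditions while preserving between-unit heterogeneity. p-values use the
add-one convention p = (1 + #{perm >= obs}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations, product

import numpy as np
from statsmodels.stats.multitest import multipletests


def largest_remainder(weights: dict, total: int) -> dict:
    """Apportion ``total`` integer seats proportionally to ``weights``.

    Hamilton / largest-remainder rounding: floor each quota, then hand the
    spare seats to the largest fractional remainders. Ties on the remainder
    go first to the key with the smaller floored allocation, then by key
    order, so the result is deterministic.
    """
    from fractions import Fraction

    if total < 0:
        raise ValueError("total must be non-negative")
    keys = list(weights)
    w = [Fraction(str(weights[k])) for k in keys]
    if any(v < 0 for v in w):
        raise ValueError("weights must be non-negative")
    s = sum(w)
    if s == 0:
        if total:
            raise ValueError("cannot apportion a positive total over zero weights")
        return {k: 0 for k in keys}
    # exact rational quotas so remainder ties are genuine ties
    quota = [v / s * total for v in w]
    alloc = [int(q) for q in quota]
    remainder = [q - a for q, a in zip(quota, alloc)]
    spare = total - sum(alloc)
    order = sorted(range(len(keys)),
                   key=lambda i: (-remainder[i], alloc[i], keys[i]))
    for i in order[:spare]:
        alloc[i] += 1
    return {k: int(a) for k, a in zip(keys, alloc)}


def holm(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class WithinUnitTest:
    """Result of a within-unit condition-label permutation test."""

    conditions: list
    means: dict                  # condition -> observed mean
    pairwise_diff: dict          # (a, b) -> mean(a) - mean(b)
    pairwise_p: dict             # (a, b) -> raw permutation p (two-sided on |diff|)
    pairwise_p_holm: dict        # Holm-adjusted over the pairwise contrasts
    global_stat: float           # max over pairs of |mean difference|
    global_p: float
    n_units: int
    n_permutations: int


def within_unit_permutation(values: np.ndarray, conditions, *, b: int,
                            seed: int) -> WithinUnitTest:
    """Permutation test for a condition effect with one value per
    unit x condition.

    ``values`` is (n_units, k). Under the null the k values of each unit are
    exchangeable, so each permutation independently shuffles every row. The
    global statistic is the maximum absolute pairwise difference of condition
    means; per-pair p-values use that pair's |mean difference|.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(conditions):
        raise ValueError("values must be (n_units, n_conditions)")
    if b < 1:
        raise ValueError("number of permutations must be positive")
    n, k = x.shape
    if n == 0:
        raise ValueError("no units to test")
    # canonical row order: the p-value is then exactly invariant to how the
    # caller happened to order the units
    x = x[np.lexsort(x.T[::-1])]
    rng = np.random.default_rng(seed)

    pairs = list(combinations(range(k), 2))
    obs_means = x.mean(axis=0)
    obs_diff = {p: obs_means[p[0]] - obs_means[p[1]] for p in pairs}
    obs_abs = np.array([abs(obs_diff[p]) for p in pairs])
    obs_global = obs_abs.max()

    ge_pair = np.zeros(len(pairs), dtype=np.int64)
    ge_global = 0
    chunk = max(1, int(2_000_000 // max(1, n * k)))
    done = 0
    while done < b:
        m = min(chunk, b - done)
        idx = np.argsort(rng.random((m, n, k)), axis=2)
        perm = np.take_along_axis(np.broadcast_to(x, (m, n, k)), idx, axis=2)
        means = perm.mean(axis=1)                    # (m, k)
        d = np.stack([np.abs(means[:, i] - means[:, j]) for i, j in pairs], axis=1)
        ge_pair += (d >= obs_abs[None, :] - 1e-12).sum(axis=0)
        ge_global += int((d.max(axis=1) >= obs_global - 1e-12).sum())
        done += m

    raw_p = (1.0 + ge_pair) / (b + 1.0)
    adj = holm(raw_p)
    key = [(conditions[i], conditions[j]) for i, j in pairs]
    return WithinUnitTest(
        conditions=list(conditions),
        means={c: float(m) for c, m in zip(conditions, obs_means)},
        pairwise_diff={kk: float(obs_diff[p]) for kk, p in zip(key, pairs)},
        pairwise_p={kk: float(p_) for kk, p_ in zip(key, raw_p)},
        pairwise_p_holm={kk: float(p_) for kk, p_ in zip(key, adj)},
        global_stat=float(obs_global),
        global_p=float((1 + ge_global) / (b + 1)),
        n_units=n,
        n_permutations=b,
    )


def within_unit_exact(values: np.ndarray, conditions) -> dict:
    """Exact enumeration analog of :func:`within_unit_permutation`.

    Feasible only for tiny tables (k! ** n arrangements); used as an
    independent oracle in tests, and exposed for small-sample runs.
    """
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    pairs = list(combinations(range(k), 2))
    obs_means = x.mean(axis=0)
    obs_abs = np.array([abs(obs_means[i] - obs_means[j]) for i, j in pairs])
    obs_global = obs_abs.max()
    perms = list(permutations(range(k)))
    ge_pair = np.zeros(len(pairs), dtype=np.int64)
    ge_global = 0
    total = 0
    for assignment in product(perms, repeat=n):
        perm = np.stack([x[i, list(assignment[i])] for i in range(n)])
        means = perm.mean(axis=0)
        d = np.array([abs(means[i] - means[j]) for i, j in pairs])
        ge_pair += d >= obs_abs - 1e-12
        ge_global += d.max() >= obs_global - 1e-12
        total += 1
    key = [(conditions[i], conditions[j]) for i, j in pairs]
    return {
        "pairwise_p": {kk: ge_pair[i] / total for i, kk in enumerate(key)},
        "global_p": ge_global / total,
        "n_arrangements": total,
    }


def group_label_permutation(values_a, values_b, *, b: int, seed: int) -> dict:
    """Two-group permutation test on |mean(A) - mean(B)|."""
    a = np.asarray(values_a, dtype=float)
    bb = np.asarray(values_b, dtype=float)
    if b < 1:
        raise ValueError("number of permutations must be positive")
    pooled = np.concatenate([a, bb])
    na = len(a)
    obs = abs(a.mean() - bb.mean())
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(b):
        perm = rng.permutation(pooled)
        ge += abs(perm[:na].mean() - perm[na:].mean()) >= obs - 1e-12
    return {"diff": float(a.mean() - bb.mean()), "p": (1 + ge) / (b + 1),
            "n_a": na, "n_b": len(bb)}


def bootstrap_ci(values, *, b: int = 2000, seed: int, level: float = 0.95) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the mean."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(b, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)
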