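"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately use naive enumeration / pixel counting, not the package's
algorithms, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def density_by_counting(binary: np.ndarray, excluded: np.ndarray) -> float:
    """Perfusion density by explicit per-pixel loops."""
    fg = 0
    roi = 0
    h, w = binary.shape
    for i in range(h):
        for j in range(w):
            if not excluded[i, j]:
                roi += 1
                if binary[i, j]:
                    fg += 1
    return fg / roi


def wilcoxon_exact_by_enumeration(diffs) -> float:
    """Two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            ranks[np.array(signs) > 0].sum()
            for signs in itertools.product([-1, 1], repeat=n)
        ]
    )
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney_exact_by_enumeration(a, b) -> float:
    """Two-sided Mann-Whitney p over all C(n, n_a) rank splits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array(
        [
            ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            for idx in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def spearman_exact_by_enumeration(x, y) -> tuple[float, float]:
    """Exact permutation p for the rank correlation (n! permutations)."""
    rx = rankdata(x)
    ry = rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / total


def power_by_simulation(
    effect_size: float, n_per_group: int, alpha: float, n_reps: int, seed: int
) -> float:
    """Monte-Carlo two-sample t-test power (vectorized over experiments)."""
    from scipy.stats import ttest_ind

    rng = np.random.default_rng(seed)
    a = rng.normal(effect_size, 1.0, (n_reps, n_per_group))
    b = rng.normal(0.0, 1.0, (n_reps, n_per_group))
    p = ttest_ind(a, b, axis=1).pvalue
    return float(np.mean(p < alpha))
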