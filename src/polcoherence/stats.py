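"""Shared rank-test engine.

Two-sided Mann-Whitney U with a hybrid evaluation strategy: when both
groups have at most ``exact_max`` observations the permutation
distribution of U is enumerated exactly over all C(n, n1) group
assignments (midranks for ties, so tied data are handled correctly); for
larger groups the tie-corrected normal approximation with continuity
correction is used via scipy.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney_u", "EXACT_MAX_GROUP"]

#: Largest per-group size for which the exact enumeration is used.
EXACT_MAX_GROUP = 8


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #{(i,j): x_i > y_j} + ½·#{ties} (midrank convention)."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(
    x, y, exact_max: int = EXACT_MAX_GROUP
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns
    -------
    (u, p)
        ``u`` is the U statistic of the *first* group; ``p`` the two-sided
        p-value. Exact: the fraction of the C(n, n1) equally likely group
        assignments whose U deviates from the null mean n1·n2/2 at least as
        much as observed. Asymptotic: tie-corrected normal approximation
        with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    if n1 <= exact_max and n2 <= exact_max:
        pooled = np.concatenate([x, y])
        n = n1 + n2
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = math.comb(n, n1)
        all_idx = frozenset(range(n))
        for idx in combinations(range(n), n1):
            xa = pooled[list(idx)]
            ya = pooled[list(all_idx - set(idx))]
            if abs(_u_statistic(xa, ya) - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return u_obs, float(res.pvalue)
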