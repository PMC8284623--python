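"""Brute-force reference implementations used only to check the package.

These deliberately avoid the libraries the implementation relies on
(skimage labeling, scipy's Mann-Whitney, lifelines) so that agreement is
an independent check, not a tautology.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
OFFSETS_8 = OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_components(mask: np.ndarray, connectivity: int) -> int:
    """Count connected components by exhaustive breadth-first flood fill."""
    offsets = OFFSETS_4 if connectivity == 4 else OFFSETS_8
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                count += 1
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    rr, cc = q.popleft()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
    return count


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact Mann-Whitney U and two-sided p by full enumeration.

    Enumerates every assignment of the pooled observations to the two
    groups; valid for small samples with distinct values (no ties).
    """
    x, y = list(map(float, x)), list(map(float, y))
    m, n = len(x), len(y)

    def u_stat(a, b):
        return sum(1.0 for xi in a for yj in b if xi > yj) + 0.5 * sum(
            1.0 for xi in a for yj in b if xi == yj
        )

    u_obs = u_stat(x, y)
    pooled = x + y
    us = [
        u_stat([pooled[i] for i in comb], [pooled[i] for i in range(m + n) if i not in set(comb)])
        for comb in itertools.combinations(range(m + n), m)
    ]
    us = np.array(us)
    u_lo = min(u_obs, m * n - u_obs)
    p = float(np.mean(us <= u_lo) + np.mean(us >= m * n - u_lo))
    return u_obs, min(p, 1.0)


def empirical_survival(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """S(t) = fraction of observations strictly greater than t (no censoring)."""
    times = np.asarray(times, dtype=float)
    return np.array([np.mean(times > t) for t in grid])


def permutation_logrank_p(time, event, group, statistic_fn, n_perm=2000, seed=0):
    """Permutation-null p for a two-group test statistic on survival data."""
    rng = np.random.default_rng(seed)
    group = np.asarray(group)
    obs = statistic_fn(time, event, group)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        if statistic_fn(time, event, perm) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
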