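"""Independent brute-force oracles used by the tests.

Everything here is written in the most naive correct style possible (scalar
loops, direct enumeration, closed-form rank formulas) and deliberately shares
no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_run_length(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Naive per-voxel 26-direction run-length: march voxel by voxel.

    For each on voxel and each antipodal direction pair, walk in +d and -d
    until leaving the mask or the grid; pair length = (n+ + n- + 1) * step;
    result = min over the 13 pairs.  Off voxels -> 0.
    """
    mask = np.asarray(mask).astype(bool)
    shape = mask.shape
    dirs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
    out = np.zeros(shape, dtype=float)

    def march(start, d):
        n = 0
        x, y, z = start
        while True:
            x, y, z = x + d[0], y + d[1], z + d[2]
            if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
                return n
            if not mask[x, y, z]:
                return n
            n += 1

    for v in zip(*np.nonzero(mask)):
        best = math.inf
        for d in dirs:
            step = math.sqrt(sum((d[i] * spacing[i]) ** 2 for i in range(3)))
            n_plus = march(v, d)
            n_minus = march(v, tuple(-c for c in d))
            best = min(best, (n_plus + n_minus + 1) * step)
        out[v] = best
    return out


def holm_stepdown(ps, alpha=0.05):
    """Hand step-down Holm: sort ascending, running max of (m-j+1)*p, cap 1."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    corrected = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * ps[i])
        corrected[i] = min(running, 1.0)
    return corrected


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney by listing every group assignment.

    Returns (U1 of x, p) with p = twice the smaller inclusive tail, capped.
    """
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y

    def midranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    ranks = midranks(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0)
    low = sum(1 for u in us if u <= u_obs + 1e-9) / len(us)
    high = sum(1 for u in us if u >= u_obs - 1e-9) / len(us)
    return u_obs, min(1.0, 2.0 * min(low, high))


def kruskal_rank_formula(*groups):
    """H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2, no tie handling."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    for r, i in enumerate(order):
        ranks[i] = r + 1.0
    h = 0.0
    start = 0
    rbar = (n + 1) / 2.0
    for g in groups:
        gr = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (sum(gr) / len(g) - rbar) ** 2
    return 12.0 / (n * (n + 1)) * h


def spearman_d2_formula(x, y):
    """r_S = 1 - 6 sum d^2 / (n (n^2 - 1)); valid without ties."""
    n = len(x)
    rx = [sorted(x).index(v) + 1 for v in x]
    ry = [sorted(y).index(v) + 1 for v in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))
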