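"""Nonparametric group statistics.

Group differences of the atrophy indicators are tested with a Kruskal-Wallis
H omnibus test; only when the omnibus is significant are pairwise
Mann-Whitney U tests run, with Holm-Bonferroni step-down correction across
the pairwise family (the three group pairs per indicator by default).
Correlations between indicators use Spearman's rank coefficient.

Small-sample exactness: the Mann-Whitney p-value is computed by full
enumeration of group assignments when the combined sample is small and
tie-free (enumeration handles ties too when forced), and the Spearman
p-value by full permutation for n <= 9; otherwise the usual normal / t
approximations (with tie corrections) apply.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: combined-n cutoff below which the tie-free Mann-Whitney p is enumerated
MW_EXACT_MAX_N = 20
#: sample-size cutoff below which the Spearman p is a full permutation p
SPEARMAN_EXACT_MAX_N = 9


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df.

    If every value across groups is identical the statistic is undefined;
    that degenerate case is reported as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group must be non-empty")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:  # all numbers identical: H undefined
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _mw_u1(x_ranks_sum: float, n1: int) -> float:
    return x_ranks_sum - n1 * (n1 + 1) / 2.0


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by full enumeration of group assignments.

    Mid-ranks make the enumeration valid with ties; the two-sided p is twice
    the smaller inclusive tail of the U null distribution, capped at 1.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _mw_u1(ranks[:n1].sum(), n1)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    eps = 1e-9
    p_low = np.mean(u_all <= u_obs + eps)
    p_high = np.mean(u_all >= u_obs - eps)
    return float(u_obs), float(min(1.0, 2.0 * min(p_low, p_high)))


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    U is the statistic of the first sample (U1 = R1 - n1(n1+1)/2, so fully
    separated x < y gives U = 0).  ``method``:

    * ``"auto"`` — exact enumeration when combined n <= 20 with no ties,
      otherwise normal approximation with tie and continuity correction;
    * ``"exact"`` — force enumeration (valid with ties, via mid-ranks);
    * ``"asymptotic"`` — force the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (len(pooled) <= MW_EXACT_MAX_N and not has_ties) else "asymptotic"
    if method == "exact":
        if comb(len(pooled), len(x)) > 1_000_000:
            raise ValueError("sample too large for exact enumeration")
        return _mann_whitney_exact(x, y)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    # plain tie-corrected normal approximation; no continuity correction,
    # which overcorrects (conservative) at the sample sizes that reach here
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(
    raw_ps: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down corrected p-values and rejection flags.

    Sort ascending; corrected p at rank j is the running maximum of
    (m - j + 1) * p_(j), capped at 1; reject while corrected p < alpha.
    """
    ps = np.asarray(raw_ps, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, corrected, _, _ = multipletests(ps, alpha=alpha, method="holm")
    return corrected, corrected < alpha


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation r_S with a two-sided p.

    r_S is the Pearson correlation of mid-ranks.  For n <= 9 (or
    ``method="exact"``) the p-value is the full permutation p over all
    orderings of one variable; otherwise the usual t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector; correlation undefined")
    r = float(sps.spearmanr(x, y).statistic)
    if method == "auto":
        method = "exact" if n <= SPEARMAN_EXACT_MAX_N else "approx"
    if method == "approx":
        return r, float(sps.spearmanr(x, y).pvalue)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.array(list(itertools.permutations(range(n))))
    r_all = (rx[None, :] * ry[perms]).mean(axis=1)
    p = float(np.mean(np.abs(r_all) >= abs(r) - 1e-12))
    return r, p


@dataclasses.dataclass
class GroupComparisonResult:
    """Gatekept omnibus + pairwise comparison of one indicator across groups."""

    H: float
    p_overall: float
    alpha: float
    pairwise: dict[tuple[str, str], dict] | None  # None unless omnibus significant


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    mw_method: str = "auto",
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus with Holm-corrected pairwise follow-up.

    Pairwise Mann-Whitney tests are run only when the omnibus p is below
    alpha, exactly as the gatekeeping protocol prescribes; the Holm family is
    the set of group pairs of this one indicator.
    """
    names = list(samples)
    H, p = kruskal_wallis(*[samples[g] for g in names])
    pairwise = None
    if p < alpha:
        pairs = list(itertools.combinations(names, 2))
        raw = []
        stats_u = []
        for a, b in pairs:
            U, praw = mann_whitney(samples[a], samples[b], method=mw_method)
            stats_u.append(U)
            raw.append(praw)
        corrected, reject = holm_bonferroni(raw, alpha=alpha)
        pairwise = {
            pair: {
                "U": stats_u[i],
                "p_raw": raw[i],
                "p_corrected": float(corrected[i]),
                "significant": bool(reject[i]),
            }
            for i, pair in enumerate(pairs)
        }
    return GroupComparisonResult(H=H, p_overall=p, alpha=alpha, pairwise=pairwise)
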