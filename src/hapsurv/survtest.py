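"""Differential-survival rank test and the tip/interior contingency contrast.

The survival test asks whether nonsynonymous mutations that have already
spread through at least ``min_f`` haplotypes subtend, on average, more
descendant haplotypes than synonymous mutations of the same standing —
the populational analogue of contrasting old and young variation.  Under
neutrality both classes share one survival distribution; an excess of
high-``f`` nonsynonymous mutations indicates positive selection, a
deficit purifying selection.

The contrast is a Mann–Whitney rank test on the descendant-haplotype
counts ``f`` with midranks for ties.  The normal approximation uses the
tie-corrected variance

    Var(U) = n1*n2/(N*(N-1)) * ((N^3 - N)/12 - sum(t^3 - t)/12)

and a continuity correction of 0.5 (both can be read off as the
"improved" normal approximation; the correction is switchable).  The
exact two-tailed p doubles the smaller tail of the exact permutation
distribution of U, enumerated by dynamic programming over tie groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import HapsurvError

logger = logging.getLogger("hapsurv")


class StatTestError(HapsurvError):
    """A statistical test received an empty or degenerate input."""


@dataclass(frozen=True)
class RankTestResult:
    n_nonsyn: int
    n_syn: int
    R1: float                 # rank sum, nonsynonymous group
    R2: float
    U_nonsyn: float
    U_syn: float
    mean_rank_nonsyn: float
    mean_rank_syn: float
    mean_f_nonsyn: float
    mean_f_syn: float
    tie_correction: float     # sum(t^3 - t)/12 over tie groups
    z: float                  # positive = nonsynonymous ranks higher
    p_two_tailed: float
    method: str               # normal_approx | exact_permutation
    continuity: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_exact: float
    haldane: bool = False     # 0.5 added to each cell for the odds ratio


def filter_internal(table: pd.DataFrame, min_f: int = 3) -> pd.DataFrame:
    """Coding mutations that spread to at least ``min_f`` haplotypes.

    Singletons and doubletons at the tips of the network have not yet
    been through the survival filter of drift, so by default only
    mutations present in three or more haplotypes are retained; noncoding
    and indeterminate mutations are dropped.
    """
    if "f" not in table or table["f"].isna().any():
        raise StatTestError("mutation table lacks descendant counts (f)")
    kept = table[
        table["effect"].isin(["synonymous", "nonsynonymous"]) & (table["f"] >= min_f)
    ].reset_index(drop=True)
    if kept.empty:
        logger.warning("no coding mutations with f >= %d remain", min_f)
    return kept


def _exact_u_distribution(values: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact permutation distribution of R1 over tie groups.

    Returns (2*R1 lattice values, counts).  Works in doubled rank units
    so midranks stay integral.
    """
    N = len(values)
    order = np.sort(values)
    # tie groups and their doubled midranks
    groups: list[tuple[int, int]] = []
    start = 0
    while start < N:
        end = start
        while end < N and order[end] == order[start]:
            end += 1
        t = end - start
        groups.append((t, 2 * start + t + 1))  # 2*midrank of ranks start+1..end
        start = end
    max2 = N * (N + 1)
    dp = np.zeros((n1 + 1, max2 + 1))
    dp[0, 0] = 1.0
    for t, m2 in groups:
        nxt = np.zeros_like(dp)
        for k in range(min(t, n1) + 1):
            w = comb(t, k)
            shift = k * m2
            if shift:
                nxt[k:, shift:] += w * dp[: n1 + 1 - k, : max2 + 1 - shift]
            else:
                nxt += w * dp
        dp = nxt
    counts = dp[n1]
    support = counts > 0
    return np.nonzero(support)[0], counts[support]


def mann_whitney_survival(
    f_nonsyn,
    f_syn,
    method: str = "auto",
    continuity: bool = True,
) -> RankTestResult:
    """Tie-corrected Mann–Whitney contrast of descendant-haplotype counts.

    ``method='auto'`` switches to the exact permutation distribution when
    ``n1 * n2 <= 400``; ``'normal'`` and ``'exact'`` force one route.  The
    sign convention is positive z for nonsynonymous mutations ranking
    higher.
    """
    f1 = np.asarray(list(f_nonsyn), dtype=float)
    f2 = np.asarray(list(f_syn), dtype=float)
    n1, n2 = len(f1), len(f2)
    if n1 == 0 or n2 == 0:
        raise StatTestError("both mutation groups must be nonempty")
    N = n1 + n2
    pooled = np.concatenate([f1, f2])
    ranks = stats.rankdata(pooled)
    R1 = float(ranks[:n1].sum())
    R2 = float(ranks[n1:].sum())
    U1 = R1 - n1 * (n1 + 1) / 2.0
    U2 = n1 * n2 - U1
    mu = n1 * n2 / 2.0

    _, t_counts = np.unique(pooled, return_counts=True)
    tie_correction = float(((t_counts**3 - t_counts) / 12.0).sum())
    var = (n1 * n2 / (N * (N - 1.0))) * ((N**3 - N) / 12.0 - tie_correction)

    common = dict(
        n_nonsyn=n1, n_syn=n2, R1=R1, R2=R2, U_nonsyn=U1, U_syn=U2,
        mean_rank_nonsyn=R1 / n1, mean_rank_syn=R2 / n2,
        mean_f_nonsyn=float(f1.mean()), mean_f_syn=float(f2.mean()),
        tie_correction=tie_correction, continuity=continuity,
    )

    if var <= 0.0:
        # every observation tied across both groups
        return RankTestResult(z=0.0, p_two_tailed=1.0, method="degenerate", **common)

    dev = U1 - mu
    cc = 0.5 if continuity else 0.0
    z = 0.0 if abs(dev) <= cc else (dev - np.sign(dev) * cc) / sqrt(var)
    p_norm = min(1.0, 2.0 * stats.norm.sf(abs(z)))

    if method == "auto":
        method = "exact" if n1 * n2 <= 400 else "normal"
    if method == "normal":
        return RankTestResult(z=float(z), p_two_tailed=p_norm, method="normal_approx", **common)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    lattice2, counts = _exact_u_distribution(pooled, n1)
    total = counts.sum()
    r1_2 = round(2 * R1)
    lower = counts[lattice2 <= r1_2].sum() / total
    upper = counts[lattice2 >= r1_2].sum() / total
    p_exact = float(min(1.0, 2.0 * min(lower, upper)))
    return RankTestResult(z=float(z), p_two_tailed=p_exact, method="exact_permutation", **common)


def templeton_contingency(counts) -> ContingencyResult:
    """Fisher's exact contrast of tip/interior x nonsynonymous/synonymous.

    ``counts`` is a 2x2 array-like with rows (interior, tip) and columns
    (nonsynonymous, synonymous).  The sample odds ratio gets a 0.5
    Haldane correction only when a zero cell exists (flagged).
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise StatTestError("contingency table must be 2x2 nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatTestError("a margin of the contingency table is zero")
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table.astype(float)
    odds_ratio = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(
        table=tuple(map(tuple, table.tolist())),
        odds_ratio=odds_ratio,
        p_exact=float(p),
        haldane=haldane,
    )
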