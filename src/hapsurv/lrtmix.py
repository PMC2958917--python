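"""Likelihood-ratio statistics against a boundary (point-mass + chi2_1) null.

Branch-site contrasts test a parameter that sits on the edge of its space
under the null, so the LRT statistic is not chi-squared distributed:
its null is the 50:50 mixture of a point mass at zero and a chi-squared
with one degree of freedom.  The mixture halves the chi2_1 tail, giving
critical values of 2.71 (5%) and 5.41 (1%).

This module consumes log-likelihoods fitted elsewhere (codon-model
software); it does not fit codon models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import chi2

from .seqio import HapsurvError

logger = logging.getLogger("hapsurv")

#: raw statistics more negative than this are an error, not optimizer noise
_NEGATIVE_TOL = 1e-6


class LRTError(HapsurvError):
    """Invalid log-likelihood or statistic input."""


@dataclass(frozen=True)
class LRTResult:
    lnl_null: float
    lnl_alt: float
    stat: float
    df: str
    p_mixture: float
    p_chi2: float
    significant_05: bool
    significant_01: bool


def lrt(lnl_null: float, lnl_alt: float) -> float:
    """2*(lnl_alt - lnl_null), clamping small negative values to zero."""
    if not (math.isfinite(lnl_null) and math.isfinite(lnl_alt)):
        raise LRTError("log-likelihoods must be finite")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < 0.0:
        if stat < -_NEGATIVE_TOL:
            logger.warning(
                "negative LRT statistic %.6g clamped to 0 "
                "(alternative fit worse than null: optimizer noise?)", stat
            )
        stat = 0.0
    return stat


def mixture_pvalue(stat: float) -> float:
    """Tail probability under the 50:50 point-mass-at-0 / chi2_1 mixture."""
    if stat < 0.0:
        raise LRTError("LRT statistic must be nonnegative")
    if stat == 0.0:
        return 1.0
    return float(0.5 * chi2.sf(stat, df=1))


def mixture_critical(alpha: float) -> float:
    """Critical value of the mixture null at level alpha (0 < alpha < 0.5)."""
    if not 0.0 < alpha < 0.5:
        raise LRTError("alpha must lie in (0, 0.5)")
    return float(chi2.ppf(1.0 - 2.0 * alpha, df=1))


def evaluate(lnl_null: float, lnl_alt: float, df: str | int = 1) -> LRTResult:
    """Full LRT report: statistic, mixture and plain chi-squared tails."""
    stat = lrt(lnl_null, lnl_alt)
    df_num = int(df) if str(df).isdigit() else 1
    p_mix = mixture_pvalue(stat)
    p_plain = float(chi2.sf(stat, df=df_num)) if stat > 0 else 1.0
    return LRTResult(
        lnl_null=lnl_null,
        lnl_alt=lnl_alt,
        stat=stat,
        df=str(df),
        p_mixture=p_mix,
        p_chi2=p_plain,
        significant_05=stat >= mixture_critical(0.05),
        significant_01=stat >= mixture_critical(0.01),
    )
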