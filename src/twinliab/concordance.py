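"""Concordance estimators for ascertainment-classified twin counts.

Three classical estimators are computed from the counts ``C1`` (singly
ascertained concordant pairs), ``C2`` (doubly ascertained concordant pairs)
and ``D1`` (discordant pairs with a proband):

* casewise    ``(2C1 + 2C2) / (2C1 + 2C2 + D1)``
* probandwise ``(C1 + 2C2) / (C1 + 2C2 + D1)``
* pairwise    ``(C1 + C2) / (C1 + C2 + D1)``

The probandwise rate is the casewise rate corrected for incomplete
ascertainment and is the one comparable across studies and to recurrence
risks in other relatives; casewise and pairwise bracket it as ascertainment
tends to complete or to single capture.  Confidence intervals are exact
binomial (Clopper–Pearson) on the integer numerator/denominator implied by
each estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import numpy as np
from scipy.stats import beta

from .twin_data import ConcordanceCounts


class ConcordanceKind(str, Enum):
    casewise = "casewise"
    probandwise = "probandwise"
    pairwise = "pairwise"


class UndefinedEstimateError(ZeroDivisionError):
    """Raised when an estimator's denominator is zero."""


@dataclass(frozen=True)
class ConcordanceEstimate:
    kind: ConcordanceKind
    rate: float
    ci_low: float
    ci_high: float
    n_success: int
    n_trials: int
    level: float = 0.95
    adjusted: bool = False

    def as_percent(self, digits: int = 1) -> tuple[float, float, float]:
        """(rate, lo, hi) in percent, rounded half-up as in published tables."""
        return tuple(_round_half_up(100 * x, digits) for x in (self.rate, self.ci_low, self.ci_high))


def _round_half_up(x: float, digits: int = 1) -> float:
    scale = 10.0**digits
    return np.floor(x * scale + 0.5) / scale


def clopper_pearson_interval(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from the beta quantiles.

    The lower bound is 0 exactly when ``successes == 0`` and the upper bound
    1 exactly when ``successes == trials``.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes} successes in {trials} trials")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, trials - successes + 1))
    high = 1.0 if successes == trials else float(beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return low, high


def _estimate(kind: ConcordanceKind, successes: int, trials: int, level: float) -> ConcordanceEstimate:
    if trials == 0:
        raise UndefinedEstimateError(f"{kind.value} concordance undefined: zero denominator")
    low, high = clopper_pearson_interval(successes, trials, level)
    return ConcordanceEstimate(
        kind=kind,
        rate=successes / trials,
        ci_low=low,
        ci_high=high,
        n_success=successes,
        n_trials=trials,
        level=level,
    )


def casewise_concordance(counts: ConcordanceCounts, level: float = 0.95) -> ConcordanceEstimate:
    """Proportion of ascertained cases whose cotwin is affected.

    The CI treats the ``2(C1+C2)`` affected individuals in concordant pairs
    as independent trials, as the estimator's integer denominator implies;
    this ignores within-pair dependence and is a known approximation.
    """
    return _estimate(
        ConcordanceKind.casewise,
        2 * counts.C1 + 2 * counts.C2,
        2 * counts.C1 + 2 * counts.C2 + counts.D1,
        level,
    )


def probandwise_concordance(counts: ConcordanceCounts, level: float = 0.95) -> ConcordanceEstimate:
    """Proportion of probands whose cotwin is affected (ascertainment-robust)."""
    return _estimate(
        ConcordanceKind.probandwise,
        counts.C1 + 2 * counts.C2,
        counts.C1 + 2 * counts.C2 + counts.D1,
        level,
    )


def pairwise_concordance(counts: ConcordanceCounts, level: float = 0.95) -> ConcordanceEstimate:
    """Proportion of ascertained pairs that are concordant."""
    return _estimate(
        ConcordanceKind.pairwise,
        counts.C1 + counts.C2,
        counts.C1 + counts.C2 + counts.D1,
        level,
    )


_ESTIMATORS = {
    ConcordanceKind.casewise: casewise_concordance,
    ConcordanceKind.probandwise: probandwise_concordance,
    ConcordanceKind.pairwise: pairwise_concordance,
}


def concordance(counts: ConcordanceCounts, kind: ConcordanceKind | str, level: float = 0.95) -> ConcordanceEstimate:
    """Dispatch to the estimator named by ``kind``."""
    return _ESTIMATORS[ConcordanceKind(kind)](counts, level)


def sex_adjusted_rate(
    stratum_counts: Mapping[str, ConcordanceCounts],
    kind: ConcordanceKind | str = ConcordanceKind.casewise,
    weights: Optional[Mapping[str, float]] = None,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> ConcordanceEstimate:
    """Directly standardized concordance rate across sex strata.

    The adjusted rate is the weighted average of stratum-specific rates.
    ``weights`` default to each stratum's share of probands
    (``C1 + 2*C2 + D1``); they must sum to 1 and a stratum with an empty
    denominator must carry zero weight.  The CI is a stratified percentile
    bootstrap over pair classes, resampling each stratum's ``(C1, C2, D1)``
    multinomially with a seeded generator.
    """
    kind = ConcordanceKind(kind)
    strata = list(stratum_counts)
    if weights is None:
        totals = {s: stratum_counts[s].C1 + 2 * stratum_counts[s].C2 + stratum_counts[s].D1 for s in strata}
        grand = sum(totals.values())
        if grand == 0:
            raise UndefinedEstimateError("no probands in any stratum")
        weights = {s: totals[s] / grand for s in strata}
    w = np.array([weights[s] for s in strata], dtype=float)
    if w.sum() <= 0:
        raise ValueError("stratum weights must not all be zero")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"stratum weights must sum to 1, got {w.sum()}")

    def weighted_rate(counts_list: list[ConcordanceCounts]) -> float:
        total = 0.0
        for wi, ci in zip(w, counts_list):
            if wi == 0.0:
                continue
            total += wi * _ESTIMATORS[kind](ci, level).rate
        return total

    base = [stratum_counts[s] for s in strata]
    for wi, ci in zip(w, base):
        if wi > 0 and ci.n_ascertained == 0:
            raise UndefinedEstimateError("stratum with positive weight has no ascertained pairs")
    rate = weighted_rate(base)

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    probs = [
        np.array([c.C1, c.C2, c.D1], dtype=float) / max(c.n_ascertained, 1)
        for c in base
    ]
    sizes = [c.n_ascertained for c in base]
    for b in range(n_boot):
        resampled = []
        for c, p, n in zip(base, probs, sizes):
            if n == 0:
                resampled.append(c)
                continue
            c1, c2, d1 = rng.multinomial(n, p)
            resampled.append(ConcordanceCounts(C1=int(c1), C2=int(c2), D1=int(d1)))
        try:
            reps[b] = weighted_rate(resampled)
        except UndefinedEstimateError:
            reps[b] = np.nan
    alpha = 1.0 - level
    lo, hi = np.nanquantile(reps, [alpha / 2, 1 - alpha / 2])

    return ConcordanceEstimate(
        kind=kind,
        rate=float(rate),
        ci_low=float(lo),
        ci_high=float(hi),
        n_success=sum(c.C1 + c.C2 for c in base),
        n_trials=sum(c.n_ascertained for c in base),
        level=level,
        adjusted=True,
    )
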