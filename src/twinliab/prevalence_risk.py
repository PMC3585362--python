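"""Prevalence estimation and cotwin recurrence-risk ratios.

Crude prevalence is cases over responders with an exact binomial CI;
direct standardization re-weights stratum prevalences to a reference
population.  The recurrence-risk ratio divides a cotwin concordance rate by
the population prevalence: the relative risk of disease given an affected
cotwin, the quantity comparable to sibling or offspring recurrence risks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .concordance import ConcordanceEstimate, ConcordanceKind, clopper_pearson_interval


@dataclass(frozen=True)
class PrevalenceEstimate:
    cases: int
    denominator: int
    crude: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    standardized: Optional[float] = None


@dataclass(frozen=True)
class RecurrenceRisk:
    numerator_kind: ConcordanceKind
    ratio: float
    ci_low: float
    ci_high: float


def crude_prevalence(cases: int, denominator: int, level: float = 0.95) -> PrevalenceEstimate:
    """Cases over denominator, with a Clopper-Pearson interval."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= cases <= denominator:
        raise ValueError("cases must lie in [0, denominator]")
    low, high = clopper_pearson_interval(cases, denominator, level)
    return PrevalenceEstimate(
        cases=cases,
        denominator=denominator,
        crude=cases / denominator,
        ci_low=low,
        ci_high=high,
        level=level,
    )


def direct_standardize(
    stratum_prevalences: Mapping[str, float], reference_weights: Mapping[str, float]
) -> float:
    """Directly standardized prevalence: sum of weight_i * prevalence_i.

    Strata must match exactly between the two mappings and the reference
    weights must sum to 1.  The result always lies between the smallest and
    largest stratum prevalence.
    """
    if set(stratum_prevalences) != set(reference_weights):
        raise ValueError(
            "strata mismatch: "
            f"{sorted(set(stratum_prevalences) ^ set(reference_weights))}"
        )
    total_w = sum(reference_weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"reference weights must sum to 1, got {total_w}")
    return sum(reference_weights[s] * stratum_prevalences[s] for s in stratum_prevalences)


def recurrence_risk_ratio(
    concordance: ConcordanceEstimate, prevalence: float
) -> RecurrenceRisk:
    """Concordance rate over population prevalence (lambda for cotwins).

    CI endpoints are the concordance CI endpoints divided by the prevalence,
    treating the prevalence (estimated on tens of thousands of responders)
    as fixed relative to the concordance rate.
    """
    if prevalence <= 0:
        raise ValueError("prevalence must be positive")
    return RecurrenceRisk(
        numerator_kind=concordance.kind,
        ratio=concordance.rate / prevalence,
        ci_low=concordance.ci_low / prevalence,
        ci_high=concordance.ci_high / prevalence,
    )
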