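"""Two-source capture-recapture ascertainment and proband classification.

A survey and an administrative registry each find an (incomplete) set of
cases.  Treating the two sources as independent captures, the overlap
estimates each source's ascertainment probability and, via the Chapman
bias-corrected estimator, the total number of cases:

    N_hat = (n_a + 1)(n_b + 1) / (m + 1) - 1

where m is the overlap.  Registries whose diagnoses are only partially
valid are handled by multiplying each registration stratum by its known
confirmation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .twin_data import ConcordanceCounts, TwinPairRecord, aggregate_counts, classify_pair


@dataclass(frozen=True)
class CaptureRecaptureResult:
    n_source_a: int
    n_source_b: int
    n_overlap: int
    #: probability that source A captures a case known to source B (m / n_b)
    p_ascertain_a: float
    #: probability that source B captures a case known to source A (m / n_a)
    p_ascertain_b: float
    #: Chapman bias-corrected estimate of the total number of cases
    n_total_hat: float
    #: uncorrected Lincoln-Petersen estimate, for reference
    n_total_lincoln_petersen: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    unstable: bool = False


@dataclass(frozen=True)
class RegistryCategory:
    """One registry stratum with its diagnosis confirmation rate."""

    label: str
    n_registered: int
    confirmation_rate: float

    def __post_init__(self) -> None:
        if self.n_registered < 0:
            raise ValueError("n_registered must be non-negative")
        if not 0.0 <= self.confirmation_rate <= 1.0:
            raise ValueError("confirmation_rate must lie in [0, 1]")


def capture_recapture(
    n_source_a: int, n_source_b: int, n_overlap: int, level: float = 0.95
) -> CaptureRecaptureResult:
    """Two-source capture-recapture with the Chapman total estimate.

    ``p_ascertain_a = n_overlap / n_source_b`` (how often source A finds a
    case validated by B) and symmetrically for B.  The CI for the total is
    the standard log-normal interval on the number of unseen cases
    ``N_hat - n_union``; with zero overlap the total is flagged unstable.
    """
    if n_source_a <= 0 or n_source_b <= 0:
        raise ValueError("both sources must contain at least one case")
    if n_overlap > min(n_source_a, n_source_b):
        raise ValueError("overlap cannot exceed either source count")
    if n_overlap < 0:
        raise ValueError("overlap must be non-negative")

    m = n_overlap
    p_a = m / n_source_b
    p_b = m / n_source_a
    chapman = (n_source_a + 1) * (n_source_b + 1) / (m + 1) - 1
    lp = math.inf if m == 0 else n_source_a * n_source_b / m
    n_union = n_source_a + n_source_b - m

    var = (
        (n_source_a + 1)
        * (n_source_b + 1)
        * (n_source_a - m)
        * (n_source_b - m)
        / ((m + 1) ** 2 * (m + 2))
    )
    f0 = chapman - n_union  # estimated unseen cases
    if f0 <= 1e-9 or var <= 0:
        ci_low = ci_high = chapman  # complete overlap: nothing unseen
    else:
        z = _z_from_level(level)
        c_factor = math.exp(z * math.sqrt(math.log(1.0 + var / f0**2)))
        ci_low = n_union + f0 / c_factor
        ci_high = n_union + f0 * c_factor

    return CaptureRecaptureResult(
        n_source_a=n_source_a,
        n_source_b=n_source_b,
        n_overlap=m,
        p_ascertain_a=p_a,
        p_ascertain_b=p_b,
        n_total_hat=chapman,
        n_total_lincoln_petersen=lp,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        unstable=(m == 0),
    )


def _z_from_level(level: float) -> float:
    from scipy.stats import norm

    return float(norm.isf((1.0 - level) / 2.0))


def expected_true_cases(categories: Sequence[RegistryCategory]) -> tuple[float, float]:
    """Expected true cases among registry registrations.

    Each stratum contributes ``n_registered * confirmation_rate``.  Returns
    ``(expected_total, overall_confirmation_rate)``; the overall rate is the
    registration-weighted mean of the stratum rates (0 for an empty registry).
    """
    expected = sum(c.n_registered * c.confirmation_rate for c in categories)
    registered = sum(c.n_registered for c in categories)
    overall = expected / registered if registered > 0 else 0.0
    return expected, overall


def classify_probands(
    records: Sequence[TwinPairRecord],
) -> tuple[list[str], ConcordanceCounts]:
    """Per-pair ascertainment class plus the aggregate count summary.

    The classes are ``C1`` / ``C2`` / ``D1`` / ``U`` (neither affected) /
    ``remainder`` (affected pair without usable proband information); the
    summary equals :func:`twinliab.twin_data.aggregate_counts` on the same
    records by construction.
    """
    labels = [classify_pair(r) for r in records]
    return labels, aggregate_counts(records)
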