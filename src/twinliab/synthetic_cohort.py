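"""Seeded twin-cohort simulator under the liability-threshold ACE(/ADE) model.

Each twin's liability is a weighted sum of independent standard-normal
components: additive-genetic (cross-twin correlation 1 in MZ pairs, 1/2 in
DZ pairs), dominance (1 in MZ, 1/4 in DZ), shared environment (correlation
1 in all pairs) and unique environment (independent).  With weights
sqrt(a2), sqrt(d2), sqrt(c2), sqrt(e2) the liabilities are standard normal
with the cross-twin correlations the ACE algebra prescribes.  A twin is
affected when its liability exceeds the threshold fixed by the population
prevalence, and each affected twin is independently flagged as a proband
(survey self-report) with the ascertainment probability.

Default parameters mirror a nationwide registry survey of rheumatoid
arthritis in twins: prevalence 0.37%, ascertainment probability 0.80,
variance split a2 = 0.12, c2 = 0.50, e2 = 0.38, and roughly 17,000 intact
pairs split across MZ, DZ same-sexed and DZ opposite-sexed groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .liability import threshold_from_prevalence
from .twin_data import ConcordanceCounts, Sex, TwinPairRecord, Zygosity, classify_pair


#: cross-twin correlations of the additive and dominance components
_ADDITIVE_CORR = {Zygosity.MZ: 1.0, Zygosity.DZss: 0.5, Zygosity.DZos: 0.5}
_DOMINANCE_CORR = {Zygosity.MZ: 1.0, Zygosity.DZss: 0.25, Zygosity.DZos: 0.25}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated twin cohort.

    Parameters
    ----------
    a2, c2, d2, e2
        Variance proportions (must sum to 1): additive genetic, shared
        environment, dominance, unique environment.
    prevalence
        Population prevalence K fixing the liability threshold.
    n_pairs
        Pairs per zygosity group.
    sex_ratio_f
        Probability that a same-sexed pair is female.
    ascertainment_prob
        Per-affected-twin probability of being a proband.
    acpa_prob
        Probability that an affected twin is ACPA-positive.
    seed
        Seed for the random generator; same seed, same cohort.
    """

    a2: float = 0.12
    c2: float = 0.50
    e2: float = 0.38
    d2: float = 0.0
    prevalence: float = 0.0037
    n_pairs: dict = field(
        default_factory=lambda: {Zygosity.MZ: 4200, Zygosity.DZss: 6300, Zygosity.DZos: 6300}
    )
    sex_ratio_f: float = 0.5
    ascertainment_prob: float = 0.80
    acpa_prob: float = 0.78
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.a2 + self.c2 + self.d2 + self.e2
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"variance components must sum to 1, got {total}")
        for name in ("a2", "c2", "d2", "e2", "sex_ratio_f", "ascertainment_prob", "acpa_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    def rho(self, zygosity: Zygosity) -> float:
        """True liability correlation implied by the components."""
        ra = _ADDITIVE_CORR[zygosity]
        rd = _DOMINANCE_CORR[zygosity]
        return ra * self.a2 + self.c2 + rd * self.d2


@dataclass(frozen=True)
class SimulationManifest:
    """Ground truth and realized classification of one simulated cohort."""

    config: SimulationConfig
    threshold: float
    true_rho: dict
    class_counts: dict

    def counts(self, zygosity: Zygosity) -> ConcordanceCounts:
        return ConcordanceCounts(**self.class_counts[zygosity])


def _correlated_pair(rng: np.random.Generator, n: int, corr: float) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal vectors with the given cross correlation."""
    shared = rng.standard_normal(n)
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    w_s = np.sqrt(corr)
    w_u = np.sqrt(1.0 - corr)
    return w_s * shared + w_u * u1, w_s * shared + w_u * u2


def simulate_cohort(config: SimulationConfig) -> tuple[list[TwinPairRecord], SimulationManifest]:
    """Draw a full twin cohort; reproducible given ``config.seed``.

    Returns the per-pair records (all pairs, including unaffected ones) and
    a manifest with the true thresholds, the true liability correlations per
    zygosity and the realized ascertainment-class counts.
    """
    rng = np.random.default_rng(config.seed)
    t = threshold_from_prevalence(config.prevalence)

    records: list[TwinPairRecord] = []
    class_counts: dict[Zygosity, dict[str, int]] = {}
    a, c, d, e = (np.sqrt(config.a2), np.sqrt(config.c2), np.sqrt(config.d2), np.sqrt(config.e2))

    for zygosity in (Zygosity.MZ, Zygosity.DZss, Zygosity.DZos):
        n = int(config.n_pairs.get(zygosity, 0))
        tally = {"C1": 0, "C2": 0, "D1": 0, "U": 0, "remainder": 0}
        class_counts[zygosity] = tally
        if n == 0:
            continue

        A1, A2 = _correlated_pair(rng, n, _ADDITIVE_CORR[zygosity])
        D1_, D2_ = _correlated_pair(rng, n, _DOMINANCE_CORR[zygosity])
        C_ = rng.standard_normal(n)
        E1 = rng.standard_normal(n)
        E2 = rng.standard_normal(n)
        liab1 = a * A1 + d * D1_ + c * C_ + e * E1
        liab2 = a * A2 + d * D2_ + c * C_ + e * E2
        affected1 = liab1 > t
        affected2 = liab2 > t
        proband1 = affected1 & (rng.random(n) < config.ascertainment_prob)
        proband2 = affected2 & (rng.random(n) < config.ascertainment_prob)
        acpa1 = rng.random(n) < config.acpa_prob
        acpa2 = rng.random(n) < config.acpa_prob
        if zygosity is Zygosity.DZos:
            first_f = rng.random(n) < 0.5
        else:
            pair_f = rng.random(n) < config.sex_ratio_f

        for i in range(n):
            if zygosity is Zygosity.DZos:
                sex = (Sex.F, Sex.M) if first_f[i] else (Sex.M, Sex.F)
            else:
                sex = (Sex.F, Sex.F) if pair_f[i] else (Sex.M, Sex.M)
            record = TwinPairRecord(
                pair_id=f"{zygosity.value}-{i:06d}",
                zygosity=zygosity,
                affected=(bool(affected1[i]), bool(affected2[i])),
                proband=(bool(proband1[i]), bool(proband2[i])),
                sex=sex,
                acpa_positive=(
                    bool(acpa1[i]) if affected1[i] else None,
                    bool(acpa2[i]) if affected2[i] else None,
                ),
            )
            records.append(record)
            tally[classify_pair(record)] += 1

    manifest = SimulationManifest(
        config=config,
        threshold=t,
        true_rho={z: config.rho(z) for z in Zygosity},
        class_counts=class_counts,
    )
    return records, manifest


def published_ra_counts() -> dict[str, dict[Zygosity, ConcordanceCounts]]:
    """Ascertainment-classified counts of a published nationwide RA twin table.

    Fixture for tests and worked examples: per zygosity, the concordant
    pairs split into singly (C1) and doubly (C2) ascertained according to
    the published secondary-case footnote, the discordant-with-proband
    count D1, for the full cohort and for the ACPA-positive stratum.
    """
    return {
        "all": {
            Zygosity.MZ: ConcordanceCounts(C1=1, C2=1, D1=30),
            Zygosity.DZss: ConcordanceCounts(C1=3, C2=1, D1=73),
            Zygosity.DZos: ConcordanceCounts(C1=1, C2=0, D1=45),
        },
        "acpa": {
            Zygosity.MZ: ConcordanceCounts(C1=1, C2=1, D1=19),
            Zygosity.DZss: ConcordanceCounts(C1=3, C2=1, D1=55),
            Zygosity.DZos: ConcordanceCounts(C1=1, C2=0, D1=36),
        },
    }
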