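import pytest

from twinliab import SimulationConfig, Sex, TwinPairRecord, Zygosity, simulate_cohort
from twinliab.synthetic_cohort import published_ra_counts


def mz_pair(pair_id, affected, proband, acpa=(None, None)):
    return TwinPairRecord(
        pair_id=pair_id,
        zygosity=Zygosity.MZ,
        affected=affected,
        proband=proband,
        sex=(Sex.F, Sex.F),
        acpa_positive=acpa,
    )


def records_from_counts(zygosity, C1, C2, D1, U=0, acpa=True):
    """Build a minimal record list realizing given ascertainment-class counts."""
    sex = (Sex.F, Sex.M) if zygosity is Zygosity.DZos else (Sex.F, Sex.F)
    status = True if acpa else None
    records = []
    i = 0
    for _ in range(C2):
        records.append(TwinPairRecord(f"{zygosity.value}-{i}", zygosity, (True, True),
                                      (True, True), sex, (status, status)))
        i += 1
    for _ in range(C1):
        records.append(TwinPairRecord(f"{zygosity.value}-{i}", zygosity, (True, True),
                                      (True, False), sex, (status, status)))
        i += 1
    for _ in range(D1):
        records.append(TwinPairRecord(f"{zygosity.value}-{i}", zygosity, (True, False),
                                      (True, False), sex, (status, None)))
        i += 1
    for _ in range(U):
        records.append(TwinPairRecord(f"{zygosity.value}-{i}", zygosity, (False, False),
                                      (False, False), sex))
        i += 1
    return records


@pytest.fixture(scope="session")
def published_counts():
    """Ascertainment-classified counts of the published nationwide RA table."""
    return published_ra_counts()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared across tests (fixed seed)."""
    config = SimulationConfig(
        prevalence=0.05,
        n_pairs={Zygosity.MZ: 20_000, Zygosity.DZss: 20_000, Zygosity.DZos: 10_000},
        seed=2024,
    )
    records, manifest = simulate_cohort(config)
    return config, records, manifest
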