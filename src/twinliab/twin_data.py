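"""Twin-pair records and ascertainment-classified concordance counts.

The classical twin design for a binary disease collects pairs of twins and
records, for each member, whether the disease is present and whether the
member was ascertained independently of the cotwin ("proband") or only
through the cotwin ("secondary case").  Concordance estimators that correct
for incomplete ascertainment are computed not from raw affected counts but
from the ascertainment-classified counts

* ``C1`` — concordant pairs with exactly one proband (singly ascertained),
* ``C2`` — concordant pairs in which both twins are probands,
* ``D1`` — discordant pairs whose affected member is a proband.

Concordant pairs in which *no* member is a proband, and discordant pairs
whose affected member is not a proband, carry no ascertainment information
and are excluded from the estimators; they are tallied separately so that
nothing is silently dropped.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, TextIO, Union


class Zygosity(str, Enum):
    """Twin zygosity: monozygotic, dizygotic same-sexed, dizygotic opposite-sexed."""

    MZ = "MZ"
    DZss = "DZss"
    DZos = "DZos"


class Sex(str, Enum):
    F = "F"
    M = "M"


class PairTableError(ValueError):
    """Raised when a pair table or a single record violates its contract."""


#: CSV header for the standard pair table, in column order.
PAIR_TABLE_COLUMNS = (
    "pair_id",
    "zygosity",
    "affected_1",
    "affected_2",
    "proband_1",
    "proband_2",
    "sex_1",
    "sex_2",
    "acpa_1",
    "acpa_2",
    "discordance_time",
)


@dataclass(frozen=True)
class TwinPairRecord:
    """One twin pair.

    Within-pair order carries no meaning: every consumer in this package
    symmetrizes over the two members.

    Parameters
    ----------
    pair_id : str
        Opaque identifier.
    zygosity : Zygosity
    affected : tuple(bool, bool)
        Disease status of member 1 and 2.
    proband : tuple(bool, bool)
        Whether each member was independently ascertained.  A proband must
        be affected.
    sex : tuple(Sex, Sex)
        Must agree with zygosity (same-sexed groups have equal sexes,
        opposite-sexed pairs differ).
    acpa_positive : tuple(bool | None, bool | None)
        Autoantibody (ACPA) status; defined only for affected members.
    discordance_time : float | None
        Years between the onsets in a concordant pair, or follow-up since
        onset in a discordant pair; non-negative when present.
    """

    pair_id: str
    zygosity: Zygosity
    affected: tuple[bool, bool]
    proband: tuple[bool, bool]
    sex: tuple[Sex, Sex]
    acpa_positive: tuple[Optional[bool], Optional[bool]] = (None, None)
    discordance_time: Optional[float] = None

    def __post_init__(self) -> None:
        for i in (0, 1):
            if self.proband[i] and not self.affected[i]:
                raise PairTableError(
                    f"pair {self.pair_id!r}: member {i + 1} is a proband but not affected"
                )
            if self.acpa_positive[i] is not None and not self.affected[i]:
                raise PairTableError(
                    f"pair {self.pair_id!r}: member {i + 1} has ACPA status but is unaffected"
                )
        same_sexed = self.sex[0] == self.sex[1]
        if self.zygosity in (Zygosity.MZ, Zygosity.DZss) and not same_sexed:
            raise PairTableError(
                f"pair {self.pair_id!r}: {self.zygosity.value} pair with unequal sexes"
            )
        if self.zygosity is Zygosity.DZos and same_sexed:
            raise PairTableError(f"pair {self.pair_id!r}: DZos pair with equal sexes")
        if self.discordance_time is not None and self.discordance_time < 0:
            raise PairTableError(f"pair {self.pair_id!r}: negative discordance time")

    @property
    def n_affected(self) -> int:
        return int(self.affected[0]) + int(self.affected[1])

    @property
    def n_probands(self) -> int:
        return int(self.proband[0]) + int(self.proband[1])


@dataclass(frozen=True)
class ConcordanceCounts:
    """Ascertainment-classified pair counts for one zygosity group / subset.

    ``U`` counts pairs with neither member affected (needed only by the
    liability model); ``remainder`` counts affected pairs carrying no
    proband information, which the concordance estimators must exclude.
    """

    C1: int = 0
    C2: int = 0
    D1: int = 0
    U: int = 0
    remainder: int = 0

    def __post_init__(self) -> None:
        for name in ("C1", "C2", "D1", "U", "remainder"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise PairTableError(f"count {name} must be a non-negative integer, got {v!r}")

    @property
    def n_pairs(self) -> int:
        return self.C1 + self.C2 + self.D1 + self.U + self.remainder

    @property
    def n_ascertained(self) -> int:
        return self.C1 + self.C2 + self.D1


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip()
    if v == "1":
        return True
    if v == "0":
        return False
    raise PairTableError(f"row {row}: column {column!r} must be 0 or 1, got {value!r}")


def _parse_opt_bool(value: str, row: int, column: str) -> Optional[bool]:
    if value is None or value.strip() == "":
        return None
    return _parse_bool(value, row, column)


def read_pair_table(
    source: Union[str, Path, TextIO], *, delimiter: str = ","
) -> list[TwinPairRecord]:
    """Read the standard pair CSV into validated records, preserving row order.

    The expected header is ``pair_id,zygosity,affected_1,affected_2,
    proband_1,proband_2,sex_1,sex_2,acpa_1,acpa_2,discordance_time`` with
    booleans coded 0/1 and missing values as empty fields.

    Raises
    ------
    PairTableError
        Naming the offending row and field for any malformed or
        invariant-violating row.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as handle:
            return read_pair_table(handle, delimiter=delimiter)

    reader = csv.reader(source, delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise PairTableError("empty input: missing header row") from None
    header = [h.strip() for h in header]
    if tuple(header) != PAIR_TABLE_COLUMNS:
        raise PairTableError(
            f"unexpected header {header!r}; expected {list(PAIR_TABLE_COLUMNS)!r}"
        )

    records: list[TwinPairRecord] = []
    for row_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(PAIR_TABLE_COLUMNS):
            raise PairTableError(
                f"row {row_no}: expected {len(PAIR_TABLE_COLUMNS)} fields, got {len(row)}"
            )
        cells = dict(zip(PAIR_TABLE_COLUMNS, row))
        zyg_code = cells["zygosity"].strip()
        try:
            zygosity = Zygosity(zyg_code)
        except ValueError:
            raise PairTableError(
                f"row {row_no}: unknown zygosity code {zyg_code!r}"
            ) from None
        try:
            sex = tuple(Sex(cells[f"sex_{i}"].strip()) for i in (1, 2))
        except ValueError:
            raise PairTableError(f"row {row_no}: sex codes must be F or M") from None
        dt_raw = cells["discordance_time"].strip()
        if dt_raw:
            try:
                discordance_time = float(dt_raw)
            except ValueError:
                raise PairTableError(
                    f"row {row_no}: column 'discordance_time' is not numeric: {dt_raw!r}"
                ) from None
        else:
            discordance_time = None
        try:
            record = TwinPairRecord(
                pair_id=cells["pair_id"].strip(),
                zygosity=zygosity,
                affected=(
                    _parse_bool(cells["affected_1"], row_no, "affected_1"),
                    _parse_bool(cells["affected_2"], row_no, "affected_2"),
                ),
                proband=(
                    _parse_bool(cells["proband_1"], row_no, "proband_1"),
                    _parse_bool(cells["proband_2"], row_no, "proband_2"),
                ),
                sex=sex,  # type: ignore[arg-type]
                acpa_positive=(
                    _parse_opt_bool(cells["acpa_1"], row_no, "acpa_1"),
                    _parse_opt_bool(cells["acpa_2"], row_no, "acpa_2"),
                ),
                discordance_time=discordance_time,
            )
        except PairTableError as exc:
            raise PairTableError(f"row {row_no}: {exc}") from None
        records.append(record)
    return records


def write_pair_table(records: Iterable[TwinPairRecord], destination: Union[str, Path, TextIO]) -> None:
    """Write records back to the standard pair CSV format."""
    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8", newline="") as handle:
            write_pair_table(records, handle)
            return

    writer = csv.writer(destination)
    writer.writerow(PAIR_TABLE_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.pair_id,
                r.zygosity.value,
                int(r.affected[0]),
                int(r.affected[1]),
                int(r.proband[0]),
                int(r.proband[1]),
                r.sex[0].value,
                r.sex[1].value,
                "" if r.acpa_positive[0] is None else int(r.acpa_positive[0]),
                "" if r.acpa_positive[1] is None else int(r.acpa_positive[1]),
                "" if r.discordance_time is None else r.discordance_time,
            ]
        )


def acpa_positive_pair(record: TwinPairRecord) -> bool:
    """Subset rule for the ACPA-positive stratum.

    A pair enters the stratum when every *affected* member is ACPA-positive;
    an affected member with unknown ACPA status excludes the pair.
    Unaffected pairs pass (their liability information is antibody-free).
    """
    for i in (0, 1):
        if record.affected[i] and record.acpa_positive[i] is not True:
            return False
    return True


def classify_pair(record: TwinPairRecord) -> str:
    """Map one pair to its ascertainment class.

    Returns one of ``"C2"`` (both affected, both probands), ``"C1"`` (both
    affected, one proband), ``"D1"`` (one affected, a proband), ``"U"``
    (neither affected) or ``"remainder"`` (affected pair without the proband
    configuration the estimators require).
    """
    n_aff = record.n_affected
    n_pro = record.n_probands
    if n_aff == 0:
        return "U"
    if n_aff == 2:
        if n_pro == 2:
            return "C2"
        if n_pro == 1:
            return "C1"
        return "remainder"
    # exactly one affected
    return "D1" if n_pro == 1 else "remainder"


def aggregate_counts(
    records: Sequence[TwinPairRecord],
    zygosity: Optional[Union[Zygosity, Iterable[Zygosity]]] = None,
    subset: Optional[Callable[[TwinPairRecord], bool]] = None,
) -> ConcordanceCounts:
    """Aggregate records into ascertainment-classified concordance counts.

    Parameters
    ----------
    records
        Validated twin-pair records.
    zygosity
        A single zygosity, an iterable of zygosities, or None for all.
    subset
        Optional pair-level predicate (e.g. :func:`acpa_positive_pair`)
        applied after the zygosity filter.

    The result is invariant to record order and to within-pair member order,
    and the five classes partition the filtered pairs exactly.
    """
    if zygosity is None:
        wanted = set(Zygosity)
    elif isinstance(zygosity, Zygosity):
        wanted = {zygosity}
    else:
        wanted = set(zygosity)

    tally = {"C1": 0, "C2": 0, "D1": 0, "U": 0, "remainder": 0}
    for record in records:
        if record.zygosity not in wanted:
            continue
        if subset is not None and not subset(record):
            continue
        tally[classify_pair(record)] += 1
    return ConcordanceCounts(**tally)
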