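"""Prescription data model, validation, code mapping, and corpus file I/O.

A *prescription* is one outpatient clinic-visit record: patient age and sex,
a set of ICD-10-CM diagnosis codes and a set of ATC medication codes.  The
corpus file format is a plain delimited layout (tab-separated by default)
with the multi-valued code columns joined by a secondary delimiter (``;``):

    rx_id  patient_id  age  sex  diagnoses        medications
    rx001  p001        74   female  E78.5;I10;I35.0  B01AC06;C10AA05

Code sets are written in sorted order so that write/read round-trips are
exact.  Medication code systems other than ATC (EPIC, HCPCS, RxNorm) are
supported only through a user-supplied :class:`CodeMapTable`; no licensed
dictionary is bundled.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Sentinel stratum under which pooled (all ages, both sexes) counts are stored.
POOLED_SEX = "all"
POOLED_BAND = -1

AGE_BAND_WIDTH = 5


class CorpusFormatError(ValueError):
    """Raised for structurally unreadable corpus / mapping / label files."""


@dataclass(frozen=True, order=True)
class Stratum:
    """A demographic cell: sex crossed with a 5-year age band.

    ``age_band`` is the half-open band index ``k`` covering ages
    ``[5k, 5k+5)``; the pooled sentinel uses ``sex='all', age_band=-1``.
    """

    sex: str
    age_band: int

    @property
    def is_pooled(self) -> bool:
        return self.age_band == POOLED_BAND


POOLED = Stratum(POOLED_SEX, POOLED_BAND)


def stratum_of(age: int, sex: str) -> Stratum:
    """Map an (age, sex) pair to its stratum.

    Bands are half-open ``[5k, 5k+5)`` indexed ``k = floor(age/5)``:
    age 74 -> band 14, age 75 -> band 15.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    return Stratum(sex, int(age) // AGE_BAND_WIDTH)


def _as_code_set(codes: Iterable[str], what: str) -> frozenset[str]:
    out = frozenset(str(c).strip() for c in codes if str(c).strip())
    if not out:
        raise ValueError(f"prescription must have at least one {what}")
    return out


@dataclass(frozen=True)
class Prescription:
    """One visit's prescription: demographics plus diagnosis and medication sets.

    Duplicate codes are collapsed (sets); both sets must be non-empty and age
    must be non-negative, mirroring the cohort rule of keeping only records
    with at least one diagnosis and one medication.
    """

    rx_id: str
    patient_id: str
    age: int
    sex: str
    diagnoses: frozenset[str]
    medications: frozenset[str]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        object.__setattr__(self, "diagnoses", _as_code_set(self.diagnoses, "diagnosis"))
        object.__setattr__(self, "medications", _as_code_set(self.medications, "medication"))

    @property
    def stratum(self) -> Stratum:
        return stratum_of(self.age, self.sex)


@dataclass(frozen=True)
class RxLabel:
    """Ground-truth label for one prescription (synthetic corpora, adjudication).

    ``substantiated`` is False iff the prescription carries at least one
    medication with no indication among its diagnoses; those medications are
    listed in ``flagged`` and, when they were deliberately injected, carry a
    severity grade (life_threatening / serious / significant).
    """

    rx_id: str
    substantiated: bool
    flagged: frozenset[str] = frozenset()
    severity: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "flagged", frozenset(self.flagged))
        if self.substantiated and self.flagged:
            raise ValueError("a substantiated label cannot carry flagged medications")


@dataclass
class RowError:
    line_no: int
    message: str
    raw: str = ""


@dataclass(frozen=True)
class CorpusDialect:
    """Column layout of the corpus file."""

    delimiter: str = "\t"
    code_sep: str = ";"


DEFAULT_DIALECT = CorpusDialect()
CORPUS_COLUMNS = ("rx_id", "patient_id", "age", "sex", "diagnoses", "medications")


def read_corpus(
    path: str | Path,
    dialect: CorpusDialect = DEFAULT_DIALECT,
    on_error: str = "collect",
) -> tuple[list[Prescription], list[RowError]]:
    """Read a corpus file.

    Malformed rows (bad age, unknown sex, empty code sets, wrong arity) are
    never silently dropped: with ``on_error='collect'`` they are returned as
    :class:`RowError` records, with ``on_error='raise'`` the first one aborts.
    """
    if on_error not in ("collect", "raise"):
        raise ValueError("on_error must be 'collect' or 'raise'")
    path = Path(path)
    prescriptions: list[Prescription] = []
    errors: list[RowError] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        header = next(reader, None)
        if header is None:
            return [], []  # empty file: empty corpus, zero errors
        if tuple(h.strip() for h in header) != CORPUS_COLUMNS:
            raise CorpusFormatError(
                f"{path}: expected header {CORPUS_COLUMNS}, got {tuple(header)}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                if len(row) != len(CORPUS_COLUMNS):
                    raise ValueError(f"expected {len(CORPUS_COLUMNS)} columns, got {len(row)}")
                rx_id, patient_id, age_s, sex, dx_s, med_s = (c.strip() for c in row)
                rx = Prescription(
                    rx_id=rx_id,
                    patient_id=patient_id,
                    age=int(age_s),
                    sex=sex,
                    diagnoses=frozenset(dx_s.split(dialect.code_sep)) if dx_s else frozenset(),
                    medications=frozenset(med_s.split(dialect.code_sep)) if med_s else frozenset(),
                )
            except ValueError as exc:
                err = RowError(line_no, str(exc), dialect.delimiter.join(row))
                if on_error == "raise":
                    raise CorpusFormatError(f"{path}:{line_no}: {exc}") from exc
                errors.append(err)
                continue
            prescriptions.append(rx)
    return prescriptions, errors


def write_corpus(
    corpus: Sequence[Prescription],
    path: str | Path,
    dialect: CorpusDialect = DEFAULT_DIALECT,
) -> None:
    """Write a corpus file; code sets are sorted so round-trips are exact."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(CORPUS_COLUMNS)
        for rx in corpus:
            writer.writerow(
                [
                    rx.rx_id,
                    rx.patient_id,
                    str(rx.age),
                    rx.sex,
                    dialect.code_sep.join(sorted(rx.diagnoses)),
                    dialect.code_sep.join(sorted(rx.medications)),
                ]
            )


LABEL_COLUMNS = ("rx_id", "label", "flagged_medications", "severity")
SUBSTANTIATED = "substantiated"
UNSUBSTANTIATED = "unsubstantiated"


def write_labels(
    labels: Iterable[RxLabel],
    path: str | Path,
    dialect: CorpusDialect = DEFAULT_DIALECT,
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(LABEL_COLUMNS)
        for lab in labels:
            writer.writerow(
                [
                    lab.rx_id,
                    SUBSTANTIATED if lab.substantiated else UNSUBSTANTIATED,
                    dialect.code_sep.join(sorted(lab.flagged)),
                    lab.severity or "",
                ]
            )


def read_labels(
    path: str | Path, dialect: CorpusDialect = DEFAULT_DIALECT
) -> dict[str, RxLabel]:
    out: dict[str, RxLabel] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        header = next(reader, None)
        if header is None:
            return {}
        if tuple(h.strip() for h in header) != LABEL_COLUMNS:
            raise CorpusFormatError(f"{path}: expected header {LABEL_COLUMNS}")
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            rx_id, label, flagged_s, severity = (c.strip() for c in row)
            if label not in (SUBSTANTIATED, UNSUBSTANTIATED):
                raise CorpusFormatError(f"{path}: bad label {label!r} for {rx_id}")
            out[rx_id] = RxLabel(
                rx_id=rx_id,
                substantiated=label == SUBSTANTIATED,
                flagged=frozenset(flagged_s.split(dialect.code_sep)) if flagged_s else frozenset(),
                severity=severity or None,
            )
    return out


# ---------------------------------------------------------------------------
# Code mapping (EPIC / HCPCS / RxNorm -> ATC)
# ---------------------------------------------------------------------------

SOURCE_SYSTEMS = ("EPIC", "HCPCS", "RxNorm", "other")


@dataclass
class CodeMapTable:
    """Many-to-one mapping of source medication codes onto ATC codes.

    Loaded from a 3-column delimited file: source_system, source_code,
    atc_code.  Lookups are by source code; a source code mapped to two
    different ATC codes across systems is rejected to keep the lookup
    deterministic.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "CodeMapTable":
        mapping: dict[str, str] = {}
        for system, source, atc in rows:
            system = system.strip()
            source = source.strip()
            atc = atc.strip()
            if system not in SOURCE_SYSTEMS:
                raise CorpusFormatError(f"unknown source system {system!r}")
            if not source or not atc:
                raise CorpusFormatError("empty source or ATC code in mapping table")
            if mapping.get(source, atc) != atc:
                raise CorpusFormatError(
                    f"source code {source!r} maps to both {mapping[source]!r} and {atc!r}"
                )
            mapping[source] = atc
        return cls(mapping)

    @classmethod
    def from_file(
        cls, path: str | Path, delimiter: str = "\t"
    ) -> "CodeMapTable":
        rows = []
        with Path(path).open(newline="") as fh:
            reader = csv.reader(fh, delimiter=delimiter)
            for row in reader:
                if not row or row[0].startswith("#"):
                    continue
                if len(row) != 3:
                    raise CorpusFormatError(f"{path}: mapping rows need 3 columns, got {row}")
                rows.append((row[0], row[1], row[2]))
        return cls.from_rows(rows)


def map_codes(
    corpus: Sequence[Prescription], table: CodeMapTable
) -> tuple[list[Prescription], Counter]:
    """Replace medication codes by their ATC targets.

    Codes absent from the table are left unchanged and reported with their
    corpus frequency (never silently dropped).
    """
    unmapped: Counter = Counter()
    out: list[Prescription] = []
    for rx in corpus:
        meds = set()
        for med in rx.medications:
            target = table.mapping.get(med)
            if target is None:
                unmapped[med] += 1
                meds.add(med)
            else:
                meds.add(target)
        out.append(replace(rx, medications=frozenset(meds)))
    return out, unmapped


def train_validation_split(
    corpus: Sequence[Prescription], n_validation: int, seed: int
) -> tuple[list[Prescription], list[Prescription]]:
    """Randomly split a corpus into training and validation subsets.

    Sampling is without replacement with a fixed seed; relative order within
    each subset follows the input corpus.
    """
    if not 0 < n_validation < len(corpus):
        raise ValueError(
            f"n_validation must be in (0, {len(corpus)}), got {n_validation}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(corpus), size=n_validation, replace=False)
    val_set = set(int(i) for i in idx)
    train = [rx for i, rx in enumerate(corpus) if i not in val_set]
    validation = [rx for i, rx in enumerate(corpus) if i in val_set]
    return train, validation
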