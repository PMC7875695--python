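"""Substantiation classification of prescriptions against an association table.

A medication on a prescription is *explained* when it has a positive
association (Q strictly greater than the threshold alpha) with at least one
diagnosis on the same prescription (D-M) and/or at least one of the other
medications (M-M).  A prescription is *substantiated* iff every one of its
medications is explained; otherwise it is *unsubstantiated* and the
unexplained medications are flagged as problematic.

Two aggregation rules are provided (the source protocol describes both):

``dm_or_mm`` (default)
    explained = D-M positive OR M-M positive.
``dm_and_mm``
    explained = D-M positive AND M-M positive; for single-medication
    prescriptions the M-M clause is vacuously true by default
    (``vacuous_mm``), since otherwise every monotherapy would be flagged.

Equality with alpha is negative (positive requires Q > alpha).  Absent
association records are negative evidence.  Per-medication D-M evidence is
the maximum-Q diagnosis on the prescription, which at a strict threshold is
equivalent to the existential test and implements the keep-only-the-
highest-Q-diagnosis rule at classification time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import SUBSTANTIATED, UNSUBSTANTIATED, CorpusDialect, DEFAULT_DIALECT, Prescription
from .mining import FALLBACK_POOLED, AssociationTable, PairKey

RULE_DM_OR_MM = "dm_or_mm"
RULE_DM_AND_MM = "dm_and_mm"


@dataclass(frozen=True)
class ClassifierParams:
    """Decision parameters: threshold alpha, aggregation rule, lookup policy."""

    alpha: float = 1.0
    rule: str = RULE_DM_OR_MM
    fallback: str = FALLBACK_POOLED
    vacuous_mm: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.rule not in (RULE_DM_OR_MM, RULE_DM_AND_MM):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class MedicationVerdict:
    medication: str
    dm_positive: bool
    best_dm: tuple[str, float] | None
    mm_positive: bool
    best_mm: tuple[str, float] | None
    explained: bool


@dataclass(frozen=True)
class SubstantiationResult:
    rx_id: str
    substantiated: bool
    medication_verdicts: tuple[MedicationVerdict, ...]

    @property
    def verdict(self) -> str:
        return SUBSTANTIATED if self.substantiated else UNSUBSTANTIATED

    @property
    def flagged(self) -> frozenset[str]:
        """Medications that could not be explained."""
        return frozenset(v.medication for v in self.medication_verdicts if not v.explained)


def _best_evidence(
    codes: Sequence[str],
    make_pair,
    table: AssociationTable,
    stratum,
    fallback: str,
) -> tuple[str, float] | None:
    """Highest-Q partner code among ``codes``; ties toward the smaller code."""
    best: tuple[str, float] | None = None
    for code in sorted(codes):
        q = table.q_lookup(make_pair(code), stratum, fallback)
        if q is not None and (best is None or q > best[1]):
            best = (code, q)
    return best


def medication_evidence(
    rx: Prescription,
    med: str,
    table: AssociationTable,
    fallback: str = FALLBACK_POOLED,
) -> tuple[tuple[str, float] | None, tuple[str, float] | None]:
    """Best D-M and M-M evidence for one medication, independent of alpha."""
    stratum = rx.stratum
    best_dm = _best_evidence(
        sorted(rx.diagnoses), lambda d: PairKey.dm(d, med), table, stratum, fallback
    )
    others = sorted(rx.medications - {med})
    best_mm = _best_evidence(
        others, lambda m: PairKey.mm(m, med), table, stratum, fallback
    )
    return best_dm, best_mm


def _verdict_from_evidence(
    med: str,
    n_medications: int,
    best_dm: tuple[str, float] | None,
    best_mm: tuple[str, float] | None,
    params: ClassifierParams,
) -> MedicationVerdict:
    dm_positive = best_dm is not None and best_dm[1] > params.alpha
    mm_positive = best_mm is not None and best_mm[1] > params.alpha
    if params.rule == RULE_DM_OR_MM:
        explained = dm_positive or mm_positive
    else:
        mm_clause = mm_positive
        if n_medications == 1 and params.vacuous_mm:
            mm_clause = True
        explained = dm_positive and mm_clause
    return MedicationVerdict(
        medication=med,
        dm_positive=dm_positive,
        best_dm=best_dm if dm_positive else best_dm,
        mm_positive=mm_positive,
        best_mm=best_mm,
        explained=explained,
    )


def evaluate_medication(
    rx: Prescription,
    med: str,
    table: AssociationTable,
    params: ClassifierParams = ClassifierParams(),
) -> MedicationVerdict:
    """Decide whether one medication on a prescription is explained."""
    if med not in rx.medications:
        raise ValueError(f"medication {med!r} is not on prescription {rx.rx_id!r}")
    best_dm, best_mm = medication_evidence(rx, med, table, params.fallback)
    return _verdict_from_evidence(med, len(rx.medications), best_dm, best_mm, params)


def classify_prescription(
    rx: Prescription,
    table: AssociationTable,
    params: ClassifierParams = ClassifierParams(),
) -> SubstantiationResult:
    """Classify one prescription: substantiated iff every medication is explained."""
    verdicts = tuple(
        evaluate_medication(rx, med, table, params) for med in sorted(rx.medications)
    )
    return SubstantiationResult(
        rx_id=rx.rx_id,
        substantiated=all(v.explained for v in verdicts),
        medication_verdicts=verdicts,
    )


def classify_corpus(
    corpus: Sequence[Prescription],
    table: AssociationTable,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[list[SubstantiationResult], dict[str, int]]:
    """Classify a corpus, preserving order; returns results and summary counts."""
    results = [classify_prescription(rx, table, params) for rx in corpus]
    n_sub = sum(r.substantiated for r in results)
    summary = {SUBSTANTIATED: n_sub, UNSUBSTANTIATED: len(results) - n_sub}
    return results, summary


def write_results(
    results: Sequence[SubstantiationResult],
    path: str | Path,
    dialect: CorpusDialect = DEFAULT_DIALECT,
) -> None:
    """Delimited classification report: verdict plus flagged-medication evidence."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(["rx_id", "verdict", "flagged_medications", "evidence"])
        for res in results:
            evidence = []
            for v in res.medication_verdicts:
                if v.explained:
                    continue
                best = v.best_dm or v.best_mm
                evidence.append(
                    f"{v.medication}:{best[0]}:{best[1]:.4g}" if best else f"{v.medication}:-:-"
                )
            writer.writerow(
                [
                    res.rx_id,
                    res.verdict,
                    dialect.code_sep.join(sorted(res.flagged)),
                    dialect.code_sep.join(evidence),
                ]
            )
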