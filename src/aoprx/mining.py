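"""Co-occurrence counting and Q-value (lift) estimation over a corpus.

For each diagnosis-medication (D-M) pair and each medication-medication
(M-M) pair observed on at least one prescription, the miner counts, per
demographic stratum (sex x 5-year age band) and pooled over all strata::

    n_joint  prescriptions carrying both codes
    n_a/n_b  prescriptions carrying each code alone
    n_total  prescriptions in the stratum

and estimates the association strength as the lift

    Q = P(a, b) / (P(a) P(b)) = n_joint * n_total / (n_a * n_b)

with probabilities taken as per-prescription frequencies.  Q = 1 is the
independence point, which is why the classifier's default threshold is
alpha = 1.  Pairs never co-occurring produce no record; the classifier
treats their absence as negative evidence.  The lift formula is isolated
in :func:`_q_value` so an alternative association statistic can be swapped
in without touching the counting machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import POOLED, POOLED_BAND, POOLED_SEX, Prescription, Stratum

DM = "DM"
MM = "MM"

FALLBACK_POOLED = "pooled"
FALLBACK_NONE = "none"


class ModelFormatError(ValueError):
    """Raised when a serialized association table is corrupt or incompatible."""


@dataclass(frozen=True, order=True)
class PairKey:
    """A D-M or M-M code pair.

    M-M pairs are stored in canonical lexicographic order, so Q is invariant
    to the order in which the two medications are given.
    """

    kind: str
    code_a: str
    code_b: str

    def __post_init__(self) -> None:
        if self.kind not in (DM, MM):
            raise ValueError(f"kind must be {DM!r} or {MM!r}, got {self.kind!r}")
        if self.kind == MM:
            if self.code_a == self.code_b:
                raise ValueError("an M-M pair needs two distinct medication codes")
            if self.code_a > self.code_b:
                a, b = self.code_b, self.code_a
                object.__setattr__(self, "code_a", a)
                object.__setattr__(self, "code_b", b)

    @classmethod
    def dm(cls, diagnosis: str, medication: str) -> "PairKey":
        return cls(DM, diagnosis, medication)

    @classmethod
    def mm(cls, med_a: str, med_b: str) -> "PairKey":
        return cls(MM, med_a, med_b)


@dataclass(frozen=True)
class AssociationRecord:
    pair: PairKey
    stratum: Stratum
    n_joint: int
    n_a: int
    n_b: int
    n_total: int
    q: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_joint <= min(self.n_a, self.n_b) <= self.n_total:
            raise ValueError(
                f"invalid counts for {self.pair}: joint={self.n_joint}, "
                f"a={self.n_a}, b={self.n_b}, total={self.n_total}"
            )


def _q_value(n_joint: int, n_a: int, n_b: int, n_total: int) -> float:
    """Lift of a pair from its contingency counts (the Q value)."""
    return (n_joint * n_total) / (n_a * n_b)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


class CooccurrenceCounts:
    """Marginal and joint per-prescription counts, per stratum plus pooled."""

    def __init__(
        self,
        totals: dict[Stratum, int],
        diag_marg: dict[tuple[Stratum, str], int],
        med_marg: dict[tuple[Stratum, str], int],
        dm_joint: dict[tuple[Stratum, str, str], int],
        mm_joint: dict[tuple[Stratum, str, str], int],
        stratified: bool,
    ) -> None:
        self.totals = totals
        self.diag_marg = diag_marg
        self.med_marg = med_marg
        self.dm_joint = dm_joint
        self.mm_joint = mm_joint
        self.stratified = stratified


def count_cooccurrence(
    corpus: Sequence[Prescription], stratified: bool = True
) -> CooccurrenceCounts:
    """Count code marginals and pair co-occurrences over a corpus.

    The pooled stratum is always computed; per-stratum tables are added when
    ``stratified`` is true.  Pairs that never co-occur are absent.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")

    diag_rows = []
    med_rows = []
    for i, rx in enumerate(corpus):
        s = rx.stratum
        for code in rx.diagnoses:
            diag_rows.append((i, s.sex, s.age_band, code))
        for code in rx.medications:
            med_rows.append((i, s.sex, s.age_band, code))
    dd = pd.DataFrame(diag_rows, columns=["i", "sex", "band", "code"])
    md = pd.DataFrame(med_rows, columns=["i", "sex", "band", "code"])

    totals: dict[Stratum, int] = {POOLED: len(corpus)}
    diag_marg: dict[tuple[Stratum, str], int] = {}
    med_marg: dict[tuple[Stratum, str], int] = {}
    dm_joint: dict[tuple[Stratum, str, str], int] = {}
    mm_joint: dict[tuple[Stratum, str, str], int] = {}

    def _marg(df: pd.DataFrame, out: dict, pooled_only: bool) -> None:
        for code, n in df.groupby("code").size().items():
            out[(POOLED, code)] = int(n)
        if not pooled_only:
            for (sex, band, code), n in df.groupby(["sex", "band", "code"]).size().items():
                out[(Stratum(sex, int(band)), code)] = int(n)

    _marg(dd, diag_marg, pooled_only=not stratified)
    _marg(md, med_marg, pooled_only=not stratified)

    dm = dd.merge(md[["i", "code"]], on="i", suffixes=("_d", "_m"))
    for (a, b), n in dm.groupby(["code_d", "code_m"]).size().items():
        dm_joint[(POOLED, a, b)] = int(n)
    mm = md.merge(md[["i", "code"]], on="i", suffixes=("_a", "_b"))
    mm = mm[mm["code_a"] < mm["code_b"]]
    for (a, b), n in mm.groupby(["code_a", "code_b"]).size().items():
        mm_joint[(POOLED, a, b)] = int(n)

    if stratified:
        for rx in corpus:
            totals[rx.stratum] = totals.get(rx.stratum, 0) + 1
        for (sex, band, a, b), n in dm.groupby(["sex", "band", "code_d", "code_m"]).size().items():
            dm_joint[(Stratum(sex, int(band)), a, b)] = int(n)
        for (sex, band, a, b), n in mm.groupby(["sex", "band", "code_a", "code_b"]).size().items():
            mm_joint[(Stratum(sex, int(band)), a, b)] = int(n)

    return CooccurrenceCounts(totals, diag_marg, med_marg, dm_joint, mm_joint, stratified)


# ---------------------------------------------------------------------------
# The association table (the fitted parameter store)
# ---------------------------------------------------------------------------

_COLUMNS = ("kind", "code_a", "code_b", "sex", "age_band", "n_joint", "n_a", "n_b", "n_total", "q", "provenance")
_MAGIC = "#aoprx-association-table v1"


class AssociationTable:
    """Mined Q values indexed by (stratum, pair), with provenance and metadata.

    At most one record exists per (stratum, pair).  ``meta`` carries the
    training corpus size, mining options and a provenance label (e.g. "O",
    "L", "H").  ``provenance`` optionally maps record keys to the source
    model label for merged (hybrid) tables, leaving the records themselves
    byte-identical to their source records.
    """

    def __init__(
        self,
        records: Mapping[tuple[Stratum, PairKey], AssociationRecord],
        meta: Mapping[str, object],
        provenance: Mapping[tuple[Stratum, PairKey], str] | None = None,
    ) -> None:
        self.records = dict(records)
        self.meta = dict(meta)
        self.provenance = dict(provenance or {})

    # -- core queries ------------------------------------------------------

    @property
    def label(self) -> str:
        return str(self.meta.get("label", ""))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return (
            self.records == other.records
            and self.meta == other.meta
            and self.provenance == other.provenance
        )

    def get(self, pair: PairKey, stratum: Stratum) -> AssociationRecord | None:
        return self.records.get((stratum, pair))

    def q_lookup(
        self, pair: PairKey, stratum: Stratum, fallback: str = FALLBACK_POOLED
    ) -> float | None:
        """Stratum-specific Q, with optional fall-back to the pooled stratum.

        Returns None when the pair has no record (treated as a negative
        association downstream; no imputation).
        """
        rec = self.records.get((stratum, pair))
        if rec is not None:
            return rec.q
        if fallback == FALLBACK_POOLED and not stratum.is_pooled:
            rec = self.records.get((POOLED, pair))
            if rec is not None:
                return rec.q
        elif fallback not in (FALLBACK_POOLED, FALLBACK_NONE):
            raise ValueError(f"unknown fallback policy {fallback!r}")
        return None

    def pairs(self) -> set[PairKey]:
        return {pair for (_, pair) in self.records}

    # -- transformations ---------------------------------------------------

    def prune_global_top1(self) -> "AssociationTable":
        """Keep, per (stratum, medication), only the highest-Q D-M record.

        This is the global reading of the pseudo-association rule (use only
        the strongest diagnosis per medication; discard the rest).  Ties are
        broken toward the lexicographically smaller diagnosis code.  M-M
        records are untouched.
        """
        best: dict[tuple[Stratum, str], tuple[float, str]] = {}
        for (stratum, pair), rec in self.records.items():
            if pair.kind != DM:
                continue
            key = (stratum, pair.code_b)
            cand = (rec.q, pair.code_a)
            prev = best.get(key)
            # larger q wins; on equal q, the smaller diagnosis code wins
            if prev is None or cand[0] > prev[0] or (cand[0] == prev[0] and cand[1] < prev[1]):
                best[key] = cand
        records = {
            key: rec
            for key, rec in self.records.items()
            if rec.pair.kind == MM
            or best[(key[0], rec.pair.code_b)][1] == rec.pair.code_a
        }
        meta = dict(self.meta)
        meta["pruned_top1"] = True
        prov = {k: v for k, v in self.provenance.items() if k in records}
        return AssociationTable(records, meta, prov)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (stratum, pair), rec in sorted(
            self.records.items(), key=lambda kv: (kv[0][1], kv[0][0])
        ):
            rows.append(
                (
                    pair.kind,
                    pair.code_a,
                    pair.code_b,
                    stratum.sex,
                    stratum.age_band,
                    rec.n_joint,
                    rec.n_a,
                    rec.n_b,
                    rec.n_total,
                    rec.q,
                    self.provenance.get((stratum, pair), ""),
                )
            )
        return pd.DataFrame(rows, columns=_COLUMNS)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Versioned tab-separated serialization; bit-exact round trip.

        Floats are written with ``repr`` so parsing recovers them exactly;
        the record count in the header detects truncated files on load.
        """
        path = Path(path)
        with path.open("w") as fh:
            fh.write(_MAGIC + "\n")
            fh.write("#meta " + json.dumps(self.meta, sort_keys=True) + "\n")
            fh.write(f"#records {len(self.records)}\n")
            fh.write("\t".join(_COLUMNS) + "\n")
            df = self.to_dataframe()
            for row in df.itertuples(index=False):
                fh.write(
                    "\t".join(
                        [
                            row.kind,
                            row.code_a,
                            row.code_b,
                            row.sex,
                            str(row.age_band),
                            str(row.n_joint),
                            str(row.n_a),
                            str(row.n_b),
                            str(row.n_total),
                            repr(float(row.q)),
                            row.provenance,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "AssociationTable":
        path = Path(path)
        with path.open() as fh:
            lines = fh.read().splitlines()
        if not lines or lines[0] != _MAGIC:
            raise ModelFormatError(f"{path}: not an aoprx association table (bad magic)")
        if len(lines) < 4 or not lines[1].startswith("#meta ") or not lines[2].startswith("#records "):
            raise ModelFormatError(f"{path}: missing metadata header")
        try:
            meta = json.loads(lines[1][len("#meta "):])
            n_records = int(lines[2][len("#records "):])
        except (json.JSONDecodeError, ValueError) as exc:
            raise ModelFormatError(f"{path}: corrupt metadata: {exc}") from exc
        if tuple(lines[3].split("\t")) != _COLUMNS:
            raise ModelFormatError(f"{path}: unexpected column header")
        records: dict[tuple[Stratum, PairKey], AssociationRecord] = {}
        provenance: dict[tuple[Stratum, PairKey], str] = {}
        for line in lines[4:]:
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise ModelFormatError(f"{path}: corrupt record line: {line!r}")
            kind, code_a, code_b, sex, band, nj, na, nb, nt, q, prov = parts
            try:
                pair = PairKey(kind, code_a, code_b)
                stratum = Stratum(sex, int(band))
                rec = AssociationRecord(
                    pair, stratum, int(nj), int(na), int(nb), int(nt), float(q)
                )
            except ValueError as exc:
                raise ModelFormatError(f"{path}: corrupt record: {exc}") from exc
            records[(stratum, pair)] = rec
            if prov:
                provenance[(stratum, pair)] = prov
        if len(records) != n_records:
            raise ModelFormatError(
                f"{path}: truncated or corrupt file: header says {n_records} records, "
                f"found {len(records)}"
            )
        return cls(records, meta, provenance)


def compute_q(
    counts: CooccurrenceCounts,
    min_support: int = 1,
    label: str = "model",
) -> AssociationTable:
    """Turn count tables into an :class:`AssociationTable` of lift records.

    Records whose joint count falls below ``min_support`` are omitted (no
    support floor by default).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    records: dict[tuple[Stratum, PairKey], AssociationRecord] = {}
    for (stratum, a, b), n_joint in counts.dm_joint.items():
        if n_joint < min_support:
            continue
        rec = AssociationRecord(
            PairKey.dm(a, b),
            stratum,
            n_joint,
            counts.diag_marg[(stratum, a)],
            counts.med_marg[(stratum, b)],
            counts.totals[stratum],
            _q_value(n_joint, counts.diag_marg[(stratum, a)], counts.med_marg[(stratum, b)], counts.totals[stratum]),
        )
        records[(stratum, rec.pair)] = rec
    for (stratum, a, b), n_joint in counts.mm_joint.items():
        if n_joint < min_support:
            continue
        rec = AssociationRecord(
            PairKey.mm(a, b),
            stratum,
            n_joint,
            counts.med_marg[(stratum, a)],
            counts.med_marg[(stratum, b)],
            counts.totals[stratum],
            _q_value(n_joint, counts.med_marg[(stratum, a)], counts.med_marg[(stratum, b)], counts.totals[stratum]),
        )
        records[(stratum, rec.pair)] = rec
    meta = {
        "label": label,
        "n_prescriptions": counts.totals[POOLED],
        "stratified": counts.stratified,
        "min_support": min_support,
        "pruned_top1": False,
    }
    return AssociationTable(records, meta)


def mine(
    corpus: Sequence[Prescription],
    stratified: bool = True,
    min_support: int = 1,
    prune_top1: bool = False,
    label: str = "model",
) -> AssociationTable:
    """Mine a corpus end to end: count, compute Q, optionally prune."""
    table = compute_q(count_cooccurrence(corpus, stratified=stratified), min_support, label)
    if prune_top1:
        table = table.prune_global_top1()
    return table
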