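"""One-shot federated merging of two association tables into a hybrid model.

The merge is the association-rule analogue of federated learning used here:
no training data is exchanged, only the mined tables.  For every
(stratum, pair) present in both the original (O) and locally trained (L)
tables, the hybrid (H) table keeps the record whose training corpus showed
the pair more often — the larger joint co-occurrence count ``n_joint``,
which is the only co-occurrence frequency the models store.  Pairs present
in exactly one table are included (``union``, default) or dropped
(``intersection``).  Every H record is copied unmodified from its source;
per-record provenance ("O"/"L") is tracked alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mining import AssociationTable


class IncompatibleModelsError(ValueError):
    """The two tables were not mined under the same stratification scheme."""


TIE_PREFER_O = "prefer_O"
TIE_PREFER_L = "prefer_L"
UNSHARED_UNION = "union"
UNSHARED_INTERSECTION = "intersection"


@dataclass(frozen=True)
class MergePolicy:
    """Deterministic merge policy.

    Shared pairs always go to the record with larger ``n_joint``; ties go to
    O by default (the larger, longer-established corpus).
    """

    tie_break: str = TIE_PREFER_O
    unshared: str = UNSHARED_UNION

    def __post_init__(self) -> None:
        if self.tie_break not in (TIE_PREFER_O, TIE_PREFER_L):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.unshared not in (UNSHARED_UNION, UNSHARED_INTERSECTION):
            raise ValueError(f"unknown unshared policy {self.unshared!r}")


def merge_models(
    o_model: AssociationTable,
    l_model: AssociationTable,
    policy: MergePolicy = MergePolicy(),
    label: str = "H",
) -> AssociationTable:
    """Merge O and L tables into the hybrid table H under ``policy``."""
    if bool(o_model.meta.get("stratified")) != bool(l_model.meta.get("stratified")):
        raise IncompatibleModelsError(
            "cannot merge: one table is stratified and the other is not"
        )
    records = {}
    provenance = {}
    o_keys = set(o_model.records)
    l_keys = set(l_model.records)
    for key in o_keys & l_keys:
        o_rec = o_model.records[key]
        l_rec = l_model.records[key]
        if o_rec.n_joint > l_rec.n_joint:
            winner, source = o_rec, "O"
        elif l_rec.n_joint > o_rec.n_joint:
            winner, source = l_rec, "L"
        else:
            winner, source = (
                (o_rec, "O") if policy.tie_break == TIE_PREFER_O else (l_rec, "L")
            )
        records[key] = winner
        provenance[key] = source
    if policy.unshared == UNSHARED_UNION:
        for key in o_keys - l_keys:
            records[key] = o_model.records[key]
            provenance[key] = "O"
        for key in l_keys - o_keys:
            records[key] = l_model.records[key]
            provenance[key] = "L"
    meta = {
        "label": label,
        "merged_from": [o_model.label, l_model.label],
        "tie_break": policy.tie_break,
        "unshared": policy.unshared,
        "stratified": bool(o_model.meta.get("stratified")),
        "min_support": max(
            int(o_model.meta.get("min_support", 1)), int(l_model.meta.get("min_support", 1))
        ),
        "pruned_top1": bool(o_model.meta.get("pruned_top1"))
        and bool(l_model.meta.get("pruned_top1")),
        "n_prescriptions": {
            "O": o_model.meta.get("n_prescriptions"),
            "L": l_model.meta.get("n_prescriptions"),
        },
    }
    return AssociationTable(records, meta, provenance)
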