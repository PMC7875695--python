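"""Model/Results facade over the mining, classification and merge layers.

Usage follows the estimator/results convention of statistical modelling
packages::

    model = AOPModel(corpus, stratified=True, min_support=1, label="L")
    results = model.fit()           # mines the association table
    print(results.summary())
    res = results.classify(rx)      # SubstantiationResult
    hybrid = o_results.merge(l_results)   # federated one-shot merge
    results.save("l_model.tsv"); AOPResults.load("l_model.tsv")

The "parameters" of the fitted model are the per-stratum pair records
(counts and Q values), exposed as a DataFrame via ``results.params``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import (
    ClassifierParams,
    SubstantiationResult,
    classify_corpus,
    classify_prescription,
)
from .corpus import CORPUS_COLUMNS, Prescription, Stratum
from .merge import MergePolicy, merge_models
from .mining import DM, MM, AssociationTable, PairKey, mine


class AOPModel:
    """Prescription-appropriateness model specification bound to a corpus.

    Parameters
    ----------
    corpus
        Sequence of :class:`~aoprx.corpus.Prescription` to mine.
    stratified
        Mine per sex x 5-year-age-band stratum in addition to the pooled
        stratum (the pooled stratum is always available as a fall-back).
    min_support
        Minimum joint count for a pair record to be kept (default 1: no
        support floor).
    prune_top1
        Keep only the highest-Q diagnosis per medication and stratum (the
        global reading of the pseudo-association rule); off by default —
        the classifier applies the per-prescription maximum instead.
    label
        Provenance label stored in the fitted table ("O", "L", "H", ...).
    """

    def __init__(
        self,
        corpus: Sequence[Prescription],
        stratified: bool = True,
        min_support: int = 1,
        prune_top1: bool = False,
        label: str = "model",
    ) -> None:
        if len(corpus) == 0:
            raise ValueError("empty corpus")
        self.corpus = list(corpus)
        self.stratified = stratified
        self.min_support = min_support
        self.prune_top1 = prune_top1
        self.label = label

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, code_sep: str = ";", **kwargs) -> "AOPModel":
        """Build from a DataFrame with the corpus file columns.

        ``diagnoses`` and ``medications`` may be iterables of codes or
        ``code_sep``-joined strings.
        """
        missing = set(CORPUS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing corpus columns: {sorted(missing)}")

        def codes(value):
            if isinstance(value, str):
                return frozenset(value.split(code_sep))
            return frozenset(value)

        corpus = [
            Prescription(
                rx_id=str(row.rx_id),
                patient_id=str(row.patient_id),
                age=int(row.age),
                sex=str(row.sex),
                diagnoses=codes(row.diagnoses),
                medications=codes(row.medications),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(corpus, **kwargs)

    def fit(self) -> "AOPResults":
        table = mine(
            self.corpus,
            stratified=self.stratified,
            min_support=self.min_support,
            prune_top1=self.prune_top1,
            label=self.label,
        )
        return AOPResults(table)


class AOPResults:
    """Fitted association model: mined Q values plus decision methods."""

    def __init__(self, table: AssociationTable) -> None:
        self.table = table

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> pd.DataFrame:
        """One row per (stratum, pair) record: counts, Q, provenance."""
        return self.table.to_dataframe()

    @property
    def label(self) -> str:
        return self.table.label

    def q_lookup(self, pair: PairKey, stratum: Stratum, fallback: str = "pooled") -> float | None:
        return self.table.q_lookup(pair, stratum, fallback)

    # -- decisions ---------------------------------------------------------

    def classify(
        self, rx: Prescription, params: ClassifierParams = ClassifierParams()
    ) -> SubstantiationResult:
        return classify_prescription(rx, self.table, params)

    def classify_corpus(
        self,
        corpus: Sequence[Prescription],
        params: ClassifierParams = ClassifierParams(),
    ) -> tuple[list[SubstantiationResult], dict[str, int]]:
        return classify_corpus(corpus, self.table, params)

    # -- composition -------------------------------------------------------

    def merge(
        self,
        local: "AOPResults",
        policy: MergePolicy = MergePolicy(),
        label: str = "H",
    ) -> "AOPResults":
        """One-shot federated merge: self is the original (O) model."""
        return AOPResults(merge_models(self.table, local.table, policy, label))

    def prune_global_top1(self) -> "AOPResults":
        return AOPResults(self.table.prune_global_top1())

    # -- persistence and reporting ----------------------------------------

    def save(self, path: str | Path) -> None:
        self.table.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "AOPResults":
        return cls(AssociationTable.load(path))

    def summary(self, top: int = 10) -> str:
        df = self.params
        n_dm = int((df["kind"] == DM).sum())
        n_mm = int((df["kind"] == MM).sum())
        pooled = df[df["age_band"] == -1]
        lines = [
            "Prescription appropriateness model",
            "==================================",
            f"label:                 {self.label}",
            f"training prescriptions: {self.table.meta.get('n_prescriptions')}",
            f"stratified:            {self.table.meta.get('stratified')}",
            f"min support:           {self.table.meta.get('min_support')}",
            f"pruned top-1 D-M:      {self.table.meta.get('pruned_top1')}",
            f"records:               {len(self.table)} ({n_dm} D-M, {n_mm} M-M)",
            "",
            f"strongest pooled associations (top {top} by Q, joint count >= 5):",
        ]
        strong = pooled[pooled["n_joint"] >= 5].sort_values("q", ascending=False).head(top)
        for row in strong.itertuples(index=False):
            lines.append(
                f"  {row.kind}  {row.code_a:<10} {row.code_b:<10} "
                f"Q={row.q:8.2f}  n_joint={row.n_joint}"
            )
        return "\n".join(lines) + "\n"
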