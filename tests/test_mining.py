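"""Co-occurrence counting, lift computation, lookup, pruning, serialization."""

import numpy as np
import pytest

from aoprx.corpus import FEMALE, MALE, POOLED, Stratum
from aoprx.mining import (
    AssociationRecord,
    AssociationTable,
    ModelFormatError,
    PairKey,
    compute_q,
    count_cooccurrence,
    mine,
)
from conftest import make_rx, random_corpus


def brute_force_counts(corpus):
    """Independent double-loop oracle: all strata, marginals and joints."""
    totals, diag, med, dm, mm = {}, {}, {}, {}, {}
    for rx in corpus:
        for s in (POOLED, rx.stratum):
            totals[s] = totals.get(s, 0) + 1
            for d in rx.diagnoses:
                diag[(s, d)] = diag.get((s, d), 0) + 1
            for m in rx.medications:
                med[(s, m)] = med.get((s, m), 0) + 1
            for d in rx.diagnoses:
                for m in rx.medications:
                    dm[(s, d, m)] = dm.get((s, d, m), 0) + 1
            for a in rx.medications:
                for b in rx.medications:
                    if a < b:
                        mm[(s, a, b)] = mm.get((s, a, b), 0) + 1
    return totals, diag, med, dm, mm


class TestCounting:
    def test_exhaustive_enumeration_single_rx(self):
        corpus = [make_rx("r1", {"D"}, {"M1", "M2"})]
        counts = count_cooccurrence(corpus)
        assert counts.dm_joint[(POOLED, "D", "M1")] == 1
        assert counts.dm_joint[(POOLED, "D", "M2")] == 1
        assert counts.mm_joint[(POOLED, "M1", "M2")] == 1
        assert counts.totals[POOLED] == 1

    def test_hand_counted_two_by_two(self):
        # D and M co-occur once; each occurs twice; 4 prescriptions total.
        corpus = [
            make_rx("r1", {"D"}, {"M"}),
            make_rx("r2", {"D"}, {"Mx"}),
            make_rx("r3", {"Dx"}, {"M"}),
            make_rx("r4", {"Dx"}, {"Mx"}),
        ]
        counts = count_cooccurrence(corpus)
        assert counts.dm_joint[(POOLED, "D", "M")] == 1
        assert counts.diag_marg[(POOLED, "D")] == 2
        assert counts.med_marg[(POOLED, "M")] == 2
        assert counts.totals[POOLED] == 4
        table = compute_q(counts)
        assert table.get(PairKey.dm("D", "M"), POOLED).q == pytest.approx(1.0)

    def test_duplication_scales_counts_but_not_q(self):
        rng = np.random.default_rng(3)
        corpus = random_corpus(rng, 25)
        base = mine(corpus)
        dup = mine(
            [
                make_rx(f"{rx.rx_id}-{k}", rx.diagnoses, rx.medications, rx.age, rx.sex)
                for k in range(3)
                for rx in corpus
            ]
        )
        assert dup.pairs() == base.pairs()
        for (stratum, pair), rec in base.records.items():
            dup_rec = dup.get(pair, stratum)
            assert dup_rec.n_joint == 3 * rec.n_joint
            assert dup_rec.q == pytest.approx(rec.q)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            count_cooccurrence([])

    def test_matches_bruteforce_on_random_corpora(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            corpus = random_corpus(rng, int(rng.integers(3, 40)))
            counts = count_cooccurrence(corpus)
            totals, diag, med, dm, mm = brute_force_counts(corpus)
            assert counts.totals == totals
            assert counts.diag_marg == diag
            assert counts.med_marg == med
            assert {(s, a, b): n for (s, a, b), n in counts.dm_joint.items()} == dm
            assert {(s, a, b): n for (s, a, b), n in counts.mm_joint.items()} == mm


class TestComputeQ:
    def test_independence_gives_lift_one(self):
        corpus = [
            make_rx("r1", {"D"}, {"M"}),
            make_rx("r2", {"D"}, {"Mx"}),
            make_rx("r3", {"Dx"}, {"M"}),
            make_rx("r4", {"Dx"}, {"Mx"}),
        ]
        table = mine(corpus, stratified=False)
        assert table.get(PairKey.dm("D", "M"), POOLED).q == pytest.approx(1.0)

    def test_perfect_dependence_gives_inverse_prevalence(self):
        # M present iff D present; D in 10 of 100 prescriptions -> lift 10.
        corpus = [make_rx(f"r{i}", {"D"}, {"M"}) for i in range(10)] + [
            make_rx(f"s{i}", {"Dx"}, {"Mx"}) for i in range(90)
        ]
        table = mine(corpus, stratified=False)
        assert table.get(PairKey.dm("D", "M"), POOLED).q == pytest.approx(10.0)

    def test_never_cooccurring_pair_absent(self):
        corpus = [make_rx("r1", {"D"}, {"Mx"}), make_rx("r2", {"Dx"}, {"M"})]
        table = mine(corpus)
        assert table.get(PairKey.dm("D", "M"), POOLED) is None
        assert table.q_lookup(PairKey.dm("D", "M"), Stratum(FEMALE, 12)) is None

    def test_min_support_filters_records(self):
        corpus = [make_rx("r1", {"D"}, {"M"})] + [
            make_rx(f"r{i}", {"E"}, {"N"}) for i in range(2, 5)
        ]
        table = mine(corpus, min_support=2, stratified=False)
        assert table.get(PairKey.dm("D", "M"), POOLED) is None
        assert table.get(PairKey.dm("E", "N"), POOLED) is not None

    def test_mm_symmetric_in_code_order(self):
        corpus = [make_rx("r1", {"D"}, {"M2", "M1"}), make_rx("r2", {"D"}, {"M1"})]
        table = mine(corpus)
        assert table.q_lookup(PairKey.mm("M1", "M2"), POOLED) == table.q_lookup(
            PairKey.mm("M2", "M1"), POOLED
        )

    def test_record_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            AssociationRecord(PairKey.dm("D", "M"), POOLED, 5, 3, 4, 10, 1.0)


class TestLookup:
    def make_table(self):
        s = Stratum(FEMALE, 10)
        pair = PairKey.dm("D", "M")
        records = {
            (s, pair): AssociationRecord(pair, s, 2, 4, 4, 10, 1.25),
            (POOLED, pair): AssociationRecord(pair, POOLED, 5, 10, 10, 100, 5.0),
        }
        return AssociationTable(records, {"label": "t", "stratified": True})

    def test_direct_hit(self):
        table = self.make_table()
        assert table.q_lookup(PairKey.dm("D", "M"), Stratum(FEMALE, 10)) == 1.25

    def test_pooled_fallback(self):
        table = self.make_table()
        assert table.q_lookup(PairKey.dm("D", "M"), Stratum(MALE, 3)) == 5.0
        assert table.q_lookup(PairKey.dm("D", "M"), Stratum(MALE, 3), fallback="none") is None

    def test_absent_everywhere(self):
        table = self.make_table()
        assert table.q_lookup(PairKey.dm("Dx", "M"), Stratum(FEMALE, 10)) is None


class TestPruneTop1:
    def make_table(self, q1, q2):
        recs = {}
        for d, q in (("D1", q1), ("D2", q2)):
            pair = PairKey.dm(d, "M")
            n_joint = 1
            recs[(POOLED, pair)] = AssociationRecord(pair, POOLED, n_joint, 10, 10, 100, q)
        mm_pair = PairKey.mm("M", "M2")
        recs[(POOLED, mm_pair)] = AssociationRecord(mm_pair, POOLED, 1, 10, 10, 100, 2.0)
        return AssociationTable(recs, {"label": "t", "stratified": False})

    def test_argmax_retained(self):
        pruned = self.make_table(5.0, 2.0).prune_global_top1()
        assert pruned.get(PairKey.dm("D1", "M"), POOLED) is not None
        assert pruned.get(PairKey.dm("D2", "M"), POOLED) is None
        assert pruned.get(PairKey.mm("M", "M2"), POOLED) is not None  # MM untouched

    def test_singleton_unchanged(self):
        table = self.make_table(5.0, 2.0).prune_global_top1()
        again = table.prune_global_top1()
        assert again.records == table.records

    def test_tie_prefers_smaller_diagnosis_code(self):
        pruned = self.make_table(3.0, 3.0).prune_global_top1()
        assert pruned.get(PairKey.dm("D1", "M"), POOLED) is not None
        assert pruned.get(PairKey.dm("D2", "M"), POOLED) is None


class TestSerialization:
    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        table = mine(random_corpus(rng, 40), label="O")
        path = tmp_path / "model.tsv"
        table.save(path)
        back = AssociationTable.load(path)
        assert back == table
        assert back.meta["label"] == "O"

    def test_truncated_file_is_corrupt(self, tmp_path):
        rng = np.random.default_rng(8)
        table = mine(random_corpus(rng, 30))
        path = tmp_path / "model.tsv"
        table.save(path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[: len(lines) - 5]) + "\n")
        with pytest.raises(ModelFormatError):
            AssociationTable.load(path)

    def test_wrong_magic_rejected(self, tmp_path):
        path = tmp_path / "junk.tsv"
        path.write_text("not a model\n")
        with pytest.raises(ModelFormatError):
            AssociationTable.load(path)
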