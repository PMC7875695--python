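"""Evaluation protocol: sampling, exclusion, adjudication, metrics, kappa,
group comparisons, class tables and model discordance."""

import math

import numpy as np
import pytest

from aoprx.classify import MedicationVerdict, SubstantiationResult
from aoprx.corpus import FEMALE, MALE, SUBSTANTIATED, UNSUBSTANTIATED
from aoprx import evaluation as ev
from conftest import make_rx


def result(rx_id, substantiated, flagged=()):
    verdicts = tuple(
        MedicationVerdict(m, False, None, False, None, False) for m in flagged
    )
    return SubstantiationResult(rx_id, substantiated, verdicts)


def reviews_for(rx_id, label_a, label_b, conf_a=6, conf_b=6, sev_a=None, sev_b=None):
    return [
        ev.ReviewRecord(rx_id, "rater_a", label_a, sev_a, conf_a),
        ev.ReviewRecord(rx_id, "rater_b", label_b, sev_b, conf_b),
    ]


class TestEnrichedSampling:
    def make_results(self, n_sub, n_unsub):
        return [result(f"s{i}", True) for i in range(n_sub)] + [
            result(f"u{i}", False) for i in range(n_unsub)
        ]

    def test_balanced_sample_of_600(self):
        results = self.make_results(400, 350)
        sample = ev.build_enriched_test_set(results, 300, seed=9)
        assert len(sample) == 600 and len(set(sample)) == 600
        assert sum(rx.startswith("u") for rx in sample) == 300

    def test_exhaustive_when_class_sizes_equal_request(self):
        sample = ev.build_enriched_test_set(self.make_results(1, 1), 1, seed=0)
        assert sorted(sample) == ["s0", "u0"]

    def test_same_seed_reproduces_bit_for_bit(self):
        results = self.make_results(50, 50)
        assert ev.build_enriched_test_set(results, 20, seed=4) == ev.build_enriched_test_set(
            results, 20, seed=4
        )

    def test_class_too_small(self):
        with pytest.raises(ValueError):
            ev.build_enriched_test_set(self.make_results(10, 2), 5, seed=0)


class TestConfidenceExclusion:
    def test_either_rater_below_threshold_excludes(self):
        reviews = reviews_for("r1", SUBSTANTIATED, SUBSTANTIATED, conf_a=3, conf_b=6)
        reviews += reviews_for("r2", SUBSTANTIATED, SUBSTANTIATED, conf_a=6, conf_b=6)
        retained, excluded = ev.apply_confidence_exclusion(reviews)
        assert retained == ["r2"] and excluded == ["r1"]

    def test_all_confident_all_retained(self):
        reviews = []
        for i in range(10):
            reviews += reviews_for(f"r{i}", SUBSTANTIATED, SUBSTANTIATED)
        retained, excluded = ev.apply_confidence_exclusion(reviews)
        assert len(retained) == 10 and excluded == []

    def test_600_minus_4(self):
        reviews = []
        for i in range(600):
            conf = 3 if i in (5, 120, 340, 599) else 6
            reviews += reviews_for(f"r{i}", SUBSTANTIATED, SUBSTANTIATED, conf_a=conf)
        retained, excluded = ev.apply_confidence_exclusion(reviews)
        assert len(retained) == 596 and len(excluded) == 4

    def test_missing_rater_record_rejected(self):
        reviews = [ev.ReviewRecord("r1", "rater_a", SUBSTANTIATED)]
        reviews += reviews_for("r2", SUBSTANTIATED, SUBSTANTIATED)
        with pytest.raises(ValueError):
            ev.apply_confidence_exclusion(reviews)


class TestAdjudication:
    def test_agreement_passes_through(self):
        reviews = reviews_for(
            "r1", UNSUBSTANTIATED, UNSUBSTANTIATED, sev_a="serious", sev_b="serious"
        )
        out = ev.adjudicate(reviews)
        assert out["r1"].label == UNSUBSTANTIATED and out["r1"].severity == "serious"

    def test_split_resolved_by_tie_breaker(self):
        reviews = reviews_for("r1", SUBSTANTIATED, UNSUBSTANTIATED, sev_b="significant")
        out = ev.adjudicate(
            reviews, {"r1": ev.AdjudicatedLabel("r1", SUBSTANTIATED)}
        )
        assert out["r1"].label == SUBSTANTIATED

    def test_split_without_tie_breaker_is_an_error(self):
        reviews = reviews_for("r1", SUBSTANTIATED, UNSUBSTANTIATED, sev_b="significant")
        with pytest.raises(ev.AdjudicationError):
            ev.adjudicate(reviews)


class TestConfusionAndMetrics:
    def test_perfect_predictions(self):
        truths = {f"p{i}": UNSUBSTANTIATED for i in range(4)}
        truths.update({f"n{i}": SUBSTANTIATED for i in range(6)})
        cm = ev.confusion_counts(dict(truths), truths)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (4, 6, 0, 0)
        m = ev.compute_metrics(cm)
        assert m.sensitivity == m.specificity == m.ppv == m.npv == m.accuracy == 1.0

    def test_all_positive_predictor(self):
        truths = {f"p{i}": UNSUBSTANTIATED for i in range(4)}
        truths.update({f"n{i}": SUBSTANTIATED for i in range(6)})
        preds = {k: UNSUBSTANTIATED for k in truths}
        cm = ev.confusion_counts(preds, truths)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (4, 6, 0, 0)
        m = ev.compute_metrics(cm)
        assert m.npv is None and m.specificity == 0.0  # undefined vs defined

    def test_hand_arithmetic(self):
        cm = ev.ConfusionMatrix(tp=204, fp=95, tn=269, fn=28)
        m = ev.compute_metrics(cm)
        assert m.sensitivity == pytest.approx(204 / 232)
        assert m.specificity == pytest.approx(269 / 364)
        assert m.ppv == pytest.approx(204 / 299)
        assert m.npv == pytest.approx(269 / 297)
        assert m.accuracy == pytest.approx(473 / 596)

    def test_degenerate_denominators_are_none_not_zero(self):
        cm = ev.ConfusionMatrix(tp=0, fp=0, tn=5, fn=2)
        m = ev.compute_metrics(cm)
        assert m.ppv is None and m.specificity == 1.0


class TestCohenKappa:
    def test_perfect_agreement(self):
        labels = [SUBSTANTIATED] * 5 + [UNSUBSTANTIATED] * 5
        res = ev.cohen_kappa(labels, labels)
        assert res.kappa == pytest.approx(1.0)
        assert res.ci_low <= res.kappa <= res.ci_high

    def test_hand_computed_two_by_two(self):
        # agreement table a=40, b=10 / c=10, d=40: p_o=0.8, p_e=0.5, kappa=0.6
        a = ["x"] * 40 + ["x"] * 10 + ["y"] * 10 + ["y"] * 40
        b = ["x"] * 40 + ["y"] * 10 + ["x"] * 10 + ["y"] * 40
        res = ev.cohen_kappa(a, b)
        assert res.p_observed == pytest.approx(0.8)
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = list(rng.choice(["x", "y"], size=200))
        b = list(rng.choice(["x", "y"], size=200))
        assert ev.cohen_kappa(a, b).kappa == pytest.approx(ev.cohen_kappa(b, a).kappa)

    def test_independent_random_rater_near_zero_in_expectation(self):
        rng = np.random.default_rng(2)
        kappas = []
        for _ in range(200):
            a = list(rng.choice(["x", "y"], size=100))
            b = list(rng.choice(["x", "y"], size=100))
            kappas.append(ev.cohen_kappa(a, b).kappa)
        assert abs(float(np.mean(kappas))) < 0.03

    def test_degenerate_marginals_explicit_error(self):
        with pytest.raises(ValueError):
            ev.cohen_kappa(["x"] * 10, ["x"] * 10)

    def test_three_level_severity_scale(self):
        a = ["serious"] * 5 + ["significant"] * 10 + ["life_threatening"] * 2
        res = ev.cohen_kappa(a, a)
        assert res.kappa == pytest.approx(1.0)

    def test_matches_sklearn_cross_check(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        a = list(rng.choice(["x", "y"], size=300, p=[0.7, 0.3]))
        b = [x if rng.random() < 0.8 else ("y" if x == "x" else "x") for x in a]
        ours = ev.cohen_kappa(a, b).kappa
        theirs = sklearn_metrics.cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs)


class TestGroupComparison:
    def corpus_and_truths(self, shift=0, n=50):
        corpus, truths = [], {}
        rng = np.random.default_rng(11)
        for i in range(n):
            dx = [f"D{j}" for j in range(int(rng.integers(1, 5)))]
            meds = [f"M{j}" for j in range(int(rng.integers(1, 4)))]
            rx = make_rx(f"s{i}", dx, meds, age=int(rng.integers(40, 90)), sex=MALE if i % 2 else FEMALE)
            corpus.append(rx)
            truths[rx.rx_id] = SUBSTANTIATED
        for i in range(n):
            dx = [f"D{j}" for j in range(int(rng.integers(1, 5)))]
            meds = [f"M{j}" for j in range(int(rng.integers(1, 4)) + shift)]
            rx = make_rx(f"u{i}", dx, meds, age=int(rng.integers(40, 90)), sex=MALE if i % 2 else FEMALE)
            corpus.append(rx)
            truths[rx.rx_id] = UNSUBSTANTIATED
        return corpus, truths

    def test_identical_groups_null_case(self):
        corpus, truths = self.corpus_and_truths(shift=0)
        df = ev.compare_groups(corpus, truths)
        age_row = df[df["characteristic"].str.startswith("age")].iloc[0]
        assert age_row["p_value"] > 0.5 or abs(age_row["statistic"]) < 2

    def test_shifted_medication_counts_detected(self):
        corpus, truths = self.corpus_and_truths(shift=2, n=200)
        df = ev.compare_groups(corpus, truths)
        med_row = df[df["characteristic"].str.startswith("number of medications")].iloc[0]
        assert med_row["p_value"] < 0.05

    def test_zero_variance_equal_means_t_statistic_zero(self):
        corpus = [make_rx(f"s{i}", {"D"}, {"M"}, age=70) for i in range(5)]
        corpus += [make_rx(f"u{i}", {"D"}, {"M", "M2"}, age=70) for i in range(5)]
        truths = {rx.rx_id: (SUBSTANTIATED if rx.rx_id.startswith("s") else UNSUBSTANTIATED) for rx in corpus}
        df = ev.compare_groups(corpus, truths)
        age_row = df[df["characteristic"].str.startswith("age")].iloc[0]
        assert age_row["statistic"] == 0.0 and age_row["p_value"] == 1.0


class TestMedicationClasses:
    def test_prefix_mapping_counts(self):
        flagged = [("N02AA01", None), ("N02AA05", None), ("N05BA01", None)]
        df = ev.tabulate_medication_classes(flagged)
        total = df[df["stratum"] == "total"].set_index("medication_class")["count"]
        assert total["opioid analgesic"] == 2 and total["benzodiazepine"] == 1

    def test_empty_flag_set(self):
        assert ev.tabulate_medication_classes([]).empty

    def test_order_invariance_and_severity_strata(self):
        flagged = [("N02AA01", "serious"), ("A02BC01", "significant"), ("N02AA05", "serious")]
        df1 = ev.tabulate_medication_classes(flagged)
        df2 = ev.tabulate_medication_classes(list(reversed(flagged)))
        assert df1.equals(df2)
        serious = df1[df1["stratum"] == "serious"].set_index("medication_class")["count"]
        assert serious["opioid analgesic"] == 2


class TestDiscordance:
    def test_identical_models_no_flips(self):
        res = [result(f"r{i}", i % 2 == 0, () if i % 2 == 0 else ("N02AA01",)) for i in range(10)]
        truths = {r.rx_id: r.verdict for r in res}
        report = ev.discordance_analysis(res, res, truths)
        assert report["true_positive_flips"]["n_flipped"] == 0
        assert report["false_positive_flips"]["n_flipped"] == 0

    def test_hand_built_forty_percent(self):
        # 5 truth-positives, all O-positive; H flips 2 back to substantiated.
        truths = {f"p{i}": UNSUBSTANTIATED for i in range(5)}
        truths.update({f"n{i}": SUBSTANTIATED for i in range(5)})
        res_o = [result(f"p{i}", False, ("N02AA01",)) for i in range(5)]
        res_o += [result(f"n{i}", True) for i in range(5)]
        res_h = [result(f"p{i}", i < 2) for i in range(5)]
        res_h += [result(f"n{i}", True) for i in range(5)]
        report = ev.discordance_analysis(res_o, res_h, truths)
        tp = report["true_positive_flips"]
        assert tp["n_flipped"] == 2 and tp["fraction"] == pytest.approx(0.4)
        top = tp["top_classes"].set_index("medication_class")["count"]
        assert top["opioid analgesic"] == 2


class TestSweepShape:
    def test_default_grid_has_eleven_rows_per_model(self, small_world, fixtures):
        _, test, results = small_world
        corpus = test.prescriptions[:300]
        truths = {rx.rx_id: test.truth_labels[rx.rx_id] for rx in corpus}
        df = ev.threshold_sweep({"L": results.table}, corpus, truths)
        assert len(df) == 11 and set(df["model"]) == {"L"}

    def test_single_alpha_consistent_with_direct_metrics(self, small_world):
        _, test, results = small_world
        corpus = test.prescriptions[:300]
        truths = {rx.rx_id: test.truth_labels[rx.rx_id] for rx in corpus}
        df = ev.threshold_sweep({"L": results.table}, corpus, truths, alphas=[1.0])
        res, _ = results.classify_corpus(corpus)
        cm = ev.confusion_counts({r.rx_id: r.verdict for r in res}, truths)
        row = df.iloc[0]
        assert (row.tp, row.fp, row.tn, row.fn) == (cm.tp, cm.fp, cm.tn, cm.fn)

    def test_sensitivity_non_decreasing_in_alpha(self, small_world):
        _, test, results = small_world
        corpus = test.prescriptions[:800]
        truths = {rx.rx_id: test.truth_labels[rx.rx_id] for rx in corpus}
        df = ev.threshold_sweep({"L": results.table}, corpus, truths).sort_values("alpha")
        sens = df["sensitivity"].tolist()
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))

    def test_formatted_table_mentions_na_and_models(self, small_world):
        _, test, results = small_world
        corpus = test.prescriptions[:100]
        truths = {rx.rx_id: test.truth_labels[rx.rx_id] for rx in corpus}
        df = ev.threshold_sweep({"L": results.table, "L2": results.table}, corpus, truths)
        text = ev.format_metrics_table(df)
        assert "L" in text and "Sen" in text and "Accu" in text
        assert len(text.splitlines()) == 13  # 2 header lines + 11 thresholds


class TestSplitSummary:
    def test_percentages(self):
        s = ev.summarize_split(667572, 60000)
        assert s["n_training"] == 607572
        assert s["pct_validation"] == pytest.approx(100 * 60000 / 667572)
        assert s["pct_validation"] + s["pct_training"] == pytest.approx(100.0)
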