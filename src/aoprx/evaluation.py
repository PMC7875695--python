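"""Evaluation protocol: enriched test sets, rater adjudication, metrics.

The protocol mirrors a prospective chart-review validation of the
substantiation classifier:

1. classify a held-out validation corpus at alpha=1 and sample an *enriched*
   test set with equal numbers of model-predicted substantiated and
   unsubstantiated prescriptions;
2. collect two independent reviewer labels per prescription (with a
   confidence score on a 6-point scale and a severity grade for
   unsubstantiated calls), exclude prescriptions where either reviewer's
   confidence fell below 4, and adjudicate disagreements with a third
   (senior) label;
3. score the models against the adjudicated ground truth — sensitivity,
   specificity, PPV, NPV and accuracy with *unsubstantiated* as the positive
   class — across a grid of thresholds (default alpha 0.5..1.5 in steps of
   0.1);
4. report interrater agreement (Cohen's kappa with a large-sample 95% CI),
   group comparisons of patient characteristics, the medication classes most
   often flagged, and the discordance between two models' errors.

Undefined metrics (zero denominators) are reported as None and printed as
"NA", never as 0.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    ClassifierParams,
    SubstantiationResult,
    medication_evidence,
)
from .corpus import SUBSTANTIATED, UNSUBSTANTIATED, Prescription
from .mining import FALLBACK_POOLED, AssociationTable

SEVERITIES = ("life_threatening", "serious", "significant")
DEFAULT_ALPHAS = tuple(round(0.5 + 0.1 * i, 1) for i in range(11))  # 0.5 .. 1.5


class AdjudicationError(ValueError):
    """A reviewer disagreement could not be resolved (no tie-breaker given)."""


@dataclass(frozen=True)
class ReviewRecord:
    """One reviewer's judgment of one prescription."""

    rx_id: str
    rater_id: str
    label: str
    severity: str | None = None
    confidence: int = 6

    def __post_init__(self) -> None:
        if self.label not in (SUBSTANTIATED, UNSUBSTANTIATED):
            raise ValueError(f"bad label {self.label!r}")
        if not 1 <= self.confidence <= 6:
            raise ValueError("confidence must be on the 6-point scale (1..6)")
        if self.severity is not None:
            if self.label != UNSUBSTANTIATED:
                raise ValueError("severity applies only to unsubstantiated labels")
            if self.severity not in SEVERITIES:
                raise ValueError(f"bad severity {self.severity!r}")


@dataclass(frozen=True)
class AdjudicatedLabel:
    rx_id: str
    label: str
    severity: str | None = None


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive class = unsubstantiated prescription."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRow:
    """Sen/Spe/PPV/NPV/Accu at one threshold; None marks an undefined metric."""

    alpha: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_expected: float
    n: int


# ---------------------------------------------------------------------------
# Test set construction and adjudication
# ---------------------------------------------------------------------------


def build_enriched_test_set(
    results: Sequence[SubstantiationResult],
    n_per_class: int,
    seed: int,
) -> list[str]:
    """Sample ``n_per_class`` rx ids from each predicted class, shuffled.

    Sampling is without replacement with the stated seed, so the same seed
    reproduces the same test set bit for bit.
    """
    by_class: dict[str, list[str]] = {SUBSTANTIATED: [], UNSUBSTANTIATED: []}
    for res in results:
        by_class[res.verdict].append(res.rx_id)
    for cls, members in by_class.items():
        if len(members) < n_per_class:
            raise ValueError(
                f"predicted class {cls!r} has only {len(members)} members, "
                f"need {n_per_class}"
            )
    rng = np.random.default_rng(seed)
    sample: list[str] = []
    for cls in (SUBSTANTIATED, UNSUBSTANTIATED):
        members = by_class[cls]
        idx = rng.choice(len(members), size=n_per_class, replace=False)
        sample.extend(members[int(i)] for i in idx)
    rng.shuffle(sample)
    return sample


def apply_confidence_exclusion(
    reviews: Sequence[ReviewRecord],
    min_confidence: int = 4,
) -> tuple[list[str], list[str]]:
    """Keep prescriptions where *every* reviewer's confidence >= threshold.

    Returns (retained rx ids, excluded rx ids), each in first-seen order.
    Raises if any prescription is missing a record from any reviewer.
    """
    raters = sorted({r.rater_id for r in reviews})
    seen: dict[str, set[str]] = defaultdict(set)
    min_conf: dict[str, int] = {}
    order: list[str] = []
    for rec in reviews:
        if rec.rx_id not in min_conf:
            order.append(rec.rx_id)
            min_conf[rec.rx_id] = rec.confidence
        else:
            min_conf[rec.rx_id] = min(min_conf[rec.rx_id], rec.confidence)
        seen[rec.rx_id].add(rec.rater_id)
    for rx_id in order:
        missing = set(raters) - seen[rx_id]
        if missing:
            raise ValueError(f"prescription {rx_id!r} missing review from {sorted(missing)}")
    retained = [rx for rx in order if min_conf[rx] >= min_confidence]
    excluded = [rx for rx in order if min_conf[rx] < min_confidence]
    return retained, excluded


def adjudicate(
    reviews: Sequence[ReviewRecord],
    tie_breaker: Mapping[str, AdjudicatedLabel] | None = None,
) -> dict[str, AdjudicatedLabel]:
    """Resolve paired reviews into one ground-truth label (+severity) per rx.

    Agreement yields the shared label; disagreement requires a tie-breaking
    label (the senior physician) or raises :class:`AdjudicationError`.
    Severity is adjudicated the same way among unsubstantiated calls.
    """
    by_rx: dict[str, list[ReviewRecord]] = defaultdict(list)
    for rec in reviews:
        by_rx[rec.rx_id].append(rec)
    out: dict[str, AdjudicatedLabel] = {}
    for rx_id, recs in by_rx.items():
        labels = {r.label for r in recs}
        if len(labels) == 1:
            label = labels.pop()
            severity = None
            if label == UNSUBSTANTIATED:
                sevs = {r.severity for r in recs}
                if len(sevs) == 1:
                    severity = sevs.pop()
                elif tie_breaker is not None and rx_id in tie_breaker:
                    severity = tie_breaker[rx_id].severity
                else:
                    raise AdjudicationError(
                        f"severity disagreement on {rx_id!r} with no tie-breaker"
                    )
            out[rx_id] = AdjudicatedLabel(rx_id, label, severity)
        else:
            if tie_breaker is None or rx_id not in tie_breaker:
                raise AdjudicationError(
                    f"label disagreement on {rx_id!r} with no tie-breaker"
                )
            tb = tie_breaker[rx_id]
            out[rx_id] = AdjudicatedLabel(rx_id, tb.label, tb.severity)
    return out


def severity_summary(truths: Iterable[AdjudicatedLabel]) -> dict[str, object]:
    """Counts and percentages of severity grades among unsubstantiated labels."""
    unsub = [t for t in truths if t.label == UNSUBSTANTIATED]
    counts = Counter(t.severity for t in unsub)
    n = len(unsub)
    return {
        "n_unsubstantiated": n,
        "counts": {sev: counts.get(sev, 0) for sev in SEVERITIES},
        "percent": {
            sev: (100.0 * counts.get(sev, 0) / n) if n else None for sev in SEVERITIES
        },
    }


def summarize_split(n_total: int, n_validation: int) -> dict[str, float]:
    """Report a train/validation split as counts and percentages."""
    if not 0 < n_validation < n_total:
        raise ValueError("need 0 < n_validation < n_total")
    return {
        "n_total": n_total,
        "n_validation": n_validation,
        "n_training": n_total - n_validation,
        "pct_validation": 100.0 * n_validation / n_total,
        "pct_training": 100.0 * (n_total - n_validation) / n_total,
    }


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


def confusion_counts(
    predictions: Mapping[str, str],
    truths: Mapping[str, str],
) -> ConfusionMatrix:
    """Tally the 2x2 table; positive = unsubstantiated."""
    if set(predictions) != set(truths):
        raise ValueError("predictions and truths must cover the same prescriptions")
    tp = fp = tn = fn = 0
    for rx_id, pred in predictions.items():
        truth = truths[rx_id]
        if truth == UNSUBSTANTIATED:
            if pred == UNSUBSTANTIATED:
                tp += 1
            else:
                fn += 1
        else:
            if pred == UNSUBSTANTIATED:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(cm: ConfusionMatrix, alpha: float | None = None) -> MetricsRow:
    """Diagnostic metrics at full precision; zero denominators yield None."""
    return MetricsRow(
        alpha=alpha,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
    )


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def threshold_sweep(
    tables: Mapping[str, AssociationTable],
    test_corpus: Sequence[Prescription],
    truths: Mapping[str, str],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    params: ClassifierParams = ClassifierParams(),
) -> pd.DataFrame:
    """Metrics per (model, alpha) over a grid, reusing evidence across alphas.

    The per-medication best D-M and M-M Q values do not depend on alpha, so
    they are computed once per model and thresholded per grid point.  The
    returned tidy frame has one row per (model, alpha) with the confusion
    counts and metrics (None for undefined).
    """
    if len(alphas) == 0:
        raise ValueError("alpha grid must be non-empty")
    rows = []
    for name, table in tables.items():
        evidence = []  # per rx: (rx_id, [(n_meds, best_dm_q, best_mm_q), ...])
        for rx in test_corpus:
            per_med = []
            for med in sorted(rx.medications):
                best_dm, best_mm = medication_evidence(rx, med, table, params.fallback)
                per_med.append(
                    (
                        best_dm[1] if best_dm else None,
                        best_mm[1] if best_mm else None,
                    )
                )
            evidence.append((rx.rx_id, len(rx.medications), per_med))
        for alpha in alphas:
            preds: dict[str, str] = {}
            for rx_id, n_meds, per_med in evidence:
                ok = True
                for dm_q, mm_q in per_med:
                    dm_pos = dm_q is not None and dm_q > alpha
                    mm_pos = mm_q is not None and mm_q > alpha
                    if params.rule == "dm_and_mm":
                        mm_clause = mm_pos or (n_meds == 1 and params.vacuous_mm)
                        explained = dm_pos and mm_clause
                    else:
                        explained = dm_pos or mm_pos
                    if not explained:
                        ok = False
                        break
                preds[rx_id] = SUBSTANTIATED if ok else UNSUBSTANTIATED
            cm = confusion_counts(preds, truths)
            metrics = compute_metrics(cm, alpha=alpha)
            rows.append(
                {
                    "model": name,
                    "alpha": alpha,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "fn": cm.fn,
                    "sensitivity": metrics.sensitivity,
                    "specificity": metrics.specificity,
                    "ppv": metrics.ppv,
                    "npv": metrics.npv,
                    "accuracy": metrics.accuracy,
                }
            )
    return pd.DataFrame(rows)


def format_metrics_table(sweep: pd.DataFrame) -> str:
    """Render a sweep as a fixed-width table: models side by side, one row
    per threshold (descending), metrics to two decimals, NA for undefined."""
    models = list(dict.fromkeys(sweep["model"]))
    metrics = ["sensitivity", "specificity", "ppv", "npv", "accuracy"]
    short = {"sensitivity": "Sen", "specificity": "Spe", "ppv": "PPV", "npv": "NPV", "accuracy": "Accu"}

    def fmt(x: float | None) -> str:
        return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.2f}"

    header1 = "alpha".ljust(7) + "".join(m.center(5 * len(metrics) + 2) for m in models)
    header2 = "".ljust(7) + "".join(
        ("".join(short[k].ljust(5) for k in metrics) + "  ") for _ in models
    )
    lines = [header1, header2]
    for alpha in sorted(set(sweep["alpha"]), reverse=True):
        line = f"{alpha:<7.1f}"
        for m in models:
            row = sweep[(sweep["model"] == m) & (sweep["alpha"] == alpha)].iloc[0]
            line += "".join(fmt(row[k]).ljust(5) for k in metrics) + "  "
        lines.append(line.rstrip())
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Interrater agreement
# ---------------------------------------------------------------------------


def cohen_kappa(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    ci_level: float = 0.95,
) -> KappaResult:
    """Cohen's kappa with the standard large-sample (agreement-based) CI.

    kappa = (p_o - p_e) / (1 - p_e), p_e from the raters' marginal products;
    SE = sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).  Works for any number of
    categories (binary substantiation labels or the 3-level severity scale).
    Degenerate marginals (p_e = 1) are an explicit error.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label vectors")
    cats = sorted(set(labels_a) | set(labels_b))
    a_idx = [cats.index(x) for x in labels_a]
    b_idx = [cats.index(x) for x in labels_b]
    table = np.zeros((len(cats), len(cats)))
    for i, j in zip(a_idx, b_idx):
        table[i, j] += 1
    p = table / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if p_e >= 1.0 - 1e-12:
        raise ValueError("degenerate marginals (p_e = 1): kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(max(p_o * (1 - p_o), 0.0) / (n * (1 - p_e) ** 2))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return KappaResult(
        kappa=kappa,
        ci_low=kappa - z * se,
        ci_high=kappa + z * se,
        p_observed=p_o,
        p_expected=p_e,
        n=n,
    )


# ---------------------------------------------------------------------------
# Group comparison (patient characteristics)
# ---------------------------------------------------------------------------


def compare_groups(
    corpus: Sequence[Prescription],
    truths: Mapping[str, str],
) -> pd.DataFrame:
    """Compare patient characteristics between truth groups.

    Age: two-tailed t test (mean, SD per group).  Sex: chi-square.  Numbers
    of diagnoses and medications: median, IQR and Wilcoxon rank-sum.  Both
    groups must be non-empty.  Returns a small frame shaped like a
    characteristics table (one row per characteristic, with a P value).
    """
    by_id = {rx.rx_id: rx for rx in corpus}
    groups: dict[str, list[Prescription]] = {SUBSTANTIATED: [], UNSUBSTANTIATED: []}
    for rx_id, label in truths.items():
        groups[label].append(by_id[rx_id])
    g_sub, g_unsub = groups[SUBSTANTIATED], groups[UNSUBSTANTIATED]
    if not g_sub or not g_unsub:
        raise ValueError("both truth groups must be non-empty")

    def ages(g):
        return np.array([rx.age for rx in g], dtype=float)

    def _ttest(x, y):
        if np.var(x) == 0 and np.var(y) == 0:
            # degenerate: no variance in either arm
            return (0.0, 1.0) if np.mean(x) == np.mean(y) else (math.inf, 0.0)
        t, p = stats.ttest_ind(x, y, equal_var=True)
        return float(t), float(p)

    t_stat, t_p = _ttest(ages(g_sub), ages(g_unsub))

    sex_table = np.array(
        [
            [sum(rx.sex == "male" for rx in g_sub), sum(rx.sex == "female" for rx in g_sub)],
            [sum(rx.sex == "male" for rx in g_unsub), sum(rx.sex == "female" for rx in g_unsub)],
        ]
    )
    if (sex_table.sum(axis=0) == 0).any():
        chi2_p = None
    else:
        chi2_p = float(stats.chi2_contingency(sex_table)[1])

    def _wilcoxon(x, y):
        if np.array_equal(np.sort(x), np.sort(y)):
            return 1.0
        return float(stats.mannwhitneyu(x, y, alternative="two-sided")[1])

    n_dx_sub = np.array([len(rx.diagnoses) for rx in g_sub], dtype=float)
    n_dx_unsub = np.array([len(rx.diagnoses) for rx in g_unsub], dtype=float)
    n_med_sub = np.array([len(rx.medications) for rx in g_sub], dtype=float)
    n_med_unsub = np.array([len(rx.medications) for rx in g_unsub], dtype=float)

    def iqr(x):
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    rows = [
        {
            "characteristic": "sex (male/female)",
            "substantiated": f"{sex_table[0,0]}/{sex_table[0,1]}",
            "unsubstantiated": f"{sex_table[1,0]}/{sex_table[1,1]}",
            "statistic": None,
            "p_value": chi2_p,
        },
        {
            "characteristic": "age (years), mean (SD)",
            "substantiated": f"{np.mean(ages(g_sub)):.1f} ({np.std(ages(g_sub), ddof=1):.1f})"
            if len(g_sub) > 1
            else f"{np.mean(ages(g_sub)):.1f} (0.0)",
            "unsubstantiated": f"{np.mean(ages(g_unsub)):.1f} ({np.std(ages(g_unsub), ddof=1):.1f})"
            if len(g_unsub) > 1
            else f"{np.mean(ages(g_unsub)):.1f} (0.0)",
            "statistic": t_stat,
            "p_value": t_p,
        },
        {
            "characteristic": "number of diagnoses, median (IQR)",
            "substantiated": f"{np.median(n_dx_sub):g} ({iqr(n_dx_sub):g})",
            "unsubstantiated": f"{np.median(n_dx_unsub):g} ({iqr(n_dx_unsub):g})",
            "statistic": None,
            "p_value": _wilcoxon(n_dx_sub, n_dx_unsub),
        },
        {
            "characteristic": "number of medications, median (IQR)",
            "substantiated": f"{np.median(n_med_sub):g} ({iqr(n_med_sub):g})",
            "unsubstantiated": f"{np.median(n_med_unsub):g} ({iqr(n_med_unsub):g})",
            "statistic": None,
            "p_value": _wilcoxon(n_med_sub, n_med_unsub),
        },
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Medication-class tables and model discordance
# ---------------------------------------------------------------------------

#: ATC prefix -> medication class.  Longest matching prefix wins; unmatched
#: codes fall into "other".  Covers the classes reported for flagged
#: medications in outpatient internal-medicine prescribing.
DEFAULT_ATC_CLASS_MAP: tuple[tuple[str, str], ...] = (
    ("N02A", "opioid analgesic"),
    ("N05BA", "benzodiazepine"),
    ("N05CD", "benzodiazepine"),
    ("N05CF", "nonbenzodiazepine hypnotic"),
    ("N06AB", "SSRI"),
    ("N02B", "nonopioid analgesic"),
    ("M01A", "nonopioid analgesic"),
    ("A02BC", "PPI"),
    ("R06A", "antihistamine"),
    ("B01AA", "anticoagulant"),
    ("B01AF", "anticoagulant"),
    ("B01AC", "antiplatelet"),
    ("C07", "beta-blocker"),
    ("C09", "ACEi/ARB"),
    ("N05A", "antipsychotic"),
    ("N03A", "anticonvulsant"),
    ("A10", "antidiabetic"),
    ("C10AA", "statin"),
    ("C03", "diuretic"),
    ("C08", "calcium channel blocker"),
    ("H03AA", "thyroid hormone"),
    ("J01", "antibiotic"),
    ("R03", "respiratory inhalant"),
    ("L01BA", "antifolate immunosuppressant"),
    ("P01BA", "antimalarial DMARD"),
    ("B03BB", "folate supplement"),
    ("N06AA", "tricyclic antidepressant"),
    ("C01", "cardiac glycoside/antiarrhythmic"),
    ("J01XE", "antibiotic"),
)


def atc_class(code: str, class_map: Sequence[tuple[str, str]] = DEFAULT_ATC_CLASS_MAP) -> str:
    best = ""
    name = "other"
    for prefix, cls in class_map:
        if code.startswith(prefix) and len(prefix) > len(best):
            best, name = prefix, cls
    return name


def tabulate_medication_classes(
    flagged: Iterable[tuple[str, str | None]],
    class_map: Sequence[tuple[str, str]] = DEFAULT_ATC_CLASS_MAP,
) -> pd.DataFrame:
    """Frequency of flagged medications per class, overall and per severity.

    ``flagged`` is an iterable of (ATC code, severity-or-None).  The result
    is a tidy frame (stratum, medication_class, count) sorted by descending
    count within each stratum; the "total" stratum counts every flag.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for code, severity in sorted(flagged):
        cls = atc_class(code, class_map)
        counts["total"][cls] += 1
        if severity is not None:
            counts[severity][cls] += 1
    rows = []
    for stratum in ("total",) + SEVERITIES:
        for cls, n in sorted(counts.get(stratum, Counter()).items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({"stratum": stratum, "medication_class": cls, "count": n})
    return pd.DataFrame(rows, columns=["stratum", "medication_class", "count"])


def discordance_analysis(
    results_o: Sequence[SubstantiationResult],
    results_h: Sequence[SubstantiationResult],
    truths: Mapping[str, str],
    class_map: Sequence[tuple[str, str]] = DEFAULT_ATC_CLASS_MAP,
) -> dict[str, object]:
    """Where do the O and H models disagree, relative to the ground truth?

    For each truth group, counts the prescriptions the O model called
    unsubstantiated that the H model called substantiated (O-positive ->
    H-negative flips), as a fraction of the group, plus the medication
    classes the O model had flagged among the flipped cases.
    """
    o_by = {r.rx_id: r for r in results_o}
    h_by = {r.rx_id: r for r in results_h}
    if set(o_by) != set(h_by) or not set(truths) <= set(o_by):
        raise ValueError("O and H results must cover the same test set as the truths")
    report: dict[str, object] = {}
    for group, key in ((UNSUBSTANTIATED, "true_positive_flips"), (SUBSTANTIATED, "false_positive_flips")):
        members = [rx for rx, lab in truths.items() if lab == group]
        flips = [
            rx
            for rx in members
            if not o_by[rx].substantiated and h_by[rx].substantiated
        ]
        flagged = [
            (med, None) for rx in flips for med in sorted(o_by[rx].flagged)
        ]
        classes = tabulate_medication_classes(flagged, class_map)
        report[key] = {
            "n_group": len(members),
            "n_flipped": len(flips),
            "fraction": (len(flips) / len(members)) if members else None,
            "percent": (100.0 * len(flips) / len(members)) if members else None,
            "top_classes": classes[classes["stratum"] == "total"].drop(columns="stratum"),
            "rx_ids": flips,
        }
    return report
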