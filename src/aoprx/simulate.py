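"""Synthetic outpatient prescription generator with known ground truth.

The generator emulates the structure the association miner is meant to
exploit in real outpatient data:

* **Demographics** — age drawn from a truncated normal and sex from a fixed
  ratio.  Two presets are shipped: ``local`` (age mean 53.4, SD 19.8, 36%
  male — a US academic-hospital outpatient profile) and ``original`` (mean
  46.6, SD 23.3, 45% male — a Taiwanese national-claims profile), enabling
  original-vs-local-vs-hybrid experiments on genuinely different
  populations.
* **Diagnoses** — each visit's diagnosis list is short and problem-focused:
  k iid draws (k from a small fixed distribution, deduplicated) from a
  disease catalog with per-stratum weights (age/sex modifiers).  Drawing a
  *fixed number* of diagnoses, rather than independent per-disease coin
  flips, reproduces the key empirical feature that an unrelated diagnosis
  *displaces* a medication's indication: unindicated disease-medication
  pairs sit at lift < 1, not at 1.
* **Comorbidity** — conditional add rules (if A is drawn and B absent, add B
  with probability p) plant pseudo-associations, e.g. hypertension pulling
  in type 2 diabetes so that insulin acquires a spurious lift with
  hypertension.
* **Medications** — each diagnosis independently contributes its indicated
  medications with per-pair probabilities; companion rules add co-medication
  structure (folate alongside methotrexate) that only an M-M association can
  explain; optional *background* medications are drawn independently of all
  diagnoses (planted lift exactly 1, used for calibration).
* **Error injection** — with probability ``error_rate`` the prescription
  receives one extra medication indicated by *none* of its diagnoses (an
  indicated medication of a randomly chosen absent disease), recorded in the
  ground-truth label together with a severity grade drawn from
  ``severity_mix``.

:func:`analytic_lift` gives the closed-form expected lift of a pair under
the generative process (derivations in the docstring), serving as an
independent oracle for the miner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .corpus import (
    FEMALE,
    MALE,
    Prescription,
    RxLabel,
    Stratum,
    write_corpus,
    write_labels,
)
from .mining import DM, MM, AssociationRecord, AssociationTable, PairKey
from .evaluation import SEVERITIES, ReviewRecord
from .corpus import SUBSTANTIATED, UNSUBSTANTIATED


@dataclass(frozen=True)
class Demographics:
    """Truncated-normal age distribution plus a sex ratio."""

    age_mean: float
    age_sd: float
    age_min: int = 18
    age_max: int = 95
    male_fraction: float = 0.5


LOCAL_DEMOGRAPHICS = Demographics(age_mean=53.4, age_sd=19.8, male_fraction=0.36)
ORIGINAL_DEMOGRAPHICS = Demographics(age_mean=46.6, age_sd=23.3, male_fraction=0.45)


@dataclass(frozen=True)
class Disease:
    """Catalog entry: base draw weight with age/sex modifiers.

    The per-stratum weight is ``weight * age_factor * sex_factor`` where
    ``age_factor = clip(1 + age_slope * (band_mid - 50)/50, 0.05, inf)``;
    weights are normalized within a stratum before sampling.
    """

    code: str
    name: str
    weight: float
    age_slope: float = 0.0
    male_factor: float = 1.0
    female_factor: float = 1.0


@dataclass(frozen=True)
class ComorbidityRule:
    """If ``disease_a`` is drawn and ``disease_b`` absent, add b with prob p."""

    disease_a: str
    disease_b: str
    p_add: float


#: Default severity mix for injected errors: no life-threatening errors,
#: roughly one in nine serious, the rest significant.
DEFAULT_SEVERITY_MIX = {
    "life_threatening": 0.0,
    "serious": 27 / 232,
    "significant": 205 / 232,
}


@dataclass
class GeneratorTruth:
    """The synthetic world: catalog, indication map, structure, error model."""

    diseases: tuple[Disease, ...]
    indications: dict[str, dict[str, float]]
    comorbidity: tuple[ComorbidityRule, ...] = ()
    co_medication: dict[str, dict[str, float]] = field(default_factory=dict)
    background_meds: dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.1
    severity_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEVERITY_MIX))
    demographics: Demographics = LOCAL_DEMOGRAPHICS
    n_dx_probs: tuple[float, ...] = (0.20, 0.30, 0.30, 0.13, 0.07)

    def __post_init__(self) -> None:
        if not self.diseases:
            raise ValueError("disease catalog must be non-empty")
        codes = [d.code for d in self.diseases]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate disease codes in catalog")
        if set(self.indications) - set(codes):
            raise ValueError("indication map references unknown diseases")
        for d in codes:
            if not self.indications.get(d):
                raise ValueError(f"disease {d} has no indicated medication")
        for probs in self.indications.values():
            for p in probs.values():
                if not 0 <= p <= 1:
                    raise ValueError("indication probabilities must be in [0,1]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0,1]")
        if abs(sum(self.severity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")
        if abs(sum(self.n_dx_probs) - 1.0) > 1e-9:
            raise ValueError("n_dx_probs must sum to 1")

    # -- cached structure --------------------------------------------------

    @property
    def disease_codes(self) -> tuple[str, ...]:
        return tuple(d.code for d in self.diseases)

    def indication_of(self, med: str) -> str | None:
        """The unique disease indicating ``med`` (None for companions/background)."""
        hits = [d for d, meds in self.indications.items() if med in meds]
        if len(hits) > 1:
            raise ValueError(f"medication {med} has multiple indications: {hits}")
        return hits[0] if hits else None

    def stratum_weights(self, stratum: Stratum) -> np.ndarray:
        mid = stratum.age_band * 5 + 2.5
        w = np.array(
            [
                d.weight
                * max(1.0 + d.age_slope * (mid - 50.0) / 50.0, 0.05)
                * (d.male_factor if stratum.sex == MALE else d.female_factor)
                for d in self.diseases
            ]
        )
        total = w.sum()
        if total <= 0:
            raise ValueError(f"no disease has positive weight in stratum {stratum}")
        return w / total


@dataclass
class LabeledCorpus:
    """A generated corpus plus its ground-truth labels keyed by rx id."""

    prescriptions: list[Prescription]
    labels: dict[str, RxLabel]

    def write(self, corpus_path: str | Path, labels_path: str | Path) -> None:
        write_corpus(self.prescriptions, corpus_path)
        write_labels([self.labels[rx.rx_id] for rx in self.prescriptions], labels_path)

    @property
    def truth_labels(self) -> dict[str, str]:
        return {
            rx_id: SUBSTANTIATED if lab.substantiated else UNSUBSTANTIATED
            for rx_id, lab in self.labels.items()
        }


# ---------------------------------------------------------------------------
# Default catalog
# ---------------------------------------------------------------------------

_CATALOG: tuple[tuple, ...] = (
    # code, name, weight, slope, male_f, female_f, {med: prob}
    ("I10", "essential hypertension", 0.060, 0.8, 1.0, 1.0, {"C09CA01": 0.55, "C08CA01": 0.35}),
    ("E11.9", "type 2 diabetes mellitus", 0.040, 0.5, 1.0, 1.0, {"A10BA02": 0.75, "A10AB01": 0.30}),
    ("E78.5", "hyperlipidemia", 0.055, 0.6, 1.0, 1.0, {"C10AA05": 0.85}),
    ("I25.10", "coronary artery disease", 0.030, 1.0, 1.2, 0.9, {"B01AC06": 0.80}),
    ("I50.9", "heart failure", 0.020, 1.2, 1.0, 1.0, {"C03CA01": 0.75}),
    ("I35.0", "aortic stenosis", 0.010, 1.5, 1.0, 1.0, {"C07AB02": 0.60}),
    ("J45.909", "asthma", 0.040, -0.4, 1.0, 1.0, {"R03AC02": 0.80, "R03BA02": 0.35}),
    ("G40.309", "generalized idiopathic epilepsy", 0.015, 0.0, 1.0, 1.0, {"N03AX14": 0.85}),
    ("M06.9", "rheumatoid arthritis", 0.018, 0.3, 0.7, 1.3, {"L01BA01": 0.70, "P01BA02": 0.30}),
    ("F32.9", "major depressive disorder", 0.045, -0.2, 0.8, 1.2, {"N06AB03": 0.75}),
    ("F41.9", "anxiety disorder", 0.040, -0.3, 0.8, 1.2, {"N05BA06": 0.60}),
    ("K21.9", "gastro-esophageal reflux", 0.050, 0.2, 1.0, 1.0, {"A02BC01": 0.85}),
    ("E03.9", "hypothyroidism", 0.035, 0.4, 0.5, 1.5, {"H03AA01": 0.90}),
    ("I48.91", "atrial fibrillation", 0.020, 1.3, 1.2, 0.9, {"B01AA03": 0.60, "C01AA05": 0.20}),
    ("N39.0", "urinary tract infection", 0.030, -0.1, 0.6, 1.4, {"J01XE01": 0.85}),
    ("M54.5", "low back pain", 0.050, 0.0, 1.0, 1.0, {"M01AE01": 0.65, "N02AA05": 0.15}),
    ("J06.9", "upper respiratory infection", 0.045, -0.6, 1.0, 1.0, {"N02BE01": 0.60, "R06AE07": 0.35}),
    ("G47.00", "insomnia", 0.030, 0.0, 1.0, 1.0, {"N05CF02": 0.65}),
    ("R26.9", "gait abnormality", 0.012, 1.0, 1.0, 1.0, {"M01AB05": 0.50}),
    ("E66.9", "obesity", 0.030, -0.2, 1.0, 1.0, {"A08AB01": 0.50}),
    ("M81.0", "osteoporosis", 0.020, 1.4, 0.4, 1.6, {"M05BA04": 0.70}),
    ("N40.0", "benign prostatic hyperplasia", 0.022, 1.6, 2.0, 0.0, {"G04CA02": 0.80}),
    ("N95.1", "menopausal disorder", 0.020, 0.3, 0.0, 2.0, {"G03CA03": 0.60}),
    ("F17.210", "nicotine dependence", 0.025, -0.1, 1.3, 0.8, {"N07BA03": 0.40}),
    ("G43.909", "migraine", 0.025, -0.3, 0.7, 1.3, {"N02CC01": 0.70}),
    ("K58.9", "irritable bowel syndrome", 0.020, -0.2, 0.9, 1.1, {"A03AA04": 0.55}),
    ("D64.9", "anemia", 0.020, 0.3, 0.8, 1.2, {"B03AA07": 0.75}),
)

#: Companion (co-medication) rules: folate cover with methotrexate; a PPI
#: alongside chronic NSAID use.
_DEFAULT_CO_MEDICATION = {
    "L01BA01": {"B03BB01": 0.85},
    "M01AE01": {"A02BC01": 0.25},
}

#: The planted comorbidity: hypertension pulls in type 2 diabetes, giving
#: insulin a pseudo-association with hypertension.
_DEFAULT_COMORBIDITY = (ComorbidityRule("I10", "E11.9", 0.35),)


def default_truth(
    preset: str = "local",
    error_rate: float = 0.1,
    background_meds: Mapping[str, float] | None = None,
    severity_mix: Mapping[str, float] | None = None,
) -> GeneratorTruth:
    """The shipped synthetic world.

    ``preset`` selects the demographic profile ("local" or "original"); all
    structural truth (catalog, indications, comorbidity, co-medication) is
    shared so that models mined from the two presets overlap, as two health
    systems' corpora would.  ``background_meds`` plants diagnosis-independent
    medications (lift exactly 1) for calibration studies; the clinical
    default plants none, because an indication-less medication is
    unsubstantiated by definition yet sits exactly at the classifier's
    independence point.
    """
    demographics = {"local": LOCAL_DEMOGRAPHICS, "original": ORIGINAL_DEMOGRAPHICS}.get(preset)
    if demographics is None:
        raise ValueError(f"unknown preset {preset!r}; use 'local' or 'original'")
    return GeneratorTruth(
        diseases=tuple(
            Disease(code, name, w, slope, mf, ff) for code, name, w, slope, mf, ff, _ in _CATALOG
        ),
        indications={code: dict(meds) for code, _, _, _, _, _, meds in _CATALOG},
        comorbidity=_DEFAULT_COMORBIDITY,
        co_medication={k: dict(v) for k, v in _DEFAULT_CO_MEDICATION.items()},
        background_meds=dict(background_meds or {}),
        error_rate=error_rate,
        severity_mix=dict(severity_mix) if severity_mix else dict(DEFAULT_SEVERITY_MIX),
        demographics=demographics,
    )


def generate_truth(seed: int = 0, **params) -> GeneratorTruth:
    """Deterministic truth constructor (same truth for the same arguments).

    The shipped catalog is fixed, so ``seed`` does not perturb it; it is
    accepted so callers can treat truth construction like the other seeded
    generator stages.
    """
    del seed
    return default_truth(**params)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def _age_band_probs(dem: Demographics) -> dict[int, float]:
    """P(age band) under rounded, clipped normal ages."""
    ages = np.arange(dem.age_min, dem.age_max + 1)
    lo = ages - 0.5
    hi = ages + 0.5
    p = sps.norm.cdf(hi, dem.age_mean, dem.age_sd) - sps.norm.cdf(lo, dem.age_mean, dem.age_sd)
    # clipping piles tail mass onto the boundary ages
    p[0] = sps.norm.cdf(hi[0], dem.age_mean, dem.age_sd)
    p[-1] = 1.0 - sps.norm.cdf(lo[-1], dem.age_mean, dem.age_sd)
    p = p / p.sum()
    bands: dict[int, float] = {}
    for age, prob in zip(ages, p):
        bands[int(age) // 5] = bands.get(int(age) // 5, 0.0) + float(prob)
    return bands


def generate_corpus(
    truth: GeneratorTruth,
    n: int,
    seed: int,
    id_prefix: str = "rx",
) -> LabeledCorpus:
    """Generate ``n`` labeled prescriptions; deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dem = truth.demographics
    codes = truth.disease_codes
    n_dis = len(codes)
    kmax = len(truth.n_dx_probs)

    ages = np.clip(np.rint(rng.normal(dem.age_mean, dem.age_sd, size=n)), dem.age_min, dem.age_max).astype(int)
    sexes = np.where(rng.random(n) < dem.male_fraction, MALE, FEMALE)
    ks = rng.choice(np.arange(1, kmax + 1), size=n, p=np.asarray(truth.n_dx_probs))

    # Per-stratum disease draws (weights differ by stratum); strata visited in
    # sorted order so the RNG stream is reproducible.
    draws = np.empty((n, kmax), dtype=np.int64)
    strata: dict[Stratum, list[int]] = {}
    for i in range(n):
        strata.setdefault(Stratum(str(sexes[i]), int(ages[i]) // 5), []).append(i)
    for stratum in sorted(strata):
        idx = strata[stratum]
        w = truth.stratum_weights(stratum)
        draws[idx, :] = rng.choice(n_dis, size=(len(idx), kmax), p=w)

    sev_names = list(truth.severity_mix)
    sev_probs = np.array([truth.severity_mix[s] for s in sev_names])
    comorbidity = sorted(truth.comorbidity, key=lambda r: (r.disease_a, r.disease_b))
    background = sorted(truth.background_meds.items())

    prescriptions: list[Prescription] = []
    labels: dict[str, RxLabel] = {}
    for i in range(n):
        dx = {codes[j] for j in draws[i, : ks[i]]}
        for rule in comorbidity:
            if rule.disease_a in dx and rule.disease_b not in dx and rng.random() < rule.p_add:
                dx.add(rule.disease_b)
        meds: set[str] = set()
        for d in sorted(dx):
            for m, p in truth.indications[d].items():
                if rng.random() < p:
                    meds.add(m)
        for m, p in background:
            if rng.random() < p:
                meds.add(m)
        for m in sorted(meds):
            for f, p in truth.co_medication.get(m, {}).items():
                if f not in meds and rng.random() < p:
                    meds.add(f)
        if not meds:
            # visit always leaves with at least one indicated medication
            d = sorted(dx)[rng.integers(len(dx))]
            options = list(truth.indications[d].items())
            probs = np.array([p for _, p in options])
            meds.add(options[int(rng.choice(len(options), p=probs / probs.sum()))][0])
        flagged: str | None = None
        severity: str | None = None
        if rng.random() < truth.error_rate:
            absent = [d for d in codes if d not in dx]
            for j in rng.permutation(len(absent)):
                d_err = absent[int(j)]
                options = [(m, p) for m, p in truth.indications[d_err].items() if m not in meds]
                if options:
                    probs = np.array([p for _, p in options])
                    flagged = options[int(rng.choice(len(options), p=probs / probs.sum()))][0]
                    meds.add(flagged)
                    severity = sev_names[int(rng.choice(len(sev_names), p=sev_probs))]
                    break
        rx_id = f"{id_prefix}{i:07d}"
        prescriptions.append(
            Prescription(
                rx_id=rx_id,
                patient_id=f"p{i:07d}",
                age=int(ages[i]),
                sex=str(sexes[i]),
                diagnoses=frozenset(dx),
                medications=frozenset(meds),
            )
        )
        labels[rx_id] = RxLabel(
            rx_id=rx_id,
            substantiated=flagged is None,
            flagged=frozenset([flagged] if flagged else []),
            severity=severity,
        )
    return LabeledCorpus(prescriptions, labels)


# ---------------------------------------------------------------------------
# Analytic lift oracle
# ---------------------------------------------------------------------------


def _strata_probs(truth: GeneratorTruth) -> list[tuple[Stratum, float]]:
    bands = _age_band_probs(truth.demographics)
    male = truth.demographics.male_fraction
    out = []
    for sex, p_sex in ((MALE, male), (FEMALE, 1 - male)):
        for band, p_band in bands.items():
            out.append((Stratum(sex, band), p_sex * p_band))
    return out


def _draw_present(truth: GeneratorTruth, stratum: Stratum, codes: Sequence[str]) -> float:
    """P(all ``codes`` drawn in the base diagnosis draw | stratum).

    Inclusion–exclusion over the k iid weighted draws:
    P(all of S present) = sum_{T subset S} (-1)^|T| E_k[(1 - w_T)^k].
    """
    w = truth.stratum_weights(stratum)
    index = {c: j for j, c in enumerate(truth.disease_codes)}
    ws = [w[index[c]] for c in dict.fromkeys(codes)]
    total = 0.0
    m = len(ws)
    for mask in range(1 << m):
        w_t = sum(ws[j] for j in range(m) if mask >> j & 1)
        sign = -1 if bin(mask).count("1") % 2 else 1
        ek = sum(
            p * (1.0 - w_t) ** k for k, p in enumerate(truth.n_dx_probs, start=1)
        )
        total += sign * ek
    return total


def _present(truth: GeneratorTruth, stratum: Stratum, codes: Sequence[str]) -> float:
    """P(all ``codes`` present after comorbidity rules | stratum).

    A rule (a, b, p) only ever *adds* b, so only rules whose target is in
    the query set contribute: P(S) = P_draw(S) + p (P_draw(S\\{b} + a)
    - P_draw(S + a)).  Multiple rules targeting the same disease are summed
    (exact for the shipped single rule, additive approximation otherwise).
    """
    codes = list(dict.fromkeys(codes))
    p = _draw_present(truth, stratum, codes)
    for rule in truth.comorbidity:
        if rule.disease_b in codes:
            rest = [c for c in codes if c != rule.disease_b]
            p += rule.p_add * (
                _draw_present(truth, stratum, rest + [rule.disease_a])
                - _draw_present(truth, stratum, codes + [rule.disease_a])
            )
    return p


def _expected_n_dx(truth: GeneratorTruth, stratum: Stratum) -> float:
    return sum(_present(truth, stratum, [c]) for c in truth.disease_codes)


def _injection_rate(truth: GeneratorTruth, stratum: Stratum, med: str, d_med: str) -> float:
    """P(``med`` is the injected error | stratum), to first order.

    The injector picks one absent disease uniformly and one of its indicated
    medications with probability proportional to the indication weight:
    error_rate * P(d_med absent) / E[#absent diseases] * relw(med | d_med).
    """
    probs = truth.indications[d_med]
    relw = probs[med] / sum(probs.values())
    n_absent = len(truth.disease_codes) - _expected_n_dx(truth, stratum)
    p_absent = 1.0 - _present(truth, stratum, [d_med])
    return truth.error_rate * p_absent / max(n_absent, 1.0) * relw


def _med_paths(truth: GeneratorTruth, med: str):
    """How ``med`` can appear: its indication (if any) and companion rules.

    Returns ``(ind, comps)`` with ``ind = (disease, prob)`` or None and
    ``comps`` a list of ``(parent_disease, parent_prob, companion_prob)``
    for every parent medication that pulls ``med`` in as a companion.
    """
    d = truth.indication_of(med)
    ind = (d, truth.indications[d][med]) if d is not None else None
    comps = []
    for parent, companions in truth.co_medication.items():
        if med in companions:
            d_p = truth.indication_of(parent)
            if d_p is None:
                raise ValueError(f"companion parent {parent} has no indication")
            comps.append((d_p, truth.indications[d_p][parent], companions[med]))
    return ind, comps


def _med_joint_with(truth: GeneratorTruth, stratum: Stratum, med: str, extra: list[str]) -> float:
    """P(``med`` present AND all diseases in ``extra`` present | stratum).

    Union of the indication path and companion paths with pairwise overlap
    corrections, plus the injection cross-term (indication path only; a
    medication is never injected while its own indication is listed).
    With ``extra = []`` this is the medication marginal.
    """
    if med in truth.background_meds:
        return truth.background_meds[med] * _present(truth, stratum, extra) if extra else truth.background_meds[med]
    ind, comps = _med_paths(truth, med)
    if ind is None and not comps:
        raise ValueError(f"medication {med} is not reachable in this truth")
    total = 0.0
    if ind is not None:
        d, q = ind
        total += _present(truth, stratum, extra + [d]) * q
        if not any(a == d for a in extra):
            total += _injection_rate(truth, stratum, med, d) * (
                # injection requires the indication absent; an extra disease
                # being present scales the term by its conditional presence
                (_present(truth, stratum, extra) - _present(truth, stratum, extra + [d]))
                / max(1.0 - _present(truth, stratum, [d]), 1e-12)
                if extra
                else 1.0
            )
    for d_p, q_p, c in comps:
        total += _present(truth, stratum, extra + [d_p]) * q_p * c
        if ind is not None:
            d, q = ind
            total -= _present(truth, stratum, extra + [d, d_p]) * q * q_p * c
    # pairwise overlap between two companion parents (rare structure)
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            d1, q1, c1 = comps[i]
            d2, q2, c2 = comps[j]
            total -= _present(truth, stratum, extra + [d1, d2]) * q1 * c1 * q2 * c2
    return total


def _med_marginal(truth: GeneratorTruth, stratum: Stratum, med: str) -> float:
    return _med_joint_with(truth, stratum, med, [])


def analytic_lift(truth: GeneratorTruth, pair: PairKey) -> float:
    """Closed-form expected lift of a pair under the generative process.

    Derivations (per stratum s, then marginalized over the stratum mix):

    * D-M with medication m indicated by disease d:
      P(a, m | s) = P(a, d | s) q_dm + err(a, m | s) where the injection
      cross-term err = error_rate (P(a|s) - P(a,d|s)) / E[#absent] * relw(m)
      vanishes when a = d (a medication is never injected while its own
      indication is listed).  Lift = sum_s pi_s P(a,m|s) / (P(a) P(m)).
    * D-M with a background medication: exactly 1 (drawn independently).
    * M-M companion pair (parent m, companion f added with prob c):
      P(m, f | s) = P(m | s) c, so lift = sum_s pi_s P(m|s) c / (P(m) P(f)).
    * M-M between two indicated medications (diseases d1, d2):
      P(m1, m2 | s) = P(d1, d2 | s) q1 q2.

    Small terms deliberately ignored (documented approximations, each well
    under the 10% oracle tolerance at the shipped parameters): the forced
    draw that guarantees a non-empty medication set, second-order injection
    interactions, and companion-of-injected paths.
    """
    strata = _strata_probs(truth)

    def pooled(fn) -> float:
        return sum(pi * fn(s) for s, pi in strata)

    if pair.kind == DM:
        a, m = pair.code_a, pair.code_b
        if m in truth.background_meds:
            return 1.0
        p_a = pooled(lambda s: _present(truth, s, [a]))
        p_m = pooled(lambda s: _med_marginal(truth, s, m))
        joint = pooled(lambda s: _med_joint_with(truth, s, m, [a]))
        return joint / (p_a * p_m)

    # M-M
    m1, m2 = pair.code_a, pair.code_b
    p_m1 = pooled(lambda s: _med_marginal(truth, s, m1))
    p_m2 = pooled(lambda s: _med_marginal(truth, s, m2))
    for parent, companion in ((m1, m2), (m2, m1)):
        if companion in truth.co_medication.get(parent, {}):
            # companion rule joint, plus the independent-arrival cross term
            # when the companion also has an indication of its own
            c = truth.co_medication[parent][companion]
            d_p = truth.indication_of(parent)
            q_p = truth.indications[d_p][parent]
            joint = pooled(lambda s: _present(truth, s, [d_p]) * q_p) * c
            d_c = truth.indication_of(companion)
            if d_c is not None:
                q_c = truth.indications[d_c][companion]
                joint += (1 - c) * pooled(
                    lambda s: _present(truth, s, [d_p, d_c]) * q_p * q_c
                )
            return joint / (p_m1 * p_m2)
    if m1 in truth.background_meds or m2 in truth.background_meds:
        return 1.0
    d1 = truth.indication_of(m1)
    d2 = truth.indication_of(m2)
    if d1 is None or d2 is None:
        raise ValueError(f"unsupported M-M structure for pair {pair}")
    q1 = truth.indications[d1][m1]
    q2 = truth.indications[d2][m2]
    if d1 == d2:
        joint = pooled(lambda s: _present(truth, s, [d1]) * q1 * q2)
    else:
        joint = pooled(lambda s: _present(truth, s, [d1, d2]) * q1 * q2)
    return joint / (p_m1 * p_m2)


def planted_indication_pairs(truth: GeneratorTruth) -> list[PairKey]:
    """All planted D-M indication pairs of the truth."""
    return [
        PairKey.dm(d, m) for d, meds in truth.indications.items() for m in meds
    ]


# ---------------------------------------------------------------------------
# Reviewer simulation
# ---------------------------------------------------------------------------


def simulate_reviews(
    test_ids: Sequence[str],
    labels: Mapping[str, RxLabel],
    seed: int,
    rater_ids: Sequence[str] = ("rater_a", "rater_b"),
    flip_rate: float = 0.02,
    low_confidence_rate: float = 0.0033,
) -> list[ReviewRecord]:
    """Ground truth plays the reviewers, with label noise and confidence.

    Each rater reports the true label flipped with probability ``flip_rate``
    (the default reproduces the high interrater agreement, kappa around
    0.92, seen in physician chart review of balanced test sets); severity
    follows the truth (or, for a flip onto unsubstantiated, the default
    severity mix); confidence is 5 or 6 except with probability
    ``low_confidence_rate``, where it drops below 4 (triggering exclusion —
    a few prescriptions per 600-case review round).
    """
    rng = np.random.default_rng(seed)
    sev_names = [s for s in SEVERITIES if DEFAULT_SEVERITY_MIX.get(s, 0) > 0]
    sev_probs = np.array([DEFAULT_SEVERITY_MIX[s] for s in sev_names])
    sev_probs = sev_probs / sev_probs.sum()
    out: list[ReviewRecord] = []
    for rx_id in test_ids:
        truth = labels[rx_id]
        for rater in rater_ids:
            flip = rng.random() < flip_rate
            substantiated = truth.substantiated != flip
            severity = None
            if not substantiated:
                if truth.severity is not None:
                    severity = truth.severity
                else:
                    severity = sev_names[int(rng.choice(len(sev_names), p=sev_probs))]
            if rng.random() < low_confidence_rate:
                confidence = int(rng.integers(1, 4))
            else:
                confidence = int(rng.integers(5, 7))
            out.append(
                ReviewRecord(
                    rx_id=rx_id,
                    rater_id=rater,
                    label=SUBSTANTIATED if substantiated else UNSUBSTANTIATED,
                    severity=severity,
                    confidence=confidence,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureBundle:
    """Two reviewer-adjudicated example prescriptions and a hand-set model.

    ``substantiated_rx`` (a 74-year-old woman with aortic stenosis,
    hypertension, Raynaud's disease and hyperlipidemia on aspirin,
    atorvastatin, furosemide and losartan) is fully explained by the model;
    ``unsubstantiated_rx`` (a 76-year-old man seen for gait abnormality and
    epilepsy on seven medications) has only levetiracetam explained by his
    epilepsy — the remaining six medications are flagged.
    """

    substantiated_rx: Prescription
    unsubstantiated_rx: Prescription
    model: AssociationTable
    expected_flagged: frozenset[str]


def paper_fixtures() -> FixtureBundle:
    table1 = Prescription(
        rx_id="fixture-substantiated",
        patient_id="fixture-p1",
        age=74,
        sex=FEMALE,
        diagnoses=frozenset({"I35.0", "I10", "I73.0", "E78.5"}),
        medications=frozenset({"B01AC06", "C10AA05", "C03CA01", "C09CA01"}),
    )
    table2 = Prescription(
        rx_id="fixture-unsubstantiated",
        patient_id="fixture-p2",
        age=76,
        sex=MALE,
        diagnoses=frozenset({"R26.9", "G40.309"}),
        medications=frozenset(
            {"C10AA01", "L01BA01", "N03AX14", "A02BC01", "B01AA03", "P01BA02", "B03BB01"}
        ),
    )
    from .corpus import POOLED

    hand_set = [
        ("I35.0", "B01AC06", 6.0),
        ("E78.5", "C10AA05", 9.0),
        ("I10", "C03CA01", 4.0),
        ("I10", "C09CA01", 7.5),
        ("G40.309", "N03AX14", 8.0),
    ]
    records = {}
    n_total, n_a, n_b = 1000, 100, 80
    for d, m, q in hand_set:
        n_joint = round(q * n_a * n_b / n_total)
        rec = AssociationRecord(PairKey.dm(d, m), POOLED, n_joint, n_a, n_b, n_total, q)
        records[(POOLED, rec.pair)] = rec
    model = AssociationTable(
        records,
        meta={
            "label": "fixture",
            "n_prescriptions": n_total,
            "stratified": False,
            "min_support": 1,
            "pruned_top1": False,
        },
    )
    return FixtureBundle(
        substantiated_rx=table1,
        unsubstantiated_rx=table2,
        model=model,
        expected_flagged=frozenset(
            {"C10AA01", "L01BA01", "A02BC01", "B01AA03", "P01BA02", "B03BB01"}
        ),
    )
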