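import numpy as np
import pytest
from hypothesis import settings

from aoprx.corpus import FEMALE, MALE, Prescription
from aoprx.model import AOPModel
from aoprx.simulate import default_truth, generate_corpus, paper_fixtures

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def make_rx(rx_id, dx, meds, age=60, sex=FEMALE, patient_id=None):
    return Prescription(
        rx_id=rx_id,
        patient_id=patient_id or f"p-{rx_id}",
        age=age,
        sex=sex,
        diagnoses=frozenset(dx),
        medications=frozenset(meds),
    )


def random_corpus(rng, n, n_dx_codes=6, n_med_codes=8):
    """Small random corpora for brute-force oracle comparisons."""
    dx_codes = [f"D{i}" for i in range(n_dx_codes)]
    med_codes = [f"M{i}" for i in range(n_med_codes)]
    corpus = []
    for i in range(n):
        k_d = int(rng.integers(1, 4))
        k_m = int(rng.integers(1, 5))
        corpus.append(
            make_rx(
                f"r{i}",
                rng.choice(dx_codes, size=k_d, replace=False),
                rng.choice(med_codes, size=k_m, replace=False),
                age=int(rng.integers(0, 100)),
                sex=MALE if rng.random() < 0.5 else FEMALE,
            )
        )
    return corpus


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def small_world(truth):
    """A moderate mined world shared across classifier/evaluation tests:
    30k training prescriptions (pooled model) plus a 2k labeled test set."""
    train = generate_corpus(truth, 30_000, seed=101, id_prefix="tr")
    test = generate_corpus(truth, 2_000, seed=102, id_prefix="te")
    results = AOPModel(train.prescriptions, stratified=False, label="L").fit()
    return train, test, results
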