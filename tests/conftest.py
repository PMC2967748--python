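import random

import pytest
from hypothesis import settings

from ademiner.reports import Report

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


TC4 = [
    ("R1", ["D1", "D2"], ["E1"]),
    ("R2", ["D1", "D2"], ["E1"]),
    ("R3", ["D1"], ["E2"]),
    ("R4", ["D2"], ["E1"]),
]


def build_tc4() -> list[Report]:
    return [Report.build(rid, drugs, events) for rid, drugs, events in TC4]


@pytest.fixture
def tc4() -> list[Report]:
    """Four-report toy corpus: R1={D1,D2|E1}, R2={D1,D2|E1}, R3={D1|E2}, R4={D2|E1}."""
    return build_tc4()


def random_corpus(seed: int, max_drugs: int = 10, max_events: int = 8,
                  max_reports: int = 300) -> list[Report]:
    """Small random corpus for oracle cross-checks (bounded item universe)."""
    rng = random.Random(seed)
    n_drugs = rng.randint(3, max_drugs)
    n_events = rng.randint(2, max_events)
    n_reports = rng.randint(20, max_reports)
    drugs = [f"D{i}" for i in range(n_drugs)]
    events = [f"E{i}" for i in range(n_events)]
    corpus = []
    for i in range(n_reports):
        d = rng.sample(drugs, rng.randint(1, min(4, n_drugs)))
        e = rng.sample(events, rng.randint(1, min(3, n_events)))
        corpus.append(Report.build(f"R{i}", d, e))
    return corpus


@pytest.fixture
def make_random_corpus():
    return random_corpus
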