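import numpy as np
import pandas as pd
import pytest

import asrtlearn as al


@pytest.fixture
def cycle():
    return al.make_cycle("2r4r3r1r")


@pytest.fixture
def all_cycles():
    return al.canonical_cycles()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A small fixed-sequence cohort reused by scoring-level tests."""
    config = al.SimConfig(n_accuracy=6, n_speed=6, n_blocks=25, seed=11,
                          sequence="2r4r3r1r")
    return al.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_sets(small_cohort):
    return al.filter_trials(small_cohort)


def make_records(rt_by_label, participant="p1", block=1, correct=True):
    """Hand-built annotated trial records: one block, trials 8..,
    alternating labels per the given {label: [rt, ...]} mapping."""
    rows = []
    trial = 8
    for label, rts in rt_by_label.items():
        for rt in rts:
            rows.append({
                "participant": participant, "block": block, "trial": trial,
                "position": 1, "origin": "random", "triplet_label": label,
                "triplet_category": "neither", "response": 1,
                "correct": correct, "rt_ms": rt,
            })
            trial += 1
    return pd.DataFrame(rows)
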