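import numpy as np
import pandas as pd
import pytest

from catperc.design import (
    make_discrimination_schedule,
    make_identification_schedule,
    make_tone_continuum,
    make_vot_continuum,
)
from catperc.simulate import ListenerProfile


@pytest.fixture(scope="session")
def tone():
    return make_tone_continuum()


@pytest.fixture(scope="session")
def vot():
    return make_vot_continuum()


@pytest.fixture(scope="session")
def tone_id_schedule(tone):
    return make_identification_schedule(tone, reps=8, seed=101)


@pytest.fixture(scope="session")
def tone_disc_schedule(tone):
    return make_discrimination_schedule(tone, step=2, reps=5, seed=102)


@pytest.fixture
def adult_profile():
    return ListenerProfile("adult-001", "adult", mu=3.8, width=1.0, seed=7)


def identification_frame(props_cat2, reps=8, listener="p1", experiment="tone"):
    """Build an identification response table realising exact per-stimulus
    category-2 proportions."""
    rows = []
    for i, p in enumerate(props_cat2, start=1):
        k = int(round(p * reps))
        for j in range(reps):
            rows.append(
                {
                    "listener_id": listener,
                    "group": "g",
                    "experiment": experiment,
                    "task": "identification",
                    "block": "formal",
                    "trial_index": len(rows) + 1,
                    "stimulus_a": i,
                    "stimulus_b": pd.NA,
                    "response": "cat2" if j < k else "cat1",
                }
            )
    return pd.DataFrame(rows)


def discrimination_frame(trial_specs, listener="p1", experiment="tone"):
    """Build a discrimination response table from (a, b, response) triples."""
    rows = []
    for idx, (a, b, resp) in enumerate(trial_specs, start=1):
        rows.append(
            {
                "listener_id": listener,
                "group": "g",
                "experiment": experiment,
                "task": "discrimination",
                "block": "formal",
                "trial_index": idx,
                "stimulus_a": a,
                "stimulus_b": b,
                "response": resp,
            }
        )
    return pd.DataFrame(rows)
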