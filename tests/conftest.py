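import numpy as np
import pandas as pd
import pytest

from respimeta import fdt_engine as fe
from respimeta import interoception_measures as im
from respimeta import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_row():
    """A typical cohort row for building observers."""
    return pd.Series(
        dict(is_filters=4, decision_c=0.1, mratio_true=0.84, metacog_bias=6.22)
    )


@pytest.fixture
def default_observer(default_row):
    return sd.make_observer(default_row)


def simulate_fixed_level_trials(observer, level, n_trials, rng):
    """Alternating resistance/sham trials at one staircase level."""
    trials = []
    for i in range(n_trials):
        cond = "resistance" if i % 2 == 0 else "sham"
        resp, conf = sd.observer_respond(observer, level, cond, rng)
        trials.append(
            fe.TrialRecord(
                index=i + 1,
                condition=cond,
                filter_count=level if cond == "resistance" else 0,
                response=resp,
                correct=(cond == "resistance") == (resp == "yes"),
                confidence=conf,
                level_at_trial=level,
            )
        )
    return trials


@pytest.fixture
def analyzed_trials(default_observer, rng):
    return simulate_fixed_level_trials(default_observer, 4, 60, rng)
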