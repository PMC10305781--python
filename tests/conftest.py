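import numpy as np
import pandas as pd
import pytest

from bowmimic.bayes import SamplerSettings
from bowmimic.synthetic import ScoreSpec, StrokeEvent, generate_avatar


@pytest.fixture(scope="session")
def simple_score():
    """Ten alternating 300 mm strokes of 0.5 s each."""
    return ScoreSpec(
        [
            StrokeEvent("down" if i % 2 == 0 else "up", 300.0, 0.5, dynamic=0.8)
            for i in range(10)
        ]
    )


@pytest.fixture(scope="session")
def avatar(simple_score):
    return generate_avatar(simple_score, seed=1)


@pytest.fixture(scope="session")
def avatar_trace(avatar):
    return avatar[0]


@pytest.fixture(scope="session")
def avatar_audio(avatar):
    return avatar[1]


@pytest.fixture
def fast_sampler():
    return SamplerSettings(chains=4, warmup=400, draws=400, seed=0)


def simulate_cells(
    effect=0.0,
    seed=0,
    n_participants=11,
    n_trials=4,
    sd_participant=0.3,
    sd_trial=0.15,
    sd_resid=0.5,
    cov_slope=0.0,
):
    """Simulate a per-cell dataset from the varying-intercept model itself.

    ``effect`` is the condition-1-minus-condition-2 difference in response
    units; a standardised covariate column ``difficulty`` is always present
    (with slope ``cov_slope``).
    """
    rng = np.random.default_rng(seed)
    conditions = ["2D", "3D"]
    u = {(c, p): rng.normal(0, sd_participant) for c in conditions for p in range(1, n_participants + 1)}
    w = {(c, t): rng.normal(0, sd_trial) for c in conditions for t in range(1, n_trials + 1)}
    rows = []
    for p in range(1, n_participants + 1):
        for c in conditions:
            for t in range(1, n_trials + 1):
                x = rng.standard_normal()
                mu = (effect / 2 if c == "2D" else -effect / 2) + u[(c, p)] + w[(c, t)]
                rows.append(
                    dict(
                        participant=p,
                        condition=c,
                        trial=t,
                        difficulty=x,
                        value=mu + cov_slope * x + rng.normal(0, sd_resid),
                    )
                )
    return pd.DataFrame(rows)


def pooled_sd(sd_participant=0.3, sd_trial=0.15, sd_resid=0.5):
    return float(np.sqrt(sd_participant**2 + sd_trial**2 + sd_resid**2))
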