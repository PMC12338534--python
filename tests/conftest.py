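import numpy as np
import pandas as pd
import pytest

from cograte.metmodel import MetabolicModel, Reaction


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_A -> A -> B -> biomass, all capacities 10."""
    return MetabolicModel(
        "chain",
        ["A", "B"],
        [
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0, True),
            Reaction("r1", {"A": -1.0, "B": 1.0}, 0.0, 10.0, False),
            Reaction("bio", {"B": -1.0}, 0.0, 10.0, False),
        ],
        "bio",
    )


@pytest.fixture
def crossfeed_pair() -> tuple[MetabolicModel, MetabolicModel]:
    """Producer A (glc -> biomass + acetate) and consumer B (acetate -> biomass)."""
    producer = MetabolicModel(
        "A",
        ["glc", "ac", "X"],
        [
            Reaction("EX_glc", {"glc": 1.0}, 0.0, 10.0, True),
            Reaction("ferment", {"glc": -1.0, "X": 1.0, "ac": 1.0}, 0.0, 10.0, False),
            Reaction("EX_ac", {"ac": -1.0}, 0.0, 1000.0, True),
            Reaction("bio", {"X": -1.0}, 0.0, 1000.0, False),
        ],
        "bio",
    )
    consumer = MetabolicModel(
        "B",
        ["ac", "X"],
        [
            Reaction("EX_ac", {"ac": 1.0}, 0.0, 10.0, True),
            Reaction("assim", {"ac": -1.0, "X": 1.0}, 0.0, 10.0, False),
            Reaction("bio", {"X": -1.0}, 0.0, 1000.0, False),
        ],
        "bio",
    )
    return producer, consumer


@pytest.fixture
def training_trials() -> pd.DataFrame:
    """Noise-free training trials for one mouse: y = -(1 + 0.5*day), uncensored."""
    days = np.repeat(np.arange(1, 7), 3).astype(float)
    y = -(1.0 + 0.5 * days)
    return pd.DataFrame(
        {
            "mouse_id": "m1",
            "phase": "training",
            "day": days,
            "trial_index": np.tile([1, 2, 3], 6),
            "latency": np.exp(-y),
            "censored": False,
            "cognitive_score": 0.5,
        }
    )
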