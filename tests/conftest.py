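"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ieegstim.pipeline import process_session
from ieegstim.synth import GeneratorConfig, generate_session


def events_frame(onsets, duration=0.5, amplitude=1.0, frequency=50.0,
                 anode="CH01", cathode="CH02"):
    return pd.DataFrame(
        {
            "onset": list(onsets),
            "duration": duration,
            "amplitude": amplitude,
            "frequency": frequency,
            "anode": anode,
            "cathode": cathode,
        }
    )


@pytest.fixture(scope="session")
def null_session():
    """Small session without injected effects or artifacts."""
    return generate_session(GeneratorConfig(n_channels=8, rng_seed=42))


@pytest.fixture(scope="session")
def effect_session():
    """Session with a x3 theta band-power effect injected at CH05."""
    return generate_session(
        GeneratorConfig(n_channels=8, effect_map={("CH05", "theta"): 3.0}, rng_seed=7)
    )


@pytest.fixture(scope="session")
def artifact_session():
    """Session with a stimulation-artifact channel (CH08)."""
    return generate_session(
        GeneratorConfig(n_channels=8, artifact_channels=("CH08",), rng_seed=11)
    )


@pytest.fixture(scope="session")
def processed_null(null_session):
    return process_session(null_session)


@pytest.fixture(scope="session")
def processed_effect(effect_session):
    return process_session(effect_session)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
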