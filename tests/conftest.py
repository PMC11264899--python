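"""Shared fixtures: compact simulated sessions for fast, deterministic tests.

The compact montage keeps only the three occipital channels the features
read, so simulations stay cheap while exercising the identical code paths
as the 19-channel default montage.
"""

import numpy as np
import pytest
from hypothesis import settings

import ssvepbci as sb

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

COMPACT_GAINS = {"O1": 1.0, "O2": 1.0, "OZ": 1.0}


def compact_config(**overrides) -> sb.SimConfig:
    """High-contrast 3-channel simulation config (attended 1.0 vs 0.3, snr 1)."""
    kwargs = dict(channel_gains=dict(COMPACT_GAINS))
    kwargs.update(overrides)
    return sb.SimConfig(**kwargs)


def simulate_baseline(seed: int, **overrides) -> list[sb.TrialEpoch]:
    """60 labeled baseline epochs (30 attend-Gabor + 30 attend-Face)."""
    cfg = compact_config(**overrides)
    sched = sb.build_schedule(seed, include_feedback=False)
    rec, labels = sb.simulate_session(cfg, sched, seed)
    return sb.epoch(rec, labels=labels)


@pytest.fixture(scope="session")
def baseline_epochs() -> list[sb.TrialEpoch]:
    return simulate_baseline(seed=11)


@pytest.fixture(scope="session")
def fitted_decoder(baseline_epochs) -> sb.DecoderResults:
    return sb.AttentionDecoder(baseline_epochs, config=sb.FeatureConfig()).fit(seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
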