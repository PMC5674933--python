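"""Shared fixtures: one small simulated participant reused across tests.

Session-scoped so the simulation and assembly run once. All randomness is
seeded; nothing here depends on test execution order.
"""

import numpy as np
import pytest

import throwcast as tc
from throwcast.dataset import assemble_participant
from throwcast.features import N_RESAMPLE, AlignedTrial


@pytest.fixture(scope="session")
def sim_cfg():
    """Thirty trials with a single informative marker (l_ankle, ramp from
    decile 6, 0.10 m amplitude)."""
    return tc.ThrowSimConfig(
        n_trials=30,
        seed=7,
        informative_markers=(tc.InformativeMarker("l_ankle", 6, 0.10),),
    )


@pytest.fixture(scope="session")
def sim_pairs(sim_cfg):
    return tc.simulate_participant(sim_cfg)


@pytest.fixture(scope="session")
def sim_records(sim_pairs):
    return [rec for rec, _ in sim_pairs]


@pytest.fixture(scope="session")
def sim_truths(sim_pairs):
    return {truth.trial_id: truth for _, truth in sim_pairs}


@pytest.fixture(scope="session")
def participant(sim_records):
    return assemble_participant(sim_records)


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, gap-free variant for exact ground-truth comparisons."""
    return tc.ThrowSimConfig(
        n_trials=8,
        seed=21,
        noise_sigma=0.0,
        jitter_sigma=0.0,
        ball_noise_sigma=0.0,
        gap_rate=0.0,
        informative_markers=(),
    )


@pytest.fixture(scope="session")
def clean_pairs(clean_cfg):
    return tc.simulate_participant(clean_cfg)


@pytest.fixture
def aligned_factory():
    """Build random release-aligned trials directly (no simulation)."""

    def make(n_trials: int, n: int = N_RESAMPLE, seed: int = 0,
             window_s: float = 1.2):
        rng = np.random.default_rng(seed)
        out = []
        for k in range(n_trials):
            data = rng.standard_normal((len(tc.CANONICAL_MARKERS), 6, n))
            out.append(AlignedTrial(f"trial_{k:03d}", data, window_s, 2.0))
        return out

    return make
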