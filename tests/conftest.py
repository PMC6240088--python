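"""Shared fixtures: small protocols, a trained encoder, one closed-loop run.

Everything is generated programmatically; session scope keeps the expensive
objects (trained agents, the closed-loop study) to one computation per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from meabayes import agent, generative, study


@pytest.fixture(scope="session")
def small_experiment():
    """Four sessions of 256 one-second epochs (1024 epochs)."""
    sources = generative.sample_sources(4, 256, seed=0)
    stimuli = generative.sample_stimuli(sources, seed=0)
    return sources, stimuli


@pytest.fixture(scope="session")
def trained_512(small_experiment):
    """Blind encoder trained for the paper-scale 512 epochs, seed 0."""
    _, stimuli = small_experiment
    return agent.run_training(stimuli, 512, agent.AgentConfig(seed=0))


@pytest.fixture(scope="session")
def loop8():
    """One closed-loop synthetic study: 8 sessions x 256 epochs, seed 0."""
    return study.closed_loop(seed=0, n_sessions=8, epochs_per_session=256)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
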