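"""Shared fixtures: small task configs and meta-trained agents.

The trained-agent fixture is expensive (three networks, 300 sessions each)
and is therefore session-scoped; it backs both the meta-learning and the
inactivation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from metabandit import agent, task_env

TRAIN_SEEDS = (1, 2, 3)
N_TRAIN_SESSIONS = 300


@pytest.fixture(scope="session")
def task_cfg() -> task_env.TaskConfig:
    return task_env.TaskConfig()


@pytest.fixture(scope="session")
def train_cfg() -> agent.TrainConfig:
    return agent.TrainConfig(n_sessions=N_TRAIN_SESSIONS)


@pytest.fixture(scope="session")
def trained_agents(task_cfg, train_cfg):
    """Three independently meta-trained networks (300 sessions each)."""
    return {
        seed: agent.train(task_cfg, train_cfg, seed=seed)
        for seed in TRAIN_SEEDS
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
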