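"""Shared fixtures: synthetic networks, sessions and windowed FC stacks.

Heavy fixtures are session-scoped so the sliding-window estimation for the
3-task sessions is computed once and shared between the dynamics,
task-state and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import fcdyn
from fcdyn.dynamics import sliding_fc

N_SESSION_SEEDS = 5
SESSION_NODES = 10
SESSION_DENSITY = 0.2
BLOCK_S = 60.0
TASKS = ("t1", "t2", "t3")


def make_three_task_session(seed: int) -> fcdyn.TaskSession:
    """A 3 x 60 s session with distinct truth networks per task."""
    nets = {t: fcdyn.make_network(SESSION_NODES, SESSION_DENSITY,
                                  seed=seed * 10 + i)
            for i, t in enumerate(TASKS)}
    return fcdyn.simulate_session(nets, [(t, BLOCK_S) for t in TASKS],
                                  seed=seed)


@pytest.fixture(scope="session")
def three_task_wfcs() -> list[fcdyn.WindowedFC]:
    """Windowed fused FC (5 s / 50% overlap) for 5 independent sessions."""
    out = []
    for seed in range(N_SESSION_SEEDS):
        s = make_three_task_session(seed)
        out.append(sliding_fc(s.recording, s.annotations,
                              order="auto", max_order=5))
    return out


@pytest.fixture(scope="session")
def small_session() -> fcdyn.TaskSession:
    """One quick 2-task session for smoke-level pipeline tests."""
    nets = {t: fcdyn.make_network(5, 0.3, seed=i) for i, t in enumerate(["a", "b"])}
    return fcdyn.simulate_session(nets, [("a", 20.0), ("b", 20.0)], seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
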