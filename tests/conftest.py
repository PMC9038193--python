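import numpy as np
import pandas as pd
import pytest

from cachechoice import ParameterVector, default_arena, simulate_bird
from cachechoice.events import BirdDataset
from cachechoice.simulate import AgentPolicy, dirichlet_bias

#: per-bird best-fit medians reported for the free Caching task, used as
#: generative truth throughout the simulation-based tests
CACHING_TRUTH = dict(
    gamma_prv=0.94, sigma_prv=15.5, gamma_occ=-0.32, gamma_emp=0.13
)


@pytest.fixture(scope="session")
def arena():
    return default_arena()


@pytest.fixture(scope="session")
def caching_truth():
    return ParameterVector(**CACHING_TRUTH)


def make_dataset(rows, bird="t"):
    """Build a BirdDataset from (session, trial, phase, time, site, delta)."""
    frame = pd.DataFrame(
        rows, columns=["session", "trial", "phase", "time", "site", "delta"]
    )
    return BirdDataset(bird, frame)


@pytest.fixture()
def toy_dataset():
    """One short Caching-task session: feeder visit, caches, checks, retrieval."""
    return make_dataset(
        [
            (0, 0, 0, 1.0, 64, -1),   # seed from feeder
            (0, 0, 0, 5.0, 3, 1),     # cache at 3
            (0, 0, 0, 9.0, 5, 0),     # check empty 5
            (0, 0, 0, 12.0, 64, -1),  # another seed
            (0, 0, 0, 15.0, 10, 1),   # cache at 10
            (0, 0, 0, 20.0, 3, -1),   # retrieve from 3
        ]
    )


@pytest.fixture(scope="session")
def caching_bird(arena, caching_truth):
    """One simulated Caching-task bird at the reference effect sizes."""
    rng = np.random.default_rng(1234)
    policy = AgentPolicy(
        theta=caching_truth, pbias=dirichlet_bias(arena, 2.0, rng)
    )
    return simulate_bird(
        policy, arena, n_sessions=10, task="caching", seed=77, bird="cb"
    )


@pytest.fixture(scope="session")
def retrieval_bird(arena):
    """One simulated Retrieval-task bird with proximity and cache attraction."""
    theta = ParameterVector(
        gamma_prv=1.0, sigma_prv=13.0, gamma_occc=0.42, gamma_occr=0.26
    )
    from cachechoice import simulate_retrieval_task

    policy = AgentPolicy(theta=theta)
    return simulate_retrieval_task(
        policy, default_arena(), n_trials=25, seed=21, bird="rb"
    )
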