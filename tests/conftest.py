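import numpy as np
import pytest

from flotcea.cohort_engine import TransitionSchedule
from flotcea.econ_model import load_parameters
from flotcea.pipeline import CEModel


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def ce_model():
    """Fitted engine on the default synthetic trial (shared; do not mutate)."""
    return CEModel.from_synthetic(seed=0)


def microsimulate(
    schedule: TransitionSchedule, n_walkers: int, n_cycles: int, rng
) -> np.ndarray:
    """Individual-walker Monte-Carlo oracle for the cohort engine.

    Tracks each walker's state and state-entry cycle so that PD1/PD2
    transitions use the same residence clock as the cohort trace. Returns
    start-of-cycle occupancy proportions, shape (n_cycles + 1, 4).
    """
    state = np.zeros(n_walkers, dtype=np.int8)  # 0 EFS, 1 PD1, 2 PD2, 3 Death
    entry = np.zeros(n_walkers, dtype=np.int64)
    occ = np.zeros((n_cycles + 1, 4))
    for u in range(n_cycles):
        occ[u] = np.bincount(state, minlength=4) / n_walkers
        r = rng.random(n_walkers)
        res = np.clip(u - entry, 0, n_cycles - 1)

        efs = state == 0
        q = schedule.efs_exit[u]
        w = schedule.efs_death_share[u]
        efs_die = efs & (r < q * w)
        efs_prog = efs & ~efs_die & (r < q)

        pd1 = state == 1
        d1 = schedule.pd1_death[res]
        p12 = schedule.pd1_prog[res]
        pd1_die = pd1 & (r < d1)
        pd1_prog = pd1 & ~pd1_die & (r < d1 + p12)

        pd2 = state == 2
        pd2_die = pd2 & (r < schedule.pd2_death[res])

        state[efs_die | pd1_die | pd2_die] = 3
        state[efs_prog] = 1
        entry[efs_prog] = u + 1
        state[pd1_prog] = 2
        entry[pd1_prog] = u + 1
    occ[n_cycles] = np.bincount(state, minlength=4) / n_walkers
    return occ
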