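"""Four-state semi-Markov cohort engine.

States: EFS (event-free, on/after first-line treatment), PD1 (first
progression, second-line treatment), PD2 (subsequent progression, best
supportive care) and Death. The model runs on 4-week cycles over a
10-year horizon (130 cycles of 28 days).

EFS exits are driven by model time (time since randomization); PD1 and
PD2 exits are driven by residence time (clock reset on state entry),
which is what makes the model semi-Markov: occupancy of PD1/PD2 is
book-kept per entry cohort ("tunnel" accounting).

The split of EFS exits between progression and pre-progression death is
not identifiable from marginal EFS/OS curves alone. Default: the death
share of each cycle's EFS exit is min(1, h_OS(t)/h_EFS(t)) from the
first-line OS and EFS fits, the remainder goes to PD1; a constant split
is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .survival_fit import FittedSurvivalModel, transition_probability

__all__ = [
    "STATES",
    "CYCLE_LENGTH_MONTHS",
    "N_CYCLES_10Y",
    "TransitionSchedule",
    "CohortTrace",
    "DiscountSpec",
    "build_transition_schedule",
    "run_cohort",
    "half_cycle_correct",
    "discount_weights",
]

STATES = ("EFS", "PD1", "PD2", "Death")

#: 28-day cycle expressed in average months (30.4375 days/month)
CYCLE_LENGTH_MONTHS = 28.0 / 30.4375
#: 10 years x 365.25 / 28 days = 130.4 -> 130 whole cycles
N_CYCLES_10Y = 130

_ROW_TOL = 1e-10


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities for the 4-state model.

    ``efs_exit[u]`` is the total probability of leaving EFS during model
    cycle u, of which fraction ``efs_death_share[u]`` goes to Death and
    the rest to PD1. ``pd1_death[r]``/``pd1_prog[r]`` and ``pd2_death[r]``
    are indexed by residence cycle r (cycles since state entry).
    """

    efs_exit: np.ndarray
    efs_death_share: np.ndarray
    pd1_death: np.ndarray
    pd1_prog: np.ndarray
    pd2_death: np.ndarray
    cycle_len: float = CYCLE_LENGTH_MONTHS

    def __post_init__(self) -> None:
        for name in ("efs_exit", "efs_death_share", "pd1_death", "pd1_prog", "pd2_death"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any((arr < -_ROW_TOL) | (arr > 1 + _ROW_TOL)):
                bad = int(np.argmax((arr < 0) | (arr > 1)))
                raise ValueError(f"{name}[{bad}] outside [0, 1]: {arr[bad]}")
        if np.any(self.pd1_death + self.pd1_prog > 1 + _ROW_TOL):
            bad = int(np.argmax(self.pd1_death + self.pd1_prog > 1))
            raise ValueError(f"PD1 exit probabilities exceed 1 at residence {bad}")

    @property
    def n_cycles(self) -> int:
        return len(self.efs_exit)

    def matrix(self, cycle: int, residence_pd1: int, residence_pd2: int) -> np.ndarray:
        """Dense 4x4 row-stochastic matrix for one (cycle, residence) pair."""
        q = self.efs_exit[cycle]
        w = self.efs_death_share[cycle]
        d1, p12 = self.pd1_death[residence_pd1], self.pd1_prog[residence_pd1]
        d2 = self.pd2_death[residence_pd2]
        m = np.array([
            [1 - q, q * (1 - w), 0.0, q * w],
            [0.0, 1 - d1 - p12, p12, d1],
            [0.0, 0.0, 1 - d2, d2],
            [0.0, 0.0, 0.0, 1.0],
        ])
        assert np.allclose(m.sum(axis=1), 1.0, atol=_ROW_TOL)
        return m


@dataclass
class CohortTrace:
    """Start-of-cycle occupancy (n_cycles + 1 rows) over the 4 states.

    ``pd1_ledger``/``pd2_ledger`` give, for each recorded cycle, the
    occupancy of the tunnel state broken down by entry cycle.
    """

    occupancy: np.ndarray
    cycle_len: float = CYCLE_LENGTH_MONTHS
    pd1_ledger: np.ndarray | None = field(default=None, repr=False)
    pd2_ledger: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(STATES):
            raise ValueError("occupancy must be (cycles+1) x 4")
        if np.any(occ < -1e-12):
            raise ValueError("negative occupancy")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("occupancy rows must sum to 1")
        if np.any(np.diff(occ[:, 3]) < -1e-12):
            raise ValueError("Death occupancy must be nondecreasing")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def times_months(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0]) * self.cycle_len

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.occupancy, columns=list(STATES)).assign(
            cycle=np.arange(self.occupancy.shape[0]),
            time_months=self.times_months,
        )


@dataclass
class DiscountSpec:
    """Annual discount rate applied on cycle midpoints."""

    annual_rate: float = 0.03
    cycle_len: float = CYCLE_LENGTH_MONTHS

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("discount rate must be nonnegative")
        if self.cycle_len <= 0:
            raise ValueError("cycle length must be positive")


def _per_cycle_probs(fit: FittedSurvivalModel, n_cycles: int, cycle_len: float) -> np.ndarray:
    return np.array(
        [transition_probability(fit, u, cycle_len) for u in range(n_cycles)]
    )


def build_transition_schedule(
    efs_fit: FittedSurvivalModel,
    os_fit: FittedSurvivalModel,
    pd1_os_fit: FittedSurvivalModel,
    pd1_pfs_fit: FittedSurvivalModel,
    n_cycles: int = N_CYCLES_10Y,
    cycle_len: float = CYCLE_LENGTH_MONTHS,
    efs_split: str = "hazard_ratio",
    constant_death_share: float = 0.0,
) -> TransitionSchedule:
    """Derive per-cycle transition probabilities from fitted curves.

    EFS exit comes from the first-line EFS fit at model time. Its death
    share is h_OS/h_EFS at the cycle midpoint (``efs_split="hazard_ratio"``)
    or a constant (``efs_split="constant"``). PD1 exits combine the
    second-line OS fit (death) and PFS fit (progression; PFS events net of
    deaths) on the residence clock; PD2 deaths reuse the second-line OS
    hazard on a fresh residence clock.
    """
    efs_exit = _per_cycle_probs(efs_fit, n_cycles, cycle_len)

    if efs_split == "hazard_ratio":
        mid = (np.arange(n_cycles) + 0.5) * cycle_len
        h_os = np.asarray(os_fit.hazard(mid), dtype=float)
        h_efs = np.clip(np.asarray(efs_fit.hazard(mid), dtype=float), 1e-300, None)
        share = np.clip(h_os / h_efs, 0.0, 1.0)
    elif efs_split == "constant":
        if not 0.0 <= constant_death_share <= 1.0:
            raise ValueError("constant_death_share must be in [0, 1]")
        share = np.full(n_cycles, constant_death_share)
    else:
        raise KeyError(f"unknown efs_split {efs_split!r}")

    q_os = _per_cycle_probs(pd1_os_fit, n_cycles, cycle_len)
    q_pfs = _per_cycle_probs(pd1_pfs_fit, n_cycles, cycle_len)
    pd1_death = q_os
    pd1_prog = np.clip(q_pfs - q_os, 0.0, 1.0 - pd1_death)
    pd2_death = q_os.copy()

    return TransitionSchedule(efs_exit, share, pd1_death, pd1_prog, pd2_death, cycle_len)


def run_cohort(
    schedule: TransitionSchedule,
    n_cycles: int | None = None,
    init: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate the cohort with per-entry-cohort (tunnel) bookkeeping.

    ``init`` is the starting occupancy over (EFS, PD1, PD2, Death);
    default puts the whole cohort in EFS. Entries into PD1/PD2 during
    cycle u are placed at entry cycle u+1 with residence 0 there.
    """
    if n_cycles is None:
        n_cycles = schedule.n_cycles
    if n_cycles > schedule.n_cycles:
        raise ValueError("schedule shorter than requested number of cycles")
    if init is None:
        init = np.array([1.0, 0.0, 0.0, 0.0])
    init = np.asarray(init, dtype=float)
    if not np.isclose(init.sum(), 1.0):
        raise ValueError("initial occupancy must sum to 1")

    efs = float(init[0])
    dead = float(init[3])
    pd1 = np.zeros(n_cycles + 1)  # mass by entry cycle
    pd2 = np.zeros(n_cycles + 1)
    pd1[0] = float(init[1])
    pd2[0] = float(init[2])

    occ = np.zeros((n_cycles + 1, 4))
    led1 = np.zeros((n_cycles + 1, n_cycles + 1))
    led2 = np.zeros((n_cycles + 1, n_cycles + 1))

    for u in range(n_cycles):
        occ[u] = (efs, pd1.sum(), pd2.sum(), dead)
        led1[u], led2[u] = pd1, pd2

        exit_efs = efs * schedule.efs_exit[u]
        to_death = exit_efs * schedule.efs_death_share[u]
        to_pd1 = exit_efs - to_death
        efs -= exit_efs

        res = u - np.arange(u + 1)  # residence of entry cohorts 0..u
        m1 = pd1[: u + 1]
        d1 = m1 * schedule.pd1_death[res]
        p12 = m1 * schedule.pd1_prog[res]
        pd1 = pd1.copy()
        pd1[: u + 1] = m1 - d1 - p12

        m2 = pd2[: u + 1]
        d2 = m2 * schedule.pd2_death[res]
        pd2 = pd2.copy()
        pd2[: u + 1] = m2 - d2

        pd1[u + 1] += to_pd1
        pd2[u + 1] += p12.sum()
        dead += to_death + d1.sum() + d2.sum()

    occ[n_cycles] = (efs, pd1.sum(), pd2.sum(), dead)
    led1[n_cycles], led2[n_cycles] = pd1, pd2
    return CohortTrace(occ, schedule.cycle_len, led1, led2)


def half_cycle_correct(trace: CohortTrace) -> np.ndarray:
    """Effective within-cycle occupancy: trapezoid of start/end occupancy.

    Returns n_cycles rows; row u is the mean of start-of-cycle u and
    start-of-cycle u+1 occupancy, crediting mid-cycle transitions with
    half a cycle in each state.
    """
    occ = trace.occupancy
    if occ.shape[0] < 2:
        raise ValueError("need at least 2 recorded cycles")
    return (occ[:-1] + occ[1:]) / 2.0


def discount_weights(spec: DiscountSpec, n_cycles: int) -> np.ndarray:
    """Discount weight per cycle, evaluated at the cycle midpoint."""
    t_mid = (np.arange(n_cycles) + 0.5) * spec.cycle_len
    return (1.0 + spec.annual_rate) ** (-t_mid / 12.0)
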