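"""Synthetic two-arm trial evidence generator.

No patient-level data from the perioperative G/GEJ trial (or from the
second-line trial informing post-progression transitions) are publicly
deposited; only marginal summaries are printed. This module generates
individual patient data, Kaplan-Meier coordinates and number-at-risk
tables with the statistical structure the downstream analysis assumes,
calibrated to those published summaries:

* first-line event-free survival: control arm exponential calibrated to
  the published 2-year landmark (58.5%), treatment arm obtained by a
  proportional-hazards multiplier (HR 0.71) on the control hazard;
* first-line overall survival: each arm exponential calibrated to its own
  published 2-year landmark (70.4% / 75.7%);
* second-line OS/PFS: Weibull with configurable medians. The defaults are
  placeholders in the right clinical range for ramucirumab + paclitaxel
  (median OS ~9.6 months, median PFS ~4.4 months), not trial estimates.

Times are in months throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter

from .ipd import DigitizedCurve, PseudoIPD

__all__ = [
    "ArmSpec",
    "calibrate_exponential_rate",
    "simulate_arm_ipd",
    "km_coordinates_from_ipd",
    "simulate_two_arm_trial",
    "matterhorn_like_evidence",
    "second_line_evidence",
    "MATTERHORN_EFS_LANDMARK",
    "MATTERHORN_OS_LANDMARK",
    "MATTERHORN_EFS_HR",
]

#: published 2-year (24-month) landmarks and EFS hazard ratio
MATTERHORN_EFS_LANDMARK = {"FLOT": 0.585, "DFLOT": 0.674}
MATTERHORN_OS_LANDMARK = {"FLOT": 0.704, "DFLOT": 0.757}
MATTERHORN_EFS_HR = 0.71
#: subjects per arm, approximately the trial's randomized arm size
DEFAULT_N_PER_ARM = 474
#: administrative censoring horizon for the synthetic first-line trial
DEFAULT_CENSOR_MONTHS = 36.0

_GENERATOR_FAMILIES = ("exponential", "weibull")


def calibrate_exponential_rate(surv_prob: float, landmark: float) -> float:
    """Exponential hazard (per month) hitting ``surv_prob`` at ``landmark``.

    Solves exp(-lambda * landmark) = surv_prob.
    """
    if not 0.0 < surv_prob <= 1.0:
        raise ValueError(f"survival probability must be in (0, 1], got {surv_prob}")
    if landmark <= 0:
        raise ValueError("landmark must be positive")
    return -math.log(surv_prob) / landmark


@dataclass
class ArmSpec:
    """Recipe for one synthetic trial arm.

    ``params`` are the reference-arm distribution parameters; the arm's own
    hazard is the reference hazard scaled by ``hazard_ratio`` (proportional
    hazards), i.e. S_arm(t) = S_ref(t) ** hazard_ratio.
    """

    n: int
    family: str
    params: dict = field(default_factory=dict)
    hazard_ratio: float = 1.0
    censor_time: float = DEFAULT_CENSOR_MONTHS
    seed: int = 0
    arm: str = "arm"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 subjects per arm")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


def _draw_event_times(spec: ArmSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "exponential":
        rate = spec.params["rate"] * spec.hazard_ratio
        if rate == 0:
            return np.full(spec.n, np.inf)
        return rng.exponential(1.0 / rate, size=spec.n)
    if spec.family == "weibull":
        shape = spec.params["shape"]
        scale = spec.params["scale"] * spec.hazard_ratio ** (-1.0 / shape)
        return scale * rng.weibull(shape, size=spec.n)
    raise KeyError(
        f"unknown generator family {spec.family!r}; "
        f"available: {_GENERATOR_FAMILIES}"
    )


def simulate_arm_ipd(spec: ArmSpec) -> PseudoIPD:
    """Simulate one arm's IPD with administrative censoring.

    Event times are drawn from the arm's proportional-hazards-adjusted
    distribution; subjects still event-free at ``censor_time`` are censored
    there. Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    t = _draw_event_times(spec, rng)
    event = (t <= spec.censor_time).astype(int)
    time = np.minimum(t, spec.censor_time)
    return PseudoIPD(time, event, np.full(spec.n, spec.arm, dtype=object))


def km_coordinates_from_ipd(
    ipd: PseudoIPD, grid: np.ndarray, risk_interval: float = 6.0
) -> DigitizedCurve:
    """Evaluate the product-limit curve on a grid with a risk table.

    Emulates what a figure digitizer would extract from a published KM
    plot: survival probabilities at the grid times plus the number at risk
    at every ``risk_interval`` boundary.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must start at 0 and be strictly increasing")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    surv[0] = 1.0
    risk_times = np.arange(0.0, grid[-1] + 1e-9, risk_interval)
    n_at_risk = np.array([(ipd.time >= rt).sum() for rt in risk_times], dtype=float)
    curve = DigitizedCurve(grid, surv, risk_times, n_at_risk, label=str(ipd.arm[0]))
    curve.validate()
    return curve


def simulate_two_arm_trial(
    ref_spec: ArmSpec, treat_arm: str, hazard_ratio: float, seed_offset: int = 1
) -> PseudoIPD:
    """Reference arm plus a PH-scaled treatment arm, pooled."""
    treat = ArmSpec(
        n=ref_spec.n,
        family=ref_spec.family,
        params=ref_spec.params,
        hazard_ratio=hazard_ratio,
        censor_time=ref_spec.censor_time,
        seed=ref_spec.seed + seed_offset,
        arm=treat_arm,
    )
    return PseudoIPD.concat([simulate_arm_ipd(ref_spec), simulate_arm_ipd(treat)])


def matterhorn_like_evidence(
    seed: int = 0,
    n_per_arm: int = DEFAULT_N_PER_ARM,
    censor_time: float = DEFAULT_CENSOR_MONTHS,
    risk_interval: float = 6.0,
) -> dict:
    """Synthetic first-line EFS and OS evidence for both arms.

    EFS: FLOT exponential calibrated to the published 2-year landmark,
    DFLOT via the published hazard ratio. OS: each arm calibrated directly
    to its own 2-year landmark (the OS effect is not proportional over the
    whole follow-up, so only the landmarks are matched).

    Returns ``{(endpoint, arm): {"ipd": PseudoIPD, "curve": DigitizedCurve}}``
    for endpoint in {"EFS", "OS"} and arm in {"DFLOT", "FLOT"}.
    """
    grid = np.arange(0.0, censor_time + 1e-9, 0.5)
    out: dict = {}
    efs_rate = calibrate_exponential_rate(MATTERHORN_EFS_LANDMARK["FLOT"], 24.0)
    specs = {
        ("EFS", "FLOT"): ArmSpec(
            n_per_arm, "exponential", {"rate": efs_rate}, 1.0, censor_time,
            seed, "FLOT",
        ),
        ("EFS", "DFLOT"): ArmSpec(
            n_per_arm, "exponential", {"rate": efs_rate}, MATTERHORN_EFS_HR,
            censor_time, seed + 1, "DFLOT",
        ),
        ("OS", "FLOT"): ArmSpec(
            n_per_arm, "exponential",
            {"rate": calibrate_exponential_rate(MATTERHORN_OS_LANDMARK["FLOT"], 24.0)},
            1.0, censor_time, seed + 2, "FLOT",
        ),
        ("OS", "DFLOT"): ArmSpec(
            n_per_arm, "exponential",
            {"rate": calibrate_exponential_rate(MATTERHORN_OS_LANDMARK["DFLOT"], 24.0)},
            1.0, censor_time, seed + 3, "DFLOT",
        ),
    }
    for key, spec in specs.items():
        ipd = simulate_arm_ipd(spec)
        out[key] = {
            "ipd": ipd,
            "curve": km_coordinates_from_ipd(ipd, grid, risk_interval),
        }
    return out


def second_line_evidence(
    seed: int = 10,
    n: int = 330,
    median_os: float = 9.6,
    median_pfs: float = 4.4,
    shape: float = 1.2,
    censor_time: float = 24.0,
    risk_interval: float = 3.0,
) -> dict:
    """Synthetic second-line (post-progression) OS and PFS evidence.

    Single-arm Weibull stand-ins for the ramucirumab + paclitaxel arm of
    the second-line trial; the default medians are placeholders chosen in
    the published clinical range, not digitized trial values.
    """
    grid = np.arange(0.0, censor_time + 1e-9, 0.25)
    out: dict = {}
    for endpoint, median, s in (("OS", median_os, seed), ("PFS", median_pfs, seed + 1)):
        scale = median / math.log(2.0) ** (1.0 / shape)
        spec = ArmSpec(
            n, "weibull", {"shape": shape, "scale": scale}, 1.0, censor_time,
            s, f"2L-{endpoint}",
        )
        ipd = simulate_arm_ipd(spec)
        out[endpoint] = {
            "ipd": ipd,
            "curve": km_coordinates_from_ipd(ipd, grid, risk_interval),
        }
    return out
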