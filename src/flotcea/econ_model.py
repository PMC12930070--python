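"""Costs, utilities and incremental cost-effectiveness.

Maps a cohort trace to discounted category costs (treatment/drug, adverse
event management, follow-up, end-of-life), life-years and QALYs, using
the published parameter table, the perioperative dosing calendar, the
NCCN-style surveillance schedule, and one-off terminal costs.

Cost category conventions (mirroring the published base-case table):

* "drug": drug acquisition + infusion administration for first-line
  treatment (EFS-gated), the gastrectomy, second-line treatment while in
  PD1, and best supportive care while in PD2;
* "ae": expected grade >=3 adverse-event management, charged once at
  treatment start (undiscounted);
* "followup": CT scans, visits and CBC per the surveillance calendar,
  applied to alive non-PD2 occupancy;
* "eol": one hospice episode per incident death.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_engine import (
    CYCLE_LENGTH_MONTHS,
    CohortTrace,
    DiscountSpec,
    discount_weights,
    half_cycle_correct,
)

__all__ = [
    "Param",
    "EconParameterSet",
    "EconOptions",
    "EconResult",
    "IcerResult",
    "load_parameters",
    "mosteller_bsa",
    "drug_cost_per_cycle",
    "treatment_calendar",
    "ae_burden",
    "followup_schedule",
    "followup_cost",
    "accumulate",
    "icer",
    "AES",
    "ARMS",
]

logger = logging.getLogger(__name__)

AES = ("Diarrhea", "Anemia", "Neutropenia", "Thrombocytopenia")
ARMS = ("DFLOT", "FLOT")

# composite keys "group/label" mirroring the published parameter table
K_AE_INC = {arm: {ae: f"Risk for main adverse events in {arm} group/{ae}" for ae in AES}
            for arm in ARMS}
K_AE_DIS = {ae: f"AEs disutility/{ae}" for ae in AES}
K_AE_COST = {ae: f"AEs cost per/{ae}" for ae in AES}
K_U_EFS = "Utility/EFS"
K_U_PD = "Utility/PD"
K_U_GASTRECTOMY = "Utility/Gastrectomy"
K_DURVALUMAB = "Drug cost per cycle/Durvalumab"
K_FLOT_DRUGS = tuple(f"Drug cost per cycle/{d}" for d in
                     ("Fluorouracil", "Leucovorin", "Oxaliplatin", "Docetaxel"))
K_RAMUCIRUMAB = "Drug cost per cycle/Ramucirumab"
K_PACLITAXEL = "Drug cost per cycle/Paclitaxel"
K_CT = "Administration cost per/CT"
K_VISIT_INIT = "Administration cost per/Ppps, initial visit"
K_VISIT_SUB = "Administration cost per/Ppps, subsequent visit"
K_CBC = "Administration cost per/CBC"
K_IV_SHORT = "Administration cost per/IV infusion 1h"
K_IV_LONG = "Administration cost per/IV infusion over 1h"
K_GASTRECTOMY = "Administration cost per/Removal of stomach"
K_BSC = "Administration cost per/Best supportive care"
K_HOSPICE = "Administration cost per/Hospice care"
K_WEIGHT = "Patient/Body weight (kg)"
K_BSA = "Patient/BSA (m^2)"
K_GASTR_CYCLES = "Patient/Gastrectomy utility duration(cycle)"
K_DISCOUNT = "Patient/Discount rate, %"


@dataclass(frozen=True)
class Param:
    value: float
    min: float
    max: float
    dist: str  # beta | gamma | normal | fixed


@dataclass
class EconParameterSet:
    """Flat registry of model parameters keyed by 'group/label'."""

    params: dict

    def __getitem__(self, key: str) -> Param:
        return self.params[key]

    def value(self, key: str) -> float:
        return self.params[key].value

    def keys(self):
        return self.params.keys()

    def with_value(self, key: str, value: float) -> "EconParameterSet":
        new = dict(self.params)
        new[key] = replace(new[key], value=float(value))
        return EconParameterSet(new)

    def with_values(self, updates: dict) -> "EconParameterSet":
        new = dict(self.params)
        for k, v in updates.items():
            new[k] = replace(new[k], value=float(v))
        return EconParameterSet(new)

    def validate(self) -> None:
        for key, p in self.params.items():
            if "Utility" in key or "disutility" in key or "Risk" in key:
                if not 0.0 <= p.value <= 1.0:
                    raise ValueError(f"{key} outside [0, 1]: {p.value}")
            if ("cost" in key.lower() or "Drug" in key) and p.value < 0:
                raise ValueError(f"negative cost for {key}")

    @property
    def discount_rate(self) -> float:
        return self.value(K_DISCOUNT) / 100.0


def load_parameters(path: str | Path | None = None) -> EconParameterSet:
    """Load the parameter table (package default or a user file).

    Ranges failing min <= value <= max are repaired to +/-25% of the base
    value with a warning (the published best-supportive-care minimum
    exceeds its base value).
    """
    if path is None:
        text = resources.files("flotcea").joinpath("data/table1.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    flat: dict[str, Param] = {}
    for group, rows in raw.items():
        for label, spec in rows.items():
            p = Param(float(spec["value"]), float(spec["min"]), float(spec["max"]),
                      str(spec["dist"]))
            if not p.min <= p.value <= p.max:
                logger.warning(
                    "range for %r does not bracket the base value; repaired to +/-25%%",
                    f"{group}/{label}",
                )
                p = Param(p.value, 0.75 * p.value, 1.25 * p.value, p.dist)
            flat[f"{group}/{label}"] = p
    ps = EconParameterSet(flat)
    ps.validate()
    return ps


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Mosteller body-surface area sqrt(height * weight / 3600), m^2."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


@dataclass
class EconOptions:
    """Policy switches for the cost mapping."""

    #: "model": drug-cost-per-cycle table rows are per 4-week model cycle;
    #: "chemo": per 2-week chemotherapy cycle (doubles FLOT drug costs)
    flot_cycle_reading: str = "model"
    #: best supportive care per PD2 cycle or once per PD2 entry
    bsc_mode: str = "per_cycle"
    #: expected postoperative durvalumab monotherapy cycles (10 = full)
    expected_mono_cycles: float = 10.0
    surgery_cycle: int = 2
    n_mono_cycles: int = 10


def treatment_calendar(arm: str, options: EconOptions | None = None) -> dict:
    """Cycle-indexed treatment phases for one strategy.

    Two neoadjuvant model cycles (each bundling two 2-week chemotherapy
    cycles), surgery, two adjuvant model cycles, then 10 durvalumab
    monotherapy cycles for the DFLOT arm only. Durvalumab is given on day
    1 of every treatment model cycle, for 14 cycles total in DFLOT.
    """
    if arm not in ARMS:
        raise KeyError(f"unknown arm {arm!r}")
    opt = options or EconOptions()
    s = opt.surgery_cycle
    cal = {0: "neoadjuvant", 1: "neoadjuvant", s: "surgery",
           s + 1: "adjuvant", s + 2: "adjuvant"}
    if arm == "DFLOT":
        for j in range(opt.n_mono_cycles):
            cal[s + 3 + j] = "monotherapy"
    return cal


def _flot_drug_component(params: EconParameterSet, options: EconOptions) -> float:
    per_cycle = sum(params.value(k) for k in K_FLOT_DRUGS)
    mult = 2.0 if options.flot_cycle_reading == "chemo" else 1.0
    return per_cycle * mult


def drug_cost_per_cycle(
    arm: str,
    phase: str,
    params: EconParameterSet,
    options: EconOptions | None = None,
) -> float:
    """Drug acquisition + infusion administration cost per model cycle.

    FLOT phases bundle two 2-week chemotherapy administrations (each
    billed one long-infusion fee); durvalumab adds its per-cycle price
    plus one short-infusion fee; second-line is one 28-day ramucirumab +
    paclitaxel cycle (day 1/15 billed long, day 8 short).
    """
    if arm not in ARMS:
        raise KeyError(f"unknown arm {arm!r}")
    opt = options or EconOptions()
    iv_short = params.value(K_IV_SHORT)
    iv_long = params.value(K_IV_LONG)
    if phase in ("neoadjuvant", "adjuvant"):
        cost = _flot_drug_component(params, opt) + 2 * iv_long
        if arm == "DFLOT":
            cost += params.value(K_DURVALUMAB) + iv_short
        return cost
    if phase == "monotherapy":
        if arm != "DFLOT":
            raise KeyError("monotherapy phase applies to the DFLOT arm only")
        return params.value(K_DURVALUMAB) + iv_short
    if phase == "second_line":
        drugs = params.value(K_RAMUCIRUMAB) + params.value(K_PACLITAXEL)
        return drugs + 2 * iv_long + iv_short
    raise KeyError(f"unknown phase {phase!r}")


def ae_burden(incidences, unit_costs, disutilities) -> tuple[float, float]:
    """Expected one-off AE cost and utility decrement: sum p_i c_i, sum p_i d_i."""
    p = np.asarray(incidences, dtype=float)
    c = np.asarray(unit_costs, dtype=float)
    d = np.asarray(disutilities, dtype=float)
    if not (len(p) == len(c) == len(d)):
        raise ValueError("incidence/cost/disutility vectors must align")
    return float(p @ c), float(p @ d)


def _arm_ae_burden(arm: str, params: EconParameterSet) -> tuple[float, float]:
    p = [params.value(K_AE_INC[arm][ae]) for ae in AES]
    c = [params.value(K_AE_COST[ae]) for ae in AES]
    d = [params.value(K_AE_DIS[ae]) for ae in AES]
    return ae_burden(p, c, d)


def followup_schedule(n_cycles: int, cycle_len: float = CYCLE_LENGTH_MONTHS):
    """Surveillance encounters per cycle from the guideline calendar.

    CT every 6 months for 2 years then annually to 5 years; H&P + CBC
    every 3 months for 2 years then every 6 months for the rest of the
    horizon. Returns (ct_count, visit_count) arrays of length n_cycles.
    """
    horizon = n_cycles * cycle_len
    ct_months = [m for m in (6, 12, 18, 24, 36, 48, 60) if m <= horizon]
    visit_months = [float(m) for m in range(3, 25, 3)]
    m = 30.0
    while m <= horizon:
        visit_months.append(m)
        m += 6.0
    ct = np.zeros(n_cycles)
    visits = np.zeros(n_cycles)
    for mth in ct_months:
        u = min(int(mth / cycle_len), n_cycles - 1)
        ct[u] += 1
    for mth in visit_months:
        u = min(int(mth / cycle_len), n_cycles - 1)
        visits[u] += 1
    return ct, visits


def followup_cost(
    cycle: int,
    params: EconParameterSet,
    n_cycles: int = 131,
    cycle_len: float = CYCLE_LENGTH_MONTHS,
) -> float:
    """Expected surveillance cost scheduled in one model cycle.

    The first scheduled visit is priced as an initial visit, later ones
    as subsequent visits; every visit includes a CBC.
    """
    if cycle < 0:
        raise ValueError("cycle must be nonnegative")
    ct, visits = followup_schedule(n_cycles, cycle_len)
    if cycle >= n_cycles:
        return 0.0
    first_visit_cycle = int(np.argmax(visits > 0)) if visits.any() else -1
    cost = ct[cycle] * params.value(K_CT)
    if visits[cycle] > 0:
        n_init = 1.0 if cycle == first_visit_cycle else 0.0
        cost += n_init * params.value(K_VISIT_INIT)
        cost += (visits[cycle] - n_init) * params.value(K_VISIT_SUB)
        cost += visits[cycle] * params.value(K_CBC)
    return float(cost)


@dataclass
class EconResult:
    """Discounted outcomes for one strategy."""

    strategy: str
    cost_drug: float
    cost_ae: float
    cost_followup: float
    cost_eol: float
    life_years: float
    qalys: float

    @property
    def total_cost(self) -> float:
        return self.cost_drug + self.cost_ae + self.cost_followup + self.cost_eol

    def categories(self) -> dict:
        return {
            "Drug": self.cost_drug,
            "AEs Management": self.cost_ae,
            "Follow up": self.cost_followup,
            "End-of-life": self.cost_eol,
        }

    def to_series(self) -> pd.Series:
        return pd.Series({**self.categories(), "Total cost": self.total_cost,
                          "Total life years": self.life_years, "QALY": self.qalys},
                         name=self.strategy)


def accumulate(
    trace: CohortTrace,
    params: EconParameterSet,
    arm: str,
    discount: DiscountSpec | None = None,
    options: EconOptions | None = None,
) -> EconResult:
    """Fold the cohort trace into discounted costs, life-years and QALYs.

    Per-cycle quantities use half-cycle-corrected occupancy times the
    cycle's midpoint discount weight; adverse-event burden is charged once
    at treatment start, undiscounted; hospice once per incident death.
    """
    opt = options or EconOptions()
    disc = discount or DiscountSpec(params.discount_rate, trace.cycle_len)
    if abs(disc.cycle_len - trace.cycle_len) > 1e-9:
        raise ValueError("discount spec and trace use different cycle lengths")
    n = trace.n_cycles
    hcc = half_cycle_correct(trace)
    w = discount_weights(disc, n)
    cyc_years = trace.cycle_len / 12.0

    efs_o, pd1_o, pd2_o = hcc[:, 0], hcc[:, 1], hcc[:, 2]
    alive = efs_o + pd1_o + pd2_o

    # --- treatment (drug) costs ---
    cal = treatment_calendar(arm, opt)
    mono_scale = opt.expected_mono_cycles / opt.n_mono_cycles
    drug = 0.0
    for u, phase in cal.items():
        if u >= n:
            continue
        if phase == "surgery":
            drug += params.value(K_GASTRECTOMY) * efs_o[u] * w[u]
        else:
            c = drug_cost_per_cycle(arm, phase, params, opt)
            if phase == "monotherapy":
                c *= mono_scale
            drug += c * efs_o[u] * w[u]
    # second line while in PD1
    c2 = drug_cost_per_cycle(arm, "second_line", params, opt)
    drug += float((c2 * pd1_o * w).sum())
    # best supportive care in PD2
    bsc = params.value(K_BSC)
    if opt.bsc_mode == "per_cycle":
        drug += float((bsc * pd2_o * w).sum())
    elif opt.bsc_mode == "per_episode":
        if trace.pd2_ledger is None:
            raise ValueError("per-episode BSC needs a trace with a PD2 ledger")
        # mass entering PD2 during cycle u sits at entry index u+1 next cycle
        inflow = np.array([trace.pd2_ledger[u + 1, u + 1] for u in range(n)])
        drug += float((bsc * inflow * w).sum())
    else:
        raise KeyError(f"unknown bsc_mode {opt.bsc_mode!r}")

    # --- adverse events: one-off at treatment start, undiscounted ---
    ae_cost, ae_dis = _arm_ae_burden(arm, params)

    # --- follow-up ---
    ct, visits = followup_schedule(n, trace.cycle_len)
    first_visit_cycle = int(np.argmax(visits > 0)) if visits.any() else -1
    fu = ct * params.value(K_CT) + visits * (params.value(K_VISIT_SUB)
                                             + params.value(K_CBC))
    if first_visit_cycle >= 0:
        fu[first_visit_cycle] += params.value(K_VISIT_INIT) - params.value(K_VISIT_SUB)
    followup = float((fu * (efs_o + pd1_o) * w).sum())

    # --- end of life: hospice per incident death ---
    deaths = np.diff(trace.occupancy[:, 3])
    eol = float((params.value(K_HOSPICE) * deaths * w).sum())

    # --- utilities ---
    u_efs = np.full(n, params.value(K_U_EFS))
    g0 = opt.surgery_cycle
    g1 = min(g0 + int(round(params.value(K_GASTR_CYCLES))), n)
    u_efs[g0:g1] = params.value(K_U_GASTRECTOMY)
    u_pd = params.value(K_U_PD)
    qaly_cycles = (efs_o * u_efs + (pd1_o + pd2_o) * u_pd) * w
    qalys = float(qaly_cycles.sum() * cyc_years) - ae_dis * cyc_years
    life_years = float((alive * w).sum() * cyc_years)

    return EconResult(arm, drug, ae_cost, followup, eol, life_years, qalys)


@dataclass
class IcerResult:
    """Incremental comparison of two strategies (a vs b)."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str  # "icer" | "a dominant" | "a dominated" | "undefined"

    def __str__(self) -> str:
        if self.label == "icer":
            return f"{self.icer:,.2f} USD/QALY"
        return f"{self.label} (dC={self.delta_cost:,.2f}, dQ={self.delta_qaly:.4f})"


def icer(a: EconResult, b: EconResult) -> IcerResult:
    """ICER of strategy a vs b, with dominance labelling.

    Returns a ratio only when the trade-off is real (one strategy costs
    more and yields more QALYs); otherwise labels dominance, or
    "undefined" when the QALY difference is zero.
    """
    dc = a.total_cost - b.total_cost
    dq = a.qalys - b.qalys
    if dq == 0.0:
        return IcerResult(dc, dq, None, "undefined")
    if dc <= 0 and dq > 0:
        return IcerResult(dc, dq, None, "a dominant")
    if dc >= 0 and dq < 0:
        return IcerResult(dc, dq, None, "a dominated")
    return IcerResult(dc, dq, dc / dq, "icer")
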