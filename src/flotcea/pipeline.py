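"""End-to-end model assembly: evidence -> fits -> trace -> economics.

Glue layer used by the CLI and the sensitivity analyses. The base-case
survival family assignments are: Weibull for DFLOT event-free survival,
exponential for FLOT event-free survival, gamma for second-line overall
survival and a Royston-Parmar hazard-scale spline for second-line
progression-free survival; first-line OS fits (used only to split EFS
exits between progression and death) default to the same families as a
parsimonious choice. All assignments are overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import km_reconstruct, trial_synthesis
from .cohort_engine import (
    CYCLE_LENGTH_MONTHS,
    N_CYCLES_10Y,
    CohortTrace,
    DiscountSpec,
    TransitionSchedule,
    build_transition_schedule,
    run_cohort,
)
from .econ_model import (
    EconOptions,
    EconParameterSet,
    EconResult,
    IcerResult,
    accumulate,
    icer,
    load_parameters,
)
from .ipd import DigitizedCurve, PseudoIPD
from .survival_fit import FittedSurvivalModel, fit_by_id

__all__ = ["EVIDENCE_KEYS", "DEFAULT_FAMILY_MAP", "CEModel",
           "synthetic_evidence_curves", "reconstruct_all", "fit_evidence"]

logger = logging.getLogger(__name__)

EVIDENCE_KEYS = (
    ("EFS", "DFLOT"), ("EFS", "FLOT"), ("OS", "DFLOT"), ("OS", "FLOT"),
    ("2L", "OS"), ("2L", "PFS"),
)

DEFAULT_FAMILY_MAP = {
    ("EFS", "DFLOT"): "weibull",
    ("EFS", "FLOT"): "exponential",
    ("OS", "DFLOT"): "weibull",
    ("OS", "FLOT"): "exponential",
    ("2L", "OS"): "gamma",
    ("2L", "PFS"): "rp_hazard",
}


def synthetic_evidence_curves(seed: int = 0, n_per_arm: int | None = None) -> dict:
    """Digitized-curve stand-ins for every evidence source the model needs."""
    kw = {} if n_per_arm is None else {"n_per_arm": n_per_arm}
    first = trial_synthesis.matterhorn_like_evidence(seed=seed, **kw)
    second = trial_synthesis.second_line_evidence(seed=seed + 100)
    curves = {k: v["curve"] for k, v in first.items()}
    curves[("2L", "OS")] = second["OS"]["curve"]
    curves[("2L", "PFS")] = second["PFS"]["curve"]
    return curves


def reconstruct_all(curves: dict) -> dict:
    """Guyot-style pseudo-IPD for every evidence curve."""
    return {k: km_reconstruct.reconstruct_ipd(c, arm=str(k)) for k, c in curves.items()}


def fit_evidence(ipds: dict, family_map: dict | None = None) -> dict:
    fam = dict(DEFAULT_FAMILY_MAP)
    if family_map:
        fam.update(family_map)
    fits = {}
    for key, ipd in ipds.items():
        fits[key] = fit_by_id(ipd, fam[key])
        if not fits[key].converged:
            logger.warning("fit %s (%s) flagged non-converged", key, fam[key])
    return fits


@dataclass
class CEModel:
    """Configured cost-effectiveness engine for the two strategies."""

    fits: dict
    params: EconParameterSet = field(default_factory=load_parameters)
    options: EconOptions = field(default_factory=EconOptions)
    n_cycles: int = N_CYCLES_10Y
    cycle_len: float = CYCLE_LENGTH_MONTHS
    efs_split: str = "hazard_ratio"
    constant_death_share: float = 0.0
    _trace_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_synthetic(cls, seed: int = 0, family_map: dict | None = None,
                       **kw) -> "CEModel":
        curves = synthetic_evidence_curves(seed=seed)
        fits = fit_evidence(reconstruct_all(curves), family_map)
        return cls(fits=fits, **kw)

    def schedule(self, arm: str, fits: dict | None = None) -> TransitionSchedule:
        f = fits or self.fits
        return build_transition_schedule(
            f[("EFS", arm)], f[("OS", arm)], f[("2L", "OS")], f[("2L", "PFS")],
            n_cycles=self.n_cycles, cycle_len=self.cycle_len,
            efs_split=self.efs_split, constant_death_share=self.constant_death_share,
        )

    def trace(self, arm: str, fits: dict | None = None) -> CohortTrace:
        if fits is None:
            if arm not in self._trace_cache:
                self._trace_cache[arm] = run_cohort(self.schedule(arm))
            return self._trace_cache[arm]
        return run_cohort(self.schedule(arm, fits))

    def evaluate(
        self,
        params: EconParameterSet | None = None,
        options: EconOptions | None = None,
        fits: dict | None = None,
    ) -> dict:
        """Both strategies + incremental comparison (DFLOT vs FLOT)."""
        p = params or self.params
        opt = options or self.options
        disc = DiscountSpec(p.discount_rate, self.cycle_len)
        results = {}
        for arm in ("DFLOT", "FLOT"):
            results[arm] = accumulate(self.trace(arm, fits), p, arm, disc, opt)
        results["icer"] = icer(results["DFLOT"], results["FLOT"])
        return results

    # ---- survival parameter uncertainty (PSA support) ----

    def fit_covariances(self) -> dict:
        if not hasattr(self, "_covs"):
            self._covs = {k: m.covariance() for k, m in self.fits.items()}
        return self._covs

    def resample_fits(self, rng: np.random.Generator) -> dict:
        """Multivariate-normal draw of each fit's working parameters."""
        covs = self.fit_covariances()
        out = {}
        for key, m in self.fits.items():
            theta = rng.multivariate_normal(m.theta, covs[key],
                                            method="eigh")
            out[key] = m.with_theta(theta)
        return out
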