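"""Maximum-likelihood survival fitting and extrapolation model zoo.

Fits right-censored survival data with the standard parametric families
used in health-technology-assessment extrapolation (exponential, Weibull,
Gompertz, log-normal, log-logistic, gamma, generalized gamma) plus the
flexible families: Royston-Parmar restricted-cubic-spline models on the
hazard / odds / normal scales, fractional polynomials (orders 1 and 2) on
the log-cumulative-hazard scale, and mixture-cure models. A generalized
additive family is registered for completeness but not parameterized.

All likelihoods share one form: sum of log f(t) over events plus
log S(t) over censored records. Parameters live on an unconstrained
working scale (log transforms for positives); optimization is multi-start
Nelder-Mead with a gradient polish.

Model objects expose S(t), h(t) and H(t) evaluators, AIC/BIC, and a
working-scale covariance (finite-difference observed information) for
probabilistic sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .ipd import PseudoIPD

__all__ = [
    "FittedSurvivalModel",
    "fit_parametric",
    "fit_flexible",
    "compare_models",
    "transition_probability",
    "STANDARD_FAMILIES",
    "FLEXIBLE_FAMILIES",
    "FitError",
]

logger = logging.getLogger(__name__)

_TINY = 1e-300
_CLIP_T = 1e-8

STANDARD_FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "lognormal",
    "loglogistic",
    "gamma",
    "gengamma",
)
FLEXIBLE_FAMILIES = ("rp_hazard", "rp_odds", "rp_normal", "fp1", "fp2", "mixture_cure", "gam")


class FitError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# standard parametric families (working scale -> log f, log S)
# --------------------------------------------------------------------------

class _Family:
    """One distribution family: working-scale likelihood pieces."""

    name: str = ""
    param_names: tuple = ()

    def logsf(self, theta, t):
        raise NotImplementedError

    def logpdf(self, theta, t):
        raise NotImplementedError

    def natural(self, theta) -> dict:
        raise NotImplementedError

    def inits(self, t, e) -> list:
        raise NotImplementedError


class _Exponential(_Family):
    name = "exponential"
    param_names = ("log_rate",)

    def logsf(self, theta, t):
        return -np.exp(theta[0]) * t

    def logpdf(self, theta, t):
        return theta[0] - np.exp(theta[0]) * t

    def natural(self, theta):
        return {"rate": float(np.exp(theta[0]))}

    def inits(self, t, e):
        lam = max(e.sum(), 0.5) / t.sum()
        return [np.array([np.log(lam)])]


class _Weibull(_Family):
    name = "weibull"
    param_names = ("log_shape", "log_scale")

    def logsf(self, theta, t):
        k, s = np.exp(theta)
        return -((t / s) ** k)

    def logpdf(self, theta, t):
        k, s = np.exp(theta)
        z = t / s
        return np.log(k) - np.log(s) + (k - 1) * np.log(z) - z**k

    def natural(self, theta):
        k, s = np.exp(theta)
        return {"shape": float(k), "scale": float(s)}

    def inits(self, t, e):
        m = t[e == 1].mean() if e.any() else t.mean()
        return [np.array([0.0, np.log(m)]), np.array([0.4, np.log(m)]),
                np.array([-0.4, np.log(m)])]


class _Gompertz(_Family):
    """h(t) = a exp(b t); b may be negative (decelerating hazard)."""

    name = "gompertz"
    param_names = ("log_a", "b")

    @staticmethod
    def _cumhaz(a, b, t):
        if abs(b) < 1e-9:
            return a * t
        return a / b * np.expm1(b * t)

    def logsf(self, theta, t):
        a, b = np.exp(theta[0]), theta[1]
        return -self._cumhaz(a, b, t)

    def logpdf(self, theta, t):
        a, b = np.exp(theta[0]), theta[1]
        return np.log(a) + b * t - self._cumhaz(a, b, t)

    def natural(self, theta):
        return {"rate": float(np.exp(theta[0])), "shape": float(theta[1])}

    def inits(self, t, e):
        lam = max(e.sum(), 0.5) / t.sum()
        return [np.array([np.log(lam), 0.0]), np.array([np.log(lam), 0.02]),
                np.array([np.log(lam), -0.02])]


class _LogNormal(_Family):
    name = "lognormal"
    param_names = ("mu", "log_sigma")

    def logsf(self, theta, t):
        mu, sig = theta[0], np.exp(theta[1])
        return stats.norm.logsf(np.log(t), loc=mu, scale=sig)

    def logpdf(self, theta, t):
        mu, sig = theta[0], np.exp(theta[1])
        return stats.norm.logpdf(np.log(t), loc=mu, scale=sig) - np.log(t)

    def natural(self, theta):
        return {"mu": float(theta[0]), "sigma": float(np.exp(theta[1]))}

    def inits(self, t, e):
        lt = np.log(np.clip(t[e == 1] if e.any() else t, _CLIP_T, None))
        return [np.array([lt.mean(), np.log(max(lt.std(), 0.2))])]


class _LogLogistic(_Family):
    name = "loglogistic"
    param_names = ("log_alpha", "log_beta")

    def logsf(self, theta, t):
        a, b = np.exp(theta)
        return -np.log1p((t / a) ** b)

    def logpdf(self, theta, t):
        a, b = np.exp(theta)
        z = np.log(t) - np.log(a)
        return np.log(b) - np.log(t) + b * z - 2 * np.logaddexp(0.0, b * z)

    def natural(self, theta):
        a, b = np.exp(theta)
        return {"alpha": float(a), "beta": float(b)}

    def inits(self, t, e):
        m = np.median(t[e == 1]) if e.any() else np.median(t)
        return [np.array([np.log(m), 0.0]), np.array([np.log(m), 0.5])]


class _Gamma(_Family):
    name = "gamma"
    param_names = ("log_shape", "log_scale")

    def logsf(self, theta, t):
        k, s = np.exp(theta)
        with np.errstate(divide="ignore"):
            return np.log(np.clip(special.gammaincc(k, t / s), _TINY, None))

    def logpdf(self, theta, t):
        k, s = np.exp(theta)
        return stats.gamma.logpdf(t, k, scale=s)

    def natural(self, theta):
        k, s = np.exp(theta)
        return {"shape": float(k), "scale": float(s)}

    def inits(self, t, e):
        m = t[e == 1].mean() if e.any() else t.mean()
        return [np.array([0.0, np.log(m)]), np.array([0.5, np.log(m / 1.6)])]


class _GenGamma(_Family):
    """Stacy generalized gamma via scipy's (a, c, scale) parameterization."""

    name = "gengamma"
    param_names = ("log_a", "c", "log_scale")

    def _abc(self, theta):
        a = np.exp(np.clip(theta[0], -10, 10))
        c = theta[1]
        if abs(c) < 1e-4:  # c = 0 is the log-normal limit; keep away from it
            c = 1e-4 if c >= 0 else -1e-4
        return a, c, np.exp(theta[2])

    def logsf(self, theta, t):
        a, c, s = self._abc(theta)
        with np.errstate(all="ignore"):
            v = stats.gengamma.logsf(t, a, c, scale=s)
        return np.nan_to_num(v, nan=-np.inf, neginf=-745.0)

    def logpdf(self, theta, t):
        a, c, s = self._abc(theta)
        with np.errstate(all="ignore"):
            v = stats.gengamma.logpdf(t, a, c, scale=s)
        return np.nan_to_num(v, nan=-np.inf)

    def natural(self, theta):
        a, c, s = self._abc(theta)
        return {"a": float(a), "c": float(c), "scale": float(s)}

    def inits(self, t, e):
        m = t[e == 1].mean() if e.any() else t.mean()
        return [np.array([0.0, 1.0, np.log(m)]),
                np.array([0.5, 0.7, np.log(m)]),
                np.array([0.0, 1.5, np.log(m)])]


_STANDARD = {
    f.name: f
    for f in (_Exponential(), _Weibull(), _Gompertz(), _LogNormal(),
              _LogLogistic(), _Gamma(), _GenGamma())
}


# --------------------------------------------------------------------------
# fitted model container
# --------------------------------------------------------------------------

@dataclass
class FittedSurvivalModel:
    """A fitted survival model with evaluators and fit statistics."""

    family: str
    params: dict
    theta: np.ndarray
    loglik: float
    k: int
    n: int
    converged: bool = True
    message: str = ""
    _logsf: object = field(default=None, repr=False)
    _logpdf: object = field(default=None, repr=False)
    _negloglik: object = field(default=None, repr=False)
    _rebuild: object = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.loglik

    def sf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.ones_like(t, dtype=float)
        pos = t > 0
        if pos.any():
            out[pos] = np.exp(self._logsf(self.theta, np.clip(t[pos], _CLIP_T, None)))
        return out if out.ndim else float(out)

    def cumhaz(self, t):
        s = np.clip(self.sf(t), _TINY, 1.0)
        return -np.log(s)

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, _CLIP_T, None)
        return np.exp(self._logpdf(self.theta, tc) - np.log(np.clip(self.sf(tc), _TINY, None)))

    def with_theta(self, theta: np.ndarray) -> "FittedSurvivalModel":
        """Same family/structure, different parameter vector (PSA draws)."""
        if self._rebuild is not None:
            return self._rebuild(np.asarray(theta, dtype=float))
        new = FittedSurvivalModel(
            self.family, self.params, np.asarray(theta, dtype=float), self.loglik,
            self.k, self.n, self.converged, "resampled",
            self._logsf, self._logpdf, self._negloglik, self._rebuild,
        )
        return new

    def covariance(self) -> np.ndarray:
        """Working-scale covariance from the observed information matrix."""
        if self._negloglik is None:
            raise FitError("no likelihood stored for this model")
        H = _numeric_hessian(self._negloglik, self.theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        # guard: symmetrize and floor eigenvalues at 0
        cov = (cov + cov.T) / 2
        w, v = np.linalg.eigh(cov)
        return (v * np.clip(w, 0.0, None)) @ v.T


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
            ) / eps**2
    return H


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------

def _extract(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, PseudoIPD):
        t, e = data.time, data.event
    else:
        t, e = data
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
    t = np.clip(t, _CLIP_T, None)
    if e.sum() < 1:
        raise FitError("need at least one event to fit a survival model")
    return t, e


def _optimize(negll, starts, tol=1e-8):
    best = None
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = optimize.minimize(negll, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-6, "fatol": tol, "maxiter": 4000})
            r2 = optimize.minimize(negll, r.x, method="BFGS",
                                   options={"gtol": 1e-7, "maxiter": 500})
        cand = r2 if r2.fun <= r.fun else r
        if np.isfinite(cand.fun) and (best is None or cand.fun < best.fun - 1e-12):
            best = cand
    if best is None:
        raise FitError("optimization failed from every start")
    return best


def fit_parametric(data, family: str) -> FittedSurvivalModel:
    """Maximum-likelihood fit of one of the 7 standard families.

    ``data`` is a :class:`PseudoIPD` (single arm) or a ``(times, events)``
    pair. Non-convergence is flagged on the returned model, never hidden.
    """
    if family not in _STANDARD:
        raise KeyError(f"unknown standard family {family!r}; choose from {STANDARD_FAMILIES}")
    t, e = _extract(data)
    fam = _STANDARD[family]
    ev, ce = e == 1, e == 0

    def negll(theta):
        with np.errstate(all="ignore"):
            ll = fam.logpdf(theta, t[ev]).sum() + fam.logsf(theta, t[ce]).sum()
        return -ll if np.isfinite(ll) else 1e12

    res = _optimize(negll, fam.inits(t, e))
    theta = res.x

    def rebuild(th):
        m = FittedSurvivalModel(
            family, fam.natural(th), th, -float(negll(th)), len(th), len(t),
            True, "resampled", fam.logsf, fam.logpdf, negll, None,
        )
        return m

    model = FittedSurvivalModel(
        family, fam.natural(theta), theta, -float(res.fun), len(theta), len(t),
        converged=bool(np.isfinite(res.fun)), message=str(res.message),
        _logsf=fam.logsf, _logpdf=fam.logpdf, _negloglik=negll, _rebuild=rebuild,
    )
    if not model.converged:
        logger.warning("fit of %s did not converge: %s", family, res.message)
    return model


# --------------------------------------------------------------------------
# flexible families
# --------------------------------------------------------------------------

def _rcs_basis(x: np.ndarray, knots: np.ndarray):
    """Restricted (natural) cubic spline basis and derivative.

    Basis: [1, x, v_1..v_{K-2}] with the standard restriction that the
    spline is linear beyond the boundary knots.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    K = len(knots)
    cols = [np.ones_like(x), x]
    dcols = [np.zeros_like(x), np.ones_like(x)]
    if K >= 3:
        kmin, kmax = knots[0], knots[-1]
        for j in range(1, K - 1):
            lam = (kmax - knots[j]) / (kmax - kmin)
            def cube(u):
                return np.clip(u, 0.0, None) ** 3
            def dcube(u):
                return 3 * np.clip(u, 0.0, None) ** 2
            v = (cube(x - knots[j]) - lam * cube(x - kmin)
                 - (1 - lam) * cube(x - kmax))
            dv = (dcube(x - knots[j]) - lam * dcube(x - kmin)
                  - (1 - lam) * dcube(x - kmax))
            cols.append(v)
            dcols.append(dv)
    return np.column_stack(cols), np.column_stack(dcols)


def _rp_loglik_parts(scale: str):
    """log f and log S as functions of (s, s') for an RP scale.

    hazard: ln H = s         => S = exp(-e^s),   f = e^s s'/t S
    odds:   ln(1/S - 1) = s  => S = 1/(1+e^s),   f = e^s s'/t S^2
    normal: Phi^{-1}(1-S) = s => S = Phi(-s),    f = phi(s) s'/t
    """
    if scale == "hazard":
        def logsf(s, sp, logt):
            return -np.exp(s)

        def logpdf(s, sp, logt):
            return s + np.log(np.clip(sp, _TINY, None)) - logt - np.exp(s)
    elif scale == "odds":
        def logsf(s, sp, logt):
            return -np.logaddexp(0.0, s)

        def logpdf(s, sp, logt):
            return s + np.log(np.clip(sp, _TINY, None)) - logt - 2 * np.logaddexp(0.0, s)
    elif scale == "normal":
        def logsf(s, sp, logt):
            return stats.norm.logcdf(-s)

        def logpdf(s, sp, logt):
            return stats.norm.logpdf(s) + np.log(np.clip(sp, _TINY, None)) - logt
    else:
        raise ValueError(f"unknown RP scale {scale!r}")
    return logsf, logpdf


def _fit_rp(t, e, scale: str, n_knots: int, family_id: str) -> FittedSurvivalModel:
    ev = e == 1
    lev = np.log(t[ev])
    bmin, bmax = lev.min(), lev.max()
    if bmax - bmin < 1e-6:
        bmax = bmin + 1e-6
    if n_knots > 0:
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        interior = np.quantile(lev, qs)
        knots = np.concatenate([[bmin], interior, [bmax]])
    else:
        knots = np.array([bmin, bmax])
    logsf_s, logpdf_s = _rp_loglik_parts(scale)
    logt_all = np.log(t)
    B, dB = _rcs_basis(logt_all, knots)
    pen_x = np.linspace(bmin, bmax, 41)
    _, dBpen = _rcs_basis(pen_x, knots)

    def parts(gamma, B_, dB_):
        s = B_ @ gamma
        sp = dB_ @ gamma
        return s, sp

    def negll(gamma):
        s, sp = parts(gamma, B, dB)
        pen_sp = dBpen @ gamma
        penalty = 1e6 * np.square(np.clip(-pen_sp + 1e-9, 0.0, None)).sum()
        with np.errstate(all="ignore"):
            ll = (logpdf_s(s[ev], sp[ev], logt_all[ev]).sum()
                  + logsf_s(s[~ev], sp[~ev], logt_all[~ev]).sum())
        val = -ll + penalty
        return val if np.isfinite(val) else 1e12

    # Weibull-equivalent start: ln H = k ln t - k ln scale
    wb = fit_parametric((t, e), "weibull")
    kk, ss = wb.params["shape"], wb.params["scale"]
    g0 = np.zeros(B.shape[1])
    g0[0], g0[1] = -kk * np.log(ss), kk
    starts = [g0, g0 * 0.5 + np.array([0.01] * len(g0))]
    res = _optimize(negll, starts)
    gamma = res.x

    def make_logsf(th):
        def f(theta, tt):
            Bq, dBq = _rcs_basis(np.log(tt), knots)
            s, sp = parts(theta, Bq, dBq)
            return logsf_s(s, sp, np.log(tt))
        return f

    def make_logpdf(th):
        def f(theta, tt):
            Bq, dBq = _rcs_basis(np.log(tt), knots)
            s, sp = parts(theta, Bq, dBq)
            return logpdf_s(s, np.clip(sp, _TINY, None), np.log(tt))
        return f

    params = {f"gamma{i}": float(g) for i, g in enumerate(gamma)}
    params["knots_logt"] = [float(x) for x in knots]
    model = FittedSurvivalModel(
        family_id, params, gamma, -float(res.fun), len(gamma), len(t),
        converged=bool(np.isfinite(res.fun)), message=str(res.message),
        _logsf=make_logsf(gamma), _logpdf=make_logpdf(gamma), _negloglik=negll,
    )
    return model


_FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _fp_basis(t: np.ndarray, powers: tuple):
    """Fractional-polynomial basis in t (power 0 -> ln t), with repeats."""
    t = np.clip(np.asarray(t, dtype=float), _CLIP_T, None)
    cols = [np.ones_like(t)]
    dcols = [np.zeros_like(t)]
    lt = np.log(t)
    prev = None
    for p in powers:
        if p == 0.0:
            col, dcol = lt, 1.0 / t
        else:
            col, dcol = t**p, p * t ** (p - 1)
        if prev is not None and p == prev:
            # repeated power: t^p ln t
            if p == 0.0:
                col, dcol = lt**2, 2 * lt / t
            else:
                col = t**p * lt
                dcol = t ** (p - 1) * (p * lt + 1)
        cols.append(col)
        dcols.append(dcol)
        prev = p
    return np.column_stack(cols), np.column_stack(dcols)


def _fit_fp_single(t, e, powers, family_id) -> FittedSurvivalModel:
    """FP model for ln H(t); H monotone enforced by penalty."""
    ev = e == 1
    B, dB = _fp_basis(t, powers)
    pen_t = np.linspace(t.min(), t.max(), 41)
    Bp, dBp = _fp_basis(pen_t, powers)

    def negll(beta):
        lH = B @ beta
        dlH = dB @ beta  # d lnH/dt
        pen = 1e6 * np.square(np.clip(-(dBp @ beta) + 1e-12, 0.0, None)).sum()
        H = np.exp(np.clip(lH, -700, 700))
        with np.errstate(all="ignore"):
            log_h = lH + np.log(np.clip(dlH, _TINY, None))
            ll = (log_h[ev] - H[ev]).sum() + (-H[~ev]).sum()
        val = -ll + pen
        return val if np.isfinite(val) else 1e12

    wb = fit_parametric((t, e), "weibull")
    kk, ss = wb.params["shape"], wb.params["scale"]
    beta0 = np.zeros(B.shape[1])
    # crude start: match ln H at the median event time with a flat basis
    beta0[0] = kk * (np.log(np.median(t[ev])) - np.log(ss))
    starts = [beta0, beta0 + 0.1, np.zeros(B.shape[1])]
    res = _optimize(negll, starts)
    beta = res.x

    def logsf(theta, tt):
        Bq, _ = _fp_basis(tt, powers)
        return -np.exp(np.clip(Bq @ theta, -700, 700))

    def logpdf(theta, tt):
        Bq, dBq = _fp_basis(tt, powers)
        lH = np.clip(Bq @ theta, -700, 700)
        return lH + np.log(np.clip(dBq @ theta, _TINY, None)) - np.exp(lH)

    params = {f"beta{i}": float(b) for i, b in enumerate(beta)}
    params["powers"] = list(powers)
    return FittedSurvivalModel(
        family_id, params, beta, -float(res.fun), len(beta), len(t),
        converged=bool(np.isfinite(res.fun)), message=str(res.message),
        _logsf=logsf, _logpdf=logpdf, _negloglik=negll,
    )


def _fit_fp(t, e, order: int, family_id: str) -> FittedSurvivalModel:
    if order == 1:
        combos = [(p,) for p in _FP_POWERS]
    else:
        combos = [(p1, p2) for i, p1 in enumerate(_FP_POWERS)
                  for p2 in _FP_POWERS[i:]]
    best = None
    for powers in combos:
        try:
            m = _fit_fp_single(t, e, powers, family_id)
        except FitError:
            continue
        if best is None or m.loglik > best.loglik:
            best = m
    if best is None:
        raise FitError(f"no {family_id} power combination converged")
    return best


def _fit_mcm(t, e, latency: str, family_id: str,
             fix_pi: float | None = None) -> FittedSurvivalModel:
    """Mixture cure: S(t) = pi + (1 - pi) S_u(t), pi on the logit scale."""
    if latency not in _STANDARD:
        raise KeyError(f"unknown latency family {latency!r}")
    fam = _STANDARD[latency]
    ev = e == 1

    def split(theta):
        if fix_pi is not None:
            return fix_pi, theta
        return special.expit(theta[0]), theta[1:]

    def logsf(theta, tt):
        pi, th = split(theta)
        su = np.exp(fam.logsf(th, tt))
        return np.log(np.clip(pi + (1 - pi) * su, _TINY, None))

    def logpdf(theta, tt):
        pi, th = split(theta)
        return np.log(np.clip(1 - pi, _TINY, None)) + fam.logpdf(th, tt)

    def negll(theta):
        with np.errstate(all="ignore"):
            ll = logpdf(theta, t[ev]).sum() + logsf(theta, t[~ev]).sum()
        return -ll if np.isfinite(ll) else 1e12

    base_starts = fam.inits(t, e)
    if fix_pi is not None:
        starts = base_starts
        k_free = len(base_starts[0])
    else:
        cens_frac = 1.0 - e.mean()
        p0 = np.clip(cens_frac * 0.8 + 0.05, 0.02, 0.9)
        starts = []
        for b in base_starts:
            for p in (p0, 0.1, 0.4):
                starts.append(np.concatenate([[special.logit(p)], b]))
        k_free = len(base_starts[0]) + 1
    res = _optimize(negll, starts)
    theta = res.x
    pi, th = split(theta)
    params = {"cure_fraction": float(pi), **{f"latency_{k}": v
              for k, v in fam.natural(th).items()}, "latency": latency}
    boundary = fix_pi is None and (pi < 1e-3 or pi > 1 - 1e-3)
    msg = str(res.message)
    if boundary:
        msg += " | cure fraction at boundary"
        logger.warning("mixture-cure fraction at boundary: pi=%.4g", pi)
    return FittedSurvivalModel(
        family_id, params, theta, -float(res.fun), k_free, len(t),
        converged=bool(np.isfinite(res.fun)), message=msg,
        _logsf=logsf, _logpdf=logpdf, _negloglik=negll,
    )


def fit_flexible(data, kind: str, scale: str = "hazard", n_knots: int = 1,
                 powers_order: int = 1, latency: str = "weibull",
                 fix_cure_fraction: float | None = None) -> FittedSurvivalModel:
    """Fit a flexible extrapolation model.

    kind: "rp" (Royston-Parmar spline; ``scale`` in hazard/odds/normal,
    ``n_knots`` interior knots), "fp" (fractional polynomial of order
    ``powers_order`` on the log-cumulative-hazard scale, powers selected by
    deviance), "mixture_cure" (``latency`` from the standard registry), or
    "gam" (registered, not parameterized here).
    """
    if kind == "gam":
        raise NotImplementedError("GAM family is registered but not available")
    t, e = _extract(data)
    if kind == "rp":
        if n_knots < 0:
            raise ValueError("n_knots must be >= 0")
        return _fit_rp(t, e, scale, n_knots, f"rp_{scale}")
    if kind == "fp":
        if powers_order not in (1, 2):
            raise ValueError("powers_order must be 1 or 2")
        return _fit_fp(t, e, powers_order, f"fp{powers_order}")
    if kind == "mixture_cure":
        return _fit_mcm(t, e, latency, "mixture_cure", fix_pi=fix_cure_fraction)
    raise KeyError(f"unknown flexible kind {kind!r}")


def fit_by_id(data, family_id: str, **kw) -> FittedSurvivalModel:
    """Registry dispatch: standard family name or flexible id (rp_hazard...)."""
    if family_id in _STANDARD:
        return fit_parametric(data, family_id)
    if family_id.startswith("rp_"):
        return fit_flexible(data, "rp", scale=family_id[3:], **kw)
    if family_id in ("fp1", "fp2"):
        return fit_flexible(data, "fp", powers_order=int(family_id[2]), **kw)
    if family_id == "mixture_cure":
        return fit_flexible(data, "mixture_cure", **kw)
    if family_id == "gam":
        return fit_flexible(data, "gam")
    raise KeyError(f"unknown family id {family_id!r}")


# --------------------------------------------------------------------------
# comparison & transition probabilities
# --------------------------------------------------------------------------

_REGISTRY_ORDER = STANDARD_FAMILIES + FLEXIBLE_FAMILIES
_LANDMARKS_MONTHS = {"S_2y": 24.0, "S_5y": 60.0, "S_10y": 120.0}


def compare_models(fits: list, policy: str = "conservative"):
    """Rank fits by AIC and select one.

    Policy "aic" takes the AIC-best fit. Policy "conservative" takes, among
    converged fits within 3 AIC units of the best, the one with the lowest
    extrapolated 10-year survival (guarding against over-optimistic tails).
    Ties break by BIC, then registry order.

    Returns (comparison table, selected model).
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for m in fits:
        lm = {k: float(m.sf(v)) if m.converged else np.nan
              for k, v in _LANDMARKS_MONTHS.items()}
        rows.append({"family": m.family, "converged": m.converged,
                     "loglik": m.loglik, "aic": m.aic, "bic": m.bic, **lm})
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    ok = [m for m in fits if m.converged]
    if not ok:
        raise FitError("no converged fits to select from")

    def order_key(m):
        idx = _REGISTRY_ORDER.index(m.family) if m.family in _REGISTRY_ORDER else 99
        return (m.bic, idx)

    best_aic = min(m.aic for m in ok)
    if policy == "aic":
        cands = [m for m in ok if m.aic <= best_aic + 1e-12]
        selected = min(cands, key=order_key)
    elif policy == "conservative":
        cands = [m for m in ok if m.aic <= best_aic + 3.0]
        selected = min(cands, key=lambda m: (float(m.sf(120.0)),) + order_key(m))
    else:
        raise KeyError(f"unknown selection policy {policy!r}")
    return table, selected


def transition_probability(model: FittedSurvivalModel, cycle_index: int,
                           cycle_len: float) -> float:
    """Per-cycle conditional event probability 1 - S(t_{u+1})/S(t_u)."""
    t0 = cycle_index * cycle_len
    t1 = (cycle_index + 1) * cycle_len
    s0 = float(model.sf(t0))
    if s0 <= 0.0:
        warnings.warn(f"S(t)=0 at cycle {cycle_index}; transition probability set to 1")
        return 1.0
    p = 1.0 - float(model.sf(t1)) / s0
    return float(np.clip(p, 0.0, 1.0))
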