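"""Pseudo-IPD reconstruction from digitized Kaplan-Meier evidence.

Published KM figures carry more information than the curve alone: the
number-at-risk table constrains how many censorings occurred inside each
reporting interval. The reconstruction here follows the standard
iterative scheme (Guyot et al.): within each risk-table interval,
censoring times are assumed uniform, and the interval's censoring count
is adjusted until the implied number at risk at the next boundary matches
the published one; event counts at each digitized drop then follow from
the product-limit relation.

When the published total event count is supplied it is used to rescale
the inferred event counts; by default reconstruction relies on the
drop-and-risk-table system alone.
"""

from __future__ import annotations

import logging

import numpy as np
from lifelines import KaplanMeierFitter

from .ipd import DigitizedCurve, PseudoIPD, StepCurve

__all__ = ["reconstruct_ipd", "km_estimator"]

logger = logging.getLogger(__name__)


def _prepare(curve: DigitizedCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Validate, repair digitizer noise, and align clicks with risk times.

    Survival values are monotonized by a running minimum and clipped to
    [0, 1] (manual digitization is noisy); a click is interpolated at any
    risk-table boundary that lacks one so that boundaries are exact.
    """
    t = np.asarray(curve.times, dtype=float)
    s = np.asarray(curve.survival, dtype=float)
    rt = np.asarray(curve.risk_times, dtype=float)
    nr = np.asarray(curve.n_at_risk, dtype=float)

    if len(rt) < 2:
        raise ValueError("need at least 2 risk-table entries")
    if np.any(np.diff(rt) <= 0):
        raise ValueError("risk-table times must be strictly increasing")
    if np.any(np.diff(nr) > 0):
        raise ValueError("inconsistent risk table: number at risk increases")
    if len(t) < 2 or t[0] != 0:
        raise ValueError("curve must start at time 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("curve times must be nondecreasing")

    fixed = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    fixed[0] = 1.0
    if not np.allclose(fixed, s):
        logger.warning("digitized survival repaired (monotonized/clipped)")
    s = fixed

    # insert an interpolated click at any boundary without one; boundaries
    # beyond the last click carry the last digitized value
    for b in rt:
        if not np.any(np.isclose(t, b)):
            sb = np.interp(b, t, s) if b <= t[-1] else s[-1]
            i = np.searchsorted(t, b)
            t = np.insert(t, i, b)
            s = np.insert(s, i, sb)
    return t, s, rt, nr


def reconstruct_ipd(
    curve: DigitizedCurve, total_events: int | None = None, arm: str | None = None
) -> PseudoIPD:
    """Rebuild per-subject records from a digitized curve + risk table.

    Within each risk interval censorings are spread uniformly and their
    count iterated until the implied next-interval number at risk matches
    the table. In the final interval (no closing boundary) no interior
    censoring is assumed: events come from the remaining curve drops and
    everyone still at risk is censored at the last digitized time.
    """
    t, s, rt, nr = _prepare(curve)
    label = arm if arm is not None else (curve.label or "arm")
    n_clicks = len(t)
    boundary = np.searchsorted(t, rt - 1e-9)  # click index at each risk time

    d = np.zeros(n_clicks)  # events at click k
    emit_time = t.copy()  # where each click's events are placed in the IPD
    censor_times: list[float] = []
    km_prev = 1.0
    n_enter = float(nr[0])

    # a click at time tau carries the drop accumulated since the previous
    # click, so the click sitting on a risk boundary closes the *preceding*
    # interval; each interval therefore runs over clicks first..last inclusive
    for i in range(len(rt)):
        first = int(boundary[i]) + (1 if i > 0 else 0)
        if i < len(rt) - 1:
            last = int(boundary[i + 1])
            span = (rt[i], rt[i + 1])
            target = float(nr[i + 1])
            # initial censoring guess from the survival ratio
            ncen = int(round(n_enter * s[last] / max(s[first], 1e-12) - target))
            ncen = max(ncen, 0)
            best = None
            for _ in range(60):
                ct = [
                    span[0] + (j + 1) * (span[1] - span[0]) / (ncen + 1)
                    for j in range(ncen)
                ]
                c_k = np.zeros(n_clicks)
                for x in ct:
                    k = np.searchsorted(t[: last + 1], x, side="right") - 1
                    c_k[min(k, last - 1)] += 1
                n_hat = n_enter
                km = km_prev
                d_k = np.zeros(n_clicks)
                for k in range(first, last + 1):
                    if km > 0 and n_hat > 0:
                        d_k[k] = min(round(n_hat * (1.0 - s[k] / km)), n_hat)
                        if d_k[k] > 0:
                            km = km * (1.0 - d_k[k] / n_hat)
                    n_hat = n_hat - d_k[k] - c_k[k]
                gap = n_hat - target
                cand = (abs(gap), ncen, d_k, c_k, ct, n_hat, km)
                if best is None or cand[0] < best[0]:
                    best = cand
                if abs(gap) < 0.5:
                    break
                ncen_next = max(int(ncen + gap), 0)
                if ncen_next == ncen:
                    break
                ncen = ncen_next
            _, _, d_k, c_k, ct, n_hat, km = best
            d[first:last + 1] = d_k[first:last + 1]
            # the boundary click's drop happened strictly before the
            # boundary (subjects lost there are absent from the next
            # at-risk count); emit those events inside their bin
            prev_t = t[last - 1] if last > first else rt[i]
            emit_time[last] = (prev_t + t[last]) / 2.0
            censor_times.extend(ct)
            km_prev = km
            n_enter = float(nr[i + 1])
        else:
            # final interval: events from drops, remainder censored at end
            n_hat = n_enter
            km = km_prev
            for k in range(first, n_clicks):
                if km > 0 and n_hat > 0:
                    d[k] = min(round(n_hat * (1.0 - s[k] / km)), n_hat)
                    if d[k] > 0:
                        km = km * (1.0 - d[k] / n_hat)
                        n_hat -= d[k]
            censor_times.extend([t[-1]] * int(round(n_hat)))

    if total_events is not None and d.sum() > 0:
        d = _rescale_counts(d, total_events)

    times: list[float] = []
    events: list[int] = []
    for k in range(n_clicks):
        cnt = int(round(d[k]))
        times.extend([emit_time[k]] * cnt)
        events.extend([1] * cnt)
    times.extend(censor_times)
    events.extend([0] * len(censor_times))
    if not times:
        raise ValueError("reconstruction produced no records")
    order = np.argsort(times, kind="stable")
    return PseudoIPD(
        np.asarray(times)[order],
        np.asarray(events)[order],
        np.full(len(times), label, dtype=object),
    )


def _rescale_counts(d: np.ndarray, total: int) -> np.ndarray:
    """Rescale integer event counts to a published total (largest remainder)."""
    if total < 0:
        raise ValueError("total_events must be nonnegative")
    raw = d * total / d.sum()
    out = np.floor(raw)
    rem = raw - out
    short = int(round(total - out.sum()))
    if short > 0:
        for k in np.argsort(-rem)[:short]:
            out[k] += 1
    return out


def km_estimator(ipd: PseudoIPD) -> StepCurve:
    """Product-limit estimate of the survival function.

    Ties between events and censorings at the same time are handled the
    usual way: events are processed first, so tied censored subjects still
    count as at risk for the event.
    """
    if np.any(ipd.time < 0):
        raise ValueError("negative time")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_
    bp = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    if bp[0] != 0:
        bp = np.insert(bp, 0, 0.0)
        vals = np.insert(vals, 0, 1.0)
    return StepCurve(bp, vals)
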