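"""Right-censored survival primitives: Kaplan–Meier, Nelson–Aalen, log-rank.

These are implemented from first principles so that every downstream step of
the cut-point search and signature construction rests on a single, fully
specified estimator rather than on library defaults.

Conventions (the standard right-continuous ones):

* a censored observation tied with an event time is counted at risk at that
  time;
* the Kaplan–Meier product runs over distinct *event* times only;
* the k-group log-rank statistic uses the full hypergeometric
  variance–covariance matrix (for k = 2 this reduces to the familiar
  O−E over its variance) and is referred to a χ² distribution on k−1 df;
* Greenwood's variance feeds a 95 % confidence interval on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort_io import SurvivalOutcome
from .errors import DomainError

__all__ = [
    "KMCurve",
    "CumHazardCurve",
    "LogRankResult",
    "kaplan_meier",
    "median_time",
    "nelson_aalen",
    "log_rank",
    "km_confidence_interval",
    "restricted_mean",
]


def _as_time_event(outcomes: Iterable) -> tuple[np.ndarray, np.ndarray]:
    times, events = [], []
    for o in outcomes:
        if hasattr(o, "time"):
            t, e = o.time, o.event
        else:
            t, e = o
        times.append(float(t))
        events.append(bool(e))
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise DomainError("empty outcome sequence")
    if np.any(t < 0):
        raise DomainError("survival times must be >= 0")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times.

    ``survival[i]`` is S(t) for ``event_times[i] <= t < event_times[i+1]``;
    S = 1 before the first event time.  ``greenwood_variance`` is Greenwood's
    estimate of Var[S(t)].
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_variance: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """S(t) as a right-continuous step function."""
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass(frozen=True)
class CumHazardCurve:
    """Nelson–Aalen estimate H(t) = Σ_{tᵢ≤t} dᵢ/nᵢ at distinct event times."""

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def hazard_at(self, t: float) -> float:
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 0.0 if i < 0 else float(self.cumulative_hazard[i])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]


def _event_table(t: np.ndarray, e: np.ndarray):
    """Distinct event times with at-risk and event counts."""
    et = np.unique(t[e])
    # counted at risk: everyone with observed time >= event time
    ts = np.sort(t)
    n_at_risk = t.size - np.searchsorted(ts, et, side="left")
    te = np.sort(t[e])
    d = (np.searchsorted(te, et, side="right")
         - np.searchsorted(te, et, side="left"))
    return et, n_at_risk.astype(float), d.astype(float)


def kaplan_meier(outcomes: Iterable) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Accepts :class:`SurvivalOutcome` objects or ``(time, event)`` pairs.
    With no events the curve is identically 1.
    """
    t, e = _as_time_event(outcomes)
    et, n, d = _event_table(t, e)
    frac = np.ones_like(et) if et.size == 0 else 1.0 - d / n
    surv = np.cumprod(frac)
    # Greenwood: Var[S] = S^2 * cumsum(d / (n (n - d))); 0 where S has hit 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    var = surv ** 2 * np.cumsum(terms)
    return KMCurve(event_times=et, n_at_risk=n, n_events=d,
                   survival=surv, greenwood_variance=var, n_total=t.size)


def median_time(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) ≤ 0.5; ``None`` when never reached."""
    idx = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if idx.size == 0:
        return None
    return float(curve.event_times[idx[0]])


def restricted_mean(curve: KMCurve, tau: float | None = None) -> float:
    """Area under the KM curve up to ``tau`` (default: last event time)."""
    if curve.event_times.size == 0:
        return float(tau) if tau is not None else 0.0
    if tau is None:
        tau = float(curve.event_times[-1])
    knots = np.concatenate(([0.0], curve.event_times))
    s = np.concatenate(([1.0], curve.survival))
    knots = np.clip(knots, None, tau)
    widths = np.diff(np.concatenate((knots, [tau])))
    return float(np.sum(s * np.clip(widths, 0.0, None)))


def km_confidence_interval(curve: KMCurve, alpha: float = 0.05):
    """Greenwood 95 % CI computed on the log-survival scale, clipped to [0,1]."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # Var[log S] = cumsum d / (n (n - d))
        terms = np.where(curve.n_at_risk > curve.n_events,
                         curve.n_events / (curve.n_at_risk *
                                           (curve.n_at_risk - curve.n_events)),
                         np.inf)
        se_log = np.sqrt(np.cumsum(terms))
        lo = curve.survival * np.exp(-z * se_log)
        hi = curve.survival * np.exp(z * se_log)
    lo = np.where(curve.survival > 0, np.clip(lo, 0.0, 1.0), 0.0)
    hi = np.where(curve.survival > 0, np.clip(hi, 0.0, 1.0), 0.0)
    return lo, hi


def nelson_aalen(outcomes: Iterable) -> CumHazardCurve:
    """Nelson–Aalen cumulative-hazard estimator H(t) = Σ dᵢ/nᵢ."""
    t, e = _as_time_event(outcomes)
    et, n, d = _event_table(t, e)
    return CumHazardCurve(event_times=et, cumulative_hazard=np.cumsum(d / n))


def log_rank(groups: Sequence[Iterable]) -> LogRankResult:
    """k-sample log-rank test on right-censored outcomes.

    ``groups`` is a sequence of ≥ 2 outcome sequences.  Raises
    :class:`DomainError` with fewer than two groups, an empty group, or zero
    events overall.
    """
    if len(groups) < 2:
        raise DomainError("log-rank requires at least 2 groups")
    ts, es, labels = [], [], []
    for g, outcomes in enumerate(groups):
        t, e = _as_time_event(outcomes)
        ts.append(t)
        es.append(e)
        labels.append(np.full(t.size, g))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    lab = np.concatenate(labels)
    return log_rank_arrays(t, e, lab, len(groups))


def log_rank_arrays(times: np.ndarray, events: np.ndarray,
                    labels: np.ndarray, k: int) -> LogRankResult:
    """Array fast path used by the cut-point search (labels in 0..k-1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    et = np.unique(times[events])
    if et.size == 0:
        raise DomainError("log-rank requires at least one event")

    m = et.size
    ng = np.empty((m, k))
    dg = np.empty((m, k))
    for g in range(k):
        tg = np.sort(times[labels == g])
        if tg.size == 0:
            raise DomainError(f"log-rank group {g} is empty")
        ng[:, g] = tg.size - np.searchsorted(tg, et, side="left")
        te = np.sort(times[(labels == g) & events])
        dg[:, g] = (np.searchsorted(te, et, side="right")
                    - np.searchsorted(te, et, side="left"))

    n_t = ng.sum(axis=1)
    d_t = dg.sum(axis=1)
    p = ng / n_t[:, None]
    expected = d_t[:, None] * p

    # hypergeometric variance multiplier per event time
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    V = np.diag(np.einsum("t,tg->g", c, p)) - np.einsum("t,tg,th->gh", c, p, p)

    O = dg.sum(axis=0)
    E = expected.sum(axis=0)
    u = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        chi2 = float(u @ np.linalg.solve(Vr, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(Vr) @ u)
    chi2 = max(chi2, 0.0)
    df = k - 1
    pval = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi_square=chi2, degrees_of_freedom=df,
                         p_value=min(max(pval, 0.0), 1.0),
                         observed=tuple(O), expected=tuple(E))


def curve_to_frame(curve: KMCurve, alpha: float = 0.05):
    """Export a KM curve as a DataFrame (time, at-risk, events, S, CI)."""
    import pandas as pd

    lo, hi = km_confidence_interval(curve, alpha)
    return pd.DataFrame({
        "time": curve.event_times,
        "n_at_risk": curve.n_at_risk.astype(int),
        "n_events": curve.n_events.astype(int),
        "survival": curve.survival,
        "ci_low": lo,
        "ci_high": hi,
    })
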