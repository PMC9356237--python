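"""Maximally selected cut-points for censored outcomes.

Each candidate clinical variable is dichotomised (one threshold) or
trichotomised (two thresholds) at the split that maximises the log-rank χ²
for time to relapse — "the greatest difference in TTR between the groups".
Candidates are the midpoints between consecutive distinct observed values,
subject to a minimum group size; the search is exhaustive and deterministic
(ties broken towards the smallest threshold(s)).

No selection-bias correction is applied to the reported p-values: the χ² of
a maximally selected split is inflated relative to a pre-specified one.
This mirrors the screening procedure the scheme was built with and is
flagged in the report output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort_io import CLICAL_VARIABLES, PatientRecord, clical_value
from .errors import DomainError, SearchError
from .survival_stats import (KMCurve, LogRankResult, kaplan_meier,
                             log_rank_arrays, median_time, restricted_mean)

__all__ = [
    "SearchConfig",
    "CutpointSpec",
    "ScreenResult",
    "candidate_cutpoints",
    "best_dichotomy",
    "best_trichotomy",
    "screen_variables",
    "describe_intervals",
]

log = logging.getLogger(__name__)

DICHOTOMY = "dichotomy"
TRICHOTOMY = "trichotomy"

#: per-variable search form replicating the published five-variable scheme
DEFAULT_DESIGNATIONS: dict[str, str] = {
    "age": DICHOTOMY,
    "performance_status": DICHOTOMY,
    "n_crc_primaries": DICHOTOMY,
    "cea": TRICHOTOMY,
    "n_active_mets": DICHOTOMY,
}


@dataclass(frozen=True)
class SearchConfig:
    """Search constraints.

    min_group_fraction : smallest admissible group as a fraction of the
        non-missing sample (default 0.10 — at least 8 of 85 patients).
    alpha : screening significance level on the log-rank p (default 0.05).
    """

    min_group_fraction: float = 0.10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.min_group_fraction < 0.5:
            raise DomainError("min_group_fraction must be in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class CutpointSpec:
    """An optimised split of one variable.

    ``cutpoints`` are 1 (dichotomy) or 2 (trichotomy) strictly increasing
    thresholds; interval i is ``[cutpoints[i-1], cutpoints[i])`` on the real
    line.  ``interval_subscores[i]`` is the risk sub-score of interval i:
    1 marks the highest-risk interval (shortest KM median TTR), higher
    sub-scores mark progressively lower risk.
    """

    variable: str
    cutpoints: tuple[float, ...]
    interval_subscores: tuple[int, ...]
    chi_square: float | None = None
    p_value: float | None = None
    group_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.cutpoints) not in (1, 2):
            raise DomainError("a spec has 1 or 2 cutpoints")
        if any(a >= b for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise DomainError("cutpoints must be strictly increasing")
        if sorted(self.interval_subscores) != list(range(1, len(self.cutpoints) + 2)):
            raise DomainError("interval_subscores must be a permutation of 1..k")

    def interval_of(self, value: float) -> int:
        """0-based interval index of a value."""
        return int(np.searchsorted(np.asarray(self.cutpoints), value, side="right"))

    def subscore_of(self, value: float) -> int:
        return self.interval_subscores[self.interval_of(value)]

    @property
    def n_intervals(self) -> int:
        return len(self.cutpoints) + 1


def _interval_label(i: int, cuts: Sequence[float]) -> str:
    """Human-readable interval label, integer-style (64.5 shown as '<65')."""
    up = [math.ceil(c) if c != int(c) else int(c) for c in cuts]
    if i == 0:
        return f"<{up[0]}"
    if i == len(cuts):
        return f"≥{up[-1]}"
    lo, hi = up[i - 1], up[i]
    return f"{lo}–{hi - 1}" if hi - 1 > lo else f"{lo}"


def describe_intervals(spec: CutpointSpec) -> str:
    """Render a spec in the ``'<65 vs ≥65'`` style, highest risk first."""
    order = np.argsort(spec.interval_subscores)
    return " vs ".join(_interval_label(int(i), spec.cutpoints) for i in order)


def _min_group_size(config: SearchConfig, n: int) -> int:
    """Smallest admissible group: ⌊fraction·n⌋ but never below 2.

    The floor keeps an 8-patient group admissible at n = 85 with the default
    0.10 fraction; the lower bound of 2 rules out single-observation groups
    in small samples."""
    return max(2, math.floor(config.min_group_fraction * n))


def candidate_cutpoints(values: Iterable[float], config: SearchConfig,
                        n_total: int | None = None) -> np.ndarray:
    """Midpoints between consecutive distinct values, group-size filtered.

    A threshold is kept only if both resulting groups hold at least
    ``min_group_fraction × n`` observations.  All-identical input yields an
    empty array.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size < 2:
        raise DomainError("need at least 2 values")
    distinct = np.unique(v)
    if distinct.size < 2:
        return np.empty(0)
    n = n_total if n_total is not None else v.size
    min_size = _min_group_size(config, n)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    below = np.searchsorted(v, mids, side="left")
    keep = (below >= min_size) & (v.size - below >= min_size)
    return mids[keep]


def _drop_missing(values, outcomes):
    v, t, e = [], [], []
    for val, out in zip(values, outcomes):
        if val is None or (isinstance(val, float) and math.isnan(val)) or out is None:
            continue
        v.append(float(val))
        t.append(out.time if hasattr(out, "time") else out[0])
        e.append(out.event if hasattr(out, "event") else out[1])
    return (np.asarray(v), np.asarray(t, dtype=float), np.asarray(e, dtype=bool))


def _risk_order(outcome_groups: list[tuple[np.ndarray, np.ndarray]]) -> list[int]:
    """Interval indices sorted worst → best survival.

    Primary key: KM median (not-reached counts as +inf); secondary:
    restricted mean survival; final: interval index (total, deterministic
    order)."""
    keys = []
    for i, (t, e) in enumerate(outcome_groups):
        curve = kaplan_meier(list(zip(t, e)))
        med = median_time(curve)
        keys.append((math.inf if med is None else med, restricted_mean(curve), i))
    return [k[2] for k in sorted(keys)]


def _build_spec(variable: str, cuts: tuple[float, ...], v, t, e,
                result: LogRankResult) -> CutpointSpec:
    k = len(cuts) + 1
    labels = np.searchsorted(np.asarray(cuts), v, side="right")
    groups = [(t[labels == i], e[labels == i]) for i in range(k)]
    order = _risk_order(groups)
    subscores = [0] * k
    for rank, interval in enumerate(order, start=1):
        subscores[interval] = rank
    sizes = tuple(int((labels == i).sum()) for i in range(k))
    return CutpointSpec(variable=variable, cutpoints=cuts,
                        interval_subscores=tuple(subscores),
                        chi_square=result.chi_square, p_value=result.p_value,
                        group_sizes=sizes)


def best_dichotomy(values: Iterable[float], outcomes: Iterable,
                   config: SearchConfig = SearchConfig(),
                   variable: str = "x") -> CutpointSpec:
    """Exhaustive one-threshold search maximising the 2-group log-rank χ².

    Missing values are dropped pairwise.  Ties in χ² resolve to the smallest
    threshold.  Raises :class:`SearchError` when no admissible candidate
    exists.
    """
    v, t, e = _drop_missing(values, outcomes)
    if v.size < 2:
        raise SearchError(f"{variable}: fewer than 2 non-missing observations")
    cands = candidate_cutpoints(v, config)
    if cands.size == 0:
        raise SearchError(f"{variable}: no admissible cut-point candidates")
    best: tuple[float, LogRankResult] | None = None
    for c in cands:  # ascending → strict '>' keeps the smallest threshold on ties
        labels = (v >= c).astype(int)
        res = log_rank_arrays(t, e, labels, 2)
        if best is None or res.chi_square > best[1].chi_square + 1e-12:
            best = (float(c), res)
    return _build_spec(variable, (best[0],), v, t, e, best[1])


def best_trichotomy(values: Iterable[float], outcomes: Iterable,
                    config: SearchConfig = SearchConfig(),
                    variable: str = "x") -> CutpointSpec:
    """Exhaustive two-threshold search maximising the 3-group log-rank χ².

    All ordered candidate pairs with three admissible group sizes are
    evaluated; ties resolve lexicographically by (lower, upper) threshold.
    """
    v, t, e = _drop_missing(values, outcomes)
    if np.unique(v).size < 3:
        raise SearchError(f"{variable}: fewer than 3 distinct values")
    # single-threshold feasibility is implied by the pairwise checks below
    cands = candidate_cutpoints(v, config)
    if cands.size < 2:
        raise SearchError(f"{variable}: no admissible cut-point pair")
    vs = np.sort(v)
    min_size = _min_group_size(config, v.size)
    best: tuple[tuple[float, float], LogRankResult] | None = None
    for i in range(cands.size - 1):
        c1 = cands[i]
        lo = np.searchsorted(vs, c1, side="left")
        if lo < min_size:
            continue
        for j in range(i + 1, cands.size):
            c2 = cands[j]
            mid = np.searchsorted(vs, c2, side="left") - lo
            hi = v.size - lo - mid
            if mid < min_size or hi < min_size:
                continue
            labels = np.searchsorted(np.asarray([c1, c2]), v, side="right")
            res = log_rank_arrays(t, e, labels, 3)
            if best is None or res.chi_square > best[1].chi_square + 1e-12:
                best = ((float(c1), float(c2)), res)
    if best is None:
        raise SearchError(f"{variable}: no pair satisfies the group-size constraint")
    return _build_spec(variable, best[0], v, t, e, best[1])


@dataclass
class ScreenResult:
    """Outcome of screening several variables against TTR.

    ``selected`` — significant specs, ordered by χ² descending (the scheme
    entering the score); ``rejected`` — non-significant specs with their
    p-values; ``skipped`` — variables with no admissible split, with the
    reason."""

    selected: list[CutpointSpec]
    rejected: list[CutpointSpec]
    skipped: list[tuple[str, str]]


def screen_variables(cohort: Sequence[PatientRecord],
                     designations: dict[str, str] | None = None,
                     config: SearchConfig = SearchConfig()) -> ScreenResult:
    """Optimise and significance-screen each designated variable.

    Patients missing a given variable are excluded pairwise for that
    variable only.  Variables whose optimal split has p ≤ alpha are
    selected; the rest are logged and reported as rejected/skipped.
    """
    designations = dict(DEFAULT_DESIGNATIONS if designations is None else designations)
    if not designations:
        raise DomainError("no variables to screen")
    unknown = set(designations) - set(CLICAL_VARIABLES)
    if unknown:
        raise DomainError(f"unknown variables: {sorted(unknown)}")
    selected, rejected, skipped = [], [], []
    for name, form in designations.items():
        values = [clical_value(r, name) for r in cohort]
        outcomes = [r.ttr for r in cohort]
        search = best_trichotomy if form == TRICHOTOMY else best_dichotomy
        try:
            spec = search(values, outcomes, config, variable=name)
        except (SearchError, DomainError) as exc:
            log.warning("variable %s skipped: %s", name, exc)
            skipped.append((name, str(exc)))
            continue
        if spec.p_value is not None and spec.p_value <= config.alpha:
            selected.append(spec)
        else:
            log.info("variable %s not significant (p = %.3g)", name, spec.p_value)
            rejected.append(spec)
    selected.sort(key=lambda s: (-s.chi_square, s.variable))
    return ScreenResult(selected=selected, rejected=rejected, skipped=skipped)
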