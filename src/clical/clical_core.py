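"""Categorical risk scoring and signature grouping for time to relapse.

Each significant clinical variable contributes an integer sub-score (1, 2 or
3, with 1 the greatest risk) determined by the interval the patient's value
falls into.  The patient's score is the arithmetic mean of the sub-scores;
with four dichotomised variables and one trichotomised variable the
achievable scores form the grid 1.0, 1.2, …, 2.2.

Patients are then partitioned into *signatures* — contiguous blocks of score
values — chosen as the largest number of blocks such that every pair of
adjacent blocks has significantly different relapse-free survival by
log-rank.  Signature I (lowest scores) marks the smallest benefit from
treatment, the top signature the greatest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .cohort_io import PatientRecord, clical_value
from .cutpoint_search import CutpointSpec
from .errors import DomainError, MissingDataError
from .radiobiology import RadiobiologyParams, DEFAULT_PARAMS, classify_intent
from .survival_stats import (KMCurve, LogRankResult, kaplan_meier, log_rank,
                             median_time)

__all__ = [
    "reference_scheme",
    "assign_subscores",
    "clical_score",
    "enumerate_score_grid",
    "ScoreBlock",
    "SignaturePartition",
    "form_signatures",
    "stratified_curves",
    "roman",
]

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def roman(i: int) -> str:
    """1-based Roman numeral label for a signature group."""
    return _ROMAN[i - 1]


def reference_scheme() -> tuple[CutpointSpec, ...]:
    """The five-variable colorectal-SBRT cut-point scheme used as default.

    Age dichotomised at 65 years (< 65 highest risk), performance status at
    2 (≥ 2 highest risk), number of CRC primaries at 2 (≥ 2 highest risk),
    CEA trichotomised at 5 and 10 µg/L (≥ 10 highest risk) and number of
    active metastases at 3 (≥ 3 highest risk).
    """
    return (
        CutpointSpec("age", (65.0,), (1, 2)),
        CutpointSpec("performance_status", (2.0,), (2, 1)),
        CutpointSpec("n_crc_primaries", (2.0,), (2, 1)),
        CutpointSpec("cea", (5.0, 10.0), (3, 2, 1)),
        CutpointSpec("n_active_mets", (3.0,), (2, 1)),
    )


def assign_subscores(record: PatientRecord,
                     specs: Sequence[CutpointSpec]) -> tuple[int, ...]:
    """Map a patient's variable values to per-variable sub-scores.

    Raises :class:`MissingDataError` naming the missing variables — a
    patient with incomplete data is excluded, never scored by default.
    """
    missing = tuple(v.variable for v in specs if clical_value(record, v.variable) is None)
    if missing:
        raise MissingDataError(
            f"patient {record.patient_id} missing {', '.join(missing)}",
            variables=missing)
    return tuple(s.subscore_of(clical_value(record, s.variable)) for s in specs)


def clical_score(subscores: Sequence[int]) -> float:
    """Arithmetic mean of the sub-scores (reported to one decimal)."""
    if len(subscores) == 0:
        raise DomainError("empty sub-score vector")
    return sum(subscores) / len(subscores)


def enumerate_score_grid(specs: Sequence[CutpointSpec]) -> tuple[float, ...]:
    """All achievable scores: means over the Cartesian product of sub-score sets."""
    if len(specs) == 0:
        raise DomainError("need at least one spec")
    sets = [sorted(set(s.interval_subscores)) for s in specs]
    scores = {round(sum(c) / len(c), 9) for c in product(*sets)}
    return tuple(sorted(scores))


# ---------------------------------------------------------------------------
# signature partitioning


@dataclass(frozen=True)
class ScoreBlock:
    label: str                    # Roman numeral, I = lowest scores
    scores: tuple[float, ...]     # contiguous distinct score values
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class SignaturePartition:
    """Contiguous score blocks with adjacent-pair separation evidence."""

    blocks: tuple[ScoreBlock, ...]
    adjacent_tests: tuple[LogRankResult, ...]
    alpha: float

    @property
    def n_groups(self) -> int:
        return len(self.blocks)

    def signature_of(self, score: float) -> str:
        for b in self.blocks:
            if b.scores[0] - 1e-9 <= score <= b.scores[-1] + 1e-9:
                return b.label
        raise KeyError(f"score {score} outside every block")


def _contiguous_partitions(m: int):
    """Yield all 2^(m-1) partitions of positions 0..m-1 into contiguous blocks,
    as tuples of boundary indices (position i in the tuple means a split
    between score i and i+1), in lexicographic order."""
    for mask in range(2 ** (m - 1)):
        yield tuple(i for i in range(m - 1) if mask >> i & 1)


def form_signatures(scores: Sequence[float], outcomes: Sequence,
                    alpha: float = 0.05,
                    patient_ids: Sequence[str] | None = None,
                    pairwise: str = "adjacent") -> SignaturePartition:
    """Partition score values into the largest significantly separated grouping.

    All contiguous partitions of the distinct score values are enumerated.
    A partition is admissible when every pair of adjacent blocks (or, with
    ``pairwise="all"``, every pair of blocks) differs at p ≤ ``alpha`` by
    log-rank.  Among admissible partitions the block count is maximised;
    ties go to the partition with the largest minimum adjacent χ², then to
    the lexicographically earliest boundaries.  If no multi-block partition
    is admissible a single-group partition is returned with a warning.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    if len(scores) != len(outcomes):
        raise DomainError("scores and outcomes must align")
    if patient_ids is None:
        patient_ids = [str(i) for i in range(len(scores))]
    if pairwise not in ("adjacent", "all"):
        raise DomainError("pairwise must be 'adjacent' or 'all'")

    key = [round(float(s), 9) for s in scores]
    distinct = sorted(set(key))
    m = len(distinct)
    by_score = {s: [i for i, v in enumerate(key) if v == s] for s in distinct}

    def block_outcomes(i: int, j: int):
        # scores distinct[i..j] inclusive
        return [outcomes[p] for s in distinct[i:j + 1] for p in by_score[s]]

    test_cache: dict[tuple[int, int, int, int], LogRankResult] = {}

    def pair_test(a0, a1, b0, b1) -> LogRankResult:
        key_ = (a0, a1, b0, b1)
        if key_ not in test_cache:
            test_cache[key_] = log_rank([block_outcomes(a0, a1),
                                         block_outcomes(b0, b1)])
        return test_cache[key_]

    best_boundaries: tuple[int, ...] = ()
    best_k = 1
    best_minchi = -math.inf
    best_tests: list[LogRankResult] = []
    for boundaries in _contiguous_partitions(m):
        k = len(boundaries) + 1
        if k == 1:
            continue
        edges = [-1, *boundaries, m - 1]
        spans = [(edges[i] + 1, edges[i + 1]) for i in range(k)]
        pairs = (list(zip(range(k - 1), range(1, k))) if pairwise == "adjacent"
                 else [(a, b) for a in range(k) for b in range(a + 1, k)])
        ok = True
        adjacent: list[LogRankResult] = []
        minchi = math.inf
        for a, b in pairs:
            res = pair_test(*spans[a], *spans[b])
            if res.p_value > alpha:
                ok = False
                break
            if b == a + 1:
                adjacent.append(res)
                minchi = min(minchi, res.chi_square)
        if not ok:
            continue
        if (k > best_k
                or (k == best_k and minchi > best_minchi + 1e-12)):
            # lexicographically earliest boundaries win exact ties because
            # _contiguous_partitions enumerates them in lexicographic order
            best_k, best_minchi = k, minchi
            best_boundaries, best_tests = boundaries, adjacent

    if best_k == 1 and m > 1:
        warnings.warn("no partition with >= 2 significantly separated groups; "
                      "returning a single signature", stacklevel=2)

    edges = [-1, *best_boundaries, m - 1]
    blocks = []
    for g in range(best_k):
        i, j = edges[g] + 1, edges[g + 1]
        block_scores = tuple(distinct[i:j + 1])
        members = tuple(patient_ids[p] for s in block_scores for p in by_score[s])
        blocks.append(ScoreBlock(label=roman(g + 1), scores=block_scores,
                                 member_ids=members))
    return SignaturePartition(blocks=tuple(blocks),
                              adjacent_tests=tuple(best_tests), alpha=alpha)


# ---------------------------------------------------------------------------
# stratified reporting


def _lung_only(record: PatientRecord) -> bool:
    return all(l.organ_site == "lung" for l in record.course.lesions)


def stratified_curves(partition: SignaturePartition,
                      cohort: Sequence[PatientRecord],
                      stratifier: str,
                      params: RadiobiologyParams = DEFAULT_PARAMS,
                      ) -> dict[tuple[str, str], KMCurve | None]:
    """KM curves of merged low vs high signatures, split by a treatment factor.

    ``stratifier`` is ``"intent"`` (curative vs palliative) or ``"lung_only"``
    (all treated lesions in lung vs any other site).  The low set merges the
    lower half of the signature groups (I–II of four), the high set the rest.
    Empty cells map to ``None``.
    """
    if stratifier not in ("intent", "lung_only"):
        raise DomainError("stratifier must be 'intent' or 'lung_only'")
    by_id = {r.patient_id: r for r in cohort}
    k = partition.n_groups
    n_low = max(1, (k + 1) // 2) if k > 1 else 1
    sets = {
        "-".join(b.label for b in partition.blocks[:n_low]): partition.blocks[:n_low],
        "-".join(b.label for b in partition.blocks[n_low:]): partition.blocks[n_low:],
    } if k > 1 else {partition.blocks[0].label: partition.blocks}

    def stratum_of(r: PatientRecord) -> str:
        if stratifier == "intent":
            return classify_intent(r, params)
        return "lung_only" if _lung_only(r) else "other"

    strata = (("curative", "palliative") if stratifier == "intent"
              else ("lung_only", "other"))
    out: dict[tuple[str, str], KMCurve | None] = {}
    for set_label, blocks in sets.items():
        if not blocks:
            continue
        members = [by_id[pid] for b in blocks for pid in b.member_ids
                   if pid in by_id]
        for stratum in strata:
            cell = [r.ttr for r in members
                    if r.ttr is not None and stratum_of(r) == stratum]
            out[(set_label, stratum)] = kaplan_meier(cell) if cell else None
    return out


def median_table(curves: dict[tuple[str, str], KMCurve | None]):
    """Per-cell KM median months as a DataFrame (None = empty or not reached)."""
    import pandas as pd

    rows = []
    for (group, stratum), curve in sorted(curves.items()):
        med = None if curve is None else median_time(curve)
        rows.append({"signatures": group, "stratum": stratum,
                     "n": 0 if curve is None else curve.n_total,
                     "median_ttr_months": med})
    return pd.DataFrame(rows)
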