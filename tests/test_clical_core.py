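import itertools

import numpy as np
import pytest

from clical.clical_core import (assign_subscores, clical_score,
                                enumerate_score_grid, form_signatures,
                                reference_scheme, stratified_curves)
from clical.cutpoint_search import CutpointSpec
from clical.errors import DomainError, MissingDataError
from clical.survival_stats import kaplan_meier, log_rank, median_time
from clical.synthetic_cohort import generate_cohort

from conftest import make_record, outcomes


class TestSubscores:
    def test_all_highest_risk_profile(self):
        rec = make_record(age=50, ps=2, primaries=2, cea=40.0, mets=4,
                          lesions=((17.0, 3, "lung"),) * 4)
        assert assign_subscores(rec, reference_scheme()) == (1, 1, 1, 1, 1)

    def test_all_lowest_risk_profile(self):
        rec = make_record(age=70, ps=0, primaries=1, cea=2.0, mets=1,
                          lesions=((17.0, 3, "lung"),))
        assert assign_subscores(rec, reference_scheme()) == (2, 2, 2, 3, 2)

    def test_missing_value_signals_exclusion(self):
        rec = make_record(cea=None)
        with pytest.raises(MissingDataError) as exc:
            assign_subscores(rec, reference_scheme())
        assert exc.value.variables == ("cea",)

    def test_boundary_values_fall_in_upper_interval(self):
        # half-open intervals: age 65 is ">=65", CEA 5 is the middle interval
        rec = make_record(age=65, ps=1, primaries=1, cea=5.0, mets=3)
        assert assign_subscores(rec, reference_scheme()) == (2, 2, 2, 2, 1)


class TestScore:
    @pytest.mark.parametrize("subs, expected", [
        ((1, 1, 1, 1, 1), 1.0),
        ((2, 2, 2, 3, 2), 2.2),
        ((2, 1, 2, 2, 2), 1.8),
    ])
    def test_mean_of_subscores(self, subs, expected):
        assert clical_score(subs) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(DomainError):
            clical_score(())


class TestScoreGrid:
    def test_single_dichotomy_grid(self):
        spec = CutpointSpec("x", (1.0,), (1, 2))
        assert enumerate_score_grid([spec]) == (1.0, 2.0)

    def test_reference_scheme_grid(self):
        grid = enumerate_score_grid(reference_scheme())
        assert grid == tuple(pytest.approx(x) for x in
                             (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2))
        assert max(grid) == pytest.approx(2.2)
        assert min(grid) == pytest.approx(1.0)

    def test_every_patient_score_lies_on_grid(self):
        grid = set(enumerate_score_grid(reference_scheme()))
        for r in generate_cohort(seed=9):
            if r.missing_clical_variables():
                continue
            s = clical_score(assign_subscores(r, reference_scheme()))
            assert round(s, 9) in {round(g, 9) for g in grid}


def partition_oracle(scores, outs, alpha):
    """Exhaustive enumeration over all contiguous partitions, recoded
    independently of form_signatures (recursion over first-block length)."""
    distinct = sorted(set(round(s, 9) for s in scores))
    groups = {s: [o for x, o in zip(scores, outs) if round(x, 9) == s]
              for s in distinct}

    def all_partitions(vals):
        if not vals:
            yield []
            return
        for i in range(1, len(vals) + 1):
            for rest in all_partitions(vals[i:]):
                yield [tuple(vals[:i])] + rest

    best = None
    for part in all_partitions(distinct):
        if len(part) >= 2:
            tests = []
            valid = True
            for a, b in zip(part, part[1:]):
                res = log_rank([
                    [o for s in a for o in groups[s]],
                    [o for s in b for o in groups[s]]])
                tests.append(res)
                if res.p_value > alpha:
                    valid = False
            if not valid:
                continue
            key = (len(part), min(t.chi_square for t in tests))
        else:
            key = (1, float("inf"))
        if best is None or key[0] > best[0][0] or (
                key[0] == best[0][0] and key[1] > best[0][1] + 1e-12):
            best = (key, part)
    return tuple(tuple(b) for b in best[1])


class TestSignatures:
    def test_single_shared_score_single_group(self):
        out = outcomes([(t, True) for t in range(1, 9)])
        part = form_signatures([1.4] * 8, out, alpha=0.05)
        assert part.n_groups == 1
        assert part.blocks[0].label == "I"

    def test_two_planted_strata_separate(self, rng):
        n = 200
        scores = np.where(rng.random(n) < 0.5, 1.2, 2.0)
        lam = np.where(scores == 1.2, 0.25, 0.05)
        out = outcomes([(t, True) for t in rng.exponential(1 / lam)])
        part = form_signatures(scores, out, alpha=0.05)
        assert part.n_groups == 2
        assert part.adjacent_tests[0].p_value <= 0.05
        assert part.blocks[0].scores == (1.2,)

    def test_agrees_with_brute_force_oracle(self, rng):
        grid = [1.0, 1.2, 1.4, 1.6, 1.8, 2.0]
        for trial in range(6):
            m = int(rng.integers(2, 7))
            vals = grid[:m]
            scores = rng.choice(vals, size=60)
            lam = 0.05 * (4.0 ** np.asarray(scores))  # higher score, higher hazard
            t = rng.exponential(1 / lam)
            c = rng.uniform(5, 40, 60)
            out = outcomes(list(zip(np.minimum(t, c), t <= c)))
            part = form_signatures(scores, out, alpha=0.05)
            got = tuple(b.scores for b in part.blocks)
            assert got == partition_oracle(scores, out, 0.05)

    def test_partition_invariants(self, rng):
        scores = rng.choice([1.2, 1.4, 1.6, 1.8, 2.0, 2.2], size=150)
        lam = np.where(scores <= 1.4, 0.4, np.where(scores <= 1.8, 0.1, 0.03))
        out = outcomes([(t, True) for t in rng.exponential(1 / lam)])
        part = form_signatures(scores, out, alpha=0.05)
        covered = [s for b in part.blocks for s in b.scores]
        assert covered == sorted(set(round(s, 9) for s in scores))  # contiguous+cover
        assert sum(len(b.member_ids) for b in part.blocks) == 150
        for res in part.adjacent_tests:
            assert res.p_value <= 0.05
        labels = [b.label for b in part.blocks]
        assert labels == ["I", "II", "III", "IV"][:len(labels)]

    def test_no_separation_warns_and_returns_single_group(self, rng):
        scores = rng.choice([1.2, 2.0], size=40)
        out = outcomes([(t, True) for t in rng.exponential(10, 40)])
        with pytest.warns(UserWarning):
            part = form_signatures(scores, out, alpha=1e-6)
        assert part.n_groups == 1


class TestStratifiedCurves:
    def _partition(self, cohort):
        scheme = reference_scheme()
        scored = [(r, clical_score(assign_subscores(r, scheme)))
                  for r in cohort if not r.missing_clical_variables()]
        return form_signatures([s for _, s in scored],
                               [r.ttr for r, _ in scored],
                               patient_ids=[r.patient_id for r, _ in scored]), scored

    def test_all_lung_cohort_has_empty_other_stratum(self):
        cohort = [make_record(pid=f"P{i}", age=50 + i, cea=float(1 + i % 20),
                              mets=1 + i % 3,
                              lesions=((17.0, 3, "lung"),),
                              ttr=(float(1 + i % 12), True))
                  for i in range(40)]
        part, scored = self._partition(cohort)
        cells = stratified_curves(part, cohort, "lung_only")
        for (grp, stratum), curve in cells.items():
            if stratum == "other":
                assert curve is None

    def test_lung_curves_equal_unstratified_when_all_lung(self):
        cohort = generate_cohort(seed=4)
        cohort = [r for r in cohort if not r.missing_clical_variables()]
        import dataclasses
        lung = []
        for r in cohort:
            lesions = tuple(dataclasses.replace(l, organ_site="lung")
                            for l in r.course.lesions)
            lung.append(dataclasses.replace(
                r, course=dataclasses.replace(r.course, lesions=lesions)))
        part, scored = self._partition(lung)
        cells = stratified_curves(part, lung, "lung_only")
        by_id = {r.patient_id: r for r in lung}
        for (grp, stratum), curve in cells.items():
            if curve is None:
                continue
            labels = grp.split("-")
            members = [pid for b in part.blocks if b.label in labels
                       for pid in b.member_ids]
            whole = kaplan_meier([by_id[p].ttr for p in members])
            assert np.allclose(curve.survival, whole.survival)

    def test_patient_order_invariance(self):
        cohort = list(generate_cohort(seed=6))
        part, _ = self._partition(cohort)
        a = stratified_curves(part, cohort, "intent")
        b = stratified_curves(part, cohort[::-1], "intent")
        for key in a:
            if a[key] is None:
                assert b[key] is None
            else:
                assert np.allclose(a[key].survival, b[key].survival)
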