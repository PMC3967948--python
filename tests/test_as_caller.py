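"""The four-filter cascade: Fisher test, error rate, fold change, support."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tbxsplice.as_caller import (
    ASThresholds,
    Direction,
    bayesian_error_rate,
    build_contingency,
    call_events,
    classify_direction,
    fisher_exact_two_sided,
    fold_change,
)
from tbxsplice.exon_quant import DataIntegrityError

from .conftest import make_counts, make_event


def exact_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact-integer enumeration (math.comb).

    Ties admitted under the same 1e-7 relative rule as the implementation,
    evaluated in exact integer arithmetic.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w * 10**9 <= w_obs * (10**9 + 100))
    return num / math.comb(n, c1)


class TestFisher:
    def test_perfect_homogeneity(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_perfect_separation(self):
        # only the two extreme tables are as improbable: p = 2 / C(20,10)
        p = fisher_exact_two_sided([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_degenerate_margins_give_one(self):
        assert fisher_exact_two_sided([[0, 0], [0, 0]]) == 1.0
        assert fisher_exact_two_sided([[3, 5], [0, 0]]) == 1.0
        assert fisher_exact_two_sided([[0, 5], [0, 7]]) == 1.0

    def test_matches_exact_enumeration_small_margins(self):
        """Every table with margins <= 12 agrees with the integer oracle."""
        M = 12
        for r1 in range(M + 1):
            for r2 in range(M + 1):
                for c1 in range(max(0, r1 + r2 - M), min(M, r1 + r2) + 1):
                    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                        t = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                        expected = exact_fisher_oracle(a, r1 - a, c1 - a, r2 - (c1 - a))
                        assert fisher_exact_two_sided(t) == pytest.approx(
                            expected, rel=1e-7
                        ), t

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 40, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            _, p_ref = stats.fisher_exact(t, alternative="two-sided")
            assert fisher_exact_two_sided(t) == pytest.approx(p_ref, rel=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 60), min_size=4, max_size=4))
    def test_invariant_under_transposition(self, cells):
        a, b, c, d = cells
        t = np.array([[a, b], [c, d]])
        assert fisher_exact_two_sided(t) == pytest.approx(
            fisher_exact_two_sided(t.T), rel=1e-9
        )


class TestContingency:
    def test_replicates_pool_by_summation(self):
        rows = [
            ("ev1", "c1", "control", "anterior", 1, 10, 40, 1000),
            ("ev1", "c2", "control", "anterior", 2, 12, 44, 1000),
            ("ev1", "m1", "mutant", "anterior", 1, 2, 41, 1000),
            ("ev1", "m2", "mutant", "anterior", 2, 3, 39, 1000),
        ]
        table = build_contingency(make_counts(rows), "ev1", "anterior")
        assert table.tolist() == [[22, 62], [5, 75]]

    def test_all_zero_counts_give_zero_table(self):
        rows = [
            ("ev1", "c1", "control", "anterior", 1, 0, 0, 10),
            ("ev1", "m1", "mutant", "anterior", 1, 0, 0, 10),
        ]
        assert build_contingency(make_counts(rows), "ev1", "anterior").tolist() == [[0, 0], [0, 0]]

    def test_single_replicate_equals_its_counts(self):
        rows = [
            ("ev1", "c1", "control", "anterior", 1, 7, 30, 100),
            ("ev1", "m1", "mutant", "anterior", 1, 4, 28, 100),
        ]
        assert build_contingency(make_counts(rows), "ev1", "anterior").tolist() == [[7, 23], [4, 24]]

    def test_missing_group_errors(self):
        rows = [("ev1", "c1", "control", "anterior", 1, 7, 30, 100)]
        with pytest.raises(ValueError, match="mutant"):
            build_contingency(make_counts(rows), "ev1", "anterior")


class TestFoldChange:
    def test_equal_is_one(self):
        assert fold_change(0.5, 0.5) == 1.0

    def test_exact_ratio(self):
        assert fold_change(0.6, 0.3) == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.5)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(1e-6, 1e6, allow_nan=False),
        b=st.floats(1e-6, 1e6, allow_nan=False),
    )
    def test_symmetric_and_at_least_one(self, a, b):
        assert fold_change(a, b) == fold_change(b, a) >= 1.0


class TestBayesianErrorRate:
    def test_single_event_p_one_caps_at_one(self):
        assert bayesian_error_rate([1.0]) == pytest.approx([1.0])

    def test_matches_direct_formula_evaluation(self, rng):
        """Small signal among uniform nulls: agrees with a literal loop over
        the defining formula, and the signal events clear the 0.1 bound."""
        p = np.concatenate([np.full(10, 0.001), rng.uniform(size=90)])
        ber = bayesian_error_rate(p)
        m = p.size
        pi0 = min(1.0, np.mean(p > 0.5) / 0.5)
        ranked = np.sort(p)
        for i, pi in enumerate(p):
            candidates = [
                pi0 * t * m / (np.searchsorted(ranked, t, side="right"))
                for t in ranked
                if t >= pi
            ]
            assert ber[i] == pytest.approx(min(1.0, min(candidates)), rel=1e-9)
        assert (ber[:10] <= 0.1).all()

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        ber = bayesian_error_rate(p)
        order = np.argsort(p)
        assert (np.diff(ber[order]) >= -1e-12).all()

    def test_thresholding_controls_false_discovery_proportion(self):
        """All-null vectors: events passing ber <= 0.1 are a tiny fraction
        (empirical FDP over 20 seeded replicates)."""
        called = total_discoveries = 0
        for seed in range(20):
            p = np.random.default_rng(seed).uniform(size=2000)
            ber = bayesian_error_rate(p)
            called += (ber <= 0.1).sum()
            total_discoveries += 2000
        assert called / total_discoveries <= 0.005  # nulls almost never pass

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            bayesian_error_rate([])


class TestDirection:
    def test_mutant_loss_means_factor_promotes_inclusion(self):
        assert classify_direction(0.7, 0.3) is Direction.INCLUSION

    def test_mutant_gain_means_factor_promotes_skipping(self):
        assert classify_direction(0.3, 0.7) is Direction.SKIPPING

    def test_equal_is_none(self):
        assert classify_direction(0.5, 0.5) is Direction.NONE

    def test_min_delta_dead_zone(self):
        assert classify_direction(0.52, 0.50, min_delta=0.05) is Direction.NONE


def _toy_counts_five_events():
    """Hand-constructed compartment where exactly ev1 and ev2 pass all four
    filters: ev3 fails only support, ev4 is null, ev5 fails only fold change."""
    lib = 100_000
    spec = {
        # event: per-replicate (ctl_exon, ctl_gene, mut_exon, mut_gene)
        "ev1": (80, 1000, 20, 1000),
        "ev2": (60, 1000, 30, 1000),
        "ev3": (3, 40, 0, 40),
        "ev4": (50, 1000, 50, 1000),
        "ev5": (260, 2000, 200, 2000),
    }
    rows = []
    for ev, (ce, cg, me, mg) in spec.items():
        for rep in (1, 2):
            rows.append((ev, f"c{rep}", "control", "anterior", rep, ce, cg, lib))
            rows.append((ev, f"m{rep}", "mutant", "anterior", rep, me, mg, lib))
    return make_counts(rows)


def _toy_annotation_five_events():
    # all events: alt exon 100 bp of a 1000 bp exonic gene
    exons = ((0, 450), (1000, 1100), (2000, 2450))
    return [make_event(event_id=f"ev{i}", gene_id=f"g{i}", exons=exons) for i in range(1, 6)]


class TestCallEvents:
    def test_hand_worked_filter_trace(self):
        counts = _toy_counts_five_events()
        calls = {c.event_id: c for c in call_events(counts, _toy_annotation_five_events())}
        assert {e for e, c in calls.items() if c.significant} == {"ev1", "ev2"}
        # ev3: strong usage shift but only 6 supporting reads
        assert calls["ev3"].pass_fc and not calls["ev3"].pass_support
        # ev4: no shift at all
        assert not calls["ev4"].pass_p and not calls["ev4"].pass_fc
        # ev5: clearly significant shift, fold change 1.3 < 1.5
        assert calls["ev5"].pass_p and not calls["ev5"].pass_fc
        assert calls["ev1"].direction is Direction.INCLUSION
        assert calls["ev1"].fc == pytest.approx(4.0, rel=0.01)

    def test_vacuous_thresholds_pass_every_informative_event(self):
        counts = _toy_counts_five_events()
        calls = call_events(
            counts, _toy_annotation_five_events(), ASThresholds(1.0, 1.0, 1.0, 0)
        )
        assert all(c.significant for c in calls if c.informative)

    def test_support_veto_at_printed_bound(self):
        """14 supporting reads with an extreme p still fail (the bound is 15)."""
        lib = 100_000
        rows = []
        for rep in (1, 2):
            rows.append(("ev1", f"c{rep}", "control", "anterior", rep, 7, 7, lib))
            rows.append(("ev1", f"m{rep}", "mutant", "anterior", rep, 0, 500, lib))
        counts = make_counts(rows)
        (call,) = call_events(counts, _toy_annotation_five_events()[:1])
        assert call.support == 14
        assert call.p < 1e-6
        assert not call.significant and not call.pass_support

    def test_removing_any_filter_never_shrinks_significant_set(self):
        """Conjunctive monotonicity over the four filters."""
        counts = _toy_counts_five_events()
        ann = _toy_annotation_five_events()
        base = {c.event_id for c in call_events(counts, ann) if c.significant}
        relaxed = [
            ASThresholds(1.0, 0.1, 1.5, 15),
            ASThresholds(0.05, 1.0, 1.5, 15),
            ASThresholds(0.05, 0.1, 1.0, 15),
            ASThresholds(0.05, 0.1, 1.5, 0),
        ]
        for th in relaxed:
            bigger = {c.event_id for c in call_events(counts, ann, th) if c.significant}
            assert base <= bigger

    def test_gene_below_exon_rejected(self):
        rows = [
            ("ev1", "c1", "control", "anterior", 1, 50, 40, 100),
            ("ev1", "m1", "mutant", "anterior", 1, 5, 40, 100),
        ]
        with pytest.raises(DataIntegrityError):
            call_events(make_counts(rows), _toy_annotation_five_events()[:1])
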