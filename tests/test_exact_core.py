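"""Unit and property tests for the exact distribution machinery."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from fscore import (
    ConfusionTable,
    InfeasibleTargetError,
    PerfParams,
    ResourceLimitError,
    brute_force_pmf,
    diff_pmf,
    expected_score,
    fbeta_estimate,
    fbeta_value,
    score_pmf,
    solve_p_alpha,
)
from fscore.exact_core import (
    brute_force_pmf_exact,
    read_confusion_json,
    read_confusion_tsv,
    write_confusion_json,
    write_confusion_tsv,
)


def double_sum_expectation(S, M, ps, pa, beta=1.0):
    """Independent oracle: the full (S+1) x (M+1) double sum."""
    total = 0.0
    b2 = beta * beta
    for d in range(S + 1):
        for b in range(M + 1):
            f = (1 + b2) * d / (b + d + b2 * S) if d else 0.0
            total += binom.pmf(d, S, ps) * binom.pmf(b, M, pa) * f
    return total


class TestConfusionTable:
    def test_derived_counts(self):
        t = ConfusionTable(N=10, S=4, d=3, b=2)
        assert (t.M, t.a, t.c) == (6, 4, 1)
        assert t.sensitivity == 0.75
        assert t.precision == 0.6

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=10, S=0, d=0, b=0),
            dict(N=10, S=10, d=5, b=0),
            dict(N=10, S=4, d=5, b=0),
            dict(N=10, S=4, d=0, b=7),
        ],
    )
    def test_invalid_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConfusionTable(**kwargs)

    def test_score_zero_when_no_true_positives(self):
        t = ConfusionTable(N=10, S=4, d=0, b=0)
        assert t.fbeta() == 0.0


class TestPerfParams:
    def test_f1_is_harmonic_mean(self):
        p = PerfParams(ps=0.9, pp=0.6)
        assert p.fbeta == pytest.approx(2 * 0.9 * 0.6 / 1.5)

    def test_zero_rate_gives_zero_score(self):
        assert PerfParams(ps=0.0, pp=0.6).fbeta == 0.0
        assert PerfParams(ps=0.6, pp=0.0).fbeta == 0.0

    def test_beta_weighting(self):
        # beta > 1 moves the score toward sensitivity
        hi_sens = PerfParams(ps=0.9, pp=0.5, beta=2.0)
        assert hi_sens.fbeta > PerfParams(ps=0.9, pp=0.5).fbeta

    def test_invalid(self):
        with pytest.raises(ValueError):
            PerfParams(ps=1.2, pp=0.5)
        with pytest.raises(ValueError):
            PerfParams(ps=0.5, pp=0.5, beta=0.0)


class TestSolvePAlpha:
    @pytest.mark.parametrize("M, expected", [(30, 0.40), (80, 0.15), (130, 0.09)])
    def test_published_calibration_values(self, M, expected):
        target = fbeta_value(0.9, 0.6)
        pa = solve_p_alpha(20, M, 0.9, target)
        assert round(pa, 2) == expected

    def test_boundary_perfect_score(self):
        assert solve_p_alpha(20, 30, 1.0, 1.0) == 0.0

    def test_root_satisfies_double_sum(self):
        # derived: verify against the full 6x6 double sum
        pa = solve_p_alpha(5, 5, 0.8, 0.7)
        assert double_sum_expectation(5, 5, 0.8, pa) == pytest.approx(0.7, abs=1e-9)

    def test_infeasible_target_raises(self):
        with pytest.raises(InfeasibleTargetError, match="Increase the number"):
            # S=2: even perfect prediction cannot average f1=0.99 at ps=0.5
            solve_p_alpha(2, 10, 0.5, 0.99)

    def test_expectation_monotone_decreasing(self):
        values = [expected_score(10, 20, 0.8, pa) for pa in np.linspace(0, 1, 21)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_closed_form_limit_large_n(self):
        # large-N closed form: S ps (1-pp) / (M pp)
        S, M, ps, pp = 1000, 4000, 0.9, 0.6
        exact = solve_p_alpha(S, M, ps, fbeta_value(ps, pp))
        approx = S * ps * (1 - pp) / (M * pp)
        assert abs(exact - approx) / approx < 0.01


class TestScorePmf:
    def test_tiny_instance_matches_double_loop(self):
        dist = score_pmf(2, 2, 0.5, 0.5)
        # independent oracle: 3x3 loop with Fraction keys
        expect = {}
        for d in range(3):
            for b in range(3):
                f = Fraction(2 * d, b + d + 2)
                expect[f] = expect.get(f, 0.0) + binom.pmf(d, 2, 0.5) * binom.pmf(
                    b, 2, 0.5
                )
        support = sorted(expect)
        assert np.allclose(dist.support, [float(f) for f in support])
        assert np.allclose(dist.probs, [expect[f] for f in support], atol=1e-12)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_point_mass_at_one(self):
        dist = score_pmf(5, 8, 1.0, 0.0)
        assert len(dist) == 1
        assert dist.support[0] == 1.0
        assert dist.probs[0] == pytest.approx(1.0)

    def test_zero_sensitivity_point_mass_at_zero(self):
        for pa in (0.0, 0.3, 1.0):
            dist = score_pmf(5, 8, 0.0, pa)
            assert len(dist) == 1
            assert dist.support[0] == 0.0

    def test_mean_matches_calibration_target(self):
        target = fbeta_value(0.9, 0.6)
        pa = solve_p_alpha(20, 30, 0.9, target)
        dist = score_pmf(20, 30, 0.9, pa)
        assert dist.mean() == pytest.approx(target, abs=1e-9)

    def test_resource_cap(self):
        with pytest.raises(ResourceLimitError):
            score_pmf(2000, 100000, 0.5, 0.5, max_points=1000)

    def test_rational_ties_merge(self):
        # 2*1/(0+1+3) = 2*2/(2+2+4) = 1/2 must be one support point
        dist = score_pmf(3, 4, 0.5, 0.5)
        assert np.all(np.diff(dist.support) > 0)
        halves = np.isclose(dist.support, 0.5)
        assert halves.sum() == 1


class TestBruteForce:
    def test_total_mass_exactly_one(self):
        exact = brute_force_pmf_exact(4, 6, 0.7, 0.2)
        assert sum(exact.values()) == Fraction(1)

    def test_matches_score_pmf(self):
        fast = score_pmf(5, 10, 0.7, 0.2)
        slow = brute_force_pmf(5, 10, 0.7, 0.2)
        assert len(fast) == len(slow)
        assert np.allclose(fast.support, slow.support, atol=0)
        assert np.max(np.abs(fast.probs - slow.probs)) < 1e-12

    def test_expectation_matches_double_sum(self):
        dist = brute_force_pmf(5, 10, 0.7, 0.2)
        assert dist.mean() == pytest.approx(
            double_sum_expectation(5, 10, 0.7, 0.2), abs=1e-12
        )

    def test_size_guard(self):
        with pytest.raises(ResourceLimitError):
            brute_force_pmf(200, 200, 0.5, 0.5)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("S,M", [(1, 1), (3, 7), (7, 3), (12, 12), (12, 5)])
    def test_oracle_equivalence_grid(self, S, M, beta):
        fast = score_pmf(S, M, 0.65, 0.25, beta)
        slow = brute_force_pmf(S, M, 0.65, 0.25, beta)
        assert np.allclose(fast.support, slow.support, atol=0)
        assert np.max(np.abs(fast.probs - slow.probs)) < 1e-12

    def test_oracle_equivalence_exhaustive_small(self):
        # all S, M <= 6 at beta in {0.5, 1, 2}; larger S, M spot-checked above
        for beta in (0.5, 1.0, 2.0):
            for S in range(1, 7):
                for M in range(1, 7):
                    fast = score_pmf(S, M, 0.6, 0.3, beta)
                    slow = brute_force_pmf(S, M, 0.6, 0.3, beta)
                    assert np.allclose(fast.support, slow.support, atol=0)
                    assert np.max(np.abs(fast.probs - slow.probs)) < 1e-12


class TestDiffPmf:
    def test_identical_margins_symmetric(self):
        pa = solve_p_alpha(4, 6, 0.8, fbeta_value(0.8, 0.6))
        g = score_pmf(4, 6, 0.8, pa)
        h = diff_pmf(g, g)
        assert h.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert h.mean() == pytest.approx(0.0, abs=1e-12)
        # symmetry about zero, point by point
        flipped = dict(zip(np.round(-h.support, 12), h.probs))
        for v, p in zip(np.round(h.support, 12), h.probs):
            assert abs(flipped[v] - p) < 1e-12

    def test_point_masses(self):
        one = score_pmf(3, 5, 1.0, 0.0)
        zero = score_pmf(3, 5, 0.0, 0.0)
        h = diff_pmf(one, zero)
        assert len(h) == 1
        assert h.support[0] == 1.0

    def test_four_fold_brute_force(self):
        # derived oracle: direct sum over (b1, d1, b2, d2)
        S, M = 2, 2
        pa1 = solve_p_alpha(S, M, 0.9, fbeta_value(0.9, 0.7))
        pa2 = solve_p_alpha(S, M, 0.5, fbeta_value(0.5, 0.7))
        g1 = score_pmf(S, M, 0.9, pa1)
        g2 = score_pmf(S, M, 0.5, pa2)
        h = diff_pmf(g1, g2)
        expect: dict[float, float] = {}
        for d1 in range(S + 1):
            for b1 in range(M + 1):
                for d2 in range(S + 1):
                    for b2 in range(M + 1):
                        df = round(
                            float(Fraction(2 * d1, b1 + d1 + S))
                            - float(Fraction(2 * d2, b2 + d2 + S)),
                            12,
                        )
                        pr = (
                            binom.pmf(d1, S, 0.9)
                            * binom.pmf(b1, M, pa1)
                            * binom.pmf(d2, S, 0.5)
                            * binom.pmf(b2, M, pa2)
                        )
                        if pr > 0.0:
                            expect[df] = expect.get(df, 0.0) + pr
        assert len(h) == len(expect)
        for v, p in zip(h.support, h.probs):
            assert expect[round(float(v), 12)] == pytest.approx(p, abs=1e-12)

    def test_support_in_minkowski_difference(self):
        g1 = score_pmf(3, 4, 0.8, 0.3)
        g2 = score_pmf(3, 4, 0.6, 0.2)
        h = diff_pmf(g1, g2)
        allowed = {
            round(float(a) - float(b), 12) for a in g1.support for b in g2.support
        }
        assert set(np.round(h.support, 12)).issubset(allowed)

    def test_mismatched_designs_rejected(self):
        g1 = score_pmf(3, 4, 0.8, 0.3)
        g2 = score_pmf(3, 5, 0.8, 0.3)
        with pytest.raises(ValueError):
            diff_pmf(g1, g2)

    def test_pair_cap(self):
        g = score_pmf(10, 10, 0.5, 0.5)
        with pytest.raises(ResourceLimitError):
            diff_pmf(g, g, max_pairs=10)


@settings(max_examples=25, deadline=None)
@given(
    S=st.integers(1, 10),
    M=st.integers(1, 10),
    ps=st.floats(0.05, 0.95),
    pa=st.floats(0.05, 0.95),
)
def test_pmf_normalization_property(S, M, ps, pa):
    dist = score_pmf(S, M, ps, pa)
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(dist.support) > 0)
    assert dist.support[0] >= 0.0 and dist.support[-1] <= 1.0


@settings(max_examples=15, deadline=None)
@given(
    S=st.integers(2, 8),
    M=st.integers(2, 8),
    ps=st.floats(0.1, 0.9),
)
def test_beta_one_reduces_to_f1_identity(S, M, ps):
    dist = score_pmf(S, M, ps, 0.4, beta=1.0)
    for v in dist.support:
        # every support point must be 2d/(b+d+S) for some admissible (b, d)
        ok = any(
            abs(v - 2 * d / (b + d + S)) < 1e-12
            for d in range(S + 1)
            for b in range(M + 1)
        )
        assert ok


def test_truncation_mass_recorded_small():
    pa = solve_p_alpha(38, 15803, 0.98, fbeta_value(0.98, 0.8))
    dist = score_pmf(38, 15803, 0.98, pa)
    assert dist.truncation_mass < 1e-10
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)


def test_fbeta_estimate_rational_exact():
    assert fbeta_estimate(4, 1, 4) == pytest.approx(8 / 9)
    assert fbeta_estimate(4, 0, 0) == 0.0
    # beta=2: (1+4)d / (b+d+4S)
    assert fbeta_estimate(2, 1, 2, beta=2.0) == pytest.approx(10 / 11)


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        tables = [
            ConfusionTable(N=100, S=40, d=30, b=12),
            ConfusionTable(N=50, S=20, d=19, b=0),
        ]
        path = tmp_path / "tables.tsv"
        write_confusion_tsv(path, tables)
        assert read_confusion_tsv(path) == tables

    def test_json_round_trip(self, tmp_path):
        t = ConfusionTable(N=100, S=40, d=30, b=12)
        path = tmp_path / "table.json"
        write_confusion_json(path, t)
        assert read_confusion_json(path) == t

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\tc\td\n1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="header"):
            read_confusion_tsv(path)
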