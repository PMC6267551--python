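"""Complexity/fit estimation, Bayes factors, and the best-hypothesis rule."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from nof1bayes import (
    ConditionLayout,
    EvaluationConfig,
    MCEstimate,
    PersonCounts,
    bf_pairwise,
    bf_vs_complement,
    bf_vs_unconstrained,
    complement_of,
    estimate_complexity,
    estimate_fit,
    evaluate_person,
    parse_hypothesis,
    posterior_update,
    sample_product,
    select_best,
    uniform_prior,
)
from nof1bayes.bayes import Decision, PersonEvaluation, proportion_on_pool


def beta_ordering_probability(a1, b1, a2, b2):
    """Independent oracle: P(X > Y) for X~Beta(a1,b1), Y~Beta(a2,b2) by
    deterministic numerical integration of f_X(x) F_Y(x)."""
    val, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a2, b2), 0.0, 1.0
    )
    return val


def make_evaluation(bf_u: dict) -> PersonEvaluation:
    labels = tuple(bf_u)
    pairwise = {(m, mp): bf_u[m] / bf_u[mp] for m in labels for mp in labels}
    return PersonEvaluation(
        person_id="p", labels=labels, complexity={}, fit={},
        bf_u=bf_u, bf_c={}, pairwise=pairwise,
    )


class TestComplexity:
    def test_full_ordering_j3_matches_enumeration(self):
        # by exchangeability each of the 3! orderings is equally likely
        lay = ConditionLayout(["a", "b", "c"], 5)
        h = parse_hypothesis("a > b > c", lay)
        est = estimate_complexity(h, lay, n=200_000, seed=11)
        assert est.analytic == pytest.approx(1 / 6)
        assert abs(est.value - 1 / 6) < 3 * est.std_error

    def test_full_ordering_j4(self, ordering4, layout4):
        est = estimate_complexity(ordering4, layout4, n=200_000, seed=2)
        assert est.analytic == pytest.approx(1 / 24)
        assert abs(est.value - 1 / 24) < 3 * est.std_error

    def test_averages_hypothesis_half_by_symmetry(self, averages4, layout4):
        est = estimate_complexity(averages4, layout4, n=200_000, seed=3)
        assert est.analytic is None
        assert abs(est.value - 0.5) < 3 * est.std_error

    def test_complement_complexity(self, ordering4, layout4):
        est = estimate_complexity(complement_of(ordering4), layout4, n=100_000, seed=4)
        assert est.analytic == pytest.approx(23 / 24)

    def test_all_orderings_partition_shared_pool(self, layout4):
        from itertools import permutations

        pool = sample_product(uniform_prior(layout4), 100_000, 7, source="prior")
        total = 0.0
        for perm in permutations(layout4.names):
            h = parse_hypothesis(" > ".join(perm), layout4)
            total += proportion_on_pool(h, pool).value
        assert total == pytest.approx(1.0, abs=1e-9)


class TestFit:
    def test_fit_plus_complement_fit_is_one_exactly(self, ordering4, layout4):
        data = PersonCounts("1", (7, 5, 4, 1), layout4)
        post = posterior_update(uniform_prior(layout4), data)
        pool = sample_product(post, 50_000, 5, source="posterior")
        f = proportion_on_pool(ordering4, pool)
        fc = proportion_on_pool(complement_of(ordering4), pool)
        assert f.value + fc.value == pytest.approx(1.0, abs=0)

    @pytest.mark.parametrize("x1, x2", [(5, 2), (7, 0), (3, 3), (0, 7)])
    def test_two_condition_fit_matches_integration_oracle(self, x1, x2):
        lay = ConditionLayout(["a", "b"], 7)
        h = parse_hypothesis("a > b", lay)
        post = posterior_update(
            uniform_prior(lay), PersonCounts("p", (x1, x2), lay)
        )
        est = estimate_fit(h, post, n=200_000, seed=x1 * 8 + x2)
        exact = beta_ordering_probability(x1 + 1, 8 - x1, x2 + 1, 8 - x2)
        se = max(est.std_error, np.sqrt(exact * (1 - exact) / est.n_draws))
        assert abs(est.value - exact) < 3 * se


class TestBayesFactorForms:
    def test_bf_vs_unconstrained_worked_values(self):
        assert bf_vs_unconstrained(0.5483, 1 / 24).value == pytest.approx(13.16, abs=0.01)
        assert bf_vs_unconstrained(0.01, 1 / 24).value == pytest.approx(0.24, abs=0.01)
        assert bf_vs_unconstrained(0.3, 0.3).value == pytest.approx(1.0)

    def test_bf_vs_complement_worked_values(self):
        assert bf_vs_complement(0.548, 1 / 24).value == pytest.approx(27.9, abs=0.2)
        assert bf_vs_complement(0.89, 0.5).value == pytest.approx(8.09, abs=0.01)
        assert bf_vs_complement(0.5, 0.5).value == pytest.approx(1.0)

    def test_bf_vs_complement_extremes(self):
        with pytest.warns(UserWarning):
            assert bf_vs_complement(1.0, 0.5).value == math.inf
        assert bf_vs_complement(0.0, 0.5).value == 0.0
        with pytest.raises(ValueError):
            bf_vs_complement(0.5, 1.0)
        with pytest.raises(ValueError):
            bf_vs_unconstrained(0.5, 0.0)

    def test_bf_vs_complement_monotone_in_fit(self):
        c = 1 / 24
        fits = np.linspace(0.01, 0.99, 25)
        values = [bf_vs_complement(f, c).value for f in fits]
        assert np.all(np.diff(values) > 0)
        assert bf_vs_complement(c, c).value == pytest.approx(1.0)

    def test_pairwise_ratio(self):
        assert bf_pairwise(13.16, 2.00) == pytest.approx(6.58)
        assert bf_pairwise(1.98, 0.26) == pytest.approx(7.62, abs=0.01)
        assert bf_pairwise(3.3, 3.3) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert bf_pairwise(2.0, 0.0) == math.inf

    def test_zero_fit_flagged(self):
        bf = bf_vs_unconstrained(
            MCEstimate(0.0, 0.0, 1000), MCEstimate(0.5, 0.001, 1000)
        )
        assert bf.value == 0.0 and "zero_fit" in bf.flags


class TestEvaluatePerson:
    def test_shared_pool_pairwise_identity(self, hset4, persons4):
        ev = evaluate_person(
            persons4[0], hset4, EvaluationConfig(n_draws=50_000, seed=21)
        )
        expected = float(ev.bf_u["H1"]) / float(ev.bf_u["H2"])
        assert ev.pairwise[("H1", "H2")] == expected  # exact, same pools
        assert ev.pairwise[("H1", "H1")] == 1.0

    def test_reproducible_with_seed(self, hset4, persons4):
        cfg = EvaluationConfig(n_draws=20_000, seed=33)
        a = evaluate_person(persons4[1], hset4, cfg)
        b = evaluate_person(persons4[1], hset4, cfg)
        assert float(a.bf_u["H1"]) == float(b.bf_u["H1"])
        assert a.fit["H2"].value == b.fit["H2"].value


class TestSelectBest:
    def test_two_hypotheses_at_threshold(self):
        ev = make_evaluation({"H1": 4.0, "H2": 2.0})
        decision = select_best(ev)
        assert decision.best == "H1" and decision.threshold == 2.0

    def test_minimum_threshold_is_two(self):
        # with M = 2 the threshold is max(M - 1, 2) = 2, not 1
        ev = make_evaluation({"H1": 3.0, "H2": 2.0})
        assert select_best(ev).best is None

    def test_four_hypotheses_need_threefold_support(self):
        # best advantage 1.98/.93 = 2.13 < 3 -> nothing selected
        ev = make_evaluation({"H1": 0.59, "H2": 0.93, "H3": 1.98, "H4": 0.26})
        decision = select_best(ev)
        assert decision.best is None and decision.threshold == 3.0

    def test_ties_select_nothing(self):
        ev = make_evaluation({"H1": 2.0, "H2": 2.0, "H3": 2.0})
        assert select_best(ev).best is None

    def test_threshold_override(self):
        ev = make_evaluation({"H1": 0.59, "H2": 0.93, "H3": 1.98, "H4": 0.26})
        assert select_best(ev, threshold=2.0).best == "H3"

    def test_single_hypothesis_rejected(self):
        ev = make_evaluation({"H1": 2.0})
        with pytest.raises(ValueError):
            select_best(ev)
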