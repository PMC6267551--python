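"""Truncated-prior sampling, surrogate Bayes factors, bootstrap design grid."""

import numpy as np
import pytest

from nof1bayes import (
    ConditionLayout,
    DesignConfig,
    PopulationSpec,
    bootstrap_design,
    build_surrogate,
    membership,
    parse_hypothesis,
    run_design,
    sample_wp_population,
    sample_wp_populations,
)
from nof1bayes.design import RejectionBudgetError


class TestTruncatedSampling:
    def test_under_h_draws_satisfy_the_ordering(self, ordering4, layout4):
        spec = PopulationSpec(ordering4, "under_h")
        pis = sample_wp_populations(spec, layout4, 2000, seed=1)
        assert np.all(np.diff(pis, axis=1) < 0)

    def test_under_complement_draws_violate_it(self, ordering4, layout4):
        spec = PopulationSpec(ordering4, "under_complement")
        pis = sample_wp_populations(spec, layout4, 2000, seed=2)
        assert not np.any(np.all(np.diff(pis, axis=1) < 0, axis=1))

    def test_order_statistic_means(self, ordering4, layout4):
        # sorted uniforms: k-th largest of J has mean (J + 1 - k)/(J + 1)
        spec = PopulationSpec(ordering4, "under_h")
        n = 100_000
        pis = sample_wp_populations(spec, layout4, n, seed=3)
        j = 4
        expected = (j - np.arange(j)) / (j + 1)
        se = np.sqrt(expected * (1 - expected) / n)  # conservative envelope
        np.testing.assert_allclose(pis.mean(axis=0), expected, atol=3 * se.max())

    def test_sort_shortcut_matches_plain_rejection(self):
        # J = 3 full ordering: compare coordinate-wise means of both samplers
        lay = ConditionLayout(["a", "b", "c"], 5)
        h = parse_hypothesis("a > b > c", lay)
        spec = PopulationSpec(h, "under_h")
        n = 100_000
        sort_based = sample_wp_populations(spec, lay, n, seed=4)
        rng = np.random.default_rng(5)
        kept = []
        while sum(len(k) for k in kept) < n:
            cand = rng.random((50_000, 3))
            kept.append(cand[np.all(np.diff(cand, axis=1) < 0, axis=1)])
        rejection = np.concatenate(kept)[:n]
        se = 0.25 / np.sqrt(n)
        np.testing.assert_allclose(
            sort_based.mean(axis=0), rejection.mean(axis=0), atol=3 * 2 * se
        )

    def test_mixture_fraction_matches_theta(self, ordering4, layout4):
        spec = PopulationSpec(ordering4, "mixture", theta=0.5)
        n = 10_000
        pis = sample_wp_populations(spec, layout4, n, seed=6)
        frac = np.mean(membership(ordering4, pis))
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_rejection_budget_error_reports_acceptance(self, layout8, ordering8):
        spec = PopulationSpec(ordering8, "under_h")
        # force the generic rejection path by perturbing one coefficient
        coef = ordering8.matrix.coefficients.copy()
        coef[0, 0] = 2.0
        from nof1bayes import ConstraintMatrix, Hypothesis

        h = Hypothesis("hard", "informative", ConstraintMatrix(coef))
        with pytest.raises(RejectionBudgetError, match="acceptance"):
            sample_wp_populations(
                PopulationSpec(h, "under_h"), layout8, 1000, seed=7, budget=20_000
            )

    def test_single_draw_api(self, ordering4, layout4):
        pi = sample_wp_population(PopulationSpec(ordering4, "under_h"), layout4, seed=8)
        assert pi.shape == (4,)
        assert membership(ordering4, pi)


class TestSurrogate:
    def test_under_h_median_bf_favors_hypothesis(self, layout4, ordering4):
        spec = PopulationSpec(ordering4, "under_h")
        # R = 50 replications: data are informative, BF vs complement > 1
        lay = ConditionLayout(layout4.names, 50)
        bfs = build_surrogate(spec, lay, 50, 200, seed=9, n_draws=20_000)
        assert np.median(bfs) > 1

    def test_fixed_seed_bit_identical(self, layout4, ordering4):
        spec = PopulationSpec(ordering4, "under_h")
        a = build_surrogate(spec, layout4, 7, 50, seed=10, n_draws=5_000)
        b = build_surrogate(spec, layout4, 7, 50, seed=10, n_draws=5_000)
        np.testing.assert_array_equal(a, b)

    def test_under_complement_majority_favors_complement(self, layout8, ordering8):
        # the complement has prior mass 1 - 1/40320, so it wins almost always
        spec = PopulationSpec(ordering8, "under_complement")
        bfs = build_surrogate(spec, layout8, 7, 100, seed=11, n_draws=5_000)
        assert np.mean(bfs < 1) > 0.9


class TestBootstrap:
    def test_single_person_sets_recover_surrogate_percentiles(self):
        surrogate = np.array([0.5, 2.0, 4.0, 8.0, 1.5])
        out = bootstrap_design(surrogate, p=1, sets=2000, seed=12)
        np.testing.assert_allclose(
            out["gp_bf"], np.percentile(surrogate, [2.5, 50, 97.5]), rtol=0.5
        )
        # a single BF > 1 gives ER = 1; one below 1 also gives ER = 1
        assert out["er"][1] == 1.0

    def test_degenerate_pool_of_identical_bfs(self):
        out = bootstrap_design(np.full(100, 3.0), p=10, sets=50, seed=13)
        assert out["gp_bf"] == pytest.approx((3.0, 3.0, 3.0))
        assert out["sr"] == pytest.approx((0.0, 0.0, 0.0))

    def test_percentiles_monotone(self):
        rng = np.random.default_rng(14)
        out = bootstrap_design(rng.lognormal(0.5, 1.0, 500), p=20, sets=200, seed=15)
        for stat in ("gp_bf", "er", "sr"):
            lo, med, hi = out[stat]
            assert lo <= med <= hi


class TestRunDesign:
    def test_smoke_grid(self, layout4, ordering4):
        cfg = DesignConfig(
            layout=layout4,
            populations=(
                PopulationSpec(ordering4, "under_h"),
                PopulationSpec(ordering4, "under_complement"),
            ),
            r_grid=(7,),
            p_grid=(5,),
            surrogate_size=100,
            bootstrap_sets=50,
            n_draws=2_000,
            seed=16,
        )
        result = run_design(cfg)
        assert len(result.cells) == 2
        for cell in result.cells:
            for trip in (cell.gp_bf, cell.er, cell.sr):
                assert trip[0] <= trip[1] <= trip[2]
            assert 0 <= cell.er[1] <= 1 and 0 <= cell.sr[1] <= 1
        frame = result.to_frame()
        assert set(frame["statistic"]) == {"gp_bf", "er", "sr"}
        assert len(frame) == 2 * 3 * 3

    def test_opposite_populations_straddle_one(self, layout4, ordering4):
        # reduced-size direction check: gP medians sit on opposite sides of 1
        lay = ConditionLayout(layout4.names, 21)
        cfg = DesignConfig(
            layout=lay,
            populations=(
                PopulationSpec(ordering4, "under_h"),
                PopulationSpec(ordering4, "under_complement"),
            ),
            r_grid=(21,),
            p_grid=(30,),
            surrogate_size=300,
            bootstrap_sets=100,
            n_draws=10_000,
            seed=17,
        )
        cells = {c.population: c for c in run_design(cfg).cells}
        assert cells["under_h"].gp_bf[1] > 1
        assert cells["under_complement"].gp_bf[1] < 1

    def test_median_gp_nondecreasing_in_r(self, layout4, ordering4):
        # consistency: more replications give stronger evidence on average
        medians_by_seed = []
        for seed in range(5):
            meds = []
            for r in (3, 9, 27):
                lay = ConditionLayout(layout4.names, r)
                bfs = build_surrogate(
                    PopulationSpec(ordering4, "under_h"), lay, r, 120,
                    seed=seed, n_draws=5_000,
                )
                meds.append(np.median(bfs))
            medians_by_seed.append(meds)
        mean_meds = np.mean(medians_by_seed, axis=0)
        inversions = np.sum(np.diff(mean_meds) < 0)
        assert inversions <= 1
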