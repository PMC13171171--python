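import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_bundle, midrange_bundle
from dropqc.cell_calling import (
    BarcodeRanking,
    CallParams,
    bh_adjust,
    call_cells,
    default_candidate_grid,
    estimate_ambient_profile,
    montecarlo_pvalues,
    multinomial_loglik,
    observed_cell_count,
    ordmag_call,
    ordmag_loss,
    percentile99,
    rank_barcodes,
)
from oracles import bh_stepup, exact_pvalue, enumerate_outcomes, multinomial_pmf, ordmag_bruteforce


def ranking_from(counts):
    totals = np.asarray(counts, dtype=np.int64)
    order = np.argsort(-totals, kind="stable")
    return BarcodeRanking(counts=totals[order], order=order)


class TestRankBarcodes:
    def test_sorts_descending(self):
        bundle = make_bundle([[5], [9], [1]])
        ranking = rank_barcodes(bundle)
        assert ranking.counts.tolist() == [9, 5, 1]
        assert ranking.order.tolist() == [1, 0, 2]

    def test_ties_stable(self):
        bundle = make_bundle([[7], [7]])
        assert rank_barcodes(bundle).order.tolist() == [0, 1]

    def test_all_zero_errors(self):
        bundle = make_bundle([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="no counted barcodes"):
            rank_barcodes(bundle)


class TestPercentile99:
    def test_constant_list(self):
        assert percentile99([1000] * 100) == 1000.0

    def test_single_value(self):
        assert percentile99([42]) == 42.0

    def test_linear_interpolation_1_to_100(self):
        # oracle: position 0.99*(100-1)=98.01 -> 99 + 0.01*(100-99) = 99.01
        values = list(range(1, 101))
        expected = float(np.percentile(np.asarray(values, dtype=float), 99))
        assert expected == pytest.approx(99.01)
        assert percentile99(values[::-1]) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            percentile99([])


class TestObservedCellCount:
    def test_strict_cutoff(self):
        ranking = ranking_from([100, 90, 10, 9, 1])
        assert observed_cell_count(ranking, 100) == 2  # cutoff 10, strict

    def test_zero_mk_counts_nonzero(self):
        ranking = ranking_from([100, 90, 10, 9, 1, 0])
        assert observed_cell_count(ranking, 0) == 5

    def test_fractional_cutoff(self):
        # cutoff 8.9; 100, 90, 10 and 9 are all strictly above it
        ranking = ranking_from([100, 90, 10, 9, 1])
        assert observed_cell_count(ranking, 89) == 4

    def test_matches_count_nonzero_oracle(self):
        rng = np.random.default_rng(0)
        counts = np.sort(rng.integers(0, 1000, 200))[::-1]
        ranking = BarcodeRanking(counts=counts, order=np.arange(200))
        for m_k in (0, 1, 9.5, 50, 999, 2000):
            assert observed_cell_count(ranking, m_k) == int(np.count_nonzero(counts > m_k / 10))


class TestOrdmagLoss:
    @pytest.mark.parametrize(
        "c_obs,c_exp,expected", [(100, 100, 0.0), (0, 100, 100.0), (150, 100, 25.0)]
    )
    def test_examples(self, c_obs, c_exp, expected):
        assert ordmag_loss(c_obs, c_exp) == expected

    def test_invalid_candidate(self):
        with pytest.raises(ValueError):
            ordmag_loss(10, 0)


class TestOrdmagCall:
    def test_bimodal_recovers_true_count(self):
        counts = [1000] * 100 + [10] * 900
        ranking = ranking_from(counts)
        result = ordmag_call(ranking)
        _, _, losses, expected = ordmag_bruteforce(ranking.counts.tolist(), result.candidates.tolist())
        assert result.expected_cells == expected == 100
        np.testing.assert_allclose(result.losses, losses)
        assert set(result.retained_indices.tolist()) == set(range(100))

    def test_single_population_all_equal(self):
        n, depth = 80, 500
        ranking = ranking_from([depth] * n)
        result = ordmag_call(ranking)
        _, _, _, expected = ordmag_bruteforce([depth] * n, result.candidates.tolist())
        assert result.expected_cells == expected == n

    def test_singleton_grid_matches_full_grid_at_truth(self):
        counts = [1000] * 100 + [10] * 900
        ranking = ranking_from(counts)
        full = ordmag_call(ranking)
        single = ordmag_call(ranking, grid=np.array([100]))
        assert single.expected_cells == full.expected_cells == 100
        np.testing.assert_array_equal(single.retained_indices, full.retained_indices)

    def test_retained_is_ranking_prefix(self):
        bundle, _ = midrange_bundle(seed=3)
        ranking = rank_barcodes(bundle)
        result = ordmag_call(ranking)
        np.testing.assert_array_equal(
            result.retained_indices, ranking.order[: result.expected_cells]
        )

    def test_empty_grid_after_clipping(self):
        ranking = ranking_from([5, 4])
        with pytest.raises(ValueError, match="grid"):
            ordmag_call(ranking, grid=np.array([10, 20]))

    @pytest.mark.parametrize("seed", range(5))
    def test_bruteforce_equivalence_on_seeded_fixtures(self, seed):
        bundle, _ = midrange_bundle(seed=seed, n_ambient=300)
        ranking = rank_barcodes(bundle)
        result = ordmag_call(ranking)
        m_list, obs_list, losses, expected = ordmag_bruteforce(
            ranking.counts.tolist(), result.candidates.tolist()
        )
        np.testing.assert_allclose(result.m_k, m_list)
        np.testing.assert_array_equal(result.observed, obs_list)
        np.testing.assert_allclose(result.losses, losses)
        assert result.expected_cells == expected


class TestAmbientProfile:
    def test_plain_normalization(self):
        bundle = make_bundle([[9, 1]])
        np.testing.assert_allclose(
            estimate_ambient_profile(bundle, [0], pseudocount=0.0), [0.9, 0.1]
        )

    def test_pseudocount_arithmetic(self):
        bundle = make_bundle([[0, 0, 10]])
        np.testing.assert_allclose(
            estimate_ambient_profile(bundle, [0], pseudocount=0.5),
            [0.5 / 11.5, 0.5 / 11.5, 10.5 / 11.5],
        )

    def test_sums_to_one_random(self):
        rng = np.random.default_rng(5)
        bundle = make_bundle(rng.integers(0, 20, size=(30, 8)))
        profile = estimate_ambient_profile(bundle, range(30))
        assert profile.sum() == pytest.approx(1.0, abs=1e-12)
        assert (profile > 0).all()

    def test_empty_pool_errors(self):
        bundle = make_bundle([[1, 2]])
        with pytest.raises(ValueError, match="ambient profile"):
            estimate_ambient_profile(bundle, [])


class TestMultinomialLoglik:
    def test_single_draw(self):
        assert multinomial_loglik([1, 0], [0.9, 0.1]) == pytest.approx(np.log(0.9))

    def test_two_draw_closed_form(self):
        assert multinomial_loglik([1, 1], [0.5, 0.5]) == pytest.approx(np.log(0.5))

    def test_normalization_by_enumeration(self):
        profile = [0.3, 0.7]
        total = sum(
            np.exp(multinomial_loglik(list(outcome), profile))
            for outcome in enumerate_outcomes(3, 2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_exact_pmf(self):
        profile = [0.2, 0.5, 0.3]
        for outcome in enumerate_outcomes(4, 3):
            assert np.exp(multinomial_loglik(list(outcome), profile)) == pytest.approx(
                multinomial_pmf(outcome, profile)
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            multinomial_loglik([1, 2, 3], [0.5, 0.5])

    def test_profile_must_be_positive(self):
        with pytest.raises(ValueError):
            multinomial_loglik([1, 0], [1.0, 0.0])


class TestMonteCarloPvalues:
    def test_boundary_minimum(self):
        # candidate concentrated on a 1e-4 probability gene is below every sim
        profile = np.array([1 - 1e-4, 1e-4])
        p = montecarlo_pvalues(np.array([[0, 6]]), profile, n_simulations=1000, seed=0)
        assert p[0] == pytest.approx(1 / 1001)

    def test_modal_composition_near_one(self):
        profile = np.array([0.5, 0.5])
        # most probable outcomes under uniform profile for total=4
        p = montecarlo_pvalues(np.array([[2, 2]]), profile, n_simulations=4000, seed=1)
        assert p[0] > 0.9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        cands = rng.integers(0, 6, size=(8, 3))
        profile = np.array([0.2, 0.3, 0.5])
        p = montecarlo_pvalues(cands, profile, n_simulations=500, seed=3)
        perm = rng.permutation(8)
        p_perm = montecarlo_pvalues(cands[perm], profile, n_simulations=500, seed=3)
        np.testing.assert_allclose(p_perm, p[perm])

    def test_deterministic_given_seed(self):
        cands = np.array([[3, 1], [1, 3]])
        profile = np.array([0.6, 0.4])
        a = montecarlo_pvalues(cands, profile, n_simulations=300, seed=9)
        b = montecarlo_pvalues(cands, profile, n_simulations=300, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_agrees_with_enumeration_toy(self):
        # acceptance-grade check at reduced n lives in test_acceptance
        profile = [0.3, 0.7]
        n_sims = 10_000
        for outcome in enumerate_outcomes(3, 2):
            p_exact = exact_pvalue(outcome, profile)
            expected_estimate = (1 + n_sims * p_exact) / (1 + n_sims)
            se = np.sqrt(p_exact * (1 - p_exact) / n_sims)
            p_mc = montecarlo_pvalues(
                np.array([outcome]), np.array(profile), n_simulations=n_sims, seed=4
            )[0]
            assert abs(p_mc - expected_estimate) <= 3 * se + 1e-9

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(6)
        cands = rng.integers(0, 10, size=(20, 4))
        profile = np.full(4, 0.25)
        p = montecarlo_pvalues(cands, profile, n_simulations=200, seed=0)
        assert (p > 0).all() and (p <= 1).all()
        assert (p >= 1 / 201).all()


class TestBHAdjust:
    def test_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.05, 0.05, 0.05]), [0.05, 0.05, 0.05])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    def test_fdr_geq_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1.0, 50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_literal_stepup_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_stepup(pvals), rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(pvals), expected, rtol=1e-10)


class TestCallCells:
    def test_empty_candidate_set_retains_ordmag_only(self):
        bundle, planted = midrange_bundle(seed=7, n_real_mid=0, n_amb_mid=0)
        calls = call_cells(bundle, CallParams(n_simulations=100))
        assert calls.emptydrops.candidate_indices.size == 0
        assert calls.retained == set(int(i) for i in calls.ordmag.retained_indices)
        assert calls.retained == set(planted["big"])

    def test_planted_midrange_recovery(self):
        bundle, planted = midrange_bundle(seed=1)
        calls = call_cells(bundle, CallParams(n_simulations=2000, seed=0))
        retained = calls.retained
        assert set(planted["big"]) <= retained
        assert set(planted["real_mid"]) <= retained
        assert not (set(planted["amb_mid"]) & retained)
        assert not (set(planted["ambient"]) & retained)

    def test_umi_floor_dominates(self):
        bundle, planted = midrange_bundle(seed=1)
        calls = call_cells(bundle, CallParams(umi_floor=10**7, n_simulations=100))
        assert calls.retained == set(int(i) for i in calls.ordmag.retained_indices)

    def test_retained_set_invariant(self):
        bundle, _ = midrange_bundle(seed=2)
        calls = call_cells(bundle, CallParams(n_simulations=500))
        ed = calls.emptydrops
        expected = set(int(i) for i in calls.ordmag.retained_indices)
        expected |= set(int(i) for i in ed.candidate_indices[ed.fdr <= ed.threshold_used])
        assert calls.retained == expected
        # candidates disjoint from OrdMag set
        assert not (set(ed.candidate_indices.tolist()) & set(calls.ordmag.retained_indices.tolist()))

    def test_fdr_threshold_monotonicity(self):
        bundle, _ = midrange_bundle(seed=4)
        strict = call_cells(bundle, CallParams(fdr_threshold=0.001, n_simulations=2000))
        loose = call_cells(bundle, CallParams(fdr_threshold=0.01, n_simulations=2000))
        assert strict.retained <= loose.retained

    def test_umi_floor_monotonicity_on_fixture(self):
        bundle, _ = midrange_bundle(seed=5)
        low = call_cells(bundle, CallParams(umi_floor=500, ambient_max=100, n_simulations=1000))
        high = call_cells(bundle, CallParams(umi_floor=900, ambient_max=100, n_simulations=1000))
        ordmag = set(int(i) for i in low.ordmag.retained_indices)
        assert (high.retained - ordmag) <= (low.retained - ordmag)

    def test_chemistry_fdr_default(self):
        params = CallParams()
        assert params.resolve_fdr("anything") == 0.01
        assert CallParams(fdr_threshold=0.001).resolve_fdr("anything") == 0.001


class TestParameterRecovery:
    @pytest.mark.parametrize("n_true", [50, 100])
    def test_expected_cells_equals_truth(self, n_true):
        from dropqc.synth_fixtures import SyntheticTruth, simulate_experiment

        hits = 0
        for seed in range(5):
            truth = SyntheticTruth(
                n_true_cells=n_true, n_ambient=1000, n_genes=60, seed=seed
            )
            bundle, _ = simulate_experiment(truth)
            result = ordmag_call(rank_barcodes(bundle))
            hits += result.expected_cells == n_true
        assert hits >= 4  # full 20-replicate criterion lives in test_acceptance


def test_default_grid_covers_all_magnitudes():
    grid = default_candidate_grid(5000)
    assert grid[0] == 1
    assert grid[-1] == 5000
    assert np.all(np.diff(grid) > 0)
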