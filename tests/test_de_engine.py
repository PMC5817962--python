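import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln
from scipy.stats import nbinom

from seqpower import (
    AnalysisParams,
    DispersionEstimates,
    PilotSpec,
    StudyDesign,
    bh_adjust,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    exact_test,
    generate_pilot,
    log_cpm,
    run_de,
    tmm_factors,
)
from seqpower.de import DISPERSION_BOUNDS, exact_nb_pvalues, _pseudo_counts


class TestTMM:
    def test_identical_columns_give_unit_factors(self, matrix_from_array):
        col = np.array([5, 10, 200, 40, 3, 77] * 5)
        m = matrix_from_array(np.column_stack([col, col, col]))
        f = tmm_factors(m)
        assert np.allclose(f.factors, 1.0)

    def test_proportional_columns_give_unit_factors(self, matrix_from_array):
        # depth-invariance: tripling a library changes no proportions
        col = np.array([5, 10, 200, 40, 3, 77, 12, 9, 31, 55, 8, 120])
        m = matrix_from_array(np.column_stack([col, 3 * col]))
        f = tmm_factors(m)
        assert np.allclose(f.factors, 1.0)

    def test_toy_factor_matches_hand_weighted_mean(self, matrix_from_array):
        # 6 genes, one 20x-inflated in sample 2; trimming disabled so the
        # factor equals the plain inverse-variance-weighted mean of M values.
        base = np.array([100, 200, 300, 400, 500, 600])
        other = base.copy()
        other[0] *= 20
        m = matrix_from_array(np.column_stack([base, other]))
        f = tmm_factors(m, trim_m=0.0, trim_a=0.0, min_genes=6, ref_sample="s1")
        n1, n2 = base.sum(), other.sum()
        p1, p2 = base / n1, other / n2
        mvals = np.log2(p2 / p1)
        w = 1.0 / ((n2 - other) / (n2 * other) + (n1 - base) / (n1 * base))
        expected = 2.0 ** ((w * mvals).sum() / w.sum())
        expected_pair = np.array([1.0, expected])
        expected_pair /= np.exp(np.mean(np.log(expected_pair)))
        assert np.allclose(f.factors, expected_pair)

    def test_factors_have_unit_geometric_mean(self, small_pilot):
        matrix, _, _ = small_pilot
        f = tmm_factors(matrix)
        assert abs(np.mean(np.log(f.factors))) < 1e-12

    def test_invariant_to_sample_order_with_fixed_reference(self, small_pilot):
        matrix, _, _ = small_pilot
        ref = matrix.sample_ids[0]
        f1 = tmm_factors(matrix, ref_sample=ref)
        shuffled = matrix.subset_samples(matrix.sample_ids[::-1])
        # subset keeps matrix order; build a reordered matrix explicitly
        order = list(matrix.sample_ids[::-1])
        reordered = matrix.subset_samples(order)
        f2 = tmm_factors(reordered, ref_sample=ref)
        lookup = dict(zip(f2.sample_ids, f2.factors))
        assert np.allclose(f1.factors, [lookup[s] for s in f1.sample_ids])

    def test_sparse_overlap_falls_back_to_unit_factor(self, matrix_from_array, caplog):
        m = matrix_from_array([[5, 3], [2, 1], [0, 9], [7, 0]])
        f = tmm_factors(m)  # only 2 shared positive genes < min_genes
        assert np.allclose(f.factors, 1.0)


class TestLogCPM:
    def test_zero_count_formula(self, matrix_from_array):
        # one sample cannot be TMM-normalized against itself; craft factors
        from seqpower.de import NormalizationFactors

        m = matrix_from_array([[0], [1_000_000 - 0]])
        f = NormalizationFactors(m.sample_ids, np.array([1.0]), np.array([1e6]))
        lc = log_cpm(m, f, prior_count=0.5)
        assert lc[0, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6))
        assert lc[0, 0] == pytest.approx(-1.0000014, abs=1e-6)

    def test_equal_columns_give_equal_logcpm(self, matrix_from_array):
        col = [10, 0, 500, 30, 8, 100, 41, 2, 9, 77, 13, 250]
        m = matrix_from_array(np.column_stack([col, col]))
        lc = log_cpm(m, tmm_factors(m))
        assert np.allclose(lc[:, 0], lc[:, 1])

    def test_scale_invariance_without_prior(self, matrix_from_array):
        col = np.array([10, 5, 500, 30, 8, 100, 41, 2, 9, 77, 13, 250])
        m = matrix_from_array(np.column_stack([col, 2 * col]))
        lc = log_cpm(m, tmm_factors(m), prior_count=0.0)
        assert np.allclose(lc[:, 0], lc[:, 1])


class TestCommonDispersion:
    def test_identical_replicates_hit_lower_bound(self, matrix_from_array, two_group_design):
        col = np.array([30, 50, 100, 10, 70, 25])
        m = matrix_from_array(
            np.column_stack([col] * 4), sample_ids=["A_1", "A_2", "B_1", "B_2"]
        )
        d = two_group_design(2, 2)
        phi = estimate_common_dispersion(m, d, tmm_factors(m))
        assert phi == pytest.approx(DISPERSION_BOUNDS[0])

    def test_poisson_data_estimate_near_zero(self, two_group_design):
        spec = PilotSpec(n_genes=2000, replicates_per_condition=8,
                         target_library_size=200_000, pi_de=0.0,
                         constant_dispersion=0.0, seed=8)
        m, d, _ = generate_pilot(spec)
        phi = estimate_common_dispersion(m, d, tmm_factors(m))
        assert phi <= 0.01

    def test_recovers_simulated_dispersion(self):
        spec = PilotSpec(n_genes=2000, replicates_per_condition=8,
                         target_library_size=500_000, pi_de=0.0,
                         constant_dispersion=0.1, seed=3)
        m, d, _ = generate_pilot(spec)
        phi = estimate_common_dispersion(m, d, tmm_factors(m))
        assert 0.08 <= phi <= 0.12

    def test_requires_a_replicated_condition(self, matrix_from_array):
        m = matrix_from_array([[5, 9], [3, 4]], sample_ids=["A_1", "B_1"])
        d = StudyDesign({"A_1": "A", "B_1": "B"})
        with pytest.raises(ValueError, match="2 replicates"):
            estimate_common_dispersion(m, d, tmm_factors(m))


def _conditional_loglik_oracle(pseudo, groups, phi):
    """Independent conditional NB likelihood via scipy's nbinom pmf ratio."""
    k = 1.0 / phi
    total = np.zeros(pseudo.shape[0])
    for cols in groups:
        y = pseudo[:, cols]
        s = y.sum(axis=1)
        n = len(cols)
        mu = np.maximum(s / n, 1e-8)
        p = k / (k + mu)
        total += nbinom.logpmf(y, k, p[:, None]).sum(axis=1)
        total -= nbinom.logpmf(s, n * k, (n * k) / (n * k + n * mu))
    return total


@pytest.fixture(scope="module")
def instance():
    spec = PilotSpec(n_genes=100, replicates_per_condition=6,
                     target_library_size=100_000, pi_de=0.0,
                     dispersion_shape=1.0, dispersion_scale=0.1, seed=5)
    m, d, _ = generate_pilot(spec)
    f = tmm_factors(m)
    phi_c = estimate_common_dispersion(m, d, f)
    return m, d, f, phi_c


class TestTagwiseDispersion:
    def test_huge_prior_collapses_to_common(self, instance):
        m, d, f, phi_c = instance
        tw = estimate_tagwise_dispersion(m, d, f, phi_c, prior_weight=1e9)
        assert np.allclose(np.log(tw), np.log(phi_c), atol=1e-3)

    def test_zero_prior_matches_grid_search_oracle(self, instance):
        m, d, f, phi_c = instance
        tw = estimate_tagwise_dispersion(m, d, f, phi_c, prior_weight=0.0)
        pseudo = _pseudo_counts(m, f)
        groups = [[0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11]]
        grid = np.exp(np.linspace(np.log(1e-6), np.log(10.0), 400))
        ll = np.column_stack(
            [_conditional_loglik_oracle(pseudo, groups, g) for g in grid]
        )
        oracle = grid[ll.argmax(axis=1)]
        # agreement to the oracle's own grid resolution (log spacing ~0.04)
        assert np.allclose(np.log(tw), np.log(oracle), atol=0.1)

    def test_increasing_prior_pulls_toward_common(self, instance):
        m, d, f, phi_c = instance
        dist = []
        for w in (0.0, 5.0, 50.0, 500.0):
            tw = estimate_tagwise_dispersion(m, d, f, phi_c, prior_weight=w)
            dist.append(np.abs(np.log(tw) - np.log(phi_c)).mean())
        assert all(a >= b - 1e-9 for a, b in zip(dist, dist[1:]))


class TestExactTest:
    def test_equal_sums_equal_replicates_give_p_one(self):
        p = exact_nb_pvalues(np.array([40]), np.array([40]), 3, 3, 0.05)
        assert p[0] == pytest.approx(1.0)

    def test_poisson_one_vs_one_binomial_enumeration(self):
        # phi=0, counts (0, 10): conditional law Binomial(10, 1/2);
        # partitions no more probable than the observed: {0, 10}
        p = exact_nb_pvalues(np.array([0]), np.array([10]), 1, 1, 0.0)
        assert p[0] == pytest.approx(2.0 / 1024.0, rel=1e-9)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            s = int(rng.integers(1, 500))
            a = int(rng.integers(0, s + 1))
            phi = float(rng.uniform(0.005, 2.0))
            n_a, n_b = (int(x) for x in rng.integers(1, 6, 2))
            r_a, r_b = n_a / phi, n_b / phi
            mu = float(rng.uniform(1.0, 50.0))
            aa = np.arange(s + 1)
            logw = nbinom.logpmf(aa, r_a, r_a / (r_a + mu * n_a)) + nbinom.logpmf(
                s - aa, r_b, r_b / (r_b + mu * n_b)
            )
            w = np.exp(logw - logw.max())
            w /= w.sum()
            expected = w[w <= w[a] * (1 + 1e-12)].sum()
            got = exact_nb_pvalues(np.array([a]), np.array([s - a]), n_a, n_b, phi)[0]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_total_gene_contract(self, matrix_from_array, two_group_design):
        counts = np.array([[0, 0, 0, 0], [10, 12, 50, 44], [30, 28, 7, 9]])
        m = matrix_from_array(counts, sample_ids=["A_1", "A_2", "B_1", "B_2"])
        d = two_group_design(2, 2)
        f = tmm_factors(m)
        disp = DispersionEstimates(0.05, None, "common")
        et = exact_test(m, d, disp, f, ("A", "B"))
        assert et.loc["g1", "pvalue"] == 1.0
        assert et.loc["g1", "logFC"] == 0.0

    def test_label_swap_negates_logfc_and_keeps_p(self, small_pilot):
        matrix, design, _ = small_pilot
        f = tmm_factors(matrix)
        disp = DispersionEstimates(0.05, None, "common")
        ab = exact_test(matrix, design, disp, f, ("A", "B"))
        ba = exact_test(matrix, design, disp, f, ("B", "A"))
        assert np.allclose(ab["pvalue"], ba["pvalue"])
        assert np.allclose(ab["logFC"], -ba["logFC"])

    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_null_p_values_are_conservative(self, alpha, matrix_from_array,
                                            two_group_design):
        # Poisson null with supplied phi=0: discreteness makes the exact test
        # conservative, never anti-conservative.
        rng = np.random.default_rng(4)
        counts = rng.poisson(50.0, size=(4000, 4))
        m = matrix_from_array(counts, sample_ids=["A_1", "A_2", "B_1", "B_2"])
        d = two_group_design(2, 2)
        from seqpower.de import NormalizationFactors

        f = NormalizationFactors(
            m.sample_ids, np.ones(4), m.library_sizes().astype(float)
        )
        et = exact_test(m, d, DispersionEstimates(0.0, None, "common"), f, ("A", "B"))
        frac = (et["pvalue"].to_numpy() <= alpha).mean()
        assert frac <= alpha + 0.01


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust(np.array([0.05]))[0] == pytest.approx(0.05)

    def test_hand_computed_step_up(self):
        out = bh_adjust(np.array([0.01, 0.04, 0.03]))
        assert np.allclose(out, [0.03, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([-0.1]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = rng.random(n)
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs)

    def test_output_dominates_input_and_is_monotone_in_rank(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


@pytest.fixture(scope="module")
def pilot():
    spec = PilotSpec(n_genes=250, replicates_per_condition=6,
                     target_library_size=60_000, pi_de=0.4, seed=21)
    return generate_pilot(spec)


class TestRunDE:
    def test_dispersion_mode_rule(self, pilot):
        from seqpower import subsample_replicates

        matrix, design, _ = pilot
        m4, d4 = subsample_replicates(matrix, design, 4, seed=0)
        assert run_de(m4, d4, ("A", "B")).provenance["dispersion_mode"] == "common"
        m5, d5 = subsample_replicates(matrix, design, 5, seed=0)
        assert run_de(m5, d5, ("A", "B")).provenance["dispersion_mode"] == "tagwise"

    def test_all_zero_gene_gets_unit_pvalues(self, matrix_from_array, two_group_design):
        rng = np.random.default_rng(0)
        counts = rng.poisson(30, size=(60, 4))
        counts[7] = 0
        m = matrix_from_array(counts, sample_ids=["A_1", "A_2", "B_1", "B_2"])
        res = run_de(m, two_group_design(2, 2), ("A", "B"))
        assert res.table.iloc[7]["pvalue"] == 1.0
        assert res.table.iloc[7]["padj"] == 1.0

    def test_result_covers_every_gene_once(self, pilot):
        matrix, design, _ = pilot
        res = run_de(matrix, design, ("A", "B"))
        assert res.gene_ids == matrix.gene_ids

    def test_null_pilot_rarely_declares_anything(self):
        # pi_de=0 with 5 replicates: BH at 0.05 declares nothing in almost
        # every seed (family-wise control under the complete null).  Constant
        # dispersion keeps the NB model correctly specified, isolating the BH
        # behavior from dispersion-heterogeneity effects.
        clean = 0
        for seed in range(20):
            spec = PilotSpec(n_genes=400, replicates_per_condition=5,
                             target_library_size=40_000, pi_de=0.0,
                             constant_dispersion=0.05, seed=seed)
            m, d, _ = generate_pilot(spec)
            res = run_de(m, d, ("A", "B"))
            if len(res.de_genes(0.05)) == 0:
                clean += 1
        assert clean >= 19

    def test_detects_true_effects_with_ordering(self, pilot):
        matrix, design, truth = pilot
        res = run_de(matrix, design, ("A", "B"))
        declared = res.de_genes(0.05)
        true_de = truth.de_genes()
        # most declarations should be truly DE at this depth
        assert len(declared & true_de) / max(len(declared), 1) > 0.8
        # and estimated logFC should correlate with the truth
        lfc = res.table["logFC"].to_numpy()
        assert np.corrcoef(lfc, truth.lfc)[0, 1] > 0.7
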