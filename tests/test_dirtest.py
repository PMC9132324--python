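"""The DIR test family: ratio normalization, LDA separation statistic and
its permutation null, PCA decomposition, the per-component tests, the
p-value combiners, BH adjustment and the test-comparison harness."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from isoratio import (
    CohortConfig,
    IsoformCountMatrix,
    bh_adjust,
    compare_tests,
    dir_test_cohort,
    dir_test_gene,
    fisher_combine,
    generate_cohort,
    geometric_combine,
    hmp_combine,
    independence_pvalue,
    lda_permutation_test,
    lda_project,
    normalize_isoform_vectors,
    pca_components,
    rank_sum_pvalue,
    welch_t_pvalue,
)
from isoratio.dirtest import RatioMatrix, _summary_from_projections

from conftest import null_config


def ratio_matrix_1d(pt_vals, met_vals):
    """Two-isoform RatioMatrix whose first coordinate takes given values."""
    vals = list(pt_vals) + list(met_vals)
    idx = [f"PT{i}" for i in range(len(pt_vals))] + \
          [f"MET{i}" for i in range(len(met_vals))]
    props = pd.DataFrame({"i1": vals, "i2": [1 - v for v in vals]},
                         index=idx)
    return RatioMatrix("g", props)


def labels_for(ratios):
    return pd.Series(
        ["primary" if s.startswith("PT") else "metastatic"
         for s in ratios.sample_ids],
        index=ratios.sample_ids)


class TestNormalize:
    def test_vectors_sum_to_one(self, toy_counts):
        rm = normalize_isoform_vectors(toy_counts, "gA")
        assert np.allclose(rm.proportions.sum(axis=1), 1.0)

    def test_hand_values(self):
        values = pd.DataFrame({"s1": [5.0, 5.0], "s2": [2.0, 8.0]},
                              index=["i1", "i2"])
        m = IsoformCountMatrix(values, pd.Series(["g", "g"],
                                                 index=["i1", "i2"]))
        rm = normalize_isoform_vectors(m, "g")
        assert np.allclose(rm.proportions.loc["s1"], [0.5, 0.5])
        assert np.allclose(rm.proportions.loc["s2"], [0.2, 0.8])

    def test_zero_total_samples_dropped(self):
        values = pd.DataFrame({"s1": [2.0, 3.0, 5.0], "s2": [0.0, 0.0, 0.0]},
                              index=["i1", "i2", "i3"])
        m = IsoformCountMatrix(values, pd.Series(["g"] * 3,
                                                 index=["i1", "i2", "i3"]))
        rm = normalize_isoform_vectors(m, "g")
        assert rm.sample_ids == ["s1"]
        assert rm.dropped_samples == ["s2"]
        assert np.allclose(rm.proportions.loc["s1"], [0.2, 0.3, 0.5])

    def test_untestable_genes_raise(self, toy_counts):
        with pytest.raises(ValueError, match="not testable"):
            normalize_isoform_vectors(toy_counts, "gC")  # single isoform
        with pytest.raises(ValueError, match="not testable"):
            normalize_isoform_vectors(toy_counts, "nope")


class TestLdaStatistic:
    def test_summary_formula_on_known_projections(self):
        s = _summary_from_projections(np.array([0.0, 2.0]),
                                      np.array([4.0, 6.0]))
        assert (s.mu_pt, s.mu_met) == (1.0, 5.0)
        assert s.var_pt == s.var_met == 2.0
        assert s.statistic == pytest.approx(4.0)

    def test_identical_groups_give_zero(self):
        ratios = ratio_matrix_1d([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
        _, summary = lda_project(ratios, labels_for(ratios))
        assert summary.statistic == pytest.approx(0.0, abs=1e-20)

    def test_statistic_invariant_under_projection_rescaling(self):
        rng = np.random.default_rng(3)
        proj_a, proj_b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        base = _summary_from_projections(proj_a, proj_b).statistic
        for _ in range(20):
            a, b = rng.uniform(0.1, 5), rng.normal(0, 3)
            s = _summary_from_projections(a * proj_a + b, a * proj_b + b)
            assert s.statistic == pytest.approx(base, rel=1e-9)

    def test_degenerate_variance_sentinels(self):
        same = _summary_from_projections(np.array([1.0, 1.0]),
                                         np.array([1.0, 1.0]))
        assert same.statistic == 0.0
        apart = _summary_from_projections(np.array([1.0, 1.0]),
                                          np.array([2.0, 2.0]))
        assert math.isinf(apart.statistic)

    def test_small_group_rejected(self):
        ratios = ratio_matrix_1d([0.5], [0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="insufficient group size"):
            lda_project(ratios, labels_for(ratios))

    def test_isoform_order_irrelevant(self):
        rng = np.random.default_rng(6)
        props = rng.dirichlet([2.0] * 4, size=12)
        idx = [f"PT{i}" for i in range(6)] + [f"MET{i}" for i in range(6)]
        a = RatioMatrix("g", pd.DataFrame(props, index=idx))
        perm = [2, 0, 3, 1]
        b = RatioMatrix("g", pd.DataFrame(props[:, perm], index=idx))
        sa = lda_project(a, labels_for(a))[1].statistic
        sb = lda_project(b, labels_for(b))[1].statistic
        assert sa == pytest.approx(sb, rel=1e-8)


class TestPermutationTest:
    def test_exhaustive_enumeration_oracle(self):
        """4 samples, maximal separation: of the C(4,2)=6 labelings only
        the observed one and its complement reach the observed statistic,
        so the exact p is 2/6."""
        ratios = ratio_matrix_1d([0.9, 0.8], [0.1, 0.2])
        p = lda_permutation_test(ratios, labels_for(ratios), n_iter=1000)
        assert p == pytest.approx(2 / 6)

    def test_sampled_p_respects_resolution_floor(self):
        rng = np.random.default_rng(1)
        ratios = ratio_matrix_1d(0.05 + 0.01 * rng.random(8),
                                 0.90 + 0.01 * rng.random(8))
        for n_iter in (19, 99):
            p = lda_permutation_test(ratios, labels_for(ratios),
                                     n_iter=n_iter, seed=0,
                                     exhaustive=False)
            assert p >= 1 / (n_iter + 1)

    def test_sampled_agrees_with_exhaustive(self):
        rng = np.random.default_rng(5)
        ratios = ratio_matrix_1d(rng.beta(3, 4, 5), rng.beta(4, 3, 5))
        exact = lda_permutation_test(ratios, labels_for(ratios),
                                     n_iter=10, exhaustive=True)
        sampled = lda_permutation_test(ratios, labels_for(ratios),
                                       n_iter=20000, seed=2,
                                       exhaustive=False)
        se = math.sqrt(exact * (1 - exact) / 20000)
        assert abs(sampled - exact) < 3 * se + 2 / 20000


class TestPca:
    def test_two_isoforms_give_one_component(self):
        rng = np.random.default_rng(2)
        ratios = ratio_matrix_1d(rng.random(4), rng.random(4))
        coords, var = pca_components(ratios)
        assert coords.shape == (8, 1)

    def test_identical_samples_give_zero_components(self):
        ratios = ratio_matrix_1d([0.4] * 3, [0.4] * 3)
        coords, var = pca_components(ratios)
        assert coords.shape[1] == 0

    def test_energy_conservation(self):
        """Total variance of the retained coordinates equals the total
        variance of the centered proportion matrix."""
        rng = np.random.default_rng(9)
        props = rng.dirichlet([1.5] * 5, size=20)
        idx = [f"s{i}" for i in range(20)]
        ratios = RatioMatrix("g", pd.DataFrame(props, index=idx))
        coords, var = pca_components(ratios)
        assert coords.shape[1] <= 4  # n-1 cap from the sum-to-1 constraint
        total = props.var(axis=0, ddof=1).sum()
        assert coords.to_numpy().var(axis=0, ddof=1).sum() == \
            pytest.approx(total, rel=1e-9)


class TestPerComponentTests:
    def test_welch_hand_example(self):
        # means differ by 1, each variance 1 at n=3: t = -1.2247, df = 4
        p = welch_t_pvalue([1, 2, 3], [2, 3, 4])
        t = -1 / math.sqrt(2 / 3)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), rel=1e-9)
        assert p == pytest.approx(0.288, abs=1e-3)

    def test_welch_degenerate_and_symmetry(self):
        assert welch_t_pvalue([1, 1], [1, 1]) == 1.0
        assert welch_t_pvalue([1, 1], [2, 2]) < 1e-12
        x, y = [1.0, 2.5, 3.0], [0.5, 0.7, 4.0]
        assert welch_t_pvalue(x, y) == pytest.approx(welch_t_pvalue(y, x))

    def test_independence_closed_form_example(self):
        # pooled (0,0,1,1), x = first two: Z = -sqrt(3)
        p = independence_pvalue([0, 0], [1, 1])
        assert p == pytest.approx(2 * stats.norm.sf(math.sqrt(3)), rel=1e-12)
        assert p == pytest.approx(0.0833, abs=2e-4)

    def test_independence_location_invariance_and_ties(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 7)
        assert independence_pvalue(x, y) == \
            pytest.approx(independence_pvalue(x + 10, y + 10), rel=1e-12)
        assert independence_pvalue([3, 3], [3, 3, 3]) == 1.0

    def test_rank_sum_exact_enumeration(self):
        # ranks of x are {1,2}: the single most extreme of C(4,2) splits
        assert rank_sum_pvalue([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_rank_sum_ties_and_dominance(self):
        assert rank_sum_pvalue([2, 2, 2], [2, 2], "two-sided") == 1.0
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        two = rank_sum_pvalue(x, y, "two-sided")
        assert min(rank_sum_pvalue(x, y, "less"),
                   rank_sum_pvalue(x, y, "greater")) <= two


class TestCombiners:
    def test_fisher_trivial_and_single(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        assert fisher_combine([0.37]) == pytest.approx(0.37, rel=1e-12)
        with pytest.raises(ValueError):
            fisher_combine([])

    def test_fisher_matches_chi2_tail_closed_form(self):
        # df = 4: upper tail is exp(-X/2) * (1 + X/2)
        for pair in ([0.05, 0.05], [0.2, 0.7], [0.01, 0.9]):
            x = -2 * sum(math.log(p) for p in pair)
            closed = math.exp(-x / 2) * (1 + x / 2)
            assert fisher_combine(pair) == pytest.approx(closed, rel=1e-12)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.01748,
                                                             abs=2e-5)

    def test_hmp_single_is_identity(self):
        assert hmp_combine([0.03]) == pytest.approx(0.03, rel=1e-12)

    def test_hmp_adjustment_exceeds_raw_mean(self):
        # raw harmonic mean of (0.02, 0.06) is 0.03; the asymptotically
        # exact adjustment is anti-conservative-corrected, so >= 0.03
        adj = hmp_combine([0.02, 0.06])
        assert adj >= 0.03
        assert adj < 0.2

    def test_hmp_monotone_in_each_input(self):
        grid = np.linspace(0.005, 0.9, 25)
        vals = [hmp_combine([p, 0.2, 0.5]) for p in grid]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_hmp_landau_parameterization_matches_integral_form(self):
        """scipy's Landau at loc=ln(pi/2), scale=pi/2 must reproduce the
        textbook density (1/pi)∫ exp(-t ln t - x t) sin(pi t) dt used to
        define the harmonic-mean-p tail."""
        def textbook(x):
            f = lambda t: math.exp(-t * math.log(t) - x * t) * \
                math.sin(math.pi * t)
            return quad(f, 1e-12, 80, limit=500)[0] / math.pi
        for x in (-0.5, 0.0, 1.0, 4.0):
            assert stats.landau.pdf(x, loc=math.log(math.pi / 2),
                                    scale=math.pi / 2) == \
                pytest.approx(textbook(x), rel=1e-6)

    def test_hmp_null_calibration_monte_carlo(self):
        """Under uniform null p-values the adjusted HMP is itself roughly
        uniform in the tail: P(hmp <= 0.05) ~ 0.05."""
        rng = np.random.default_rng(12)
        hits = sum(hmp_combine(rng.random(5)) <= 0.05 for _ in range(4000))
        assert abs(hits / 4000 - 0.05) < 0.015

    def test_geometric_mean(self):
        assert geometric_combine(0.04, 0.09) == pytest.approx(0.06)
        assert geometric_combine(0.3, 0.3) == pytest.approx(0.3)
        assert geometric_combine(1.0, 1.0) == 1.0


class TestBhAdjust:
    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_and_missing_passthrough(self):
        out = bh_adjust([0.2, np.nan, 0.01])
        assert np.isnan(out[1])
        assert out[2] == pytest.approx(0.02)

    def test_matches_statsmodels_on_complete_input(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.random(40)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(10)
        p = rng.random(25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDirPipeline:
    def test_geometric_identity_holds(self, small_cohort):
        counts, meta, _ = small_cohort
        res = dir_test_cohort(counts, meta, seed=0)
        ok = res.dropna(subset=["p_geo"])
        assert np.allclose(ok["p_geo"] ** 2,
                           ok["p_t_fisher"].clip(lower=np.finfo(float).eps)
                           * ok["p_coin_fisher"].clip(
                               lower=np.finfo(float).eps),
                           rtol=1e-9)

    def test_p_geo_between_its_factors(self, small_cohort):
        counts, meta, _ = small_cohort
        res = dir_test_cohort(counts, meta, seed=0).dropna(subset=["p_geo"])
        lo = np.minimum(res["p_t_fisher"], res["p_coin_fisher"])
        hi = np.maximum(res["p_t_fisher"], res["p_coin_fisher"])
        assert ((lo <= res["p_geo"] + 1e-12)
                & (res["p_geo"] <= hi + 1e-12)).all()

    def test_untestable_gene_reports_reason(self, toy_counts, toy_meta):
        res = dir_test_gene(toy_counts, toy_meta, "gC")
        assert np.isnan(res.p_geo)
        assert "not testable" in res.reason

    def test_planted_switch_is_detected(self):
        cfg = null_config(n_primary=20, n_metastatic=40, n_genes=30,
                          frac_dir_genes=0.2, dir_delta=0.3,
                          isoforms_per_gene_range=(2, 4), seed=13)
        counts, meta, truth = generate_cohort(cfg)
        res = dir_test_cohort(counts, meta, seed=1)
        planted = res.loc[list(truth.dir_genes)]
        assert (planted["p_geo"] < 0.05).mean() >= 0.9
        others = res.drop(index=list(truth.dir_genes))
        assert (others["p_geo"] < 0.05).mean() < 0.3


class TestCompareTests:
    def test_identical_candidate_is_perfect(self):
        rng = np.random.default_rng(3)
        ref = pd.Series(rng.random(200),
                        index=[f"g{i}" for i in range(200)])
        out = compare_tests(ref.rename("cand").to_frame(), ref)
        row = out.loc["cand"]
        assert row["pearson_r_p"] == pytest.approx(1.0)
        assert row["spearman_rho_rank"] == pytest.approx(1.0)
        assert row["youden_j_0.05"] == pytest.approx(1.0)

    def test_anticorrelated_candidate(self):
        ref = pd.Series(np.linspace(0.01, 0.99, 50),
                        index=[f"g{i}" for i in range(50)])
        cand = (1 - ref).rename("cand").to_frame()
        out = compare_tests(cand, ref)
        assert out.loc["cand", "spearman_rho_rank"] == pytest.approx(-1.0)

    def test_degenerate_reference_class_gives_nan_j(self):
        ref = pd.Series([0.5, 0.6, 0.7], index=list("abc"))
        out = compare_tests(ref.rename("cand").to_frame(), ref)
        assert np.isnan(out.loc["cand", "youden_j_0.05"])

    def test_geometric_mean_tracks_permutation_better_than_wilcoxon(self):
        """On a mid-power synthetic cohort the geometric-mean test agrees
        with the permutation reference at alpha=0.05 at least as well as
        the Wilcoxon-per-component variant (rank tests lose calls to the
        ties created by dropout zeros)."""
        cfg = CohortConfig(
            n_primary=30, n_metastatic=90, n_genes=300,
            frac_dir_genes=0.1, dir_delta=0.2, frac_de_genes=0.1,
            dirichlet_concentration=15.0,
            isoforms_per_gene_range=(2, 4), seed=17)
        counts, meta, _ = generate_cohort(cfg)
        res = dir_test_cohort(counts, meta, n_iter=499, seed=23,
                              run_permutation=True)
        out = compare_tests(res[["p_geo", "p_wilcoxon_fisher"]],
                            res["p_perm"])
        assert out.loc["p_geo", "youden_j_0.05"] > \
            out.loc["p_wilcoxon_fisher", "youden_j_0.05"]
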