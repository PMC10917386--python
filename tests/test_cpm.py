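"""CPM engine: partial correlation, edge selection, strengths, LOOCV,
permutation inference, FDR."""

import numpy as np
import pytest
from scipy import stats

from cpmconn import (
    EdgeMask,
    fdr_bh,
    fit_tail_model,
    loocv_cpm,
    network_strength,
    partial_correlation,
    permutation_test,
    run_cpm,
    select_edges,
)
from cpmconn.core import edge_index


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.normal(size=(2, 50))
        r, p, df = partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert df == 48

    def test_df_formula(self, rng):
        x, y = rng.normal(size=(2, 20))
        C = rng.normal(size=(20, 3))
        *_, df = partial_correlation(x, y, C)
        assert df == 15

    def test_matches_independent_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        x, y = rng.normal(size=(2, 60))
        C = rng.normal(size=(60, 2))
        d = pd.DataFrame({"x": x, "y": y, "c1": C[:, 0], "c2": C[:, 1]})
        ref = pingouin.partial_corr(d, x="x", y="y", covar=["c1", "c2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        r, p, _ = partial_correlation(x, y, C)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_removes_shared_confound(self):
        # x and y both driven by c; controlling for c leaves ~nothing
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            c = rng.normal(size=200)
            x = c + rng.normal(size=200)
            y = 2 * c + rng.normal(size=200)
            r, p, _ = partial_correlation(x, y, c)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.03
        assert np.mean(np.abs(rs)) < 0.1

    def test_zero_residual_variance_errors(self, rng):
        c = rng.normal(size=30)
        with pytest.raises(ValueError, match="residual"):
            partial_correlation(2 * c, rng.normal(size=30), c)


class TestSelectEdges:
    def test_behaviour_copy_of_edge_selected(self, rng):
        X = rng.normal(size=(40, 10))
        pos, neg = select_edges(X, X[:, 3], p_threshold=0.01)
        assert pos.to_vector()[3] == 1
        assert neg.n_edges == 0
        # N inferred from E=10 -> 5 nodes
        assert pos.n_nodes == 5

    def test_masks_disjoint_and_signed(self, rng):
        X = rng.normal(size=(60, 45))
        y = X[:, 0] - X[:, 1] + 0.5 * rng.normal(size=60)
        pos, neg = select_edges(X, y, p_threshold=0.05)
        assert pos.to_vector()[0] == 1
        assert neg.to_vector()[1] == -1
        assert not np.any((pos.to_vector() != 0) & (neg.to_vector() != 0))

    def test_zero_variance_behaviour_errors(self, rng):
        with pytest.raises(ValueError, match="variance"):
            select_edges(rng.normal(size=(20, 10)), np.ones(20))

    def test_selection_equivalent_to_p_threshold(self, rng):
        # |r| > r_critical must match two-sided p < threshold edge by edge
        X = rng.normal(size=(35, 28))
        y = rng.normal(size=35)
        C = rng.normal(size=(35, 2))
        pos, neg = select_edges(X, y, C, p_threshold=0.1)
        sel = (pos.to_vector() != 0) | (neg.to_vector() != 0)
        for e in range(28):
            _, p, _ = partial_correlation(X[:, e], y, C)
            assert sel[e] == (p < 0.1)


class TestNetworkStrength:
    def test_matches_double_loop_oracle(self, rng):
        n_nodes = 12
        E = n_nodes * (n_nodes - 1) // 2
        vals = rng.normal(size=E)
        mvec = rng.choice([-1, 0, 1], size=E, p=[0.2, 0.6, 0.2])
        mask = EdgeMask.from_vector(mvec)
        z = np.zeros((n_nodes, n_nodes))
        iu = edge_index(n_nodes)
        z[iu] = vals
        z = z + z.T
        for sign in (-1, 1):
            ref = sum(z[i, j] for i in range(n_nodes)
                      for j in range(i + 1, n_nodes)
                      if mask.values[i, j] == sign)
            assert network_strength(vals, mask, sign) == pytest.approx(ref, abs=1e-12)

    def test_empty_and_single_edge_masks(self):
        mask0 = EdgeMask.from_vector(np.zeros(6, dtype=int))
        assert network_strength(np.arange(6.0), mask0, 1) == 0.0
        m = np.zeros(6, dtype=int)
        m[2] = 1
        assert network_strength(np.arange(6.0), EdgeMask.from_vector(m), 1) == 2.0


class TestTailModel:
    def test_exact_line_recovered(self):
        s = np.array([1.0, 2, 3, 4])
        tm = fit_tail_model(s, 2 * s + 1)
        assert (tm.slope, tm.intercept) == (pytest.approx(2), pytest.approx(1))

    def test_degenerate_predicts_mean(self):
        tm = fit_tail_model(np.ones(5), np.array([1.0, 2, 3, 4, 5]))
        assert tm.degenerate
        assert np.allclose(tm.predict(np.ones(3)), 3.0)

    def test_matches_normal_equations(self, rng):
        s, y = rng.normal(size=(2, 50))
        tm = fit_tail_model(s, y)
        A = np.column_stack([s, np.ones(50)])
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        assert tm.slope == pytest.approx(ref[0], abs=1e-10)
        assert tm.intercept == pytest.approx(ref[1], abs=1e-10)


class TestLoocv:
    def test_consensus_is_intersection_of_fold_masks(self, rng):
        X = rng.normal(size=(30, 45))
        y = -2 * X[:, 5] + rng.normal(size=30)
        res = loocv_cpm(X, y, p_threshold=0.05, tail="both")
        for t in ("pos", "neg"):
            sel = res.fold_selections[t]
            cons = np.abs(res.consensus[t].to_vector()).astype(bool)
            assert np.array_equal(cons, sel.all(axis=0))
            # consensus is a subset of every fold mask
            assert np.all(sel[:, cons])
        assert res.consensus["neg"].to_vector()[5] == -1

    def test_near_noiseless_recovery(self, small_planted):
        ds = small_planted
        em, pm = ds.sample("model")
        # regenerate with tiny noise for a sharp check
        from cpmconn import GeneratorSpec, generate
        spec = GeneratorSpec(n_model=60, n_validation=0, n_control=0,
                             n_nodes=20, n_true_edges=6, noise_sd=0.05,
                             site_gamma_sd=0.0, site_gamma_mean_sd=0.0,
                             site_delta_log_sd=0.0, seed=31)
        d2 = generate(spec)
        em, pm = d2.sample("model")
        res = loocv_cpm(em, pm["score_total"].to_numpy(), tail="neg")
        assert res.evaluation["neg"][0] >= 0.9

    def test_empty_folds_predict_training_mean(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        res = loocv_cpm(X, y, p_threshold=1e-9, tail="neg")
        assert res.invalid["neg"]
        assert res.n_empty_folds["neg"] == 15
        means = np.array([np.delete(y, s).mean() for s in range(15)])
        assert np.allclose(res.predictions["neg"], means)

    def test_fold_model_reconstruction(self, rng):
        X = rng.normal(size=(20, 15))
        y = X[:, 2] + 0.3 * rng.normal(size=20)
        res = loocv_cpm(X, y, p_threshold=0.05, tail="both")
        fm = res.fold_model(7)
        assert np.array_equal(fm.training_index,
                              np.delete(np.arange(20), 7))
        assert np.array_equal(fm.positive.to_vector() == 1,
                              res.fold_selections["pos"][7])


class TestCombinedModel:
    def test_joint_model_uses_both_tails(self, rng):
        X = rng.normal(size=(50, 45))
        y = X[:, 0] - X[:, 1] + 0.4 * rng.normal(size=50)
        res = loocv_cpm(X, y, p_threshold=0.01, tail="combined")
        assert set(res.predictions) == {"pos", "neg", "combined"}
        # joint model sees both planted tails: at least as good as the
        # better single tail (tolerating cross-validation noise)
        best_single = max(res.evaluation["pos"][0], res.evaluation["neg"][0])
        assert res.evaluation["combined"][0] > best_single - 0.05

    def test_combined_permutation(self, rng):
        X = rng.normal(size=(25, 20))
        y = rng.normal(size=25)
        perm = permutation_test(X, y, tail="combined", n_perm=100, seed=4)
        assert set(perm) == {"combined"}
        assert 0 < perm["combined"].p_perm <= 1

    def test_combined_falls_back_to_mean_when_empty(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        res = loocv_cpm(X, y, p_threshold=1e-9, tail="combined")
        assert res.invalid["combined"]
        means = np.array([np.delete(y, s).mean() for s in range(15)])
        assert np.allclose(res.predictions["combined"], means)


class TestPermutation:
    def test_minimum_attainable_p(self):
        from cpmconn import GeneratorSpec, generate
        from cpmconn.harmonize import covariate_matrix
        spec = GeneratorSpec(n_model=60, n_validation=0, n_control=0,
                             n_nodes=20, n_true_edges=6, noise_sd=0.3,
                             seed=13)
        ds = generate(spec)
        em, pm = ds.sample("model")
        C = covariate_matrix(pm, ["age", "sex", "mfd"])
        res = permutation_test(em, pm["score_total"].to_numpy(), C,
                               tail="neg", n_perm=100, seed=3)
        assert res["neg"].p_perm == pytest.approx(1 / 101)
        assert len(res["neg"].null_r) == 100

    def test_same_seed_reproduces_null_sequence(self, rng):
        X = rng.normal(size=(25, 20))
        y = rng.normal(size=25)
        a = permutation_test(X, y, tail="neg", n_perm=100, seed=8)
        b = permutation_test(X, y, tail="neg", n_perm=100, seed=8)
        assert np.array_equal(a["neg"].null_r, b["neg"].null_r)
        c = permutation_test(X, y, tail="neg", n_perm=100, seed=9)
        assert not np.array_equal(a["neg"].null_r, c["neg"].null_r)

    def test_null_distribution_centred_near_zero(self, rng):
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        res = permutation_test(X, y, tail="both", n_perm=200, seed=2)
        for t in ("pos", "neg"):
            assert abs(res[t].mean_null_r) < 0.15

    def test_run_cpm_attaches_permutation(self, rng):
        X = rng.normal(size=(20, 15))
        y = X[:, 0] + 0.5 * rng.normal(size=20)
        res = run_cpm(X, y, tail="pos", n_perm=100, seed=1)
        assert "pos" in res.permutation
        assert 0 < res.permutation["pos"].p_perm <= 1


class TestFdr:
    def test_closed_form_example(self):
        q = fdr_bh([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_matches_naive_step_up(self, rng):
        p = rng.uniform(size=25)
        # independent oracle: literal BH step-up
        order = np.argsort(p)
        m = len(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        ref = np.empty(m)
        ref[order] = np.minimum(q_sorted, 1)
        assert np.allclose(fdr_bh(p), ref, atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])
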