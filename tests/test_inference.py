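import numpy as np
import pandas as pd
import pytest
from scipy import stats

from outwelling.community import dissimilarity_matrix
from outwelling.inference import (
    dblm_fit,
    dblm_select,
    gower_center,
    gradient_fit,
    normalize_env,
    oneway_anova,
    principal_coordinates,
    tukey_hsd,
)


def euclidean_dm(y):
    y = np.asarray(y, dtype=float)
    return np.abs(y[:, None] - y[None, :])


class TestGowerCentering:
    def test_zero_distances_give_zero_g(self):
        assert np.allclose(gower_center(np.zeros((4, 4))), 0.0)

    def test_recovers_centered_cross_products_on_a_line(self):
        # classical principal-coordinates identity: for Euclidean
        # distances of scalar coordinates, G_ij = (x_i - xbar)(x_j - xbar)
        x = np.array([0.0, 1.0, 3.0])
        g = gower_center(euclidean_dm(x))
        xc = x - x.mean()
        assert np.allclose(g, np.outer(xc, xc), atol=1e-12)

    def test_row_sums_zero(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        g = gower_center(d)
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-10)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            gower_center(d)


class TestDblmFit:
    def test_matches_classical_ols_f(self):
        # univariate response with Euclidean distances: pseudo-F and R^2
        # must equal the ordinary regression F and R^2
        rng = np.random.default_rng(11)
        x = np.arange(1.0, 10.0)
        y = 2.0 + 0.5 * x + rng.normal(0, 1.0, 9)
        env = pd.DataFrame({"x": x})
        res = dblm_fit(euclidean_dm(y), env, ["x"], n_perm=99, seed=0)
        lr = stats.linregress(x, y)
        n = len(y)
        f_ols = lr.rvalue**2 / (1 - lr.rvalue**2) * (n - 2)
        assert res.r2 == pytest.approx(lr.rvalue**2, abs=1e-8)
        assert res.pseudo_f == pytest.approx(f_ols, abs=1e-8)

    def test_constant_community_r2_zero(self):
        env = pd.DataFrame({"x": np.arange(5.0)})
        res = dblm_fit(np.zeros((5, 5)), env, ["x"], n_perm=99, seed=0)
        assert res.r2 == 0.0

    def test_nesting_monotone_r2(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.integers(1, 20, size=(9, 12)).astype(float))
        d = dissimilarity_matrix(mat)
        env = pd.DataFrame(rng.normal(size=(9, 3)), columns=["a", "b", "c"])
        r2 = [
            dblm_fit(d, env, cols, n_perm=99, seed=0).r2
            for cols in (["a"], ["a", "b"], ["a", "b", "c"])
        ]
        assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 2e-12

    def test_exact_permutation_on_small_n(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=6)
        env = pd.DataFrame({"x": rng.normal(size=6)})
        res = dblm_fit(euclidean_dm(y), env, ["x"], n_perm="auto", seed=0)
        assert res.metadata["permutation_scheme"] == "exact"
        assert res.n_perm == 720
        assert 0 < res.perm_p <= 1

    def test_bit_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.integers(1, 20, size=(12, 6)).astype(float))
        d = dissimilarity_matrix(mat)
        env = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        r1 = dblm_fit(d, env, ["a", "b"], n_perm=199, seed=4)
        r2 = dblm_fit(d, env, ["a", "b"], n_perm=199, seed=4)
        assert r1.perm_p == r2.perm_p and r1.terms.equals(r2.terms)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(9)
        x = np.arange(9.0)
        comm = np.outer(x, np.ones(10)) + rng.normal(0, 0.1, (9, 10)) + 5
        d = dissimilarity_matrix(pd.DataFrame(comm))
        env = pd.DataFrame({"x": x})
        res = dblm_fit(d, env, ["x"], n_perm="auto", seed=0)
        assert res.r2 > 0.9
        assert res.perm_p < 0.01


class TestDblmSelect:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=9)
        env = pd.DataFrame({"x": np.arange(9.0)})
        res = dblm_select(euclidean_dm(y), env, ["x"], criterion="adj_r2", n_perm=99, seed=0)
        assert res.selected in ([], ["x"])

    def test_true_drivers_recovered(self):
        # communities built from distance + density; four pure noise covariates
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n = 12
            dist = np.arange(n, dtype=float)
            dens = rng.normal(size=n)
            comm = (
                5
                + np.outer(dist, rng.uniform(0.5, 1.5, 15))
                + np.outer(dens, rng.uniform(0.5, 1.5, 15))
                + rng.normal(0, 0.3, (n, 15))
            )
            d = dissimilarity_matrix(pd.DataFrame(np.abs(comm)))
            env = pd.DataFrame(
                {
                    "distance": dist,
                    "density": dens,
                    **{f"noise{i}": rng.normal(size=n) for i in range(4)},
                }
            )
            res = dblm_select(d, env, list(env.columns), criterion="adj_r2", n_perm=99, seed=rep)
            if {"distance", "density"} <= set(res.selected):
                hits += 1
        assert hits >= 9

    def test_noise_covariates_pruned_by_adj_r2(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(np.abs(rng.normal(size=(9, 30))))
        d = dissimilarity_matrix(mat)
        env = pd.DataFrame(rng.normal(size=(9, 6)), columns=list("abcdef"))
        res = dblm_select(d, env, list("abcdef"), criterion="adj_r2", n_perm=99, seed=1)
        assert len(res.selected) <= 3
        assert res.adj_r2 < 0.5

    def test_selection_path_recorded(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(np.abs(rng.normal(size=(9, 10))))
        d = dissimilarity_matrix(mat)
        env = pd.DataFrame(rng.normal(size=(9, 3)), columns=["a", "b", "c"])
        res = dblm_select(d, env, ["a", "b", "c"], criterion="adj_r2", n_perm=99, seed=0)
        assert res.path[0][0] == "start"
        assert res.metadata["criterion"] == "adj_r2"


class TestNormalise:
    def test_zscore_within_groups(self):
        env = pd.DataFrame(
            {"location": ["A"] * 3 + ["B"] * 3, "v": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0]}
        )
        out = normalize_env(env, ["v"], by="location")
        for loc in ("A", "B"):
            sub = out[out["location"] == loc]["v"]
            assert sub.mean() == pytest.approx(0.0)
            assert sub.std(ddof=1) == pytest.approx(1.0)


class TestAnovaTukey:
    def test_hand_computed_f(self):
        f, df, p = oneway_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)
        assert df == (1, 4)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        f, _, p_f = oneway_anova([a, b])
        t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p_f == pytest.approx(t.pvalue, rel=1e-10)

    def test_identical_groups(self):
        f, _, p = oneway_anova([[2, 2], [2, 2], [2, 2]])
        assert f == 0.0 and p == 1.0

    def test_tukey_two_groups_matches_pooled_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        tk = tukey_hsd([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert tk.loc[0, "p"] == pytest.approx(t.pvalue, abs=1e-6)

    def test_tukey_flags_only_shifted_group(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 10)
        groups = [base, base + rng.normal(0, 1, 10) * 0.1, base + 15]
        tk = tukey_hsd(groups, labels=["g0", "g1", "g2"])
        sig = set(map(tuple, tk[tk["significant"]][["a", "b"]].to_numpy()))
        assert sig == {("g0", "g2"), ("g1", "g2")}

    def test_tukey_identical_groups_nothing_significant(self):
        tk = tukey_hsd([[1, 1, 1], [1, 1, 1]])
        assert not tk["significant"].any()


class TestGradientFit:
    def test_exact_linear(self):
        rank = np.arange(1, 10)
        fit = gradient_fit(3.0 - 0.25 * rank, rank, family="linear")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.params["slope"] == pytest.approx(-0.25)

    def test_constant_series(self):
        fit = gradient_fit(np.full(9, 2.0), np.arange(9), family="linear")
        assert fit.params["slope"] == 0.0 and fit.r2 == 0.0

    def test_exponential_decay_recovery(self):
        rng = np.random.default_rng(12)
        rank = np.arange(1, 10, dtype=float)
        y = 0.6 * np.exp(-0.3 * rank) + rng.normal(0, 0.01, 9)
        fit = gradient_fit(y, rank, family="exponential-decay")
        assert fit.params["b"] == pytest.approx(0.3, rel=0.10)
        assert fit.r2 > 0.9

    def test_categorical_bonferroni(self):
        rng = np.random.default_rng(13)
        y = np.concatenate([rng.normal(0, 0.3, 5), rng.normal(0, 0.3, 5), rng.normal(8, 0.3, 5)])
        g = ["s1"] * 5 + ["s2"] * 5 + ["s3"] * 5
        fit = gradient_fit(y, g, family="categorical")
        assert fit.p < 0.001
        pw = fit.pairwise.set_index(["a", "b"])["p_bonferroni"]
        assert pw.loc[("s1", "s3")] < 0.05 and pw.loc[("s2", "s3")] < 0.05
        assert pw.loc[("s1", "s2")] > 0.1

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            gradient_fit([1, 2, 3], [1, 2, 3], family="spline")


class TestOrdination:
    def test_pcoa_recovers_line_configuration(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        coords = principal_coordinates(euclidean_dm(x), n_axes=2)
        # first axis reproduces centred coordinates up to sign
        axis1 = coords["axis1"].to_numpy()
        xc = x - x.mean()
        assert np.allclose(np.abs(axis1), np.abs(xc), atol=1e-10)
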