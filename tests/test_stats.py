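"""Differential statistics, Dunnett comparisons, PLS-DA and VIP."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lipidquant.stats import (
    differential_stats,
    dunnett_vs_control,
    heatmap_matrix,
    plsda_fit,
    vip_scores,
)

from .oracles import dunnett_max_t_pvalue


def _frame(rows, columns=None):
    return pd.DataFrame(rows) if columns is None else pd.DataFrame(
        rows, columns=columns
    )


class TestDifferentialStats:
    def test_pooled_t_closed_form(self):
        v = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["x"],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(
            ["control"] * 3 + ["patient"] * 3, index=v.columns
        )
        out = differential_stats(v, groups)
        # closed form: t = 3.6742, df = 4 (frozen via the incomplete-beta
        # tail of the t distribution)
        assert out.loc["x", "t_p"] == pytest.approx(0.0213116, abs=1e-6)

    def test_identical_groups_degenerate(self):
        v = pd.DataFrame(
            [[5.0] * 6], index=["x"], columns=[f"s{i}" for i in range(6)]
        )
        groups = pd.Series(["control"] * 3 + ["patient"] * 3, index=v.columns)
        out = differential_stats(v, groups)
        assert out.loc["x", "t_p"] == 1.0
        assert out.loc["x", "fold"] == 1.0
        assert bool(out.loc["x", "degenerate"])

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        v = pd.DataFrame(
            rng.normal(size=(30, 8)), columns=[f"s{i}" for i in range(8)]
        )
        groups = pd.Series(["control"] * 4 + ["patient"] * 4, index=v.columns)
        out = differential_stats(v, groups)
        raw = out["t_p"]
        assert np.allclose(out["t_p_bonf"], np.minimum(raw * 30, 1.0))
        assert (out["t_p_bonf"] >= raw - 1e-15).all()

    def test_welch_option(self):
        rng = np.random.default_rng(1)
        v = pd.DataFrame(
            rng.normal(size=(5, 10)), columns=[f"s{i}" for i in range(10)]
        )
        groups = pd.Series(["control"] * 5 + ["patient"] * 5, index=v.columns)
        pooled = differential_stats(v, groups, equal_var=True)["t_p"]
        welch = differential_stats(v, groups, equal_var=False)["t_p"]
        assert not np.allclose(pooled, welch)

    def test_needs_two_per_arm(self):
        v = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        groups = pd.Series({"a": "control", "b": "patient"})
        with pytest.raises(ValueError, match="2 samples"):
            differential_stats(v, groups)


class TestDunnett:
    @staticmethod
    def _data(k=3, n=4, seed=7, shift=0.0):
        rng = np.random.default_rng(seed)
        cols, labels = [], []
        for g in range(k + 1):
            for r in range(n):
                cols.append(f"g{g}_r{r}")
                labels.append("control" if g == 0 else f"grp{g}")
        v = pd.DataFrame(
            rng.normal(size=(6, len(cols))), columns=cols
        )
        v.iloc[0, n:] += shift
        return v, pd.Series(labels, index=cols)

    def test_adjusted_at_least_raw(self):
        v, groups = self._data()
        out = dunnett_vs_control(v, groups, "control", n_mc=20_000, seed=1)
        assert (out["p_dunnett"] >= out["p_raw"] - 1e-12).all()

    def test_single_comparison_matches_t_test(self):
        v, groups = self._data(k=1, n=6)
        out = dunnett_vs_control(v, groups, "control", n_mc=100_000, seed=2)
        for name in v.index:
            x = v.loc[name, groups == "control"]
            y = v.loc[name, groups != "control"]
            p_t = scipy.stats.ttest_ind(y, x, equal_var=True).pvalue
            assert out.loc[(name, "grp1"), "p_dunnett"] == pytest.approx(
                p_t, abs=0.005
            )

    def test_matches_scipy_dunnett_oracle(self):
        v, groups = self._data(k=3, n=4, shift=1.5)
        out = dunnett_vs_control(v, groups, "control", n_mc=200_000, seed=3)
        ctrl = v.loc[:, (groups == "control").to_numpy()]
        name = v.index[0]
        arms = [
            v.loc[name, (groups == g).to_numpy()].to_numpy()
            for g in ("grp1", "grp2", "grp3")
        ]
        ref = scipy.stats.dunnett(
            *arms, control=ctrl.loc[name].to_numpy()
        ).pvalue
        mine = [
            out.loc[(name, g), "p_dunnett"] for g in ("grp1", "grp2", "grp3")
        ]
        assert np.allclose(mine, ref, atol=0.01)

    def test_matches_brute_force_mc_oracle(self):
        # balanced k=3 design: adjusted p for an observed |t| from a raw
        # data-level Monte-Carlo at 10x the replication
        v, groups = self._data(k=3, n=4, shift=1.2)
        out = dunnett_vs_control(v, groups, "control", n_mc=200_000, seed=4)
        name = v.index[0]
        t_obs = out.loc[(name, "grp1"), "t"]
        p_oracle = dunnett_max_t_pvalue(
            t_obs, [4, 4, 4], 4, n_draws=400_000, seed=99
        )
        assert out.loc[(name, "grp1"), "p_dunnett"] == pytest.approx(
            p_oracle, abs=0.005
        )

    def test_absent_control_rejected(self):
        v, groups = self._data()
        with pytest.raises(ValueError, match="absent"):
            dunnett_vs_control(v, groups, "nope")


def _informative_dataset(seed=0, n_per=10, p=50, shift=3.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p))
    X[n_per:, 0] += shift  # single informative column
    idx = [f"s{i}" for i in range(2 * n_per)]
    cols = [f"v{j}" for j in range(p)]
    groups = pd.Series(
        ["control"] * n_per + ["patient"] * n_per, index=idx
    )
    return pd.DataFrame(X, index=idx, columns=cols), groups


class TestPLSDA:
    def test_informative_column_dominates_weights_and_vip(self):
        for seed in range(10):
            X, groups = _informative_dataset(seed=seed)
            model = plsda_fit(X, groups, n_components=2)
            w1 = np.abs(model.weights[:, 0])
            assert model.feature_names[int(np.argmax(w1))] == "v0"
            vip = vip_scores(model)
            assert vip.idxmax() == "v0"

    def test_scores_orthogonal(self):
        X, groups = _informative_dataset(seed=3)
        model = plsda_fit(X, groups, n_components=3)
        T = model.scores
        g = T.T @ T
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(g)).max()

    def test_weights_unit_norm(self):
        X, groups = _informative_dataset(seed=4)
        model = plsda_fit(X, groups)
        assert np.allclose(np.linalg.norm(model.weights, axis=0), 1.0)

    def test_sample_duplication_leaves_weights_unchanged(self):
        X, groups = _informative_dataset(seed=5)
        X2 = pd.concat([X, X.set_index(X.index + "_d")])
        groups2 = pd.concat(
            [groups, groups.set_axis(groups.index + "_d")]
        )
        m1 = plsda_fit(X, groups)
        m2 = plsda_fit(X2, groups2)
        # identical up to sign per component
        for a in range(m1.n_components):
            w1, w2 = m1.weights[:, a], m2.weights[:, a]
            s = np.sign(w1 @ w2)
            assert np.allclose(w1, s * w2, atol=1e-6)

    def test_component1_agrees_with_sklearn(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, groups = _informative_dataset(seed=6)
        model = plsda_fit(X, groups, n_components=2)
        Y = np.column_stack(
            [(groups == g).to_numpy(float) for g in model.class_labels]
        )
        Xs = (X - X.mean()) / X.std(ddof=1)
        pls = sklearn.PLSRegression(n_components=2, scale=False)
        pls.fit(Xs.to_numpy(), Y - Y.mean(axis=0))
        w_ref = pls.x_weights_[:, 0]
        w = model.weights[:, 0]
        s = np.sign(w @ w_ref)
        assert np.allclose(w, s * w_ref, atol=1e-6)

    def test_too_many_components_rejected(self):
        X, groups = _informative_dataset(seed=7, n_per=3, p=4)
        with pytest.raises(ValueError, match="exceeds rank"):
            plsda_fit(X, groups, n_components=6)


class TestVIP:
    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {"only": np.r_[rng.normal(0, 1, 8), rng.normal(2, 1, 8)]},
            index=[f"s{i}" for i in range(16)],
        )
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=X.index)
        model = plsda_fit(X, groups, n_components=1)
        assert vip_scores(model)["only"] == pytest.approx(1.0, abs=1e-12)

    def test_sum_of_squares_identity(self):
        for seed in (0, 1, 2):
            X, groups = _informative_dataset(seed=seed)
            model = plsda_fit(X, groups, n_components=2)
            vip = vip_scores(model)
            assert (vip ** 2).sum() == pytest.approx(len(vip), abs=1e-6)
        assert (vip >= 0).all()


class TestHeatmap:
    def test_rows_centered(self):
        rng = np.random.default_rng(9)
        v = pd.DataFrame(
            rng.uniform(0.1, 10, (20, 6)),
            index=[f"m{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        ranking = pd.Series(rng.uniform(size=20), index=v.index)
        hm, order = heatmap_matrix(v, ranking, k=10)
        assert hm.shape == (10, 6)
        assert np.abs(hm.mean(axis=1)).max() < 1e-12

    def test_full_matrix_in_ranking_order(self):
        v = pd.DataFrame(
            np.arange(12.0).reshape(4, 3) + 1,
            index=list("abcd"), columns=["s1", "s2", "s3"],
        )
        ranking = pd.Series([0.1, 0.4, 0.2, 0.3], index=list("abcd"))
        hm, order = heatmap_matrix(v, ranking, k=4)
        assert order == ["b", "d", "c", "a"]

    def test_zero_handling_via_pseudocount(self):
        v = pd.DataFrame(
            [[0.0, 1.0, 2.0]], index=["x"], columns=["s1", "s2", "s3"]
        )
        ranking = pd.Series([1.0], index=["x"])
        hm, _ = heatmap_matrix(v, ranking, k=1)
        assert np.isfinite(hm.to_numpy()).all()

    def test_bad_k_rejected(self):
        v = pd.DataFrame([[1.0]], index=["x"], columns=["s"])
        with pytest.raises(ValueError, match="k must"):
            heatmap_matrix(v, pd.Series([1.0], index=["x"]), k=0)
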