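"""LG ratio, linear models + AIC reduction, Tukey, RDA, LOWESS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from primatefaces import models as md


class TestLGRatio:
    @pytest.mark.parametrize(
        "male, female, expected",
        [(10.0, 5.0, -1.0), (5.0, 10.0, 1.0), (7.0, 7.0, 0.0)],
    )
    def test_examples(self, male, female, expected):
        assert md.lg_ratio(male, female) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.1, 1e3, allow_nan=False),
        st.floats(0.1, 1e3, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        assert md.lg_ratio(a, b) == pytest.approx(-md.lg_ratio(b, a), abs=1e-9)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            md.lg_ratio(0.0, 5.0)


class TestFitLM:
    def test_exact_linear_fit(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        fit = md.fit_lm(df, "y", ["x"])
        assert fit.coefficients.loc["x", "estimate"] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_intercept_only_r2_zero(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=12)})
        fit = md.fit_lm(df, "y", [])
        assert fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(30, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta + rng.normal(size=30)
        df = pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"])
        df["y"] = y
        fit = md.fit_lm(df, "y", ["x1", "x2", "x3", "x4"])
        Xd = np.column_stack([np.ones(30), X])
        oracle = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(fit.coefficients["estimate"].values, oracle, atol=1e-9)

    def test_last_term_f_equals_t_squared(self, rng):
        """Type-I F of the final 1-df term equals its coefficient t^2."""
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(25, 3)), columns=["x1", "x2", "y"])
            fit = md.fit_lm(df, "y", ["x1", "x2"])
            f_last = fit.anova.loc["x2", "F"]
            t_last = fit.coefficients.loc["x2", "t"]
            assert f_last == pytest.approx(t_last**2, rel=1e-9)

    def test_aliased_term_rejected(self, rng):
        df = pd.DataFrame({"x1": rng.normal(size=20)})
        df["x2"] = 2 * df["x1"]
        df["y"] = rng.normal(size=20)
        with pytest.raises(ValueError, match="alias"):
            md.fit_lm(df, "y", ["x1", "x2"])


class TestReduceAIC:
    def test_selects_true_predictor(self, rng):
        """Backward AIC always keeps the active term; inert terms survive
        only at the known AIC keep-rate (P(chi2_1 > 2) ~ 0.157 each, so the
        exact model {x1} appears in roughly (1 - 0.157)^2 ~ 71% of runs)."""
        hits_exact = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 200
            df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x1", "x2", "x3"])
            df["y"] = 1.0 * df["x1"] + rng.normal(scale=0.5, size=n)
            red = md.reduce_aic(md.fit_lm(df, "y", ["x1", "x2", "x3"]))
            if red.terms == ["x1"]:
                hits_exact += 1
            assert "x1" in red.terms
        # expect ~71 of 100; allow generous binomial slack on either side
        assert 55 <= hits_exact <= 90

    def test_pure_noise_selects_empty_model(self, rng):
        empty = 0
        n_rep = 60
        for _ in range(n_rep):
            df = pd.DataFrame(rng.normal(size=(200, 4)),
                              columns=["x1", "x2", "x3", "y"])
            red = md.reduce_aic(md.fit_lm(df, "y", ["x1", "x2", "x3"]))
            empty += not red.terms
        assert empty > n_rep / 2

    def test_dropping_never_raises_log_likelihood(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 5)),
                          columns=["x1", "x2", "x3", "x4", "y"])
        full = md.fit_lm(df, "y", ["x1", "x2", "x3", "x4"])
        red = md.reduce_aic(full)
        assert red.log_likelihood <= full.log_likelihood + 1e-9


class TestTukey:
    def test_identical_groups_not_significant(self, rng):
        vals = np.tile(rng.normal(size=30), 3)
        groups = np.repeat(["a", "b", "c"], 30)
        out = md.tukey_hsd(vals, groups)
        assert (out["p_adjusted"] > 0.05).all()

    def test_huge_effect_detected(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(5, 1, 30)]
        )
        groups = np.repeat(["a", "b", "c"], 30)
        out = md.tukey_hsd(vals, groups).set_index(["group_a", "group_b"])
        assert out.loc[("a", "c"), "p_adjusted"] < 0.01
        assert out.loc[("b", "c"), "p_adjusted"] < 0.01
        assert out.loc[("a", "b"), "p_adjusted"] > 0.05

    def test_adjusted_p_not_below_pairwise_p(self, rng):
        vals = rng.normal(size=45)
        groups = np.repeat(["a", "b", "c"], 15)
        out = md.tukey_hsd(vals, groups)
        for row in out.itertuples():
            t = stats.ttest_ind(
                vals[groups == row.group_a], vals[groups == row.group_b]
            )
            assert row.p_adjusted >= t.pvalue - 1e-12

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            md.tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestRDAFit:
    def test_saturated_constraints_explain_everything(self, rng):
        Y = rng.normal(size=(10, 3))
        X = np.eye(10)[:, :9]  # spans all between-item contrasts
        res = md.rda_fit(Y, X)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_constraint_explains_nothing(self, rng):
        Yc = rng.normal(size=(20, 4))
        Yc -= Yc.mean(axis=0)
        # build x orthogonal to every centered response column
        q, _ = np.linalg.qr(Yc)
        x = rng.normal(size=20)
        x -= q @ (q.T @ x)
        x -= x.mean()
        res = md.rda_fit(Yc, x)
        assert res.proportion_constrained == pytest.approx(0.0, abs=1e-9)

    def test_eigenvalues_match_regress_then_pca_oracle(self, rng):
        """Two-step oracle: explicit regression, then eigen-decomposition."""
        for _ in range(5):
            Y = rng.normal(size=(12, 4))
            X = rng.normal(size=(12, 2))
            res = md.rda_fit(Y, X)
            Yc = Y - Y.mean(axis=0)
            Xc = np.column_stack([np.ones(12), X - X.mean(axis=0)])
            beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
            fitted = Xc @ beta
            ev = np.linalg.eigvalsh(fitted.T @ fitted / (12 - 1))[::-1]
            assert np.allclose(res.constrained_eigenvalues, ev[: len(
                res.constrained_eigenvalues)], atol=1e-8)

    def test_variance_conservation(self, rng):
        for _ in range(10):
            Y = rng.normal(size=(15, 5))
            X = rng.normal(size=(15, 3))
            res = md.rda_fit(Y, X)
            total = res.constrained_eigenvalues.sum() + res.unconstrained_eigenvalues.sum()
            assert total == pytest.approx(res.total_variance, abs=1e-8)

    def test_matches_vegan_reference_values(self, rng):
        """Cross-check against R vegan's rda() on the same seeded data.

        Expected values were computed once with vegan 2.7:
        ``rda(Y ~ a + b)`` on the data below gives constrained
        eigenvalues RDA1/RDA2, unconstrained PC1..PC5, and 19.47%
        constrained variance.
        """
        Y = pd.DataFrame(rng.normal(size=(14, 5)))
        X = pd.DataFrame(rng.normal(size=(14, 2)), columns=["a", "b"])
        res = md.rda_fit(Y, X)
        assert np.allclose(
            res.constrained_eigenvalues, [1.0783720, 0.2121607], atol=1e-6
        )
        assert np.allclose(
            res.unconstrained_eigenvalues,
            [2.8183375, 1.1130517, 0.7541841, 0.4923487, 0.1612786],
            atol=1e-6,
        )
        assert res.proportion_constrained == pytest.approx(0.1946583, abs=1e-6)


class TestRDAPermutation:
    def test_deterministic_under_seed(self, rng):
        Y = rng.normal(size=(20, 3))
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        p1 = md.rda_permutation_terms(Y, X, n_perm=199, seed=5)
        p2 = md.rda_permutation_terms(Y, X, n_perm=199, seed=5)
        assert p1["p_value"].equals(p2["p_value"])

    def test_huge_effect_saturates_p(self, rng):
        x = rng.normal(size=60)
        Y = np.column_stack([x + rng.normal(scale=0.5, size=60) for _ in range(3)])
        out = md.rda_permutation_terms(Y, pd.DataFrame({"x": x}), n_perm=999, seed=1)
        assert out.loc["x", "p_value"] == pytest.approx(1.0 / 1000.0)

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            md.rda_permutation_terms(
                rng.normal(size=(10, 2)), rng.normal(size=(10, 1)), n_perm=50
            )


class TestRDAModelBuild:
    def test_selects_active_terms(self, rng):
        """Forward selection finds the two active constraints."""
        exact = 0
        n_rep = 30
        for _ in range(n_rep):
            n = 100
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            inert = rng.normal(size=(n, 4))
            Y = np.column_stack(
                [x1 + rng.normal(scale=1.0, size=n) for _ in range(2)]
                + [x2 + rng.normal(scale=1.0, size=n) for _ in range(2)]
            )
            cands = {"x1": x1, "x2": x2, "z1": inert[:, 0], "z2": inert[:, 1],
                     "z3": inert[:, 2], "z4": inert[:, 3]}
            sel, _, _ = md.rda_model_build(Y, cands, n_perm=99, seed=int(rng.integers(2**31)))
            if set(sel) == {"x1", "x2"}:
                exact += 1
        assert exact >= 0.9 * n_rep

    def test_all_inert_selects_nothing(self, rng):
        empty = 0
        n_rep = 30
        for _ in range(n_rep):
            Y = rng.normal(size=(80, 3))
            cands = {f"z{i}": rng.normal(size=80) for i in range(4)}
            sel, _, _ = md.rda_model_build(Y, cands, n_perm=99,
                                           seed=int(rng.integers(2**31)))
            empty += not sel
        assert empty >= 0.9 * n_rep

    def test_constrained_proportion_monotone_in_terms(self, rng):
        Y = rng.normal(size=(40, 4))
        cols = {f"x{i}": rng.normal(size=40) for i in range(4)}
        props = []
        names = list(cols)
        for k in range(1, 5):
            res = md.rda_fit(Y, {n: cols[n] for n in names[:k]})
            props.append(res.proportion_constrained)
        assert all(b >= a - 1e-12 for a, b in zip(props, props[1:]))


class TestLowess:
    def test_linear_data_reproduced(self, rng):
        x = np.linspace(0, 10, 30)
        y = 2.0 + 0.5 * x
        fitted = md.lowess_curve(x, y, span=1.0)
        assert np.allclose(fitted, y, atol=1e-6)

    def test_u_shape_minimum_located(self):
        x = np.linspace(-2, 2, 81)
        y = x**2
        fitted = md.lowess_curve(x, y, span=0.3)
        assert abs(x[np.argmin(fitted)]) <= (x[1] - x[0]) + 1e-9

    def test_invariant_to_point_order(self, rng):
        x = rng.uniform(0, 10, 40)
        y = np.sin(x) + rng.normal(scale=0.1, size=40)
        f1 = md.lowess_curve(x, y)
        perm = rng.permutation(40)
        f2 = md.lowess_curve(x[perm], y[perm])
        assert np.allclose(f1[perm], f2, atol=1e-9)

    def test_tiny_span_widened_with_warning(self):
        x = np.arange(20.0)
        y = x.copy()
        with pytest.warns(RuntimeWarning, match="widened"):
            md.lowess_curve(x, y, span=0.05)
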