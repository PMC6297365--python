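"""ICC, Spearman-Brown, gender screens, MANOVA, variance components."""

import numpy as np
import pandas as pd
import pytest

from primatefaces import raterstats as rs
from primatefaces import synthdata as sd


def _matrix(scores, genders=None):
    scores = np.asarray(scores)
    raters = [f"r{i}" for i in range(scores.shape[0])]
    if genders is None:
        genders = ["female"] * len(raters)
    meta = pd.DataFrame({"gender": genders, "age": 25}, index=raters)
    cols = [f"s{j}" for j in range(scores.shape[1])]
    return rs.RatingMatrix(pd.DataFrame(scores, index=raters, columns=cols), meta)


class TestICC:
    def test_identical_raters_give_unit_icc(self):
        base = np.tile([1, 3, 5, 7, 2, 6], (4, 1))
        res = rs.icc_consistency(_matrix(base))
        assert res.icc_single == 1.0
        assert res.icc_average == 1.0

    def test_rater_offsets_do_not_hurt_consistency(self):
        base = np.array([1, 2, 3, 4, 5, 6])
        scores = np.vstack([base, base + 1, base + 1, base])  # constant shifts
        res = rs.icc_consistency(_matrix(scores))
        assert res.icc_single == pytest.approx(1.0, abs=1e-12)

    def test_null_matrix_icc_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.integers(1, 8, size=(50, 100))  # raters x stimuli
            vals.append(rs.icc_consistency(_matrix(scores)).icc_single)
        assert max(abs(v) for v in vals) < 0.05

    def test_matches_pingouin(self, rng):
        """Independent cross-check against pingouin's ICC3/ICC3k."""
        pingouin = pytest.importorskip("pingouin")
        scores = rng.integers(1, 8, size=(8, 12))
        m = _matrix(scores)
        res = rs.icc_consistency(m)
        long = (
            m.scores.reset_index(names="rater")
            .melt(id_vars="rater", var_name="stimulus", value_name="score")
        )
        icc = pingouin.intraclass_corr(
            data=long, targets="stimulus", raters="rater", ratings="score"
        ).set_index("Type")
        assert res.icc_single == pytest.approx(icc.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert res.icc_average == pytest.approx(icc.loc["ICC(C,k)", "ICC"], abs=1e-9)

    def test_average_equals_spearman_brown_identity(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 12))
            n = int(rng.integers(5, 20))
            scores = rng.integers(1, 8, size=(k, n))
            if np.all(scores == scores[0]):
                continue
            res = rs.icc_consistency(_matrix(scores))
            assert res.icc_average == pytest.approx(
                rs.spearman_brown(res.icc_single, k), abs=1e-10
            )

    def test_recovers_target_icc_regimes(self):
        """Simulated matrices land within 0.03 of their target single ICC."""
        for tau in (0.1, 0.2, 0.5):
            m = sd.simulate_icc_matrix(107, 286, tau, seed=3)
            res = rs.icc_consistency(m)
            assert abs(res.icc_single - tau) < 0.03


class TestSpearmanBrown:
    @pytest.mark.parametrize(
        "single, k, expected",
        [(0.182, 286, 0.985), (0.147, 91, 0.940), (0.204, 199, 0.981)],
    )
    def test_published_regimes(self, single, k, expected):
        assert rs.spearman_brown(single, k) == pytest.approx(expected, abs=5e-4)

    def test_identity_at_one_rater(self):
        for s in (-0.4, 0.0, 0.3, 0.9):
            assert rs.spearman_brown(s, 1) == pytest.approx(s)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            rs.spearman_brown(-0.5, 10)


class TestInvertScale:
    def test_involution_and_rank_reversal(self, small_study):
        m = small_study.beauty_ratings
        inv = rs.invert_scale(m)
        assert (inv.scores.values == 8 - m.scores.values).all()
        back = rs.invert_scale(inv)
        assert back.scores.equals(m.scores)
        orig_rank = m.species_means().rank()
        inv_rank = inv.species_means().rank()
        assert np.allclose(orig_rank.values, len(orig_rank) + 1 - inv_rank.values)

    def test_icc_invariant_under_inversion(self, small_study):
        m = small_study.beauty_ratings
        a = rs.icc_consistency(m)
        b = rs.icc_consistency(rs.invert_scale(m))
        assert a.icc_single == pytest.approx(b.icc_single, abs=1e-12)


class TestGenderScreen:
    def test_identical_samples_give_central_u(self):
        # every rater gives the same column: male and female samples identical
        scores = np.tile([1, 2, 3, 4, 5], (8, 1))  # 8 raters x 5 stimuli
        genders = ["male"] * 4 + ["female"] * 4
        out = rs.gender_screen(_matrix(scores, genders))
        assert np.allclose(out["u_statistic"], 4 * 4 / 2)
        assert (out["p_raw"] > 0.9).all()

    def test_flags_exactly_offset_species(self, full_study):
        """The male-preference offset species are flagged, others are not."""
        out = rs.gender_screen(full_study.beauty_ratings)
        flagged = set(out.index[out["significant"]])
        truth = set(full_study.truth["male_preferred_species"])
        assert flagged == truth
        assert len(truth) == 5

    def test_requires_both_genders(self, rng):
        scores = rng.integers(1, 8, size=(6, 4))
        with pytest.raises(ValueError):
            rs.gender_screen(_matrix(scores, ["male"] * 6))


class TestMANOVA:
    def test_single_response_reduces_to_anova_f(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y = rng.normal(size=40)
        g = np.repeat(["a", "b"], 20)
        design = pd.DataFrame({"g": g})
        out = rs.manova_wilks(pd.DataFrame({"y": y}), design, "g")
        ols = smf.ols("y ~ g", data=pd.DataFrame({"y": y, "g": g})).fit()
        f_uni = anova_lm(ols, typ=1).loc["g", "F"]
        assert out.loc["g", "f_value"] == pytest.approx(f_uni, abs=1e-9)

    def test_wilks_is_one_for_equal_group_means(self):
        base = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 0.0], [0.0, 3.0]])
        Y = pd.DataFrame(np.vstack([base, base]), columns=["y1", "y2"])
        design = pd.DataFrame({"g": np.repeat(["a", "b"], 4)})
        out = rs.manova_wilks(Y, design, "g")
        assert out.loc["g", "wilks_lambda"] == pytest.approx(1.0, abs=1e-9)

    def test_null_p_values_uniform(self, rng):
        """Size calibration: p ~ U(0,1) when responses ignore the design."""
        from scipy.stats import kstest

        pvals = []
        for _ in range(200):
            Y = pd.DataFrame(rng.normal(size=(25, 2)), columns=["y1", "y2"])
            design = pd.DataFrame({"x": rng.normal(size=25)})
            pvals.append(rs.manova_wilks(Y, design, "x").loc["x", "p_value"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_high_dimensional_response_is_reduced(self, rng):
        Y = pd.DataFrame(rng.normal(size=(20, 30)))
        Y.columns = [f"y{i}" for i in range(30)]
        design = pd.DataFrame({"x": rng.normal(size=20)})
        with pytest.warns(RuntimeWarning, match="reduced"):
            out = rs.manova_wilks(Y, design, "x")
        assert out.attrs["pca_reduced"]


class TestNestedVarianceComponents:
    @staticmethod
    def _simulate(vg, vgen, vsp, vres, a, b, c, n, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(a):
            gi = rng.normal(0, np.sqrt(vg))
            for j in range(b):
                gj = rng.normal(0, np.sqrt(vgen))
                for k in range(c):
                    sk = rng.normal(0, np.sqrt(vsp))
                    for _ in range(n):
                        rows.append(
                            {
                                "group": f"g{i}",
                                "genus": f"g{i}_gen{j}",
                                "species": f"g{i}_gen{j}_sp{k}",
                                "value": gi + gj + sk + rng.normal(0, np.sqrt(vres)),
                            }
                        )
        return pd.DataFrame(rows)

    def test_recovers_simulated_components(self):
        """Variance recovery near the taxonomic-hierarchy regime (estimates
        averaged over replicate simulated datasets to damp Monte-Carlo error
        in the coarse upper levels)."""
        truth = {"group": 0.07, "genus": 0.10, "species": 0.24, "residual": 0.05}
        ests = []
        for seed in range(30):
            df = self._simulate(0.07, 0.10, 0.24, 0.05, 30, 4, 3, 2, seed=seed)
            ests.append(rs.nested_variance_components(df)["variances"])
        for level, v in truth.items():
            mean_est = np.mean([e[level] for e in ests])
            assert abs(mean_est - v) / v < 0.20

    def test_pure_residual_variation(self):
        df = self._simulate(0, 0, 0, 1.0, 6, 3, 2, 4, seed=2)
        est = rs.nested_variance_components(df)["variances"]
        assert est["residual"] == pytest.approx(1.0, rel=0.2)
        for level in ("group", "genus", "species"):
            assert est[level] < 0.15

    def test_scaling_deviations_scales_components(self):
        df = self._simulate(0.1, 0.2, 0.3, 0.4, 8, 3, 2, 3, seed=9)
        doubled = df.copy()
        doubled["value"] = (
            df["value"].mean() + 2.0 * (df["value"] - df["value"].mean())
        )
        a = rs.nested_variance_components(df)["variances"]
        b = rs.nested_variance_components(doubled)["variances"]
        for level in a:
            assert b[level] == pytest.approx(4.0 * a[level], abs=1e-9)

    def test_nesting_violation_rejected(self):
        df = pd.DataFrame(
            {
                "group": ["g1", "g2"] * 4,
                "genus": ["shared"] * 8,  # genus in two groups
                "species": ["s1"] * 4 + ["s2"] * 4,
                "value": np.arange(8.0),
            }
        )
        with pytest.raises(ValueError, match="[Nn]esting"):
            rs.nested_variance_components(df)


class TestSpearmanScreen:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        out = rs.spearman_screen(x, pd.DataFrame({"same": x, "anti": -x}))
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)

    def test_constant_column_flagged_not_raised(self):
        x = np.arange(6.0)
        out = rs.spearman_screen(x, pd.DataFrame({"const": np.ones(6)}))
        assert out.loc["const", "constant"]
        assert np.isnan(out.loc["const", "rho"])

    def test_null_rejection_rate_calibrated(self, rng):
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            out = rs.spearman_screen(x, pd.DataFrame({"y": y}))
            hits += bool(out["significant"].iloc[0])
        rate = hits / n_rep
        # binomial 95% CI around 0.05 at 1000 reps
        assert abs(rate - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / n_rep) + 0.005
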