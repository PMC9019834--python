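"""Inference battery: elementary tests against oracles, mixed-model df
convention, FDR, and the follow-up utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from betaconn.stats import (
    CONNECTIVITY_TERMS,
    Term,
    encode_design,
    fdr_bh,
    fit_lmm,
    paired_t,
    partial_corr,
    quartile_contrast,
    run_behavior_models,
    run_brain_behavior_models,
    run_connectivity_models,
    select_low_motion_age_subsample,
    spearman,
    subsample_reanalysis,
    vif,
    wilcoxon_signed_rank,
)
from betaconn.validate import fast_cohort_tables


class TestPairedT:
    def test_zero_mean_differences_give_t_zero(self, rng):
        x = rng.normal(size=10)
        d = np.array([0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.4, -0.4, 0.5, -0.5])
        t, df, p = paired_t(x + d, x, "greater")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_constant_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_hand_computation(self):
        """t and p from the textbook formula and the t CDF."""
        x = np.array([2.1, 1.9, 2.4, 2.0])
        y = np.array([1.8, 1.7, 2.0, 1.9])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        p_hand = 2 * sps.t.sf(abs(t_hand), 3)
        t, df, p = paired_t(x, y)
        assert (t, df, p) == pytest.approx((t_hand, 3, p_hand), abs=1e-12)


class TestWilcoxon:
    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_full_enumeration(self, seed):
        """n = 6: exact p equals the brute force over all 2^6 sign patterns."""
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(size=6), 1)
        d[d == 0] = 0.3
        x = np.abs(d)
        ranks = sps.rankdata(x)
        w_obs = ranks[d > 0].sum()
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=6)
        ]
        dist = np.array(dist)
        p_enum = min(
            1.0,
            2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()),
        )
        W, p = wilcoxon_signed_rank(d, np.zeros(6))
        assert W == pytest.approx(w_obs)
        assert p == pytest.approx(p_enum, abs=1e-12)

    def test_strictly_positive_ten_pairs_one_sided(self):
        x = np.arange(1.0, 11.0)
        W, p = wilcoxon_signed_rank(x, np.zeros(10), tail="greater")
        assert p == pytest.approx(2.0**-10, abs=1e-15)

    def test_large_n_matches_scipy_normal_approx(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        W, p = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_agrees_with_scipy_when_untied(self):
        x = np.array([1.3, -0.7, 2.2, -3.1, 0.6, 1.9, -0.2, 4.0])
        W, p = wilcoxon_signed_rank(x, np.zeros(8))
        ref = sps.wilcoxon(x, method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.array([1.0, 2, 3, 4, 5])
        rho, _ = spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_tied_toy_matches_rank_then_pearson(self):
        x = np.array([1.0, 2, 2, 3])
        y = np.array([1.0, 3, 2, 4])
        rho, _ = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1, 1, 1], [1.0, 2, 3, 4])


class TestFdrVif:
    def test_bh_hand_example(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-12)

    def test_bh_single_and_equal_p_unchanged(self):
        assert fdr_bh([0.3]) == pytest.approx([0.3])
        assert fdr_bh([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_bh_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(size=30)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    def test_vif_closed_form_correlation_06(self):
        """Two predictors with exact correlation 0.6 -> VIF = 1.5625 each."""
        n = 50
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        u, v = np.cos(t), np.sin(t)  # orthogonal, equal norm, zero mean
        X = pd.DataFrame({"x1": u, "x2": 0.6 * u + 0.8 * v})
        out = vif(X).set_index("predictor")["vif"]
        assert out["x1"] == pytest.approx(1 / (1 - 0.36), abs=1e-9)
        assert out["x2"] == pytest.approx(1.5625, abs=1e-9)

    def test_vif_orthogonal_is_one_duplicate_infinite(self):
        n = 40
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        X = pd.DataFrame({"a": np.cos(t), "b": np.sin(t)})
        assert vif(X)["vif"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-9)
        X["c"] = X["a"]
        assert np.isinf(vif(X).set_index("predictor").loc["c", "vif"])

    def test_vif_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        X["d"] += 0.7 * X["a"]
        ours = vif(X)["vif"].to_numpy()
        arr = np.column_stack([np.ones(80), X.to_numpy()])
        ref = [variance_inflation_factor(arr, j + 1) for j in range(4)]
        assert ours == pytest.approx(ref, rel=1e-8)


@pytest.fixture(scope="module")
def long_table(beta_cohort):
    lt, bb = fast_cohort_tables(beta_cohort)
    return encode_design(lt)


class TestMixedModel:
    def test_df_convention(self, long_table):
        """200 obs / 50 subjects / 3 within terms: within F(1,147), subject-
        level F(1,45)."""
        res = fit_lmm(long_table, "within_mentalizing", CONNECTIVITY_TERMS)
        t = res.terms.set_index("term")
        for name in ("social", "mentalizing", "social:age"):
            assert t.loc[name, "df2"] == 147
        for name in ("age", "gender", "mean_fd", "iq"):
            assert t.loc[name, "df2"] == 45

    def test_split_engine_equals_reml_on_balanced_data(self, rng):
        """With a clearly positive random-intercept variance (interior REML
        optimum) the closed-form split decomposition matches MixedLM."""
        rows = []
        for i in range(40):
            age = rng.uniform(-2, 2)
            b_i = rng.normal(scale=0.8)  # strong subject effect
            for social in (0.5, -0.5):
                for ment in (0.5, -0.5):
                    y = b_i + 0.2 * social + 0.1 * age + rng.normal(scale=0.4)
                    rows.append({"subject_id": i, "social": social,
                                 "mentalizing": ment, "age": age, "y": y})
        df = pd.DataFrame(rows)
        terms = (Term("social", True), Term("mentalizing", True),
                 Term("age", False), Term("social:age", True))
        a = fit_lmm(df, "y", terms, engine="mixedlm")
        b = fit_lmm(df, "y", terms, engine="split")
        assert a.converged
        assert a.terms["estimate"].to_numpy() == pytest.approx(
            b.terms["estimate"].to_numpy(), rel=1e-4, abs=1e-8
        )
        assert a.terms["se"].to_numpy() == pytest.approx(
            b.terms["se"].to_numpy(), rel=1e-3
        )

    def test_zero_random_variance_matches_ols(self, rng):
        """No subject effect simulated -> fixed effects equal plain OLS."""
        n_sub = 40
        rows = []
        for i in range(n_sub):
            age = rng.uniform(-2, 2)
            for social in (0.5, -0.5):
                for ment in (0.5, -0.5):
                    y = 0.3 * social + 0.1 * age + rng.normal(scale=0.5)
                    rows.append({"subject_id": i, "social": social,
                                 "mentalizing": ment, "age": age, "y": y})
        df = pd.DataFrame(rows)
        terms = (Term("social", True), Term("mentalizing", True),
                 Term("age", False), Term("social:age", True))
        res = fit_lmm(df, "y", terms, engine="mixedlm")
        X = np.column_stack([
            np.ones(len(df)), df["social"], df["mentalizing"], df["age"],
            df["social"] * df["age"],
        ])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert res.terms["estimate"].to_numpy() == pytest.approx(
            beta[1:], abs=1e-4
        )

    def test_social_f_equals_squared_paired_t_without_covariates(self, long_table):
        """Balanced one-within-factor design: F(social) == t^2 of the paired
        t-test on per-subject condition means."""
        collapsed = (
            long_table.groupby(["subject_id", "social"])["within_mentalizing"]
            .mean()
            .reset_index()
        )
        res = fit_lmm(collapsed, "within_mentalizing",
                      (Term("social", True),), engine="split")
        wide = collapsed.set_index(["subject_id", "social"])[
            "within_mentalizing"].unstack()
        t, df, _ = paired_t(wide[0.5], wide[-0.5])
        assert res.F("social") == pytest.approx(t**2, rel=1e-6)
        assert res.terms["df2"].iloc[0] == df

    def test_too_few_observations_per_subject_rejected(self):
        df = pd.DataFrame({"subject_id": [1, 2, 3], "social": [0.5, -0.5, 0.5],
                           "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_lmm(df, "y", (Term("social", True),))


class TestBatteries:
    def test_connectivity_battery_shapes(self, beta_cohort):
        lt, _ = fast_cohort_tables(beta_cohort)
        out = run_connectivity_models(lt, engine="split")
        assert set(out["network"]) == {"within_mentalizing", "within_reward",
                                       "between"}
        for res in out["network"].values():
            assert res.n_obs == 200 and res.n_subjects == 50
            assert set(res.posthoc) == {"Peer", "Character"}
            assert res.posthoc["Peer"]["df2"] == 45
        vt = out["network"]["between"].vif
        assert (vt["vif"] >= 1.0 - 1e-9).all()

    def test_single_network_config_emits_one_model(self, beta_cohort):
        lt, _ = fast_cohort_tables(beta_cohort)
        lt = lt.drop(columns=["within_reward", "between"])
        out = run_connectivity_models(lt, engine="split")
        assert list(out["network"]) == ["within_mentalizing"]

    def test_behavior_models_recover_planted_rt_effect(self, beta_cohort):
        lt, _ = fast_cohort_tables(beta_cohort)
        beh_rows = []
        for s in beta_cohort.subjects:
            g = s.behavior.groupby(["condition", "social", "mentalizing"]).agg(
                rt=("rt", "mean"), accuracy=("correct", "mean")
            ).reset_index()
            g["subject_id"] = s.profile.subject_id
            g["age"] = s.profile.age
            g["gender"] = s.profile.gender
            g["iq"] = s.profile.iq
            beh_rows.append(g)
        beh = pd.concat(beh_rows, ignore_index=True)
        out = run_behavior_models(beh, engine="split")
        t_stat, df, p = out["rt_paired_t"]
        # planted -0.08 s contrast, n = 50 subjects
        est = out["rt"].estimate("social")
        assert est == pytest.approx(-0.08, abs=0.03)
        assert df == 49 and p < 0.05
        assert out["accuracy"] is not None

    def test_degenerate_accuracy_flagged(self, beta_cohort):
        lt, _ = fast_cohort_tables(beta_cohort)
        df = pd.DataFrame({
            "subject_id": np.repeat(np.arange(10), 4),
            "social": ["Peer", "Peer", "Character", "Character"] * 10,
            "mentalizing": ["Mental", "Non-Mental"] * 20,
            "age": np.repeat(np.linspace(8, 13, 10), 4),
            "gender": np.repeat(["M", "F"] * 5, 4),
            "iq": 100.0,
            "rt": np.random.default_rng(0).normal(2.0, 0.2, 40),
            "accuracy": 1.0,
        })
        out = run_behavior_models(df, engine="split")
        assert out["accuracy"] is None

    def test_brain_behavior_interaction_sign(self, beta_cohort):
        """Peer-specific RT coupling is planted negative by default."""
        _, bb = fast_cohort_tables(beta_cohort)
        out = run_brain_behavior_models(bb, behavior_cols=("rt",),
                                        engine="split")
        res = out[("within_mentalizing", "rt")]
        assert res.estimate("social:behavior") < 0
        assert set(res.posthoc["Peer"]) >= {"partial_r_age", "F", "p"}

    def test_brain_behavior_constant_predictor_rejected(self, beta_cohort):
        _, bb = fast_cohort_tables(beta_cohort)
        bb = bb.copy()
        bb["rt"] = 2.0
        with pytest.raises(ValueError, match="degenerate"):
            run_brain_behavior_models(bb, behavior_cols=("rt",))


class TestQuartilesAndSubsample:
    def _subject_table(self, n=52, seed=0, fd_age_rho=0.0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(8.18, 12.97, n)
        z = fd_age_rho * (age - age.mean()) / age.std() + np.sqrt(
            max(0.0, 1 - fd_age_rho**2)
        ) * rng.normal(size=n)
        diff = 0.04 * (age - age.mean()) + rng.normal(scale=0.02, size=n)
        base = rng.normal(0.2, 0.03, n)
        tab = {"subject_id": [f"s{i}" for i in range(n)], "age": age,
               "mean_fd": 0.23 + 0.08 * z}
        for o in ("within_mentalizing", "within_reward", "between"):
            tab[f"{o}_peer"] = base + diff / 2
            tab[f"{o}_character"] = base - diff / 2
        return pd.DataFrame(tab)

    def test_quartile_group_sizes_and_signs(self):
        tab = self._subject_table(52)
        out = quartile_contrast(tab)
        assert (out["n"] == 13).all()
        m = out.set_index(["group", "outcome"])["mean_diff"]
        assert m.loc[("upper", "within_mentalizing")] > 0
        assert m.loc[("lower", "within_mentalizing")] < 0

    def test_constant_age_rejected(self):
        tab = self._subject_table(20)
        tab["age"] = 10.0
        with pytest.raises(ValueError, match="quartile"):
            quartile_contrast(tab)

    def test_greedy_selector_decorrelates_age_and_motion(self):
        tab = self._subject_table(50, seed=3, fd_age_rho=0.4)
        assert abs(np.corrcoef(tab["age"], tab["mean_fd"])[0, 1]) > 0.1
        ids = select_low_motion_age_subsample(tab, target_n=30)
        sel = tab[tab["subject_id"].isin(ids)]
        assert len(sel) >= 30
        assert abs(np.corrcoef(sel["age"], sel["mean_fd"])[0, 1]) < 0.05

    def test_target_larger_than_cohort_rejected(self):
        tab = self._subject_table(20)
        with pytest.raises(ValueError):
            select_low_motion_age_subsample(tab, target_n=30)

    def test_identity_selector_reproduces_full_cohort(self, beta_cohort):
        lt, _ = fast_cohort_tables(beta_cohort)
        subj = lt.groupby("subject_id").agg(
            age=("age", "first"), mean_fd=("mean_fd", "first")
        ).reset_index()
        full = run_connectivity_models(lt, engine="split")
        sub = subsample_reanalysis(
            lt, subj, selector=lambda t: t["subject_id"].tolist(),
            engine="split",
        )
        a = full["network"]["within_mentalizing"].terms
        b = sub["network"]["within_mentalizing"].terms
        pd.testing.assert_frame_equal(a, b)


def test_partial_corr_matches_residual_correlation(rng):
    x = rng.normal(size=60)
    z = rng.normal(size=60)
    y = 0.5 * x + 0.8 * z + rng.normal(size=60)
    r, p = partial_corr(x, y, z.reshape(-1, 1))
    import pingouin as pg

    ref = pg.partial_corr(
        pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
    )
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
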