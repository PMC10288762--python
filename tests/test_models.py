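import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mrisubtype as ms
from mrisubtype.models import backward_select, fit_all_interactions

from conftest import make_regression_frame


def bh_oracle(p):
    """Hand-coded step-up adjustment: p*m/rank then cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestInteractionModel:
    def test_coefficients_match_normal_equations_oracle(self):
        df = make_regression_frame(n=120, seed=2, beta={"treatment": 2.0, "severity": 0.3,
                                                        "typicality_x_treatment": 10.0})
        spec = ms.ModelSpec("y", include_field_strength=True)
        res = ms.fit_interaction_model(df, spec)
        X = np.column_stack([
            np.ones(len(df)), df["age"], df["field_strength_3t"], df["treatment"],
            df["severity"], df["typicality"],
            df["severity"] * df["treatment"], df["typicality"] * df["treatment"],
        ])
        coef, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        order = ["const", "age", "field_strength", "treatment", "severity", "typicality",
                 "severity_x_treatment", "typicality_x_treatment"]
        np.testing.assert_allclose(res.terms.loc[order, "B"].to_numpy(), coef, atol=1e-8)

    def test_null_data_interactions_near_zero(self):
        df = make_regression_frame(n=500, seed=7, beta={}, sigma=1.0)
        res = ms.fit_interaction_model(df, ms.ModelSpec("y", include_field_strength=False))
        for term in ("severity_x_treatment", "typicality_x_treatment"):
            b, se = res.terms.loc[term, "B"], res.terms.loc[term, "se"]
            assert abs(b) < 3 * se

    def test_injected_interaction_recovered_end_to_end(self):
        cfg = ms.SimulationConfig(n_subjects=2000, seed=77)
        cfg = cfg.replace(treatment_typicality={**cfg.treatment_typicality, "ad_signature": 16.0})
        cohort = ms.generate_cohort(cfg)
        derived = ms.derive_measures(cohort)
        data = ms.build_analysis_table(cohort, derived)
        res = ms.fit_interaction_model(data, ms.ModelSpec("apc_ad_signature"))
        b = res.terms.loc["typicality_x_treatment", "B"]
        se = res.terms.loc["typicality_x_treatment", "se"]
        assert abs(b - 16.0) < 3 * se

    def test_duplicated_predictor_is_a_rank_error(self):
        df = make_regression_frame(n=60, seed=4)
        df["severity"] = df["typicality"]  # exact collinearity via the shared column
        with pytest.raises(ValueError, match="alias"):
            ms.fit_interaction_model(df, ms.ModelSpec("y", include_field_strength=False))

    def test_single_arm_is_an_error(self):
        df = make_regression_frame(n=40, seed=5)
        df["treatment"] = 1.0
        with pytest.raises(ValueError, match="arm"):
            ms.fit_interaction_model(df, ms.ModelSpec("y", include_field_strength=False))

    def test_field_strength_only_in_mri_models(self, analysis_table):
        mri = ms.fit_interaction_model(analysis_table, ms.ModelSpec("apc_ad_signature"))
        cog = ms.fit_interaction_model(analysis_table, ms.ModelSpec("pc_mmse"))
        assert "field_strength" in mri.terms.index
        assert "field_strength" not in cog.terms.index

    def test_power_with_large_standardized_effect(self):
        # strongly scaled interaction: rejection in at least 90% of replicates at n=500
        rejections = 0
        for i in range(30):
            df = make_regression_frame(n=500, seed=100 + i,
                                       beta={"typicality_x_treatment": 30.0}, sigma=1.0)
            res = ms.fit_interaction_model(df, ms.ModelSpec("y", include_field_strength=False))
            rejections += res.terms.loc["typicality_x_treatment", "p"] <= 0.05
        assert rejections >= 27


class TestBackwardSelection:
    TOY_TERMS = ("treatment", "severity", "typicality", "typicality_x_treatment")

    def test_perfect_treatment_signal_retained(self):
        df = make_regression_frame(n=80, seed=1, beta={"treatment": 2.0}, sigma=0.0)
        spec = ms.ModelSpec("y", include_field_strength=False, candidate_terms=self.TOY_TERMS)
        selected, trace = backward_select(df, spec)
        assert "treatment" in selected
        assert trace  # every step recorded

    def test_pure_noise_drops_all_candidates(self):
        df = make_regression_frame(n=1000, seed=2, beta={}, sigma=1.0)
        spec = ms.ModelSpec("y", include_field_strength=False, candidate_terms=self.TOY_TERMS)
        selected, _ = backward_select(df, spec)
        assert selected == ()

    def test_marginality_never_violated(self):
        for seed in range(10):
            df = make_regression_frame(n=150, seed=seed,
                                       beta={"typicality_x_treatment": 25.0}, sigma=1.0)
            spec = ms.ModelSpec("y", include_field_strength=False)
            selected, _ = backward_select(df, spec)
            s = set(selected)
            if "typicality_x_treatment" in s:
                assert {"typicality", "treatment"} <= s
            if "severity_x_treatment" in s:
                assert {"severity", "treatment"} <= s

    def test_greedy_equals_exhaustive_on_toy(self):
        spec = ms.ModelSpec("y", include_field_strength=False, candidate_terms=self.TOY_TERMS)
        for seed in range(25):
            df = make_regression_frame(n=160, seed=seed, beta={"treatment": 2.0, "severity": 0.1},
                                       sigma=1.0)
            exh, _ = backward_select(df, spec, strategy="exhaustive")
            grd, _ = backward_select(df, spec, strategy="greedy")
            assert set(exh) == set(grd)

    def test_selection_is_deterministic(self):
        df = make_regression_frame(n=120, seed=9, beta={"treatment": 1.0}, sigma=1.0)
        spec = ms.ModelSpec("y", include_field_strength=False)
        assert backward_select(df, spec)[0] == backward_select(df, spec)[0]


class TestSubtypeAnova:
    def make_cells(self, means, n_per_cell=6, seed=0, jitter=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        noise = [0.0, -1.0, 1.0, 0.5, -0.5, 0.3]  # identical pattern in every cell
        for (subtype, arm), mu in means.items():
            for k in range(n_per_cell):
                rows.append({
                    "categorical_subtype": subtype, "arm": arm,
                    "age": 70.0 + k, "field_strength_3t": float(k % 2),
                    "y": mu + noise[k % len(noise)] + jitter * rng.standard_normal(),
                })
        return pd.DataFrame(rows)

    def test_identical_cell_means_give_zero_interaction(self):
        means = {(s, a): 5.0 for s in ("minimal_atrophy", "limbic_predominant")
                 for a in ("placebo", "donepezil")}
        df = self.make_cells(means)
        res = ms.fit_subtype_anova(df, "y", include_field_strength=False)
        assert res.interaction_f == pytest.approx(0.0, abs=1e-10)
        assert res.interaction_p == pytest.approx(1.0, abs=1e-8)

    def test_interaction_ss_matches_design_matrix_oracle(self):
        means = {("minimal_atrophy", "placebo"): 1.0, ("minimal_atrophy", "donepezil"): 4.0,
                 ("limbic_predominant", "placebo"): 2.0, ("limbic_predominant", "donepezil"): 2.5}
        df = self.make_cells(means, jitter=0.5, seed=3)
        res = ms.fit_subtype_anova(df, "y", include_field_strength=False)

        # oracle: RSS difference between the additive and the full dummy-coded model
        def rss(X):
            coef, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
            r = df["y"].to_numpy() - X @ coef
            return float(r @ r)

        s = (df["categorical_subtype"] == "limbic_predominant").astype(float).to_numpy()
        a = (df["arm"] == "donepezil").astype(float).to_numpy()
        age = df["age"].to_numpy()
        ones = np.ones(len(df))
        X_add = np.column_stack([ones, s, a, age])
        X_full = np.column_stack([ones, s, a, age, s * a])
        ss_inter = rss(X_add) - rss(X_full)
        df_resid = len(df) - X_full.shape[1]
        f_oracle = (ss_inter / 1.0) / (rss(X_full) / df_resid)
        assert res.interaction_f == pytest.approx(f_oracle, rel=1e-8)

    def test_singleton_cell_contrast_undefined_with_warning(self):
        means = {("minimal_atrophy", "placebo"): 1.0, ("minimal_atrophy", "donepezil"): 2.0,
                 ("limbic_predominant", "placebo"): 2.0, ("limbic_predominant", "donepezil"): 2.5}
        df = self.make_cells(means, jitter=0.3, seed=4)
        df = pd.concat([df, pd.DataFrame([{
            "categorical_subtype": "typical_AD", "arm": "placebo", "age": 75.0,
            "field_strength_3t": 0.0, "y": 3.0,
        }])], ignore_index=True)
        with pytest.warns(RuntimeWarning, match="contrasts undefined"):
            res = ms.fit_subtype_anova(df, "y", include_field_strength=False)
        row = res.posthoc.set_index("subtype").loc["typical_AD"]
        assert np.isnan(row["estimate"]) and np.isnan(row["p"])
        defined = res.posthoc["p"].notna()
        assert res.posthoc.loc[defined, "p_bh"].notna().all()

    def test_single_subtype_level_is_an_error(self):
        means = {("minimal_atrophy", "placebo"): 1.0, ("minimal_atrophy", "donepezil"): 2.0}
        df = self.make_cells(means)
        with pytest.raises(ValueError, match="subtype levels"):
            ms.fit_subtype_anova(df, "y", include_field_strength=False)

    def test_interaction_invariant_to_level_recoding(self):
        means = {("minimal_atrophy", "placebo"): 1.0, ("minimal_atrophy", "donepezil"): 4.0,
                 ("limbic_predominant", "placebo"): 2.0, ("limbic_predominant", "donepezil"): 2.5}
        df = self.make_cells(means, jitter=0.4, seed=6)
        res1 = ms.fit_subtype_anova(df, "y", include_field_strength=False)
        swap = {"minimal_atrophy": "limbic_predominant", "limbic_predominant": "minimal_atrophy"}
        df2 = df.assign(categorical_subtype=df["categorical_subtype"].map(swap))
        res2 = ms.fit_subtype_anova(df2, "y", include_field_strength=False)
        assert res1.interaction_f == pytest.approx(res2.interaction_f, rel=1e-9)


class TestBhAdjustment:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([0.03, 0.03, 0.03], [0.03, 0.03, 0.03]),
    ])
    def test_stated_examples(self, p, expected):
        np.testing.assert_allclose(ms.bh_adjust(p), expected, atol=1e-12)

    def test_matches_hand_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.random(rng.integers(1, 15))
            np.testing.assert_allclose(ms.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            ms.bh_adjust([0.1, 1.2])
        with pytest.raises(ValueError):
            ms.bh_adjust([])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12), st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        np.testing.assert_allclose(ms.bh_adjust(p)[perm], ms.bh_adjust(p[perm]), atol=1e-12)


class TestBaselineTable:
    def test_identical_arms_give_unit_pvalues(self, small_cohort):
        # duplicate every placebo subject into the other arm: groups identical
        clin = small_cohort.clinical.reset_index(drop=True)
        placebo = clin[clin["arm"] == "placebo"].copy()
        mirrored = placebo.copy()
        mirrored["subject_id"] = mirrored["subject_id"] + "X"
        mirrored["arm"] = "donepezil"
        both = pd.concat([placebo, mirrored], ignore_index=True)
        morph = small_cohort.morphometry
        morph_p = morph[morph["subject_id"].isin(placebo["subject_id"])]
        morph_m = morph_p.copy()
        morph_m["subject_id"] = morph_m["subject_id"] + "X"
        from mrisubtype.io_schema import cohort_from_frames
        cohort = cohort_from_frames(pd.concat([morph_p, morph_m], ignore_index=True), both,
                                    small_cohort.config, validate=False)
        table = ms.baseline_comparison_table(cohort)
        cont = table[table["type"] == "continuous"]
        assert (cont["p"] > 1 - 1e-9).all()

    def test_chi_square_matches_textbook_statistic(self, small_cohort):
        table = ms.baseline_comparison_table(small_cohort)
        row = table.set_index("variable").loc["sex"]
        counts = pd.crosstab(small_cohort.clinical["sex"], small_cohort.clinical["arm"])
        n = counts.to_numpy().sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
        chi2 = ((counts.to_numpy() - expected) ** 2 / expected).sum()
        assert row["statistic"] == pytest.approx(chi2, rel=1e-10)

    def test_empty_arm_is_an_error(self, small_cohort):
        placebo_only = small_cohort.subset(
            small_cohort.clinical.index[small_cohort.clinical["arm"] == "placebo"])
        with pytest.raises(ValueError, match="arm"):
            ms.baseline_comparison_table(placebo_only)

    def test_absent_variable_warns_and_is_omitted(self, small_cohort):
        with pytest.warns(RuntimeWarning, match="absent"):
            table = ms.baseline_comparison_table(small_cohort, {"nonexistent": "continuous",
                                                                "age_baseline": "continuous"})
        assert list(table["variable"]) == ["age_baseline"]


def test_tidy_interaction_output_shape(analysis_table):
    table, results = fit_all_interactions(analysis_table, ("apc_ad_signature", "pc_mmse"))
    # MRI outcome has 8 terms (incl. field strength), cognitive 7
    assert len(table) == 15
    assert set(table["outcome"]) == {"apc_ad_signature", "pc_mmse"}
    assert all(r.n == len(analysis_table.dropna(subset=[r.outcome])) for r in results)
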