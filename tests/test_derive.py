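import numpy as np
import pytest

import mrisubtype as ms
from mrisubtype.simulate import _m


class TestBvCsfIndex:
    def test_stated_values(self):
        assert ms.compute_bv_csf_index(500000, 460000, 960000 / 29.0) == pytest.approx(29.0, abs=1e-10)
        assert ms.compute_bv_csf_index(500000, 460000, 960000) == pytest.approx(1.0, abs=1e-12)

    def test_zero_csf_is_an_error(self):
        with pytest.raises(ValueError):
            ms.compute_bv_csf_index(500000, 460000, 0.0)

    def test_lower_index_means_more_atrophy(self):
        shrunk = ms.compute_bv_csf_index(450000, 420000, 120000)
        intact = ms.compute_bv_csf_index(550000, 470000, 90000)
        assert shrunk < intact


class TestHcRatio:
    def regions(self, mf, ip, st):
        return {"middle_frontal": (mf, mf), "inferior_parietal": (ip, ip), "superior_temporal": (st, st)}

    def test_symmetric_inputs(self):
        assert ms.compute_hc_ratio(3000, 3000, self.regions(15000, 15000, 15000)) == pytest.approx(0.2, abs=1e-12)
        assert ms.compute_hc_ratio(3000, 3000, self.regions(3000, 3000, 3000)) == pytest.approx(1.0, abs=1e-12)

    def test_two_level_averaging(self):
        # unweighted mean of per-region L/R means, not a volume sum
        assert ms.compute_hc_ratio(3000, 3000, self.regions(12000, 15000, 18000)) == pytest.approx(
            3000 / 15000, abs=1e-12)
        asym = {"middle_frontal": (10000, 14000), "inferior_parietal": (15000, 15000),
                "superior_temporal": (17000, 19000)}
        expected = ((2800 + 3200) / 2) / ((12000 + 15000 + 18000) / 3)
        assert ms.compute_hc_ratio(2800, 3200, asym) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_volume_is_an_error(self):
        with pytest.raises(ValueError):
            ms.compute_hc_ratio(0.0, 3000, self.regions(1, 1, 1))
        with pytest.raises(ValueError, match="inferior_parietal"):
            ms.compute_hc_ratio(3000, 3000, self.regions(12000, -1.0, 18000))


class TestAdSignature:
    def thick(self, ento, it, mt, fus):
        return {"entorhinal": ento, "inferiortemporal": it, "middletemporal": mt, "fusiform": fus}

    def test_flat_and_symmetric_cases(self):
        t = self.thick((2.6, 2.6), (2.6, 2.6), (2.6, 2.6), (2.6, 2.6))
        assert ms.compute_ad_signature(t) == pytest.approx(2.6, abs=1e-12)
        t = self.thick((3.0, 2.0), (3.0, 2.0), (3.0, 2.0), (3.0, 2.0))
        assert ms.compute_ad_signature(t) == pytest.approx(2.5, abs=1e-12)

    def test_distinct_regions_match_hand_mean(self):
        t = self.thick((3.4, 3.0), (2.8, 2.6), (2.9, 2.7), (2.5, 2.3))
        expected = (3.2 + 2.7 + 2.8 + 2.4) / 4.0
        assert ms.compute_ad_signature(t) == pytest.approx(expected, abs=1e-12)

    def test_missing_region_is_an_error(self):
        with pytest.raises(ValueError):
            ms.compute_ad_signature({})


class TestChangeScores:
    @pytest.mark.parametrize("b, f, d, expected", [
        (6000.0, 5880.0, 365, -2.0),
        (6000.0, 6000.0, 200, 0.0),
        (36000.0, 37800.0, 182.5, 10.0),
    ])
    def test_apc_examples(self, b, f, d, expected):
        assert ms.compute_apc(b, f, d) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("b, f, expected", [
        (25.0, 27.0, 8.0), (160.0, 120.0, -25.0), (50.0, 50.0, 0.0),
    ])
    def test_pc_examples(self, b, f, expected):
        assert ms.compute_pc(b, f) == pytest.approx(expected, abs=1e-10)

    def test_apc_at_365_days_equals_pc(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(10, 1e6, 50)
        f = b * rng.uniform(0.8, 1.2, 50)
        np.testing.assert_allclose(ms.compute_apc(b, f, 365), ms.compute_pc(b, f), atol=1e-10)

    def test_direction_convention_is_asymmetric(self):
        # a 20% loss and the gain restoring it do not have opposite APCs:
        # the baseline denominator pins the direction convention
        loss = ms.compute_apc(100.0, 80.0, 365)
        regain = ms.compute_apc(80.0, 100.0, 365)
        assert loss == pytest.approx(-20.0, abs=1e-10)
        assert regain == pytest.approx(25.0, abs=1e-10)
        assert loss != -regain

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ms.compute_apc(0.0, 100.0, 365)
        with pytest.raises(ValueError):
            ms.compute_apc(100.0, 90.0, 0)
        with pytest.raises(ValueError):
            ms.compute_pc(0.0, 5.0)

    def test_apc_beyond_100_warns(self):
        with pytest.warns(RuntimeWarning):
            ms.compute_apc(100.0, 250.0, 365)


class TestIcvAdjustment:
    def test_proportional_values_collapse_to_mean(self):
        icv = np.array([1.2e6, 1.3e6, 1.4e6, 1.5e6, 1.6e6])
        values = 0.004 * icv
        adj = ms.adjust_icv_residual(values, icv)
        np.testing.assert_allclose(adj, np.full(5, values.mean()), rtol=1e-12)

    def test_slope_matches_normal_equations_oracle(self):
        icv = np.array([1.25e6, 1.31e6, 1.42e6, 1.55e6, 1.61e6])
        values = np.array([5200.0, 6100.0, 5900.0, 7050.0, 6600.0])
        X = np.column_stack([np.ones(5), icv])
        coef, *_ = np.linalg.lstsq(X, values, rcond=None)
        from mrisubtype.derive import icv_slope
        assert icv_slope(values, icv) == pytest.approx(coef[1], abs=1e-10)

    def test_constant_icv_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            ms.adjust_icv_residual([1.0, 2.0, 3.0], [1e6, 1e6, 1e6])

    def test_tiny_fit_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ms.adjust_icv_residual([1.0, 2.0], [1e6, 1.1e6])

    def test_mean_preserved_and_covariance_zeroed(self):
        rng = np.random.default_rng(11)
        icv = rng.normal(1.45e6, 1.3e5, 120)
        values = 0.004 * icv + rng.normal(0, 300, 120)
        mask = rng.random(120) < 0.6
        adj = ms.adjust_icv_residual(values, icv, mask)
        assert adj[mask].mean() == pytest.approx(values[mask].mean(), abs=1e-9 * abs(values.mean()))
        assert abs(np.corrcoef(adj[mask], icv[mask])[0, 1]) < 1e-10


class TestCohortDerivation:
    def test_row_order_invariance(self, small_cohort, small_derived):
        reversed_cohort = small_cohort.subset(list(small_cohort.subject_ids[::-1]))
        d2 = ms.derive_measures(reversed_cohort)
        import pandas as pd
        pd.testing.assert_frame_equal(small_derived.sort_index(), d2.sort_index())

    def test_incomplete_subjects_get_missing_change_scores(self, small_cohort):
        sid = small_cohort.subject_ids[0]
        morph = small_cohort.morphometry
        morph = morph[~((morph["subject_id"] == sid) & (morph["visit"] == "followup"))]
        from mrisubtype.io_schema import cohort_from_frames
        cohort = cohort_from_frames(morph, small_cohort.clinical.reset_index(drop=True),
                                    small_cohort.config, validate=False)
        d = ms.derive_measures(cohort)
        assert not d.loc[sid, "complete"]
        assert np.isnan(d.loc[sid, "apc_hippocampus"])
        assert d["complete"].sum() == small_cohort.n_subjects - 1

    def test_zero_noise_apc_equals_configured_rate(self):
        cfg = ms.SimulationConfig(
            n_subjects=16, seed=5, noise_scale=0.0,
            severity_slope=_m(), typicality_slope=_m(), age_slope=_m(),
            treatment_main=_m(), treatment_severity=_m(), treatment_typicality=_m(),
            base_rates=_m(hippocampus=-1.8, ventricles=5.0, gray_matter=-0.7, ad_signature=-1.0),
        )
        cohort = ms.generate_cohort(cfg, validate=True)
        d = ms.derive_measures(cohort, adjust_icv=False)
        np.testing.assert_allclose(d["apc_ad_signature"], -1.0, atol=1e-9)
        np.testing.assert_allclose(d["apc_hippocampus"], -1.8, atol=1e-9)
        np.testing.assert_allclose(d["apc_ventricles"], 5.0, atol=1e-9)
        np.testing.assert_allclose(d["apc_gray_matter"], -0.7, atol=1e-9)
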