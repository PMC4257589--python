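"""Reliability statistics: Cronbach's α, SEM, SDC, TANOVA, correlations."""

import numpy as np
import pandas as pd
import pytest

from microstates import (anova_mean_squares, cronbach_alpha,
                         feature_correlations, gfp_normalize, icc,
                         power_regression, reliability_report, sem,
                         smallest_detectable_change, tanova)


class TestCronbachAlpha:
    def test_perfectly_consistent_matrix(self):
        m = np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5]], dtype=float)
        assert cronbach_alpha(m) == pytest.approx(1.0, abs=1e-12)

    def test_independent_sessions_give_near_zero_alpha(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(200, 3))
        assert abs(cronbach_alpha(m)) < 0.15

    def test_column_constant_shift_leaves_alpha_unchanged(self):
        rng = np.random.default_rng(11)
        m = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2.0
        shifted = m.copy()
        shifted[:, 1] += 7.5
        assert cronbach_alpha(shifted) == pytest.approx(cronbach_alpha(m),
                                                        abs=1e-12)

    def test_session_column_relabeling_leaves_alpha_unchanged(self):
        rng = np.random.default_rng(12)
        m = rng.normal(size=(9, 4)) + rng.normal(size=(9, 1))
        assert cronbach_alpha(m[:, [2, 0, 3, 1]]) == pytest.approx(
            cronbach_alpha(m), abs=1e-12)

    def test_zero_between_subject_variance_is_undefined(self):
        m = np.tile([[1.0, 2.0, 3.0]], (4, 1))
        # identical subjects: subject-total variance is 0
        assert np.isnan(cronbach_alpha(m))

    def test_matches_icc3k_from_anova_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            m = (rng.normal(size=(5, 3))
                 + 2.0 * rng.normal(size=(5, 1))
                 + rng.normal(size=(1, 3)))
            assert cronbach_alpha(m) == pytest.approx(icc(m, "3k"),
                                                      abs=1e-9)

    def test_matches_pingouin_icc3k(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        m = rng.normal(size=(8, 3)) + 2 * rng.normal(size=(8, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "score": m.ravel(),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        icc3k = table.set_index("Type").loc["ICC(C,k)", "ICC"]
        assert cronbach_alpha(m) == pytest.approx(icc3k, abs=1e-9)


class TestSem:
    def test_zero_within_subject_variance(self):
        m = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0], [2.0, 2.0, 2.0]])
        assert sem(m) == pytest.approx(0.0, abs=1e-12)

    def test_shared_session_effect_contributes_nothing(self):
        # columns differing only by constants: all change is a session effect
        m = np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5]], dtype=float)
        assert sem(m) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_measurement_noise(self):
        rng = np.random.default_rng(15)
        sigma = 3.0
        true = rng.normal(50.0, 10.0, size=(200, 1))
        m = true + rng.normal(0.0, sigma, size=(200, 4))
        assert sem(m) == pytest.approx(sigma, rel=0.1)

    def test_invariant_to_global_constant(self):
        rng = np.random.default_rng(16)
        m = rng.normal(size=(10, 3))
        assert sem(m + 100.0) == pytest.approx(sem(m), abs=1e-9)

    def test_anova_decomposition_reconstructs_total_ss(self):
        rng = np.random.default_rng(17)
        m = rng.normal(size=(6, 4))
        ms_r, ms_c, ms_e = anova_mean_squares(m)
        n, k = m.shape
        total = ((m - m.mean()) ** 2).sum()
        assert ms_r * (n - 1) + ms_c * (k - 1) + ms_e * (n - 1) * (k - 1) == \
            pytest.approx(total, abs=1e-9)


class TestSmallestDetectableChange:
    def test_published_worked_example(self):
        # SEM of 6.41 ms for overall lifespan implies an SDC of 17.77 ms
        assert round(smallest_detectable_change(6.41), 2) == 17.77

    @pytest.mark.parametrize("sem_value, z, expected",
                             [(0.0, 1.96, 0.0), (5.0, 0.0, 0.0)])
    def test_degenerate_inputs(self, sem_value, z, expected):
        assert smallest_detectable_change(sem_value, z=z) == expected

    def test_fixed_ratio_to_sem(self):
        for s in (0.5, 6.41, 12.0):
            assert smallest_detectable_change(s) / s == pytest.approx(
                1.96 * np.sqrt(2.0))


class TestTanova:
    @pytest.fixture()
    def group(self, rng):
        base = gfp_normalize(rng.normal(size=16))
        return np.array([gfp_normalize(base + 0.3 * rng.normal(size=16))
                         for _ in range(10)])

    def test_identical_groups_are_maximally_insignificant(self, group):
        res = tanova(group, group.copy(), permutations=500, seed=1)
        assert res.observed_gmd == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_fixed_seed_reproduces_p_value(self, group, rng):
        other = np.array([gfp_normalize(m + 0.2 * rng.normal(size=16))
                          for m in group])
        a = tanova(group, other, permutations=500, seed=42)
        b = tanova(group, other, permutations=500, seed=42)
        assert a.p_value == b.p_value
        assert a.observed_gmd == b.observed_gmd

    def test_detects_a_genuinely_different_topography(self, group, rng):
        different = np.array([gfp_normalize(rng.normal(size=16))
                              for _ in range(10)])
        res = tanova(group, different, permutations=1000, seed=3)
        assert res.p_value < 0.05

    def test_polarity_flips_do_not_create_differences(self, group):
        flipped = group * np.where(np.arange(10) % 2 == 0, -1.0, 1.0)[:, None]
        res = tanova(group, flipped, permutations=500, seed=4)
        assert res.observed_gmd == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_two_subjects_rejected(self, group):
        with pytest.raises(ValueError):
            tanova(group[:1], group[:1], permutations=10, seed=0)


class TestReliabilityReport:
    @staticmethod
    def feature_table(rng, n_subjects=8, sessions=("ses1", "ses2", "ses3"),
                      subject_sd=10.0, noise_sd=2.0):
        rows = []
        truth = 100.0 + rng.normal(0, subject_sd, n_subjects)
        for s in range(n_subjects):
            for ses in sessions:
                for cls in ("A", "B", "All"):
                    rows.append({
                        "subject": f"S{s:02d}", "session": ses,
                        "montage": "30", "strategy": "global",
                        "algorithm": "taahc", "class": cls,
                        "mean_lifespan_ms": truth[s] + rng.normal(0, noise_sd),
                        "frequency_hz": 10.0 + rng.normal(0, 0.5),
                        "coverage": 0.25 if cls != "All" else 1.0,
                    })
        return pd.DataFrame(rows)

    def test_strong_subject_effects_give_high_alpha(self, rng):
        report = reliability_report(self.feature_table(rng))
        lifespans = report[report["feature"] == "mean_lifespan_ms"]
        assert (lifespans["alpha"] > 0.9).all()
        np.testing.assert_allclose(lifespans["sdc95"],
                                   lifespans["sem"] * 1.96 * np.sqrt(2))

    def test_coverage_all_row_is_skipped(self, rng):
        report = reliability_report(self.feature_table(rng))
        assert report[(report["feature"] == "coverage")
                      & (report["class"] == "All")].empty

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            reliability_report(pd.DataFrame({"subject": [], "class": []}))


class TestFeatureAndPowerAssociations:
    def test_perfectly_antimonotone_and_duplicated_columns(self):
        rows = []
        for i, (life, freq) in enumerate([(80, 12), (100, 10), (120, 8)]):
            rows.append({"subject": f"S{i}", "session": "ses1", "class": "A",
                         "mean_lifespan_ms": life, "frequency_hz": freq})
            rows.append({"subject": f"S{i}", "session": "ses1", "class": "B",
                         "mean_lifespan_ms": life, "frequency_hz": freq})
        table = pd.DataFrame(rows)
        corr = feature_correlations(table, classes=("A", "B"))
        anti = corr[corr["kind"] == "lifespan_vs_frequency"]
        assert np.allclose(anti["r"], -1.0)
        dup = corr[corr["kind"] == "lifespan_vs_lifespan"]
        assert np.allclose(dup["r"], 1.0)

    @staticmethod
    def power_tables(rng, slope=-100.0):
        feats, powers = [], []
        for i in range(30):
            beta = rng.uniform(0.1, 0.4)
            alpha = rng.uniform(0.3, 0.6)
            life = 130.0 + slope * beta + rng.normal(0, 2.0)
            feats.append({"subject": f"S{i}", "session": "ses1",
                          "class": "All", "mean_lifespan_ms": life,
                          "frequency_hz": 1000.0 / life, "coverage": 1.0})
            for band, val in [("delta", 0.2), ("theta", 0.2),
                              ("alpha", alpha), ("beta", beta)]:
                powers.append({"subject": f"S{i}", "session": "ses1",
                               "band": band,
                               "relative_power": val + rng.normal(0, 0.005)})
        return pd.DataFrame(feats), pd.DataFrame(powers)

    def test_recovers_negative_beta_power_association(self, rng):
        feats, powers = self.power_tables(rng)
        model = power_regression(feats, powers)
        assert model["params"]["beta"] < 0
        assert model["pvalues"]["beta"] < 0.01
        assert model["r_squared"] > 0.5

    def test_zero_variance_regressor_is_dropped(self, rng):
        feats, powers = self.power_tables(rng)
        powers.loc[powers["band"] == "delta", "relative_power"] = 0.2
        model = power_regression(feats, powers)
        assert "delta" not in model["params"].index

    def test_perfect_collinearity_is_flagged(self, rng):
        feats, powers = self.power_tables(rng)
        wide = powers.pivot_table(index=["subject", "session"],
                                  columns="band", values="relative_power")
        wide["theta"] = 2.0 * wide["beta"]
        powers = wide.reset_index().melt(
            id_vars=["subject", "session"], var_name="band",
            value_name="relative_power")
        model = power_regression(feats, powers)
        assert model["collinear"]
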