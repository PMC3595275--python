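import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rarecnv as rc


def make_population(n=2000, n_carriers=10, shift=0.0, seed=0):
    """Sex-balanced cohort with normal log10 BMI and a carrier indicator."""
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    mu = np.where(sex == "M", np.log10(25.5), np.log10(24.5))
    log_bmi = rng.normal(mu, 0.07)
    carrier = np.zeros(n, dtype=int)
    carrier[rng.choice(n, n_carriers, replace=False)] = 1
    log_bmi = log_bmi + shift * carrier
    return pd.DataFrame({"log10_bmi": log_bmi, "sex": sex, "r1": carrier})


class TestAnova:
    def test_detects_known_shift(self):
        """At a +0.08 log10-BMI carrier shift (about +5 kg/m^2) with 10
        carriers in 5000 samples, the carrier factor is significant in the
        large majority of replicates."""
        hits = 0
        n_reps = 40
        for seed in range(n_reps):
            df = make_population(5000, 10, 0.08, seed)
            (res,) = rc.anova_carrier_bmi(df, ["r1"])
            hits += res.p_value < 0.05
        assert hits / n_reps >= 0.8

    def test_type_i_error_calibrated(self):
        """With zero effect the carrier factor rejects at about the nominal
        5% rate."""
        n_reps = 600
        hits = 0
        for seed in range(n_reps):
            df = make_population(1500, 10, 0.0, seed + 10_000)
            (res,) = rc.anova_carrier_bmi(df, ["r1"])
            hits += res.p_value < 0.05
        assert hits / n_reps == pytest.approx(0.05, abs=0.02)

    def test_invariant_to_sex_relabel_and_response_shift(self):
        df = make_population(800, 8, 0.05, 3)
        (base,) = rc.anova_carrier_bmi(df, ["r1"])
        relabeled = df.assign(sex=df["sex"].map({"M": "zzz", "F": "aaa"}))
        (rel,) = rc.anova_carrier_bmi(relabeled, ["r1"])
        shifted = df.assign(log10_bmi=df["log10_bmi"] + 0.37)
        (shf,) = rc.anova_carrier_bmi(shifted, ["r1"])
        assert rel.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert shf.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_zero_variance_response_rejected(self):
        df = make_population(100, 5, 0.0, 0)
        df["log10_bmi"] = 1.4
        with pytest.raises(ValueError, match="zero variance"):
            rc.anova_carrier_bmi(df, ["r1"])

    def test_min_carriers_inclusion_rule(self):
        df = make_population(500, 2, 0.0, 1)
        assert rc.anova_carrier_bmi(df, ["r1"], min_carriers=3) == []

    def test_joint_model_close_to_marginal_for_disjoint_carriers(self):
        df = make_population(3000, 12, 0.06, 5)
        rng = np.random.default_rng(6)
        r2 = np.zeros(len(df), dtype=int)
        r2[rng.choice(np.flatnonzero(df["r1"] == 0), 8, replace=False)] = 1
        df["r2"] = r2
        marginal = {r.region_id: r.p_value
                    for r in rc.anova_carrier_bmi(df, ["r1", "r2"])}
        joint = {r.region_id: r.p_value
                 for r in rc.anova_carrier_bmi(df, ["r1", "r2"], joint=True)}
        for rid in ("r1", "r2"):
            assert joint[rid] == pytest.approx(marginal[rid], rel=0.2)


class TestCarrierMeanTest:
    def test_equal_mean_samples_centered_at_half(self):
        """Samples with exactly equal means give a one-tailed P of 0.5."""
        rng = np.random.default_rng(0)
        x = rng.normal(25, 4, 4000)
        res = rc.carrier_mean_test(x, x.copy(), tail="one")
        assert res.p_value == pytest.approx(0.5, abs=1e-9)

    def test_one_tailed_p_uniform_under_null(self):
        """Over repeated null draws the one-tailed P is uniform."""
        rng = np.random.default_rng(4)
        ps = [rc.carrier_mean_test(rng.normal(25, 4, 50),
                                   rng.normal(25, 4, 2000),
                                   tail="one").p_value
              for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_identical_samples_zero_difference(self):
        vals = [24.0, 26.0, 28.0]
        res = rc.carrier_mean_test(vals, vals, tail="two")
        assert res.diff == pytest.approx(0.0)

    def test_single_carrier_rejected(self):
        with pytest.raises(ValueError, match="2 carriers"):
            rc.carrier_mean_test([25.0], [24.0, 26.0])

    def test_ci_coverage_of_known_shift(self):
        """The 95% Welch CI covers a simulated +3 kg/m^2 shift about 95% of
        the time."""
        rng = np.random.default_rng(7)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            carriers = rng.normal(28, 4, 25)
            cohort = rng.normal(25, 4, 2000)
            res = rc.carrier_mean_test(carriers, cohort, tail="two")
            hits += res.ci_low <= 3.0 <= res.ci_high
        assert hits / n_reps == pytest.approx(0.95, abs=0.04)


class TestZScore:
    def _stats(self):
        return pd.DataFrame({"mean": [25.0], "sd": [4.0]}, index=["pop"])

    def test_carrier_at_cohort_mean_has_zero_z(self):
        carriers = pd.DataFrame({"bmi": [25.0], "cohort": ["pop"]})
        res = rc.zscore_test(carriers, self._stats())
        assert res.mean_z == pytest.approx(0.0)
        assert res.p_one_tailed == pytest.approx(0.5)

    def test_mean_z_near_published_example(self):
        """Eight carriers averaging Z = +1.10 give a one-tailed normal P
        close to 1e-3 (tail of 1.10 * sqrt(8))."""
        z = 1.10
        carriers = pd.DataFrame({"bmi": [25.0 + z * 4.0] * 8,
                                 "cohort": ["pop"] * 8})
        res = rc.zscore_test(carriers, self._stats(), ci_method="unit_null")
        assert res.mean_z == pytest.approx(1.10)
        assert res.p_one_tailed == pytest.approx(
            float(stats.norm.sf(1.10 * np.sqrt(8))), rel=1e-9)
        assert res.p_one_tailed == pytest.approx(9.3e-4, rel=0.05)

    def test_agrees_with_t_test_asymptotically(self):
        """With many carriers, the Z-score test and the Welch t-test give
        nearly identical P-values."""
        rng = np.random.default_rng(11)
        cohort = rng.normal(25, 4, 20000)
        carriers_bmi = rng.normal(26.5, 4, 60)
        stats_df = pd.DataFrame(
            {"mean": [cohort.mean()], "sd": [cohort.std(ddof=1)]},
            index=["pop"])
        carriers = pd.DataFrame({"bmi": carriers_bmi,
                                 "cohort": ["pop"] * len(carriers_bmi)})
        # compare on equal footing: scale mean Z by observed Z dispersion
        z = rc.zscore_test(carriers, stats_df)
        t = rc.carrier_mean_test(carriers_bmi, cohort, tail="one")
        p_z_studentized = float(
            stats.norm.sf(z.mean_z / (z.z_scores.std(ddof=1) / np.sqrt(z.n))))
        assert abs(p_z_studentized - t.p_value) < 1e-2

    def test_single_carrier_uses_its_own_z(self):
        carriers = pd.DataFrame({"bmi": [33.0], "cohort": ["pop"]})
        res = rc.zscore_test(carriers, self._stats())
        assert res.n == 1
        assert res.p_one_tailed == pytest.approx(float(stats.norm.sf(2.0)))


class TestSubgroupContrast:
    def test_identical_subgroups_null(self):
        rng = np.random.default_rng(3)
        pop = rng.normal(25, 4, 5000)
        a = rng.normal(25, 4, 40)
        b = rng.normal(25, 4, 40)
        res = rc.subgroup_contrast(a, b, pop, tail="one")
        assert 0.1 < res.p_between < 0.9

    def test_detects_heterogeneous_effect(self):
        """Large-deletion carriers shifted down by -0.06 log10 BMI separate
        from unshifted small-deletion carriers in most replicates."""
        hits_between = 0
        n_reps = 60
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            pop = 10 ** rng.normal(np.log10(25), 0.07, 3000)
            # 20 carriers per subgroup: the design point where the one-tailed
            # Welch test has ~0.8 power at this effect (d ~ 0.86)
            large = 10 ** rng.normal(np.log10(25) - 0.06, 0.07, 20)
            small = 10 ** rng.normal(np.log10(25), 0.07, 20)
            res = rc.subgroup_contrast(large, small, pop, tail="one")
            hits_between += res.p_between < 0.05
        assert hits_between / n_reps >= 0.7

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rc.subgroup_contrast([], [25.0], [24.0, 26.0])

    def test_singleton_subgroup_falls_back_to_z(self):
        rng = np.random.default_rng(9)
        pop = rng.normal(25, 4, 1000)
        res = rc.subgroup_contrast([10.0], [25.0, 26.0], pop, tail="one")
        assert 0 < res.p_a_vs_population < 0.01


class TestGenderCorrection:
    def test_residual_method_removes_sex_means(self):
        df = make_population(4000, 0, 0.0, 21).rename(
            columns={"log10_bmi": "lb"})
        df["bmi"] = 10 ** df["lb"]
        corrected = rc.gender_corrected_bmi(df, "residual")
        logc = np.log10(corrected)
        by_sex = logc.groupby(df["sex"]).mean()
        assert abs(by_sex["M"] - by_sex["F"]) < 1e-10

    def test_stratified_z_unit_scale(self):
        df = make_population(4000, 0, 0.0, 22).rename(
            columns={"log10_bmi": "lb"})
        df["bmi"] = 10 ** df["lb"]
        z = rc.gender_corrected_bmi(df, "stratified_z")
        for s in ("M", "F"):
            sub = z[df["sex"] == s]
            assert sub.mean() == pytest.approx(0.0, abs=1e-10)
            assert sub.std(ddof=1) == pytest.approx(1.0, rel=1e-9)
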