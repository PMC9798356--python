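"""PheWAS, thresholds, burden, and the MR estimators (one- and two-sample)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bmiphenet.config import PhecodeSpec, SimulationConfig, TwoSampleConfig
from bmiphenet.datatypes import GenotypeMatrix, PhecodeTable
from bmiphenet.grs import compute_grs
from bmiphenet.mr import (
    grs_mr,
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    wald_ratios,
    weighted_median_estimate,
)
from bmiphenet.phewas import (
    bonferroni_threshold,
    disease_burden,
    filter_phecodes,
    run_phewas,
    standardize_bmi,
)
from bmiphenet.simulate import simulate_cohort, simulate_covariates, simulate_two_sample


class TestStandardize:
    def test_three_values(self):
        z = standardize_bmi(pd.DataFrame({"bmi": [28.0, 30.0, 32.0]}))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(50)
        z = standardize_bmi(pd.DataFrame({"bmi": rng.gamma(9, 3.3, size=400)}))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(51)
        x = rng.normal(30, 5, size=200)
        z1 = standardize_bmi(pd.DataFrame({"bmi": x}))
        z2 = standardize_bmi(pd.DataFrame({"bmi": 3.0 * x + 7.0}))
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_constant_bmi_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_bmi(pd.DataFrame({"bmi": np.full(10, 30.0)}))


def _phe_table(counts, n):
    """PhecodeTable with exact case counts per code."""
    status = {}
    for code, k in counts.items():
        v = np.zeros(n, dtype=np.int8)
        v[:k] = 1
        status[code] = v
    meta = pd.DataFrame({"code": list(counts), "description": "", "disease_group": ""})
    return PhecodeTable(status=pd.DataFrame(status), meta=meta)


class TestFilter:
    def test_boundaries(self):
        phe = _phe_table({"1": 199, "2": 200, "3": 300}, n=500)
        kept = filter_phecodes(phe, min_cases=200, min_controls=200)
        assert kept.codes == ["2", "3"]  # 199 cases removed; 200/300 retained

    def test_control_boundary(self):
        phe = _phe_table({"1": 301, "2": 300}, n=500)
        kept = filter_phecodes(phe, min_cases=200, min_controls=200)
        assert kept.codes == ["2"]  # code 1 has only 199 controls

    def test_counts_match_direct_oracle(self):
        cfg = SimulationConfig(n_individuals=3_000, n_variants=10, n_causal=1, seed=52)
        *_, phe = simulate_cohort(cfg)
        kept = filter_phecodes(phe, min_cases=200, min_controls=200)
        expected = [c for c in phe.codes
                    if 200 <= phe.status[c].sum() <= len(phe.status) - 200]
        assert kept.codes == expected


class TestBonferroni:
    def test_paper_scale_thresholds(self):
        assert bonferroni_threshold(1244) == pytest.approx(4.02e-5, rel=5e-3)
        assert bonferroni_threshold(833) == pytest.approx(6.00e-5, rel=5e-3)
        assert bonferroni_threshold(1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestRunPhewas:
    def test_null_exposure_gives_uniform_p(self):
        fracs = []
        for seed in range(3):
            specs = [PhecodeSpec(str(100 + j), 0.2) for j in range(40)]
            cfg = SimulationConfig(n_individuals=2_000, n_variants=10, n_causal=1,
                                   phecode_spec=specs, seed=60 + seed)
            _, cov, trait, _, phe = simulate_cohort(cfg)
            rng = np.random.default_rng(70 + seed)
            exposure = rng.standard_normal(len(cov))
            res = run_phewas(exposure, phe, cov)
            fracs.append((res["p"] < 0.05).mean())
        frac = float(np.mean(fracs))
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 120)

    def test_or_ci_covers_generative_odds_ratio(self):
        """95% CI covers OR=2 in the overwhelming majority of replicates."""
        cover, reps = 0, 60
        for r in range(reps):
            cfg = SimulationConfig(
                n_individuals=4_000, n_variants=10, n_causal=1, h2_bmi=0.0,
                phecode_spec=[PhecodeSpec("401", 0.2, math.log(2.0))], seed=200 + r)
            _, cov, trait, _, phe = simulate_cohort(cfg)
            res = run_phewas(standardize_bmi(trait), phe, cov).iloc[0]
            cover += res["ci_low"] <= 2.0 <= res["ci_high"]
        assert cover >= int(0.87 * reps)  # ~95% nominal; binomial slack at 60 reps

    def test_constant_exposure_rejected(self):
        phe = _phe_table({"1": 250}, n=500)
        cfg = SimulationConfig(n_individuals=500, n_variants=10, n_causal=1, seed=53)
        cov = simulate_covariates(cfg)
        with pytest.raises(ValueError, match="constant"):
            run_phewas(np.ones(500), phe, cov)

    def test_separation_flagged_not_raised(self):
        cfg = SimulationConfig(n_individuals=500, n_variants=10, n_causal=1, seed=54)
        cov = simulate_covariates(cfg)
        rng = np.random.default_rng(55)
        exposure = rng.standard_normal(500)
        status = (exposure > 0).astype(np.int8)  # perfectly separated by exposure
        phe = PhecodeTable(status=pd.DataFrame({"1": status}),
                           meta=pd.DataFrame({"code": ["1"], "description": [""],
                                              "disease_group": [""]}))
        res = run_phewas(exposure, phe, cov)
        assert bool(res.loc[0, "flagged"])


class TestIVW:
    def _frame(self, bx, by, sy, sx=None):
        m = len(bx)
        return pd.DataFrame({"snp": [f"v{i}" for i in range(m)],
                             "beta_exp": bx, "se_exp": sx if sx is not None else [0.01] * m,
                             "beta_out": by, "se_out": sy})

    def test_equal_wald_ratios_return_that_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        data = self._frame(bx, 0.4 * bx, [0.01, 0.02, 0.03])
        assert mr_ivw(data).beta == pytest.approx(0.4, rel=1e-12)

    def test_two_variants_match_longhand_arithmetic(self):
        bx, by, sy = [0.1, 0.25], [0.03, 0.02], [0.01, 0.05]
        data = self._frame(bx, by, sy)
        w = [b**2 / s**2 for b, s in zip(bx, sy)]
        num = sum(bi * yi / si**2 for bi, yi, si in zip(bx, by, sy))
        expected = num / sum(w)
        res = mr_ivw(data)
        assert res.beta == pytest.approx(expected, rel=1e-12)
        assert res.se == pytest.approx((1 / sum(w)) ** 0.5, rel=1e-12)

    def test_fewer_than_two_variants_rejected(self):
        with pytest.raises(ValueError):
            mr_ivw(self._frame([0.1], [0.02], [0.01]))

    def test_unbiased_under_no_pleiotropy(self):
        est = [mr_ivw(simulate_two_sample(TwoSampleConfig(seed=s))).beta
               for s in range(300)]
        mc_err = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.1) < 4 * mc_err

    def test_variant_relabeling_and_sign_flip_equivariance(self):
        ts = simulate_two_sample(TwoSampleConfig(seed=77))
        base = mr_ivw(ts).beta
        shuffled = ts.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert mr_ivw(shuffled).beta == pytest.approx(base, rel=1e-12)
        flipped = ts.copy()
        flipped.loc[::2, ["beta_exp", "beta_out"]] *= -1.0  # recode alternate alleles
        assert mr_ivw(flipped).beta == pytest.approx(base, rel=1e-12)


class TestEgger:
    def test_five_variants_match_wls_normal_equations(self):
        ts = simulate_two_sample(TwoSampleConfig(n_variants=5, seed=80))
        res = mr_egger(ts)
        bx = ts["beta_exp"].to_numpy().copy()
        by = ts["beta_out"].to_numpy().copy()
        flip = bx < 0
        bx[flip] *= -1; by[flip] *= -1
        W = np.diag(1.0 / ts["se_out"].to_numpy() ** 2)
        X = np.column_stack([np.ones(5), bx])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        assert res.egger_intercept == pytest.approx(coef[0], rel=1e-10)
        assert res.beta == pytest.approx(coef[1], rel=1e-10)

    def test_no_pleiotropy_small_se_gives_null_intercept(self):
        ts = simulate_two_sample(TwoSampleConfig(
            n_variants=50, se_exposure=1e-7, se_outcome=1e-7, seed=81))
        res = mr_egger(ts)
        assert abs(res.egger_intercept) < 1e-6
        assert res.beta == pytest.approx(0.1, abs=1e-5)

    def test_directional_pleiotropy_recovered_in_mean(self):
        """Slope ~ beta_causal; intercept ~ mean injected direct effect."""
        slopes, icpts = [], []
        for s in range(300):
            ts = simulate_two_sample(TwoSampleConfig(
                pleiotropy_mode="directional", frac_invalid=0.3,
                pleiotropy_delta=0.05, seed=1000 + s))
            res = mr_egger(ts)
            slopes.append(res.beta)
            icpts.append(res.egger_intercept)
        target_icpt = 0.3 * 0.05  # mean pleiotropy over all instruments
        assert abs(np.mean(icpts) - target_icpt) < 4 * np.std(icpts, ddof=1) / np.sqrt(300)
        assert abs(np.mean(slopes) - 0.1) < 4 * np.std(slopes, ddof=1) / np.sqrt(300)

    def test_fewer_than_three_variants_rejected(self):
        ts = simulate_two_sample(TwoSampleConfig(seed=82)).head(2)
        with pytest.raises(ValueError):
            mr_egger(ts)


class TestWeightedMedian:
    def test_equal_ratios_return_that_ratio(self):
        data = pd.DataFrame({"snp": ["a", "b", "c"],
                             "beta_exp": [0.1, 0.2, 0.4],
                             "se_exp": [0.01] * 3,
                             "beta_out": [0.05, 0.10, 0.20],
                             "se_out": [0.01, 0.02, 0.04]})
        res = mr_weighted_median(data, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, rel=1e-10)

    def test_interpolation_rule_on_three_equal_weights(self):
        """Equal weights: cumulative midpoint weight hits 0.5 exactly at the
        middle ratio, so {1,2,9} -> 2."""
        est = weighted_median_estimate(np.array([1.0, 2.0, 9.0]), np.ones(3))
        assert est == pytest.approx(2.0, abs=1e-12)

    def test_interpolation_between_bracketing_ratios(self):
        # weights 1,3 on ratios 0 and 1: s = [1/8, 5/8]; 0.5 -> 0.75
        est = weighted_median_estimate(np.array([0.0, 1.0]), np.array([1.0, 3.0]))
        assert est == pytest.approx(0.75, abs=1e-12)

    def test_robust_to_30pct_directional_pleiotropy(self):
        wm_bias, ivw_bias = [], []
        for s in range(200):
            ts = simulate_two_sample(TwoSampleConfig(
                pleiotropy_mode="directional", frac_invalid=0.3,
                pleiotropy_delta=0.1, seed=2000 + s))
            ratios, ratio_se = wald_ratios(ts)
            wm_bias.append(weighted_median_estimate(ratios, 1 / ratio_se**2) - 0.1)
            ivw_bias.append(mr_ivw(ts).beta - 0.1)
        assert abs(np.mean(wm_bias)) < abs(np.mean(ivw_bias))

    def test_bootstrap_se_deterministic_under_seed(self):
        ts = simulate_two_sample(TwoSampleConfig(seed=83))
        r1 = mr_weighted_median(ts, n_boot=100, seed=9)
        r2 = mr_weighted_median(ts, n_boot=100, seed=9)
        assert r1.se == r2.se


@pytest.fixture(scope="module")
def causal_cohort():
    cfg = SimulationConfig(
        n_individuals=8_000, n_variants=100, n_causal=80, h2_bmi=0.2,
        ld_rho=0.0,
        phecode_spec=[PhecodeSpec("250.2", 0.25, math.log(2.0))], seed=90)
    return cfg, simulate_cohort(cfg)


class TestGrsMR:
    def _oracle_score(self, g, betas):
        w = g.variants[["snp", "ea"]].copy()
        w["weight"] = betas.to_numpy()
        return compute_grs(g, w.loc[w["weight"] != 0].reset_index(drop=True))

    def test_2sri_recovers_conditional_log_or(self, causal_cohort):
        cfg, (g, cov, trait, betas, phe) = causal_cohort
        score = self._oracle_score(g, betas)
        res = grs_mr(score, trait, phe, cov, method="2sri")[0]
        assert not res.weak_instrument
        assert abs(res.beta - math.log(2.0)) < 3 * res.se

    def test_ratio_estimator_attenuated_toward_null(self, causal_cohort):
        """The marginal (ratio) estimate sits slightly below the conditional
        one — the non-collapsibility of the odds ratio."""
        cfg, (g, cov, trait, betas, phe) = causal_cohort
        score = self._oracle_score(g, betas)
        ratio = grs_mr(score, trait, phe, cov, method="ratio")[0]
        sri = grs_mr(score, trait, phe, cov, method="2sri")[0]
        assert ratio.beta < sri.beta
        assert ratio.beta > 0.8 * sri.beta

    def test_uncorrelated_score_flags_weak_instrument(self, causal_cohort):
        cfg, (g, cov, trait, betas, phe) = causal_cohort
        rng = np.random.default_rng(91)
        res = grs_mr(rng.standard_normal(len(trait)), trait, phe, cov)[0]
        assert res.weak_instrument

    def test_single_variant_grs_ratio_equals_ivw_identity(self, causal_cohort):
        """With a single-variant instrument the one-sample ratio equals the
        IVW formula evaluated on that variant's own summary statistics."""
        import statsmodels.api as sm

        from bmiphenet.phewas import phewas_design

        cfg, (g, cov, trait, betas, phe) = causal_cohort
        snp = betas[betas != 0].abs().idxmax()
        w = pd.DataFrame({"snp": [snp], "ea": [g.variants.set_index("snp").loc[snp, "ea"]],
                          "weight": [1.0]})
        score = compute_grs(g, w)
        ratio = grs_mr(score, trait, phe, cov, method="ratio")[0]

        z = standardize_bmi(trait)
        Xc = phewas_design(cov)
        X = np.column_stack([Xc[:, :1], score, Xc[:, 1:]])
        b_x = sm.OLS(z, X).fit().params[1]
        fit = sm.Logit(phe.status.iloc[:, 0].to_numpy(float), X).fit(disp=0)
        summary = pd.DataFrame({"snp": [snp] * 2, "beta_exp": [b_x] * 2,
                                "se_exp": [0.01] * 2, "beta_out": [fit.params[1]] * 2,
                                "se_out": [fit.bse[1]] * 2})
        # IVW of the duplicated single variant reduces to the Wald ratio
        assert ratio.beta == pytest.approx(mr_ivw(summary).beta, rel=1e-10)


class TestBurden:
    def _cohort(self, seed=95):
        cfg = SimulationConfig(n_individuals=2_000, n_variants=10, n_causal=1, seed=seed)
        return simulate_cohort(cfg)

    def test_no_cases_gives_zero_means_and_p_one(self):
        g, cov, trait, _, phe = self._cohort()
        empty = PhecodeTable(
            status=pd.DataFrame({"1": np.zeros(len(trait), dtype=np.int8)},
                                index=trait.index),
            meta=pd.DataFrame({"code": ["1"], "description": [""], "disease_group": [""]}))
        summary, p = disease_burden(empty, ["1"], trait)
        assert (summary["mean_burden"].dropna() == 0).all()
        assert p == 1.0

    def test_bmi_exactly_30_in_upper_category(self):
        trait = pd.DataFrame({"bmi": [24.0, 30.0, 41.0]})
        status = pd.DataFrame({"1": [1, 1, 1]})
        phe = PhecodeTable(status=status, meta=pd.DataFrame(
            {"code": ["1"], "description": [""], "disease_group": [""]}))
        summary, _ = disease_burden(phe, ["1"], trait)
        row30 = summary.loc[summary["category"] == "[30,40)"].iloc[0]
        assert row30["n"] == 1  # the BMI=30 individual
        assert summary.loc[summary["category"] == "[25,30)", "n"].iloc[0] == 0

    def test_burden_increasing_with_bmi_detected(self, cohort20k):
        cfg, (g, cov, trait, betas, phe) = cohort20k
        positive = [p.code for p in cfg.phecode_spec if p.gamma_bmi > 0]
        summary, p = disease_burden(phe, positive, trait)
        means = summary["mean_burden"].dropna().to_numpy()
        assert np.all(np.diff(means) > 0)  # monotone across categories
        assert p < 0.001
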