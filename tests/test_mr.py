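"""Mendelian randomization: Wald/IVW, GRS-TSLS, Egger, instrument rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from amylasekit.mr import (
    CausalEstimate,
    EggerRegression,
    HarmonizationError,
    InstrumentSet,
    SnpSummaryStat,
    TwoStageLeastSquares,
    WeakInstrumentWarning,
    build_grs,
    egger_test,
    harmonize,
    instrument_scan,
    ivw_pool,
    residual_association_check,
    snp_scan,
    tsls,
    wald_ratio,
)
from amylasekit.simulate import SimulationConfig, generate_cohort, generate_snp_truth
from conftest import ivw_from_cohort, tsls_from_cohort


def _stat(snp="rs1", ea="A", oa="G", beta=0.1, se=0.02, **kw):
    return SnpSummaryStat(snp, ea, oa, beta, se, **kw)


class TestHarmonization:
    def test_matching_alleles_unchanged(self):
        out = harmonize(_stat(beta=-0.2), _stat(beta=0.05))
        assert out.beta == -0.2

    def test_swapped_alleles_flip_sign(self):
        out = harmonize(_stat(ea="G", oa="A", beta=-0.2), _stat(beta=0.05))
        assert out.beta == 0.2
        assert out.effect_allele == "A"

    def test_irreconcilable_alleles_raise(self):
        with pytest.raises(HarmonizationError):
            harmonize(_stat(ea="C", oa="T"), _stat())

    def test_snp_id_mismatch_raises(self):
        with pytest.raises(HarmonizationError):
            harmonize(_stat(snp="rs2"), _stat(snp="rs1"))

    def test_strand_ambiguous_warns(self):
        with pytest.warns(UserWarning, match="strand-ambiguous"):
            harmonize(_stat(ea="A", oa="T"), _stat(ea="A", oa="T"))


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        est = wald_ratio(_stat(beta=0.0, se=0.08), _stat(beta=0.05, se=0.01))
        assert est.beta_causal == 0.0

    def test_direct_division_and_first_order_se(self):
        est = wald_ratio(_stat(beta=-0.20, se=0.08), _stat(beta=0.04, se=0.01))
        assert est.beta_causal == pytest.approx(-5.0)
        assert est.se == pytest.approx(2.0)

    def test_second_order_se_is_larger(self):
        first = wald_ratio(_stat(beta=-0.20, se=0.08), _stat(beta=0.04, se=0.01))
        second = wald_ratio(
            _stat(beta=-0.20, se=0.08), _stat(beta=0.04, se=0.01), second_order_se=True
        )
        assert second.se > first.se

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_stat(beta=0.1, se=0.05), _stat(beta=0.0, se=0.01))

    def test_flip_invariance_of_ratio(self):
        # storing the other allele with negated effects leaves the ratio fixed
        a = wald_ratio(_stat(beta=-0.2, se=0.08), _stat(beta=0.05, se=0.01))
        b = wald_ratio(
            _stat(ea="G", oa="A", beta=0.2, se=0.08), _stat(beta=0.05, se=0.01)
        )
        assert a.beta_causal == pytest.approx(b.beta_causal)
        assert a.se == pytest.approx(b.se)


class TestIvwPool:
    def test_single_estimate_identity(self):
        e = CausalEstimate("bmi", "amy1", -2.35, 0.35, 1e-10, "ivw_ratio", "rs1")
        pooled = ivw_pool([e])
        assert pooled.beta_causal == pytest.approx(-2.35)
        assert pooled.se == pytest.approx(0.35)

    def test_equal_se_closed_form(self):
        es = [
            CausalEstimate("x", "y", b, 0.4, 0.5, "ivw_ratio", f"rs{i}")
            for i, b in enumerate([1.0, 2.0, 3.0, 6.0])
        ]
        pooled = ivw_pool(es)
        assert pooled.beta_causal == pytest.approx(3.0)
        assert pooled.se == pytest.approx(0.4 / 2.0)

    def test_duplicating_the_set_halves_variance(self):
        es = [
            CausalEstimate("x", "y", 1.0, 0.3, 0.5, "ivw_ratio", "a"),
            CausalEstimate("x", "y", 2.0, 0.6, 0.5, "ivw_ratio", "b"),
        ]
        once, twice = ivw_pool(es), ivw_pool(es + es)
        assert twice.beta_causal == pytest.approx(once.beta_causal)
        assert twice.se == pytest.approx(once.se / np.sqrt(2))

    def test_mixed_pairs_rejected(self):
        es = [
            CausalEstimate("x", "y", 1.0, 0.3, 0.5, "ivw_ratio", "a"),
            CausalEstimate("x", "z", 1.0, 0.3, 0.5, "ivw_ratio", "b"),
        ]
        with pytest.raises(ValueError, match="mixed"):
            ivw_pool(es)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-3, 3), st.floats(0.05, 2.0)), min_size=1, max_size=10
        )
    )
    def test_wald_plus_pool_equals_explicit_weighted_sum(self, data):
        """Ratio estimates pooled by IVW match the brute-force fixed-denominator
        estimator written as explicit sums over SNPs."""
        b_exp = 0.05
        ests, num, den = [], 0.0, 0.0
        for i, (b_out, se_out) in enumerate(data):
            ests.append(
                wald_ratio(
                    _stat(snp=f"rs{i}", beta=b_out, se=se_out),
                    _stat(snp=f"rs{i}", beta=b_exp, se=0.01),
                )
            )
            w = (b_exp / se_out) ** 2
            num += w * (b_out / b_exp)
            den += w
        pooled = ivw_pool(ests)
        assert pooled.beta_causal == pytest.approx(num / den, rel=1e-12, abs=1e-12)
        assert pooled.se == pytest.approx(1.0 / np.sqrt(den), rel=1e-12)


class TestGrs:
    def _inst(self, snps, signs=None):
        signs = signs or {s: 1 for s in snps}
        return InstrumentSet(snp_ids=list(snps), grs_weights=signs)

    def test_extremes(self):
        snps = [f"snp_{i:03d}" for i in range(83)]
        geno = pd.DataFrame([[2] * 83, [0] * 83], columns=snps)
        score = build_grs(geno, self._inst(snps))
        assert score.tolist() == [166.0, 0.0]

    def test_flip_invariance(self):
        rng = np.random.default_rng(0)
        snps = ["a", "b", "c"]
        geno = pd.DataFrame(rng.integers(0, 3, (50, 3)), columns=snps)
        base = build_grs(geno, self._inst(snps))
        flipped_geno = geno.copy()
        flipped_geno["b"] = 2 - flipped_geno["b"]
        flipped = build_grs(flipped_geno, self._inst(snps, {"a": 1, "b": -1, "c": 1}))
        assert np.allclose(base, flipped)

    def test_missing_snp_and_bad_dosage(self):
        geno = pd.DataFrame({"a": [0, 1]})
        with pytest.raises(KeyError):
            build_grs(geno, self._inst(["a", "zz"]))
        with pytest.raises(ValueError, match="dosages"):
            build_grs(pd.DataFrame({"a": [0, 3]}), self._inst(["a"]))

    def test_exclusions_cannot_remain_instruments(self):
        with pytest.raises(ValueError, match="excluded"):
            InstrumentSet(
                snp_ids=["a"], grs_weights={"a": 1},
                exclusion_log=[("a", "pleiotropic")],
            )


class TestTsls:
    def test_noiseless_system_exact(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, 500)
        df = pd.DataFrame({"z": z, "x": z, "y": 0.5 * z})
        est = TwoStageLeastSquares(exposure="x", outcome="y", instrument="z",
                                   covariates=()).fit(df)
        assert est.beta_causal_ == pytest.approx(0.5, abs=1e-12)

    def test_equals_reduced_form_over_first_stage(self):
        """Just-identified, no covariates: TSLS = Wald ratio of OLS slopes."""
        rng = np.random.default_rng(2)
        n = 2000
        z = rng.integers(0, 3, n).astype(float)
        u = rng.normal(0, 1, n)
        x = 0.5 * z + u + rng.normal(0, 1, n)
        y = 0.3 * x + u + rng.normal(0, 1, n)
        df = pd.DataFrame({"z": z, "x": x, "y": y})
        est = tsls(df, "x", "y", "z", covariates=())
        zc = z - z.mean()
        ratio = (zc @ y) / (zc @ x)
        assert est.beta_causal == pytest.approx(ratio, abs=1e-8)

    def test_consistency_under_confounding(self):
        """Confounder drives exposure and outcome, true effect 0: OLS is
        biased away from zero while the TSLS CI covers zero at ~95%."""
        rng = np.random.default_rng(3)
        cover, ols_bias = 0, []
        reps, n = 60, 1500
        for _ in range(reps):
            z = rng.integers(0, 3, n).astype(float)
            u = rng.normal(0, 1, n)
            x = 0.4 * z + u + rng.normal(0, 1, n)
            y = u + rng.normal(0, 1, n)  # no causal x -> y path
            df = pd.DataFrame({"z": z, "x": x, "y": y})
            est = TwoStageLeastSquares(exposure="x", outcome="y", instrument="z",
                                       covariates=()).fit(df)
            lo = est.beta_causal_ - 1.96 * est.se_
            hi = est.beta_causal_ + 1.96 * est.se_
            cover += lo <= 0.0 <= hi
            xc = x - x.mean()
            ols_bias.append((xc @ y) / (xc @ xc))
        assert cover / reps >= 0.85
        assert np.mean(ols_bias) > 0.2  # OLS inherits the confounder

    def test_weak_instrument_warns(self):
        rng = np.random.default_rng(4)
        n = 300
        df = pd.DataFrame(
            {
                "z": rng.normal(0, 1, n),
                "x": rng.normal(0, 1, n),  # instrument irrelevant
                "y": rng.normal(0, 1, n),
            }
        )
        with pytest.warns(WeakInstrumentWarning):
            TwoStageLeastSquares(exposure="x", outcome="y", instrument="z",
                                 covariates=()).fit(df)

    def test_first_stage_f_reported_strong(self, default_cohort):
        cohort, truth = default_cohort
        est_struct = tsls_from_cohort(cohort, truth)
        assert est_struct.method == "tsls"
        fitted = TwoStageLeastSquares().fit(
            cohort.assign(
                grs=build_grs(
                    cohort[truth["snp_id"]],
                    InstrumentSet(
                        snp_ids=truth["snp_id"].tolist(),
                        grs_weights={s: 1 for s in truth["snp_id"]},
                    ),
                )
            )
        )
        assert fitted.first_stage_f_ > 10


class TestEgger:
    def test_proportional_effects_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.15, 0.08])
        by = -3.0 * bx
        intercept, _, _ = egger_test(bx, by, np.full(5, 0.1))
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_constrained_intercept_reproduces_ivw_slope(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.25, 20)
        se = rng.uniform(0.1, 0.4, 20)
        by = -2.0 * bx + rng.normal(0, se)
        est = EggerRegression(fit_intercept=False).fit(bx, by, se)
        w = 1.0 / se**2
        ivw_slope = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert est.slope_ == pytest.approx(ivw_slope, rel=1e-10)

    def test_fewer_than_three_instruments_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger_test(np.array([0.1, 0.2]), np.array([0.1, 0.2]), np.array([0.1, 0.1]))

    def test_detects_directional_pleiotropy(self):
        """A constant +0.3 added to every outcome effect is detected as a
        non-zero intercept in the large majority of replicates."""
        rng = np.random.default_rng(6)
        hits, reps = 0, 100
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.25, 83)
            se = rng.uniform(0.2, 0.4, 83)
            by = -2.0 * bx + 0.3 + rng.normal(0, se)
            est = EggerRegression().fit(bx, by, se)
            hits += (est.intercept_p_ < 0.05) and (abs(est.intercept_ - 0.3) < 0.3)
        assert hits / reps > 0.8

    def test_null_intercept_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            bx = rng.uniform(0.05, 0.25, 83)
            se = rng.uniform(0.2, 0.4, 83)
            by = -2.0 * bx + rng.normal(0, se)
            pvals.append(EggerRegression().fit(bx, by, se).intercept_p_)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestInstrumentScan:
    def test_bonferroni_threshold_for_array_scale_scan(self, default_cohort):
        cohort, _ = default_cohort
        _, threshold = instrument_scan(
            cohort, "amy1_activity", n_tests=124571,
            snp_columns=[c for c in cohort.columns if c.startswith("snp_")][:5],
        )
        assert threshold == pytest.approx(0.05 / 124571, rel=1e-12)
        assert f"{threshold:.0e}" == "4e-07"

    def test_familywise_error_controlled_under_null(self):
        total_hits = 0
        for s in range(8):
            cohort = generate_cohort(
                SimulationConfig(n_individuals=400, n_snps=200,
                                 causal_scenario="null", seed=4000 + s)
            )
            kept, _ = instrument_scan(cohort, "amy1_activity")
            total_hits += len(kept)
        assert total_hits <= 2

    def test_injected_activity_snp_always_retained(self):
        """A SNP explaining ~5% of activity variance is retained by the
        Bonferroni scan in every replicate."""
        for s in range(8):
            cohort = generate_cohort(
                SimulationConfig(
                    n_individuals=3600, causal_scenario="null",
                    activity_snp_index=0, activity_snp_beta=12.0, seed=4100 + s,
                )
            )
            kept, _ = instrument_scan(cohort, "amy1_activity")
            assert "snp_001" in set(kept["snp_id"])

    def test_scan_matches_per_snp_ols(self, default_cohort):
        import statsmodels.api as sm
        from amylasekit._design import build_design

        cohort, truth = default_cohort
        snp = truth["snp_id"].iloc[3]
        res = snp_scan(cohort, "amy1_activity", [snp]).iloc[0]
        X = build_design(cohort, [snp, "age", "sex", "bmi", "pc1", "pc2"])
        fit = sm.OLS(cohort["amy1_activity"].to_numpy(), X).fit()
        assert res["beta"] == pytest.approx(fit.params[snp], rel=1e-10)
        assert res["se"] == pytest.approx(fit.bse[snp], rel=1e-10)
        assert res["p"] == pytest.approx(fit.pvalues[snp], rel=1e-8)


class TestResidualAssociationCheck:
    def test_full_mediation_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(8)
        rejections, reps = 0, 40
        for _ in range(reps):
            n = 2000
            g = rng.integers(0, 3, n).astype(float)
            act = 5.0 * g + rng.normal(0, 10, n)
            bmi = -0.1 * act + rng.normal(0, 3, n)  # candidate's only path
            df = pd.DataFrame(
                {"g": g, "act": act, "bmi": bmi,
                 "age": rng.normal(50, 8, n), "sex": rng.integers(0, 2, n),
                 "pc1": rng.normal(0, 1, n), "pc2": rng.normal(0, 1, n)}
            )
            rejections += residual_association_check(df, "g", "bmi", "act") <= 0.05
        assert rejections / reps <= 0.2

    def test_direct_path_detected(self):
        rng = np.random.default_rng(9)
        rejections, reps = 0, 40
        for _ in range(reps):
            n = 4000
            g = rng.integers(0, 3, n).astype(float)
            act = 5.0 * g + rng.normal(0, 10, n)
            bmi = -0.1 * act + 0.3 * g + rng.normal(0, 3, n)  # pleiotropic path
            df = pd.DataFrame(
                {"g": g, "act": act, "bmi": bmi,
                 "age": rng.normal(50, 8, n), "sex": rng.integers(0, 2, n),
                 "pc1": rng.normal(0, 1, n), "pc2": rng.normal(0, 1, n)}
            )
            rejections += residual_association_check(df, "g", "bmi", "act") <= 0.05
        assert rejections / reps > 0.9

    def test_candidate_identical_to_adjustment_flagged(self):
        rng = np.random.default_rng(10)
        n = 200
        act = rng.normal(40, 10, n)
        df = pd.DataFrame(
            {"act": act, "dup": act, "bmi": rng.normal(25, 3, n),
             "age": rng.normal(50, 8, n), "sex": rng.integers(0, 2, n),
             "pc1": rng.normal(0, 1, n), "pc2": rng.normal(0, 1, n)}
        )
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            residual_association_check(df, "dup", "bmi", "act")


class TestNullCalibration:
    def test_ivw_and_tsls_pvalues_uniform_under_null(self):
        """Null-scenario cohorts: causal P values from both estimators are
        uniform across replicates (Kolmogorov-Smirnov)."""
        p_ivw, p_tsls = [], []
        for s in range(120):
            cfg = SimulationConfig(n_individuals=1500, causal_scenario="null",
                                   seed=5000 + s)
            cohort = generate_cohort(cfg)
            truth = generate_snp_truth(cfg)
            p_ivw.append(ivw_from_cohort(cohort, truth).p)
            p_tsls.append(tsls_from_cohort(cohort, truth).p)
        assert stats.kstest(p_ivw, "uniform").pvalue > 0.01
        assert stats.kstest(p_tsls, "uniform").pvalue > 0.01
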