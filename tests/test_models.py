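"""Parameter recovery, Box-Cox selection and backward elimination."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import fdslink as fl


# ------------------------------------------------------------ FDS : tier


class TestFdsTier:
    def test_interaction_or_recovery(self, diff_in_diff_fit):
        est = diff_in_diff_fit["estimates"].fds_tier["high_x_both_fds"]
        truth = diff_in_diff_fit["truth"]["fds_tier"]["high_x_both_fds"]
        # truth inside the robust CI and the point estimate near it
        assert est["ci_low"] < truth < est["ci_high"]
        assert abs(est["odds_ratio"] - truth) < 0.3

    def test_class_or_recovery(self, diff_in_diff_fit):
        est = diff_in_diff_fit["estimates"].fds_tier["class_is"]
        assert est["odds_ratio"] == pytest.approx(4.1, abs=0.5)
        assert est["ci_low"] < 4.1 < est["ci_high"]

    def test_or_probability_consistency(self, diff_in_diff_fit):
        """Applying the fitted interaction OR to the fitted baseline odds
        reproduces the model-predicted cell probability exactly."""
        ft = diff_in_diff_fit["estimates"].fds_tier
        eta = (
            ft["baseline_log_odds"]
            + np.log(ft["high"]["odds_ratio"])
            + np.log(ft["both_fds"]["odds_ratio"])
        )
        baseline = expit(eta)
        shifted = baseline + fl.net_probability_shift(
            ft["high_x_both_fds"]["odds_ratio"], baseline
        )
        direct = expit(eta + np.log(ft["high_x_both_fds"]["odds_ratio"]))
        assert shifted == pytest.approx(direct, abs=1e-12)

    def test_null_configuration_type_one_error(self):
        """Flat tier cells: interaction ORs center on 1 and the rejection
        rate at 0.05 stays at or below nominal (binomial upper bound)."""
        flat = {
            (g, p, c): 0.65
            for g in fl.config.GROUPS
            for p in fl.config.PERIODS
            for c in fl.config.CLASSES
        }
        from datetime import date

        log_ors, rejections, n_tests = [], 0, 0
        for rep in range(40):
            config = fl.SimulationConfig(
                n_pcps_per_group={"non": 40, "low": 20, "high": 20},
                patients_per_pcp=12,
                tier_probabilities=dict(flat),
                # later go-live balances the two post periods so every
                # cell is comfortably populated at this small n
                interruptive_start=date(2006, 2, 1),
                seed=900 + rep,
            )
            rng = np.random.default_rng(config.seed)
            pcps, patients = fl.generate_rosters(config, rng)
            claims = fl.generate_claims(config, pcps, patients, rng)
            cohort, _ = fl.build_cohort(
                claims, pcps, rng=rng, interruptive_start=config.interruptive_start
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ft = fl.fit_fds_tier(cohort).fds_tier
            for key in (
                "low_x_noninterruptive_only",
                "low_x_both_fds",
                "high_x_noninterruptive_only",
                "high_x_both_fds",
            ):
                log_ors.append(np.log(ft[key]["odds_ratio"]))
                rejections += ft[key]["p_value"] < 0.05
                n_tests += 1
        assert n_tests == 160
        # mean log OR ~ 0 (3 SE band of the empirical mean)
        mean = np.mean(log_ors)
        assert abs(mean) < 3 * np.std(log_ors) / np.sqrt(n_tests)
        # P(X > 16 | n=160, p=0.05) < 0.004
        assert rejections <= 16

    def test_pediatric_flag_adds_sensitivity_covariate(self, small_world):
        """Default model omits the pediatric indicator; the flag adds it
        (requiring a specialty column) without disturbing the keyed ORs."""
        cohort = small_world["cohort"]
        base = fl.fit_fds_tier(cohort)
        assert "pediatric" not in base.fds_tier
        with_flag = fl.fit_fds_tier(cohort, include_pediatric=True)
        assert "pediatric" in with_flag.fds_tier
        assert with_flag.fds_tier["pediatric"]["odds_ratio"] > 0
        with pytest.raises(KeyError, match="specialty"):
            fl.fit_fds_tier(cohort.drop(columns=["specialty"]), include_pediatric=True)

    def test_empty_cell_warns_and_fit_proceeds(self, small_world):
        cohort = small_world["cohort"]
        reduced = cohort[
            ~((cohort["group"] == "high") & (cohort["period"] == "both_fds"))
        ]
        with pytest.warns(UserWarning, match="high"):
            est = fl.fit_fds_tier(reduced)
        assert "high_x_both_fds" not in est.fds_tier
        assert "class_is" in est.fds_tier


# ------------------------------------------------------------- Box-Cox


class TestBoxcoxSelect:
    @staticmethod
    def _harness(true_lam, seed, n=4000, noise=0.05):
        rng = np.random.default_rng(seed)
        copay = np.exp(rng.normal(np.log(15), 0.6, n))
        t = np.log(copay) if true_lam == 0 else copay**true_lam
        t = (t - t.mean()) / t.std()
        y = 0.7 - 0.1 * t + rng.normal(0, noise, n)
        return copay, y

    @pytest.mark.parametrize("true_lam", [0.0, 0.25, 1.0])
    def test_recovers_generating_exponent(self, true_lam):
        copay, y = self._harness(true_lam, seed=17)
        assert fl.boxcox_select(copay, response=y) == true_lam

    def test_scale_equivariant_ranking(self):
        copay, y = self._harness(0.25, seed=23)
        assert fl.boxcox_select(copay, response=y) == fl.boxcox_select(
            copay * 37.5, response=y
        )

    def test_nonpositive_copay_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            fl.boxcox_select([0.0, 1.0, 2.0], response=[0.1, 0.2, 0.3])

    def test_profile_likelihood_mode_prefers_normalizing_transform(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(2.0, 0.5, 5000))  # log-normal: lambda 0 is best
        assert fl.boxcox_select(x) == 0.0


# ------------------------------------------------------- tier : copayment


class TestTierCopay:
    def test_cell_and_difference_recovery(self, adherence_fit):
        est = fl.fit_tier_copay(adherence_fit["records"])
        diff = est.tier_copay["tier_difference"]
        assert diff["ARB"]["estimate"] == pytest.approx(1.21, abs=0.10)
        assert diff["IS"]["estimate"] == pytest.approx(1.56, abs=0.20)
        assert est.tier_copay["cells"]["ARB_preferred"] == pytest.approx(
            10.60, abs=0.10
        )

    def test_zero_dispersion_exact(self):
        config = fl.SimulationConfig(copay_model=fl.CopayModel(log_sd=0.0), seed=2)
        rng = np.random.default_rng(2)
        records = fl.generate_adherence_records(config, 2000, 50, rng)
        est = fl.fit_tier_copay(records)
        for (cls, tier), center in fl.config.DEFAULT_COPAY_CENTERS.items():
            assert est.tier_copay["cells"][f"{cls}_{tier}"] == pytest.approx(
                center, abs=1e-8
            )

    def test_permutation_invariance(self, small_world):
        cohort = small_world["cohort"]
        a = fl.fit_tier_copay(cohort)
        b = fl.fit_tier_copay(cohort.sample(frac=1.0, random_state=1))
        assert a.tier_copay["cells"] == pytest.approx(b.tier_copay["cells"])

    def test_single_tier_falls_back_to_class_model(self, small_world):
        cohort = small_world["cohort"]
        only_pref = cohort[cohort["tier"] == "preferred"]
        with pytest.warns(UserWarning, match="single tier"):
            est = fl.fit_tier_copay(only_pref)
        assert est.tier_copay.get("single_tier") is True


# --------------------------------------------------- copayment : adherence


class TestCopayAdherence:
    def test_slope_and_offsets_recovery(self, adherence_fit):
        ca = adherence_fit["estimates"].copay_adherence
        truth = adherence_fit["truth"]["copay_adherence"]
        assert ca["copay_q_slope"]["estimate"] == pytest.approx(
            truth["copay_q_slope"], abs=0.01
        )
        assert ca["is_offset"]["estimate"] == pytest.approx(
            truth["is_offset"], abs=0.01
        )
        assert ca["income_45_75k"]["estimate"] == pytest.approx(0.06, abs=0.01)
        assert ca["income_ge_75k"]["estimate"] == pytest.approx(0.08, abs=0.01)
        assert ca["freq_gt_daily"]["estimate"] == pytest.approx(-0.04, abs=0.01)
        assert ca["pcp_var"] > 0

    def test_noiseless_limit_exact(self):
        config = fl.SimulationConfig(
            copay_model=fl.CopayModel(log_sd=0.3),
            adherence_model=fl.AdherenceModel(pcp_sd=0.0, residual_sd=0.0),
            seed=6,
        )
        rng = np.random.default_rng(6)
        # single prescriber: the degenerate-variance fit runs through the
        # fixed-effects route, which is exact on noiseless data
        records = fl.generate_adherence_records(config, 3000, 1, rng)
        # keep strictly interior rows: clipped means are not linear
        interior = records[(records["pdc"] > 0) & (records["pdc"] < 1)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ca = fl.fit_copay_adherence(interior, lam=0.25).copay_adherence
        assert ca["copay_q_slope"]["estimate"] == pytest.approx(-0.08, abs=1e-6)
        assert ca["is_offset"]["estimate"] == pytest.approx(-0.49, abs=1e-6)
        assert ca["intercept"]["estimate"] == pytest.approx(0.8945, abs=1e-6)

    def test_single_prescriber_drops_random_effect(self):
        config = fl.SimulationConfig(seed=8)
        rng = np.random.default_rng(8)
        records = fl.generate_adherence_records(config, 500, 1, rng)
        with pytest.warns(UserWarning, match="random intercept"):
            ca = fl.fit_copay_adherence(records, lam=0.25).copay_adherence
        assert ca["pcp_var"] == 0.0


# --------------------------------------------------- backward elimination


class TestBackwardSelect:
    @staticmethod
    def _data(n=2000, seed=0):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = 1.0 + 0.8 * x1 + 0.5 * x2 + rng.normal(0, 1.0, n)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "junk": noise})

    def test_noise_covariate_eliminated_protected_kept(self):
        data = self._data()
        spec = fl.ModelSpec(
            response="y", terms=["x1", "x2", "junk"], protected={"x1"}, kind="ols"
        )
        reduced, result = fl.backward_select(spec, data)
        assert "junk" not in reduced.terms
        assert "x1" in reduced.terms and "x2" in reduced.terms

    def test_all_significant_unchanged(self):
        data = self._data()
        spec = fl.ModelSpec(response="y", terms=["x1", "x2"], kind="ols")
        reduced, _ = fl.backward_select(spec, data)
        assert reduced.terms == ["x1", "x2"]

    def test_alpha_one_without_criterion_removes_everything(self):
        data = self._data()
        spec = fl.ModelSpec(response="y", terms=["x1", "x2", "junk"], kind="ols")
        reduced, _ = fl.backward_select(
            spec, data, alpha=1.0, criterion_check=False
        )
        assert reduced.terms == []

    def test_mixed_model_aic_route(self, adherence_fit):
        records = adherence_fit["records"].sample(4000, random_state=0).copy()
        records["copay_q"] = records["monthly_copayment"] ** 0.25
        records["is_class"] = (records["med_class"] == "IS").astype(float)
        records["freq_gt_daily"] = (records["doses_per_day"] > 1).astype(float)
        rng = np.random.default_rng(1)
        records["junk"] = rng.normal(size=len(records))
        spec = fl.ModelSpec(
            response="pdc",
            terms=["copay_q", "is_class", "C(income, Treatment('<45k'))",
                   "freq_gt_daily", "junk"],
            protected={"copay_q"},
            kind="mixedlm",
            groups="pcp_id",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reduced, _ = fl.backward_select(spec, records)
        assert "junk" not in reduced.terms
        assert "copay_q" in reduced.terms
        assert "is_class" in reduced.terms


# ------------------------------------------------------- unadjusted table


class TestSummarizeUnadjusted:
    def test_all_preferred_input(self):
        df = pd.DataFrame(
            {
                "tier": ["preferred"] * 4,
                "group": ["non", "non", "high", "high"],
                "period": ["pre", "both_fds", "pre", "both_fds"],
            }
        )
        table = fl.summarize_unadjusted(df)
        pct = table["percent_preferred"]
        assert (pct.fillna(100.0) == 100.0).all().all()

    def test_single_claim_other_cells_undefined(self):
        df = pd.DataFrame(
            {"tier": ["preferred"], "group": ["high"], "period": ["both_fds"]}
        )
        table = fl.summarize_unadjusted(df)
        assert table.loc["high", ("percent_preferred", "both_fds")] == 100.0
        assert np.isnan(table.loc["high", ("percent_preferred", "pre")])
        assert table.loc["high", ("n", "pre")] == 0

    def test_calibrated_cells_match_targets(self, calibrated_cohort):
        """Cell frequencies converge to the configured probabilities at a
        standard-error-scaled tolerance."""
        table = fl.summarize_unadjusted(calibrated_cohort["cohort"])
        for (g, p), target in fl.config.POOLED_PREFERRED_SHARE.items():
            n = table.loc[g, ("n", p)]
            se = np.sqrt(target * (1 - target) / n)
            tol = max(100 * 3.5 * se, 0.25)
            assert table.loc[g, ("percent_preferred", p)] == pytest.approx(
                100 * target, abs=tol
            )
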