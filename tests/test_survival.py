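"""Concordance, threshold search, Kaplan-Meier, Cox and covariate encoding."""

import numpy as np
import pandas as pd
import pytest
from _oracles import brute_force_cindex, grid_search_cox_binary

from ncetseg import (
    correlate_ratios,
    cox_fit,
    encode_covariates,
    generate_survival_cohort,
    harrell_cindex,
    kaplan_meier,
    optimal_threshold,
    stratify,
)
from ncetseg.phantom import SurvivalSimConfig
from ncetseg.survival import TIERS, validate_cohort


class TestHarrellCindex:
    def test_constant_risk_gives_half(self):
        t = np.arange(1.0, 11.0)
        assert harrell_cindex(np.ones(10), t, np.ones(10)) == 0.5

    def test_perfectly_anti_ordered_risk_gives_one(self):
        t = np.arange(1.0, 11.0)
        risk = -t  # higher risk, shorter survival
        assert harrell_cindex(risk, t, np.ones(10)) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        risk = rng.choice([0.0, 0.5, 1.0], n)  # include risk ties
        t = rng.exponential(100, n)
        e = rng.random(n) < 0.7
        e[0] = True
        assert harrell_cindex(risk, t, e) == brute_force_cindex(risk, t, e)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(9)
        risk = rng.normal(size=80)
        t = rng.exponential(100, 80)
        e = rng.random(80) < 0.6
        e[0] = True
        # lifelines orders by predicted survival time: negate the risk
        assert harrell_cindex(risk, t, e) == pytest.approx(
            concordance_index(t, -risk, e), abs=1e-12
        )

    def test_orientation_flip(self):
        rng = np.random.default_rng(3)
        risk = rng.integers(0, 2, 40).astype(float)
        t = rng.exponential(10, 40)
        e = np.ones(40, dtype=int)
        c = harrell_cindex(risk, t, e)
        c_flip = harrell_cindex(1 - risk, t, e)
        assert c + c_flip == pytest.approx(1.0, abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            harrell_cindex([1.0, 2.0], [1.0, 2.0], [0, 0])


class TestOptimalThreshold:
    def test_two_point_case(self):
        th, c = optimal_threshold([0.2, 0.8], [100.0, 30.0], [1, 1])
        # the earlier death carries the higher TFHI: perfect split at 0.5
        assert th == pytest.approx(0.5)
        assert c == 1.0

    def test_identical_to_exhaustive_enumeration(self):
        df = generate_survival_cohort(SurvivalSimConfig(n_patients=120, seed=5))
        tfhi = df["tfhi"].to_numpy()
        t = df["os_days"].to_numpy()
        e = df["event"].to_numpy()
        th, c = optimal_threshold(tfhi, t, e)
        uniq = np.unique(tfhi)
        cands = (uniq[:-1] + uniq[1:]) / 2
        cs = np.array([harrell_cindex((tfhi > x).astype(float), t, e) for x in cands])
        assert c == cs.max()
        assert th == cands[np.argmax(cs)]  # smallest-threshold tie-break

    def test_null_cohort_concordance_near_half(self):
        df = generate_survival_cohort(
            SurvivalSimConfig(n_patients=400, hazard_ratio=1.0, seed=6)
        )
        _, c = optimal_threshold(df["tfhi"], df["os_days"], df["event"])
        # optimized over many cutoffs, so biased above 0.5 by O(n^-1/2)
        assert 0.5 <= c <= 0.5 + 5 / np.sqrt(len(df))

    def test_all_equal_tfhi_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            optimal_threshold([0.5, 0.5, 0.5], [1.0, 2.0, 3.0], [1, 1, 1])


class TestKaplanMeier:
    def test_hand_product_limit_no_censoring(self):
        curve = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        lookup = dict(zip(curve.times, curve.survival))
        assert lookup[1.0] == pytest.approx(0.75)
        assert lookup[2.0] == pytest.approx(0.5)
        assert lookup[3.0] == pytest.approx(0.25)
        assert lookup[4.0] == pytest.approx(0.0)
        assert curve.median() == 2.0

    def test_all_censored_has_undefined_median(self):
        curve = kaplan_meier([5.0, 6.0, 7.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert curve.median() is None

    def test_censoring_reduces_risk_set_hand_example(self):
        # deaths at 1 and 3, censored at 2: S(3) = (3/4)*(1/2)
        curve = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        lookup = dict(zip(curve.times, curve.survival))
        assert lookup[3.0] == pytest.approx(0.375)


class TestCoxFit:
    def test_single_binary_covariate_matches_grid_search_oracle(self):
        rng = np.random.default_rng(10)
        n = 300
        g = rng.integers(0, 2, n)
        lam = 0.01 * np.where(g == 1, 2.0, 1.0)
        t = rng.exponential(1 / lam)
        e = np.ones(n, dtype=int)
        res = cox_fit(pd.DataFrame({"g": g.astype(float)}), t, e)
        beta_ref = grid_search_cox_binary(g, t, e)
        assert res.coefficients["g"] == pytest.approx(beta_ref, abs=1e-3)
        assert res.hazard_ratios["g"] == pytest.approx(np.exp(res.coefficients["g"]), rel=1e-9)

    def test_null_covariate_has_small_effect(self):
        rng = np.random.default_rng(11)
        n = 500
        t = rng.exponential(400, n)
        e = np.ones(n, dtype=int)
        x = rng.normal(size=n)  # independent of survival
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert abs(res.coefficients["x"]) < 0.2
        assert res.wald_p["x"] > 0.001

    def test_sign_consistent_with_km_ordering(self):
        df = generate_survival_cohort(SurvivalSimConfig(n_patients=400, seed=12))
        high = (df["tfhi"] > 0.7).astype(float)
        res = cox_fit(pd.DataFrame({"high": high}), df["os_days"], df["event"])
        km_high = kaplan_meier(df.loc[high == 1, "os_days"], df.loc[high == 1, "event"])
        km_low = kaplan_meier(df.loc[high == 0, "os_days"], df.loc[high == 0, "event"])
        # positive coefficient <=> the high group's curve lies below
        t_common = 400.0
        s_high = km_high.survival[km_high.times <= t_common][-1]
        s_low = km_low.survival[km_low.times <= t_common][-1]
        assert (res.coefficients["high"] > 0) == (s_high < s_low)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit(pd.DataFrame({"x": [0.0, 1.0]}), [1.0, 2.0], [0, 0])


class TestEncodeCovariates:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {
                "os_days": [100.0, 200.0, 300.0, 400.0],
                "event": [1, 1, 0, 1],
                "tfhi": [0.2, 0.4, 0.6, 0.8],
                "age": [40.0, 60.0, 80.0, 50.0],
                "gender": [0.0, 1.0, 0.0, 1.0],
                "mgmt": [0.0, 0.0, 1.0, np.nan],
                "edema_volume": [1e4, 2e4, 3e4, 4e4],
                "rcbv_p90_ncet": [1.0, 2.0, 3.0, 4.0],
            }
        )

    def test_prevalence_imputation_prefers_modal_category(self):
        design = encode_covariates(self._table(), tier="clinical", include_tfhi=False)
        assert design.loc[3, "mgmt"] == 0.0  # methylated (0) is the more prevalent

    def test_minmax_scaling_of_continuous_columns(self):
        t = self._table()
        design = encode_covariates(t, tier="clinical", include_tfhi=False)
        assert list(design["age"]) == pytest.approx([0.0, 0.5, 1.0, 0.25])
        assert set(design["gender"]) <= {0.0, 1.0}  # binary columns untouched

    def test_full_tier_reproduces_six_covariate_structure(self):
        design = encode_covariates(self._table(), tier="full", include_tfhi=True)
        assert list(design.columns) == [
            "age",
            "gender",
            "mgmt",
            "rcbv_p90_ncet",
            "edema_volume",
            "tfhi",
        ]
        # everything encoded into [0, 1]
        assert design.to_numpy().min() >= 0.0 and design.to_numpy().max() <= 1.0

    def test_proportional_imputation_is_seeded(self):
        t = self._table()
        a = encode_covariates(t, tier="clinical", impute="proportional", seed=3)
        b = encode_covariates(t, tier="clinical", impute="proportional", seed=3)
        assert a.equals(b)

    def test_all_missing_mgmt_rejected(self):
        t = self._table()
        t["mgmt"] = np.nan
        with pytest.raises(ValueError, match="MGMT"):
            encode_covariates(t, tier="clinical")

    def test_missing_column_for_tier_rejected(self):
        t = self._table().drop(columns=["rcbv_p90_ncet"])
        with pytest.raises(ValueError, match="rcbv_p90_ncet"):
            encode_covariates(t, tier="full")

    def test_tier_ordering_perfusion_before_volumetry(self):
        assert TIERS["clinical+perfusion"] == ["age", "gender", "mgmt", "rcbv_p90_ncet"]
        assert "edema_volume" in TIERS["clinical+perfusion+volumetric"]


class TestStratifyAndCorrelation:
    def test_stratify_reports_consistent_groups_and_ci(self):
        df = generate_survival_cohort(SurvivalSimConfig(n_patients=300, seed=13))
        res = stratify(df)
        assert res.n_high + res.n_low == len(df)
        assert res.ci95[0] <= res.hazard_ratio <= res.ci95[1]
        assert 0.0 <= res.c_index <= 1.0
        assert res.delta_os_days == abs(res.median_high - res.median_low)

    def test_stratify_refuses_zero_event_cohort(self):
        df = generate_survival_cohort(SurvivalSimConfig(n_patients=50, seed=14))
        df["event"] = 0
        with pytest.raises(ValueError, match="zero events"):
            stratify(df)

    def test_pearson_identities(self):
        x = np.linspace(0, 1, 20)
        assert correlate_ratios(x, x) == pytest.approx(1.0)
        assert correlate_ratios(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        rng = np.random.default_rng(15)
        x = rng.random(100)
        y = 0.5 * x + rng.normal(0, 0.1, 100)
        r = correlate_ratios(x, y)
        ref = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_ratios([0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_cohort_validation_catches_bad_rows(self):
        df = generate_survival_cohort(SurvivalSimConfig(n_patients=20, seed=16))
        bad = df.copy()
        bad.loc[0, "os_days"] = 0.0
        with pytest.raises(ValueError, match="os_days"):
            validate_cohort(bad)
        bad = df.copy()
        bad.loc[0, "tfhi"] = 1.5
        with pytest.raises(ValueError, match="tfhi"):
            validate_cohort(bad)
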