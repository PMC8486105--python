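"""ANOVA decomposition, variance components, heritability, BLUP, t-test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootpue.synthetic_trial import TraitSpec, TrialConfig, generate_trial
from rootpue.trait_io import PanelError
from rootpue.variance_blup import (
    AnovaResult,
    anova_table,
    anova_two_way,
    blup_means,
    cv_percent,
    regime_t_test,
    variance_components,
)
from conftest import long_panel


def brute_force_ss(panel, trait):
    """Sums of squares by direct enumeration over observations."""
    sub = panel[panel["trait"] == trait]
    grand = sub["value"].mean()
    gm = sub.groupby("genotype")["value"].mean()
    pm = sub.groupby("regime")["value"].mean()
    cm = sub.groupby(["genotype", "regime"])["value"].mean()
    ss = dict.fromkeys(("G", "P", "GxP", "error", "total"), 0.0)
    for _, row in sub.iterrows():
        g, p, y = row["genotype"], row["regime"], row["value"]
        ss["G"] += (gm[g] - grand) ** 2
        ss["P"] += (pm[p] - grand) ** 2
        ss["GxP"] += (cm[(g, p)] - gm[g] - pm[p] + grand) ** 2
        ss["error"] += (y - cm[(g, p)]) ** 2
        ss["total"] += (y - grand) ** 2
    return ss


def toy_2x2x2():
    vals = [3.0, 5.0, 10.0, 12.0, 4.0, 8.0, 9.0, 17.0]
    rows = [
        (g, r, rep, "TRL", v)
        for (g, r, rep), v in zip(
            itertools.product(["A", "B"], ["NLP", "LP"], [1, 2]), vals
        )
    ]
    return long_panel(rows)


class TestAnova:
    def test_toy_matches_brute_force(self):
        panel = toy_2x2x2()
        res = anova_two_way(panel, "TRL")
        want = brute_force_ss(panel, "TRL")
        for k, v in want.items():
            assert res.ss[k] == pytest.approx(v, rel=1e-12), k

    def test_matches_statsmodels(self, mini_panel):
        """Independent route: OLS + anova_lm on the same balanced layout."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        sub = mini_panel[mini_panel["trait"] == "TSA"]
        fit = smf.ols("value ~ C(genotype) * C(regime)", data=sub).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        res = anova_two_way(mini_panel, "TSA")
        assert res.ss["G"] == pytest.approx(table.loc["C(genotype)", "sum_sq"])
        assert res.ss["P"] == pytest.approx(table.loc["C(regime)", "sum_sq"])
        assert res.ss["GxP"] == pytest.approx(
            table.loc["C(genotype):C(regime)", "sum_sq"])
        assert res.ss["error"] == pytest.approx(table.loc["Residual", "sum_sq"])
        assert res.p["G"] == pytest.approx(table.loc["C(genotype)", "PR(>F)"])

    def test_constant_panel_reports_na(self):
        rows = [
            (g, r, rep, "TRL", 7.0)
            for g, r, rep in itertools.product(["A", "B"], ["NLP", "LP"], [1, 2])
        ]
        res = anova_two_way(long_panel(rows), "TRL")
        assert all(v == 0 for v in res.ss.values())
        assert np.isnan(res.f["G"]) and np.isnan(res.p["GxP"])

    def test_ss_additivity(self, mini_panel):
        for trait in ("PRL", "TRT", "RV2"):
            res = anova_two_way(mini_panel, trait)
            parts = res.ss["G"] + res.ss["P"] + res.ss["GxP"] + res.ss["error"]
            assert parts == pytest.approx(res.ss["total"], rel=1e-6)

    def test_unbalanced_rejected(self, mini_panel):
        broken = mini_panel.drop(index=mini_panel.index[0])
        with pytest.raises(PanelError, match="unbalanced"):
            anova_two_way(broken, mini_panel.iloc[0]["trait"])
        with pytest.raises(PanelError, match="balanced"):
            anova_table(broken)

    def test_dof_contract(self, mini_panel):
        res = anova_two_way(mini_panel, "TRF")
        g, p, r = 10, 2, 3
        assert res.df == {"G": g - 1, "P": p - 1, "GxP": (g - 1) * (p - 1),
                          "error": g * p * (r - 1),
                          "total": g * p * r - 1}


def fake_anova(ms_g, ms_gxp, ms_e, grand_mean=40.0, g=10, p=2, r=3):
    return AnovaResult(
        trait="X", grand_mean=grand_mean, n_genotypes=g, n_regimes=p,
        n_replicates=r, ss={}, df={},
        ms={"G": ms_g, "P": 0.0, "GxP": ms_gxp, "error": ms_e}, f={}, p={},
    )


class TestVarianceComponents:
    def test_all_ms_equal_gives_zero_h2(self):
        vc = variance_components(fake_anova(2.0, 2.0, 2.0))
        assert vc.var_g == vc.var_gp == 0.0
        assert vc.heritability == 0.0

    def test_pure_genotype_variance_gives_h2_of_one(self):
        vc = variance_components(fake_anova(60.0, 0.0, 0.0))
        assert vc.heritability == 1.0

    def test_negative_estimates_truncated_and_flagged(self):
        vc = variance_components(fake_anova(1.0, 5.0, 8.0))
        assert vc.var_g == 0.0 and vc.var_gp == 0.0
        assert set(vc.truncated) == {"var_g", "var_gp"}

    def test_expected_mean_squares_inversion(self):
        # MS built forward from known components must invert exactly
        var_g, var_gp, var_e, r, p = 4.0, 1.0, 1.0, 3, 2
        ms_e = var_e
        ms_gxp = var_e + r * var_gp
        ms_g = var_e + r * var_gp + p * r * var_g
        vc = variance_components(fake_anova(ms_g, ms_gxp, ms_e))
        assert vc.var_g == pytest.approx(var_g)
        assert vc.var_gp == pytest.approx(var_gp)
        assert vc.heritability == pytest.approx(4 / (4 + 0.5 + 1 / 6))

    def test_h2_scale_invariance(self, mini_panel):
        scaled = mini_panel.copy()
        scaled["value"] = scaled["value"] * 37.5
        a = variance_components(anova_two_way(mini_panel, "TRL"))
        b = variance_components(anova_two_way(scaled, "TRL"))
        assert a.heritability == pytest.approx(b.heritability, rel=1e-10)

    def test_bad_design_arguments(self):
        with pytest.raises(ValueError):
            variance_components(fake_anova(1, 1, 1), r=0)
        with pytest.raises(ValueError):
            variance_components(fake_anova(1, 1, 1), p=1)


class TestCv:
    def test_arithmetic(self):
        assert cv_percent(fake_anova(0, 0, 4.0, grand_mean=40.0)) == 5.0
        assert cv_percent(fake_anova(0, 0, 0.0)) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(fake_anova(0, 0, 1.0, grand_mean=0.0))

    def test_calibrated_simulation_recovers_cv(self):
        # var_e/mean^2 = 0.0036 -> CV 6%
        cfg = TrialConfig(
            n_genotypes=150, n_replicates=3,
            trait_specs={"TRL": TraitSpec(mean=100.0, var_g=0.0, var_gp=0.0,
                                          var_e=36.0)},
            seed=21,
        )
        panel, _ = generate_trial(cfg)
        assert cv_percent(anova_two_way(panel, "TRL")) == pytest.approx(6.0, abs=0.5)


class TestBlup:
    def test_toy_matches_hand_mixed_model_solution(self):
        # one-way layout: means 11, 15, 22; mu=16; var_e=2, var_g=30
        panel = long_panel([
            ("A", "NLP", 1, "TRL", 10.0), ("A", "NLP", 2, "TRL", 12.0),
            ("B", "NLP", 1, "TRL", 14.0), ("B", "NLP", 2, "TRL", 16.0),
            ("C", "NLP", 1, "TRL", 21.0), ("C", "NLP", 2, "TRL", 23.0),
        ])
        got = blup_means(panel, "TRL", "NLP")
        k = 30.0 / 31.0
        want = {"A": 16 + k * -5, "B": 16 + k * -1, "C": 16 + k * 6}
        for g, v in want.items():
            assert got[g] == pytest.approx(v, rel=1e-12)

    def test_shrinkage_monotone_in_genotype_variance(self):
        base = long_panel([
            ("A", "NLP", 1, "TRL", 10.0), ("A", "NLP", 2, "TRL", 12.0),
            ("B", "NLP", 1, "TRL", 14.0), ("B", "NLP", 2, "TRL", 16.0),
        ])
        spread = base.copy()
        spread.loc[spread["genotype"] == "B", "value"] += 20.0
        k1 = abs(blup_means(base, "TRL", "NLP")["A"] - 13.0) / abs(11.0 - 13.0)
        mu2 = spread.loc[:, "value"].mean()
        got2 = blup_means(spread, "TRL", "NLP")
        k2 = abs(got2["A"] - mu2) / abs(11.0 - mu2)
        assert k2 > k1  # larger between-genotype spread shrinks less

    def test_identical_genotype_means_full_shrinkage(self):
        panel = long_panel([
            ("A", "NLP", 1, "TRL", 9.0), ("A", "NLP", 2, "TRL", 11.0),
            ("B", "NLP", 1, "TRL", 11.0), ("B", "NLP", 2, "TRL", 9.0),
        ])
        got = blup_means(panel, "TRL", "NLP")
        assert np.allclose(got, 10.0)


class TestRegimeTTest:
    def summary_frame(self, a, b, trait="TRL"):
        rows = [("G%d" % i, "NLP", trait, v) for i, v in enumerate(a)]
        rows += [("G%d" % i, "LP", trait, v) for i, v in enumerate(b)]
        return pd.DataFrame(rows, columns=["genotype", "regime", "trait", "value"])

    def test_identical_sets(self):
        s = self.summary_frame([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert regime_t_test(s, "TRL") == (0.0, 1.0)

    def test_textbook_welch(self):
        # means 2 vs 5, s^2=1, n=3: t = -3/sqrt(2/3), df = 4
        s = self.summary_frame([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        t, p = regime_t_test(s, "TRL")
        t_hand = -3.0 / np.sqrt(2.0 / 3.0)
        # LP sorts before NLP, so LP - ... direction: LP mean 2, NLP mean 5
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4), rel=1e-9)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, size=40)
        b = rng.normal(5.0, 1.0, size=40)  # 5 SD shift
        s = self.summary_frame(a, b)
        _, p = regime_t_test(s, "TRL")
        assert p < 1e-6

    def test_single_value_regime_rejected(self):
        s = self.summary_frame([1.0, 2.0], [3.0])
        with pytest.raises(ValueError):
            regime_t_test(s, "TRL")
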