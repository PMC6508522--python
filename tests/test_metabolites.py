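"""Metabolite contrast statistics: t tests, Tukey, ANOVA, heterosis calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import metab_frame
from nightcontrast import metabolites as M
from nightcontrast.metabolites import HeterosisCall
from nightcontrast.simulate import SimConfig, simulate_metabolome


def call(metabolite="m", cls="other", mid=10.0, f1=8.0, p_mid=0.5,
         trans="none", p_trans=float("nan"), ratio=float("nan"), parent="both"):
    return HeterosisCall(
        metabolite=metabolite, compound_class=cls, mid_parent=mid, f1_mean=f1,
        below_mid_parent=f1 < mid, p_mid_parent=p_mid, transgressive=trans,
        p_transgressive=p_trans, ratio=ratio, parent_detected=parent,
    )


class TestPerExperimentTTest:
    def test_equal_samples_give_p_one(self):
        rec = metab_frame([("m", "other", 1, "SH", [10, 12, 9, 11]),
                           ("m", "other", 1, "YK", [10, 12, 9, 11])])
        res = M.per_experiment_ttest(rec, "m", 1)
        assert res.pvalue == pytest.approx(1.0)

    def test_closed_form_strong_shift(self):
        rec = metab_frame([("m", "other", 1, "SH", [10, 10, 10, 10]),
                           ("m", "other", 1, "YK", [20, 20, 20, 21])])
        res = M.per_experiment_ttest(rec, "m", 1)
        assert res.pvalue < 1e-3
        # closed-form pooled t oracle
        t_oracle, p_oracle = stats.ttest_ind([10, 10, 10, 10], [20, 20, 20, 21])
        assert res.statistic == pytest.approx(float(t_oracle))
        assert res.pvalue == pytest.approx(float(p_oracle))

    def test_zero_variance_unequal_means_flagged_untestable(self):
        rec = metab_frame([("m", "other", 1, "SH", [0, 0, 0, 0]),
                           ("m", "other", 1, "YK", [5, 5, 5, 5])])
        res = M.per_experiment_ttest(rec, "m", 1)
        assert not res.testable

    def test_label_swap_preserves_pvalue(self):
        rng = np.random.default_rng(7)
        sh, yk = rng.normal(10, 2, 4), rng.normal(13, 2, 4)
        rec = metab_frame([("m", "other", 1, "SH", sh), ("m", "other", 1, "YK", yk)])
        swapped = metab_frame([("m", "other", 1, "SH", yk), ("m", "other", 1, "YK", sh)])
        a = M.per_experiment_ttest(rec, "m", 1)
        b = M.per_experiment_ttest(swapped, "m", 1)
        assert a.pvalue == pytest.approx(b.pvalue)
        assert a.statistic == pytest.approx(-b.statistic)

    def test_type_one_error_rate_controlled(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(10000, 4))
        y = rng.normal(size=(10000, 4))
        _, p = M.two_sample_ttest(x, y, axis=1)
        rate = (p <= 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestTukey:
    def test_identical_genotypes_all_p_one(self):
        rec = metab_frame([("m", "other", 2, g, [5.0, 5.0, 5.0]) for g in ("SH", "YK", "F1")])
        assert all(p == 1.0 for p in M.tukey_hsd_genotypes(rec, "m").values())

    def test_shifted_genotype_flagged_in_both_of_its_comparisons(self):
        rng = np.random.default_rng(13)
        base = rng.normal(10, 1, 3)
        rec = metab_frame([
            ("m", "other", 2, "SH", base),
            ("m", "other", 2, "YK", base + rng.normal(0, 1, 3) * 0.1),
            ("m", "other", 2, "F1", base + 30),
        ])
        p = M.tukey_hsd_genotypes(rec, "m")
        assert p[("SH", "F1")] < 0.01 and p[("YK", "F1")] < 0.01
        assert p[("SH", "YK")] > 0.1

    def test_studentized_range_boundary_case(self):
        """k=3 groups, df=6: critical q at alpha=.05 is 4.34, so a mean
        difference of q*sqrt(MSE/n) sits right at p ~ .05."""
        spread = np.array([-1.0, 0.0, 1.0])  # group SD 1, MSE 1 with ddof pooling
        diff = 4.34 * np.sqrt(1.0 / 3)
        rec = metab_frame([
            ("m", "other", 2, "SH", spread),
            ("m", "other", 2, "YK", spread),
            ("m", "other", 2, "F1", spread + diff),
        ])
        p = M.tukey_hsd_genotypes(rec, "m")[("SH", "F1")]
        assert p == pytest.approx(0.05, abs=0.005)


class TestAdditiveAnova:
    def test_matches_statsmodels_two_way_fit(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(17)
        for _ in range(50):
            n1, n2 = rng.integers(3, 6), rng.integers(2, 5)
            rows = []
            for e, n in ((1, n1), (2, n2)):
                for g in ("SH", "YK"):
                    shift = rng.normal(0, 2)
                    rows.append(("m", "other", e, g, rng.normal(10 + shift, 1, n)))
            rec = metab_frame(rows)
            p_g, p_e = M.nested_anova(rec, "m")
            df = rec.rename(columns={"value": "y"})
            fit = smf.ols("y ~ C(genotype) + C(experiment)", df).fit()
            an = sm.stats.anova_lm(fit, typ=2)
            assert p_g == pytest.approx(an["PR(>F)"]["C(genotype)"], abs=1e-10)
            assert p_e == pytest.approx(an["PR(>F)"]["C(experiment)"], abs=1e-10)

    def test_pure_genotype_shift_detected(self):
        rng = np.random.default_rng(19)
        rec = metab_frame([
            ("m", "other", 1, "SH", rng.normal(10, 0.1, 4)),
            ("m", "other", 1, "YK", rng.normal(20, 0.1, 4)),
            ("m", "other", 2, "SH", rng.normal(10, 0.1, 3)),
            ("m", "other", 2, "YK", rng.normal(20, 0.1, 3)),
        ])
        p_g, p_e = M.nested_anova(rec, "m")
        assert p_g < 1e-3 and p_e > 0.05

    def test_type_one_error_with_large_experiment_shift(self):
        """Genotype effect zero, strong experiment effect: genotype
        rejections stay at the nominal rate."""
        rng = np.random.default_rng(23)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1])
        e = np.array([0] * 8 + [1] * 6)
        reps = 10000
        y = rng.normal(size=(reps, 14)) + 5.0 * e
        p_g, _ = M.anova_additive(y, g, e)
        rate = (p_g <= 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestMidParent:
    def test_f1_exactly_at_mid_parent(self):
        rec = metab_frame([
            ("m", "other", 2, "SH", [10, 10, 10]),
            ("m", "other", 2, "YK", [20, 20, 20]),
            ("m", "other", 2, "F1", [15, 15, 15]),
        ])
        mid, f1_mean, below, t, p = M.mid_parent_test(rec, "m")
        assert (mid, f1_mean, below) == (15.0, 15.0, False)
        assert (t, p) == (0.0, 1.0)

    def test_closed_form_below_mid_parent(self):
        rec = metab_frame([
            ("m", "other", 2, "SH", [10, 10, 10]),
            ("m", "other", 2, "YK", [20, 20, 20]),
            ("m", "other", 2, "F1", [12.0, 12.1, 11.9]),
        ])
        mid, f1_mean, below, t, p = M.mid_parent_test(rec, "m")
        assert below and p < 1e-3
        t_oracle, p_oracle = stats.ttest_1samp([12.0, 12.1, 11.9], 15.0)
        assert t == pytest.approx(float(t_oracle)) and p == pytest.approx(float(p_oracle))

    def test_type_one_error_under_additivity(self):
        rng = np.random.default_rng(29)
        f1 = rng.normal(0.0, 1.0, size=(10000, 3))
        _, p = M.one_sample_ttest(f1, 0.0, axis=1)
        rate = (p <= 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestTransgressive:
    def test_f1_between_parents_is_none(self):
        rec = metab_frame([
            ("m", "other", 2, "SH", [10, 11, 9]),
            ("m", "other", 2, "YK", [20, 21, 19]),
            ("m", "other", 2, "F1", [15, 16, 14]),
        ])
        label, _, _, detected = M.transgressive_classify(rec, "m")
        assert label == "none" and detected == "both"

    def test_strong_downward_transgression(self):
        rec = metab_frame([
            ("m", "other", 2, "SH", [10.0, 10.1, 9.9]),
            ("m", "other", 2, "YK", [20.0, 20.1, 19.9]),
            ("m", "other", 2, "F1", [5.0, 5.1, 4.9]),
        ])
        label, p, ratio, _ = M.transgressive_classify(rec, "m")
        assert label == "low" and p < 0.001
        assert ratio == pytest.approx(10.0 / 5.0, rel=1e-3)

    def test_planted_transgressive_down_recovered(self):
        cfg = SimConfig(seed=37, n_metabolites=60, heterosis_mix=(0.0, 0.0, 0.0, 1.0),
                        transgressive_margin=0.5, cv_metab=0.1, parent_absent_fraction=0.0)
        rec, truth = simulate_metabolome(cfg)
        hits = sum(
            M.transgressive_classify(rec, met)[0] == "low" for met in truth.metab_class
        )
        assert hits / len(truth.metab_class) >= 0.9


class TestDirectionBinomial:
    def test_symmetric_counts_p_one(self):
        calls = [call(metabolite=f"m{i}", trans="low") for i in range(12)] + [
            call(metabolite=f"h{i}", trans="high", f1=12.0) for i in range(12)
        ]
        assert M.direction_binomial(calls)[2] == pytest.approx(1.0)

    def test_all_negative_closed_form(self):
        calls = [call(metabolite=f"m{i}", trans="low") for i in range(24)]
        n_low, n_high, p = M.direction_binomial(calls)
        assert (n_low, n_high) == (24, 0)
        assert p == pytest.approx(2 * 0.5**24, rel=1e-9)

    def test_twenty_four_split_matches_exact_binomial_sum(self):
        calls = [call(metabolite=f"m{i}", trans="low") for i in range(20)] + [
            call(metabolite=f"h{i}", trans="high", f1=12.0) for i in range(4)
        ]
        _, _, p = M.direction_binomial(calls)
        tail = sum(stats.binom.pmf(k, 24, 0.5) for k in range(20, 25))
        assert p == pytest.approx(2 * tail, rel=1e-9)

    def test_single_parent_metabolites_excluded(self):
        calls = [call(metabolite="a", trans="low"),
                 call(metabolite="b", trans="low", parent="one")]
        n_low, n_high, _ = M.direction_binomial(calls)
        assert (n_low, n_high) == (1, 0)


class TestContingency:
    def test_independent_margins_chi2_zero(self):
        stat, p = M.chi2_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        stat, p = M.chi2_independence([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert p < 1e-9

    def test_matches_hand_formula_and_scipy_on_random_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            table = rng.integers(1, 40, size=(2, 2))
            stat, p = M.chi2_independence(table)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            stat_hand = ((table - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(stat_hand, rel=1e-12)
            s2, p2 = stats.chi2_contingency(table, correction=False)[:2]
            assert stat == pytest.approx(s2) and p == pytest.approx(p2)

    def test_heterosis_contingency_assembles_table(self):
        calls = [call(metabolite="a", trans="low"), call(metabolite="b"),
                 call(metabolite="c", trans="high", f1=12.0), call(metabolite="d")]
        parental = {"a": 0.01, "b": 0.01, "c": 0.5, "d": 0.5}
        res = M.heterosis_contingency(calls, parental)
        assert res.table.sum() == 4
        np.testing.assert_array_equal(res.table, [[1, 1], [1, 1]])
        assert res.test_used == "chi-squared"


class TestStarchProxy:
    def test_printed_means_give_published_ratio(self):
        means = pd.DataFrame(
            [
                ("Maltose", 1, "SH", 1119.8), ("Maltose", 1, "YK", 678.6),
                ("Maltose", 2, "SH", 1081.4), ("Maltose", 2, "YK", 846.2),
                ("Glucose", 1, "SH", 41843.5), ("Glucose", 1, "YK", 28552.0),
                ("Glucose", 2, "SH", 16547.4), ("Glucose", 2, "YK", 6251.4),
            ],
            columns=["metabolite", "experiment", "genotype", "mean"],
        )
        ratio = M.starch_proxy_from_means(means)
        assert round(ratio, 1) == 1.7

    def test_identical_parents_ratio_one(self):
        rec = metab_frame([
            ("maltose", "carbohydrate", e, g, [5, 5, 5])
            for e in (1, 2) for g in ("SH", "YK")
        ] + [
            ("glucose", "carbohydrate", e, g, [50, 50, 50])
            for e in (1, 2) for g in ("SH", "YK")
        ])
        assert M.starch_proxy(rec) == pytest.approx(1.0)

    def test_doubling_yk_halves_ratio(self):
        rec = metab_frame([
            ("maltose", "carbohydrate", e, "SH", [10, 10]) for e in (1, 2)
        ] + [
            ("maltose", "carbohydrate", e, "YK", [20, 20]) for e in (1, 2)
        ] + [
            ("glucose", "carbohydrate", e, "SH", [100, 100]) for e in (1, 2)
        ] + [
            ("glucose", "carbohydrate", e, "YK", [200, 200]) for e in (1, 2)
        ])
        assert M.starch_proxy(rec) == pytest.approx(0.5)

    def test_missing_experiment_rejected(self):
        rec = metab_frame([
            ("maltose", "carbohydrate", 1, "SH", [10, 10]),
            ("maltose", "carbohydrate", 1, "YK", [20, 20]),
            ("glucose", "carbohydrate", 1, "SH", [10, 10]),
            ("glucose", "carbohydrate", 1, "YK", [20, 20]),
        ])
        with pytest.raises(ValueError):
            M.starch_proxy(rec)


class TestSummaries:
    def test_all_above_mid_parent_fraction_zero(self):
        calls = [call(metabolite=f"m{i}", f1=12.0) for i in range(10)]
        s = M.summarize_mid_parent_fraction(calls)
        assert s["fraction_below_mid_parent"] == 0.0

    def test_planted_below_fraction_recovered(self):
        calls = [call(metabolite=f"b{i}", f1=8.0) for i in range(60)] + [
            call(metabolite=f"a{i}", f1=12.0) for i in range(40)
        ]
        s = M.summarize_mid_parent_fraction(calls)
        assert s["fraction_below_mid_parent"] == pytest.approx(0.6)

    def test_per_class_breakdown(self):
        calls = [call(metabolite="a", cls="fatty_acid", f1=8.0),
                 call(metabolite="b", cls="fatty_acid", f1=12.0),
                 call(metabolite="c", cls="carbohydrate", f1=8.0)]
        s = M.summarize_mid_parent_fraction(calls)
        assert s["per_class_below"] == {"carbohydrate": 1.0, "fatty_acid": 0.5}

    def test_star_thresholds(self):
        assert M.stars(0.049) == "*"
        assert M.stars(0.009) == "**"
        assert M.stars(0.0009) == "***"
        assert M.stars(0.06) == "n.s."


class TestModeClassification:
    def test_confusion_diagonal_on_planted_modes(self):
        from collections import Counter, defaultdict

        confusion = defaultdict(Counter)
        for seed in range(4):
            cfg = SimConfig(seed=100 + seed)
            rec, truth = simulate_metabolome(cfg)
            modes = M.classify_heterosis_modes(rec)
            for met, (mode, *_means) in truth.metab_class.items():
                if met in truth.metab_parent_absent:
                    continue
                confusion[mode][modes[met]] += 1
        for mode, row in confusion.items():
            assert row[mode] / sum(row.values()) >= 0.85, (mode, dict(row))
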