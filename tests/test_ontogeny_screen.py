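"""Ontogeny ratios, hit calling, and the screen's statistical toolkit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multicomp import MultiComparison
from statsmodels.stats.multitest import multipletests

from ontosleep import ontogeny_screen as osc


def result_with_ratio(genotype, ratio, n=8, mature_mean=100.0):
    young = np.full(n, ratio * mature_mean)
    mature = np.full(n, mature_mean)
    return osc.compute_ontogeny_ratio(young, mature, genotype=genotype)


class TestOntogenyRatio:
    def test_ratio_of_group_means(self):
        r = osc.compute_ontogeny_ratio(np.full(5, 600.0), np.full(5, 400.0))
        assert r.ontogeny_ratio == pytest.approx(1.5)

    def test_identical_groups_give_unity(self):
        x = np.array([200.0, 300.0, 400.0])
        r = osc.compute_ontogeny_ratio(x, x)
        assert r.ontogeny_ratio == pytest.approx(1.0)

    def test_small_group_arithmetic(self):
        r = osc.compute_ontogeny_ratio(
            np.array([300.0, 350.0]), np.array([650.0, 710.0])
        )
        assert r.ontogeny_ratio == pytest.approx(325.0 / 680.0)

    def test_zero_mature_mean_is_flagged_undefined(self):
        r = osc.compute_ontogeny_ratio(np.full(8, 100.0), np.zeros(8))
        assert not r.ratio_defined
        assert np.isnan(r.ontogeny_ratio)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            osc.compute_ontogeny_ratio(np.array([]), np.array([1.0]))

    def test_ratio_is_scale_equivariant(self, rng):
        young = rng.uniform(200, 600, size=12)
        mature = rng.uniform(100, 400, size=12)
        r1 = osc.compute_ontogeny_ratio(young, mature).ontogeny_ratio
        r2 = osc.compute_ontogeny_ratio(3.7 * young, 3.7 * mature).ontogeny_ratio
        assert r1 == pytest.approx(r2)


class TestCallScreenHits:
    def test_cutoff_is_inclusive(self):
        results = [
            result_with_ratio("a", 1.0),
            result_with_ratio("b", 1.2),
            result_with_ratio("c", 1.21),
        ]
        screen = osc.call_screen_hits(results, cutoff=1.2)
        hits = set(screen.loc[screen["hit"], "genotype"])
        assert hits == {"a", "b"}

    def test_no_hits_when_all_ratios_high(self):
        results = [result_with_ratio(f"g{i}", 1.75) for i in range(5)]
        screen = osc.call_screen_hits(results)
        assert not screen["hit"].any()

    def test_sorted_ascending_by_ratio(self):
        results = [
            result_with_ratio("hi", 1.9),
            result_with_ratio("lo", 0.7),
            result_with_ratio("mid", 1.3),
        ]
        screen = osc.call_screen_hits(results)
        assert list(screen["genotype"]) == ["lo", "mid", "hi"]

    def test_minimum_n_filter_blocks_small_groups(self):
        small = result_with_ratio("small", 0.5, n=4)
        screen = osc.call_screen_hits([small], min_n=8)
        assert not screen["hit"].any()
        assert not screen["eligible"].any()

    def test_undefined_ratio_reported_but_never_hit(self):
        undef = osc.compute_ontogeny_ratio(np.full(8, 100.0), np.zeros(8))
        undef.genotype = "undef"
        screen = osc.call_screen_hits([undef, result_with_ratio("ok", 1.0)])
        row = screen.set_index("genotype").loc["undef"]
        assert not row["hit"] and not row["ratio_defined"]


class TestHolmSidak:
    def test_two_pvalue_closed_form(self):
        adj = osc.holm_sidak_adjust(np.array([0.01, 0.04]))
        assert adj[0] == pytest.approx(1 - 0.99**2, abs=1e-12)
        assert adj[1] == pytest.approx(0.04, abs=1e-12)

    def test_single_pair_is_identity(self):
        assert osc.holm_sidak_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_matches_statsmodels_reference(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(2, 10)))
            ours = osc.holm_sidak_adjust(p)
            ref = multipletests(p, method="holm-sidak")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_adjusted_ps_are_monotone_and_dominate_raw(self, rng):
        p = rng.uniform(0, 1, size=8)
        adj = osc.holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_family_of_ttests_on_identical_groups_is_null(self, rng):
        g = rng.normal(size=10)
        res = osc.holm_sidak_ttests([(g, g)] * 4)
        assert not any(r.significant for r in res)
        assert all(r.p_adj >= r.p_raw for r in res)

    def test_zero_variance_equal_means_gives_p_one(self):
        a = np.ones(5)
        res = osc.holm_sidak_ttests([(a, a.copy())])
        assert res[0].p_raw == 1.0
        assert "degenerate" in res[0].note


class TestWelch:
    def test_identical_samples_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        r = osc.welch_ttest(x, x.copy())
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_zero_variance_separation_is_flagged_degenerate(self):
        r = osc.welch_ttest(np.zeros(4), np.ones(4))
        assert np.isinf(r.statistic)
        assert r.p_raw == 0.0
        assert "degenerate" in r.note

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(3, 30)))
            b = rng.normal(0.3, 2, size=int(rng.integers(3, 30)))
            ours = osc.welch_ttest(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert ours.statistic == pytest.approx(t_ref, abs=1e-10)
            assert ours.p_raw == pytest.approx(p_ref, abs=1e-10)


class TestAnovaTukey:
    def test_identical_groups_are_null(self):
        g = np.array([1.0, 2.0, 3.0])
        overall, pairwise = osc.anova_tukey([g, g.copy(), g.copy()])
        assert overall.statistic == pytest.approx(0.0)
        assert not any(r.significant for r in pairwise)

    def test_one_separated_group_drives_all_its_pairs(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, size=6)
        b = rng.normal(0, 0.01, size=6)
        c = rng.normal(10, 0.01, size=6)
        overall, pairwise = osc.anova_tukey([a, b, c], labels=["a", "b", "c"])
        assert overall.significant
        sig = {r.comparison for r in pairwise if r.significant}
        assert sig == {"a vs c", "b vs c"}

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            osc.anova_tukey([np.ones(3), np.zeros(3)])

    def test_tukey_matches_statsmodels_reference(self, rng):
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), 1, size=8) for _ in range(4)]
            _, pairwise = osc.anova_tukey(groups)
            data = np.concatenate(groups)
            labels = np.repeat([f"g{i}" for i in range(4)], 8)
            ref = MultiComparison(data, labels).tukeyhsd()
            ref_p = np.asarray(ref.pvalues)
            ours_p = np.array([r.p_raw for r in pairwise])
            assert np.allclose(np.sort(ours_p), np.sort(ref_p), atol=1e-8)


class TestModifierContrast:
    def test_rescue_flagged_on_ratio_gain_with_significance(self, rng):
        base = osc.compute_ontogeny_ratio(
            rng.normal(270, 20, 16), rng.normal(300, 20, 16), genotype="base"
        )
        modified = osc.compute_ontogeny_ratio(
            rng.normal(480, 20, 16), rng.normal(300, 20, 16), genotype="mod"
        )
        res = osc.modifier_contrast(base, modified)
        assert res.rescue
        assert res.ratio_delta > 0.5

    def test_identical_genotypes_are_not_a_rescue(self, rng):
        vals_y = rng.normal(300, 20, 16)
        vals_m = rng.normal(300, 20, 16)
        base = osc.compute_ontogeny_ratio(vals_y, vals_m, genotype="base")
        modified = osc.compute_ontogeny_ratio(vals_y, vals_m, genotype="mod")
        res = osc.modifier_contrast(base, modified)
        assert res.ratio_delta == pytest.approx(0.0)
        assert not res.rescue

    def test_undefined_base_ratio_propagates_without_rescue(self):
        base = osc.compute_ontogeny_ratio(np.full(8, 100.0), np.zeros(8))
        modified = result_with_ratio("mod", 1.6)
        res = osc.modifier_contrast(base, modified)
        assert not res.rescue
        assert np.isnan(res.ratio_delta)
        assert "undefined" in res.note
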