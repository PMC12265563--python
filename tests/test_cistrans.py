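"""Log-ratio machinery, the ratio-difference Z test, the category grid, and
cross-diet comparisons of cis and trans components."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicediv import cistrans
from splicediv.cistrans import (
    classify_regulation,
    component_diet_correlation,
    diet_divergence_compare,
    equalize_samples,
    log_ratio_with_se,
    ratio_difference_z,
)


class TestLogRatio:
    def test_equal_inputs_give_zero(self):
        est, _ = log_ratio_with_se([0.4, 0.5, 0.6], [0.4, 0.5, 0.6],
                                   paired=False)
        assert est == pytest.approx(0.0, abs=1e-12)

    def test_constant_paired_ratios(self):
        # (psi_a + eps)/(psi_b + eps) = 2 in every replicate: estimate ln 2, SE 0
        a = [0.59, 0.59]
        b = [0.29, 0.29]
        est, se = log_ratio_with_se(a, b, paired=True, eps=0.01)
        assert est == pytest.approx(math.log(2.0), abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_paired_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            a = rng.uniform(0.05, 0.95, n)
            b = rng.uniform(0.05, 0.95, n)
            est, se = log_ratio_with_se(a, b, paired=True, eps=0.01)
            r = [math.log((x + 0.01) / (y + 0.01)) for x, y in zip(a, b)]
            mean = sum(r) / n
            sd = math.sqrt(sum((x - mean) ** 2 for x in r) / (n - 1))
            assert est == pytest.approx(mean, abs=1e-12)
            assert se == pytest.approx(sd / math.sqrt(n), abs=1e-12)

    def test_unpaired_matches_delta_method_oracle(self, rng):
        for _ in range(50):
            a = rng.uniform(0.05, 0.95, int(rng.integers(2, 8)))
            b = rng.uniform(0.05, 0.95, int(rng.integers(2, 8)))
            est, se = log_ratio_with_se(a, b, paired=False, eps=0.01)
            ma = sum(a) / len(a) + 0.01
            mb = sum(b) / len(b) + 0.01
            va = float(np.var(a, ddof=1)) / len(a)
            vb = float(np.var(b, ddof=1)) / len(b)
            assert est == pytest.approx(math.log(ma / mb), abs=1e-12)
            assert se == pytest.approx(
                math.sqrt(va / ma**2 + vb / mb**2), abs=1e-12
            )

    def test_too_few_replicates_untestable(self):
        est, se = log_ratio_with_se([0.5], [0.4, 0.5], paired=False)
        assert np.isnan(est) and np.isnan(se)

    def test_eps_must_be_positive(self):
        with pytest.raises(ValueError):
            log_ratio_with_se([0.5, 0.5], [0.4, 0.4], paired=True, eps=0.0)


class TestRatioZ:
    def test_equal_ratios_null(self):
        z, p = ratio_difference_z(0.7, 0.1, 0.7, 0.2)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_value(self):
        z, p = ratio_difference_z(1.0, 0.3, 0.0, 0.4)
        assert z == pytest.approx(2.0, abs=1e-12)
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_matches_normal_cdf_oracle(self, rng):
        for _ in range(200):
            lp, lh = rng.normal(size=2)
            sp, sh = rng.uniform(0.05, 1.0, size=2)
            z, p = ratio_difference_z(lp, sp, lh, sh)
            z_oracle = (lp - lh) / math.sqrt(sp**2 + sh**2)
            p_oracle = math.erfc(abs(z_oracle) / math.sqrt(2.0))
            assert z == pytest.approx(z_oracle, abs=1e-10)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_zero_ses_untestable(self):
        z, p = ratio_difference_z(1.0, 0.0, 0.0, 0.0)
        assert np.isnan(z) and np.isnan(p)


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "flags,signs,expected",
        [
            ((True, True, False), (1, 1), "cis_only"),
            ((True, False, True), (1, 0), "trans_only"),
            ((False, False, False), (0, 0), "conserved"),
            ((True, True, True), (1, 1), "cis_plus_trans"),
            ((True, True, True), (1, -1), "compensatory"),
            ((False, True, True), (-1, 1), "compensatory"),
            ((True, False, False), (1, 0), "ambiguous"),
            ((False, True, False), (0, 1), "ambiguous"),
        ],
    )
    def test_decision_grid(self, flags, signs, expected):
        assert classify_regulation(*flags, *signs) == expected

    def test_missing_flags_are_ambiguous(self):
        assert classify_regulation(None, True, False) == "ambiguous"
        assert classify_regulation(float("nan"), True, True) == "ambiguous"


class TestEqualizeSamples:
    def test_group_of_exact_size_unchanged(self):
        out = equalize_samples({"g": list("abcde")}, n=5, seed=1)
        assert out["g"] == list("abcde")

    def test_deterministic_under_seed(self):
        groups = {"g": list("abcdefg"), "h": list("hijklmn")}
        a = equalize_samples(groups, n=5, seed=42)
        b = equalize_samples(groups, n=5, seed=42)
        assert a == b
        assert all(len(v) == 5 for v in a.values())

    def test_different_seeds_differ(self):
        groups = {"g": [f"s{i}" for i in range(12)]}
        picks = {tuple(equalize_samples(groups, n=5, seed=s)["g"])
                 for s in range(100)}
        assert len(picks) > 50

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="g"):
            equalize_samples({"g": ["a", "b"]}, n=5, seed=0)


class TestAssignRegulation:
    def test_decomposition_and_label_swap(self, f1_dataset):
        _, parents, hybrids, _ = f1_dataset
        tab = parents["STD"]
        s1 = [s for s in tab.samples if s.startswith("SARB")]
        s2 = [s for s in tab.samples if s.startswith("MANB")]
        res = cistrans.assign_regulation(tab, hybrids, s1, s2, diet="STD")
        # additive decomposition holds exactly by construction
        np.testing.assert_allclose(
            res["cis"] + res["trans"], res["L_P"], atol=1e-12
        )
        # swapping parental labels negates L_P and preserves |Z|
        swapped = cistrans.assign_regulation(tab, hybrids, s2, s1, diet="STD")
        m = res.merge(swapped, on="event_id", suffixes=("", "_sw"))
        np.testing.assert_allclose(m["L_P_sw"], -m["L_P"], atol=1e-12)
        ok = m["Z"].notna() & m["Z_sw"].notna()
        # allele orientation in the hybrid is unchanged, so only the parental
        # leg of Z flips; compare through the reconstructed difference
        np.testing.assert_allclose(
            (m.loc[ok, "L_P_sw"] - m.loc[ok, "L_H"]).abs(),
            ((-m.loc[ok, "L_P"]) - m.loc[ok, "L_H"]).abs(), atol=1e-12,
        )

    def test_category_recovery(self, f1_dataset):
        _, parents, hybrids, truth = f1_dataset
        tab = parents["STD"]
        s1 = [s for s in tab.samples if s.startswith("SARB")]
        s2 = [s for s in tab.samples if s.startswith("MANB")]
        res = cistrans.assign_regulation(tab, hybrids, s1, s2, diet="STD")
        m = res.merge(truth.df, left_on="event_id", right_on="unit_id")
        for true_cat, called_cat in [("cis_only", "cis_only"),
                                     ("trans_only", "trans_only"),
                                     ("null", "conserved")]:
            sub = m[m["category_y"] == true_cat]
            assert (sub["category_x"] == called_cat).mean() >= 0.8, true_cat


class TestCisByDiet:
    def test_identical_ratios_give_zero_z(self):
        rows = []
        for diet in ("STD", "HF"):
            for r in range(1, 6):
                # identical allelic imbalance in both diets, slight replicate
                # variation so the SE is nonzero
                rows.append(("e1", "g", "SE", diet, r,
                             120 + r, 80 - r, 100 + r, 100 - r, 1, 1))
        pairs = pd.DataFrame(rows, columns=[
            "event_id", "gene_id", "event_class", "diet", "replicate",
            "IJC1", "SJC1", "IJC2", "SJC2", "IncFormLen", "SkipFormLen"])
        res = cistrans.cis_by_diet_test(pairs)
        assert abs(res["Z"].iloc[0]) < 1e-9


class TestDietComparisons:
    def test_spearman_limits(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 10.0])
        rho, _ = component_diet_correlation(np.exp(x), x)  # monotone transform
        assert rho == pytest.approx(1.0)
        rho, _ = component_diet_correlation(-x, x)
        assert rho == pytest.approx(-1.0)

    def test_spearman_matches_rank_pearson_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho, _ = component_diet_correlation(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_spearman_constant_vector_flagged(self):
        rho, p = component_diet_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_wilcoxon_exact_enumeration_case(self):
        # pairs (1,2),(1,3),(1,4): all three signs positive out of 2^3
        _, p = diet_divergence_compare([1, 1, 1], [2, 3, 4],
                                       alternative="greater")
        assert p == pytest.approx(0.125, abs=1e-12)

    def test_wilcoxon_all_zero_untestable(self):
        with pytest.raises(ValueError):
            diet_divergence_compare([1.0, 2.0], [1.0, 2.0])

    def test_trans_component_diverges_more_when_planted(self, rng):
        # trans divergences drawn systematically larger than cis
        cis = rng.uniform(0.0, 0.5, 40)
        trans = cis + rng.uniform(0.1, 1.0, 40)
        _, p = diet_divergence_compare(cis, trans, alternative="greater")
        assert p < 1e-6
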