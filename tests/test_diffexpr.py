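"""Dye-swap alignment, variance exclusion, and pooled paired test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssrnet import (DEConfig, TwoColorSpec, align_dye_swaps, exclude_extreme_variance,
                    gen_two_color, pooled_paired_test, run_de)
from ssrnet.synthetic import RatioTable


def make_table(fwd, swp, genes=None):
    genes = genes or [f"g{i}" for i in range(len(fwd))]
    values = pd.DataFrame({"a_fwd": fwd, "a_swp": swp}, index=genes)
    arrays = pd.DataFrame({"array_id": ["a_fwd", "a_swp"],
                           "replicate_id": ["a", "a"],
                           "orientation": ["forward", "swapped"]})
    return RatioTable(values, arrays)


class TestAlign:
    def test_perfect_dye_swap_agreement(self):
        aligned = align_dye_swaps(make_table([1.0], [-1.0]))
        assert aligned.iloc[0, 0] == pytest.approx(1.0)

    def test_pure_dye_bias_cancels(self):
        aligned = align_dye_swaps(make_table([1.0], [1.0]))
        assert aligned.iloc[0, 0] == pytest.approx(0.0)

    def test_random_table_matches_formula_oracle(self):
        spec = TwoColorSpec(n_genes=100, n_pairs=3, de_fraction=0.3, rng_seed=8)
        table, _ = gen_two_color(spec)
        aligned = align_dye_swaps(table)
        for j in range(3):
            expected = (table.values[f"rep{j}_fwd"] - table.values[f"rep{j}_swp"]) / 2.0
            assert np.allclose(aligned[f"rep{j}"], expected)

    def test_unpaired_swapped_array_is_hard_error(self):
        values = pd.DataFrame({"x": [1.0]}, index=["g0"])
        arrays = pd.DataFrame({"array_id": ["x"], "replicate_id": ["r"],
                               "orientation": ["swapped"]})
        with pytest.raises(ValueError, match="x"):
            align_dye_swaps(RatioTable(values, arrays))

    def test_missing_member_gives_missing_replicate(self):
        table = make_table([1.0, np.nan], [-1.0, 0.5])
        aligned = align_dye_swaps(table)
        assert np.isnan(aligned.iloc[1, 0])


class TestVarianceExclusion:
    def test_expected_tail_count_on_iid_noise(self):
        rng = np.random.default_rng(0)
        aligned = pd.DataFrame(rng.standard_normal((1000, 4)))
        include = exclude_extreme_variance(aligned, DEConfig())
        # E[excluded] = 0.002 * 1000 = 2; binomial(1000, 0.002) stays under 8
        assert 0 <= int((~include).sum()) <= 8

    def test_extreme_variance_gene_excluded(self):
        rng = np.random.default_rng(1)
        aligned = pd.DataFrame(rng.standard_normal((500, 4)))
        aligned.iloc[0] *= 1000.0  # variance ~1e6 x median
        include = exclude_extreme_variance(aligned, DEConfig())
        assert not include.iloc[0]

    def test_full_quantile_range_excludes_nothing(self):
        rng = np.random.default_rng(2)
        aligned = pd.DataFrame(rng.standard_normal((100, 3)))
        cfg = DEConfig(variance_exclusion_quantiles=(0.0, 1.0))
        assert exclude_extreme_variance(aligned, cfg).all()

    def test_identical_variances_exclude_nothing(self):
        aligned = pd.DataFrame([[0.0, 1.0]] * 50)
        assert exclude_extreme_variance(aligned, DEConfig()).all()


class TestPooledTest:
    def test_all_zero_ratios_give_p_one_no_calls(self):
        aligned = pd.DataFrame(np.zeros((20, 3)))
        de = pooled_paired_test(aligned)
        assert (de["p_raw"] == 1.0).all()
        assert (de["call"] == "unchanged").all()

    def test_single_gene_closed_form_normal_tail(self):
        # one tested gene with m=1, n=4 and pooled s^2 driven to 0.25 by
        # padding genes of zero mean: t = 1/sqrt(0.25/4) = 4
        rng = np.random.default_rng(3)
        pad = rng.standard_normal((4000, 4))
        pad = (pad - pad.mean(1, keepdims=True)) / pad.std(1, ddof=1, keepdims=True) * 0.5
        target = np.array([1.0, 1.0, 1.0, 1.0])
        aligned = pd.DataFrame(np.vstack([target, pad]),
                               index=[f"g{i}" for i in range(4001)])
        de = pooled_paired_test(aligned, cfg=DEConfig(variance_exclusion_quantiles=(0, 1)))
        t = de.loc["g0", "t_stat"]
        assert t == pytest.approx(4.0, rel=1e-3)
        assert de.loc["g0", "p_raw"] == pytest.approx(2 * stats.norm.sf(t), rel=1e-9)
        assert de.loc["g0", "p_raw"] == pytest.approx(6.33e-5, rel=0.01)

    def test_null_generator_calibration_single_seed(self):
        spec = TwoColorSpec(n_genes=2000, n_pairs=3, de_fraction=0.0, sigma=0.3, rng_seed=17)
        table, _ = gen_two_color(spec)
        de = run_de(table)
        tested = de[de["call"] != "excluded"]
        fpr = (tested["p_raw"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(tested))
        assert abs(fpr - 0.05) < 4 * se

    def test_power_recovery_with_planted_effect(self):
        # effect = 3 sigma / sqrt(n) on arrays whose dye-swap average has
        # noise sigma/sqrt(2): expected |t| ~ 3*sqrt(2), so raw-p
        # sensitivity at alpha = 0.05 should exceed 0.9
        n, sigma = 4, 0.4
        spec = TwoColorSpec(n_genes=2000, n_pairs=n, de_fraction=0.1,
                            effect=3 * sigma / np.sqrt(n), sigma=sigma, rng_seed=23)
        table, truth = gen_two_color(spec)
        de = run_de(table)
        de_rows = de.loc[truth["is_de"]]
        sensitivity = ((de_rows["p_raw"] < 0.05) & (de_rows["mean_log_ratio"] > 0)).mean()
        assert sensitivity >= 0.9

    def test_bonferroni_monotone_and_reorder_invariant(self):
        spec = TwoColorSpec(n_genes=300, n_pairs=3, de_fraction=0.1, rng_seed=29)
        table, _ = gen_two_color(spec)
        de = run_de(table)
        ok = de.dropna(subset=["p_raw"]).sort_values("p_raw")
        assert ok["p_bonferroni"].is_monotonic_increasing
        assert (ok["p_bonferroni"] >= ok["p_raw"]).all()
        shuffled = RatioTable(table.values.sample(frac=1, random_state=0), table.arrays)
        de2 = run_de(shuffled)
        pd.testing.assert_series_equal(de["call"].sort_index(), de2["call"].sort_index())

    def test_single_replicate_is_hard_error(self):
        aligned = pd.DataFrame(np.ones((10, 1)))
        with pytest.raises(ValueError):
            pooled_paired_test(aligned)
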