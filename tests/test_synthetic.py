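"""Generator contracts: planted structure, ground-truth completeness, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from ssrnet import (CompendiumSpec, PromoterSpec, TwoColorSpec, gen_compendium,
                    gen_promoters, gen_two_color)
from ssrnet.motifs import contains_motif


class TestCompendium:
    def test_noise_free_module_is_perfectly_correlated(self):
        spec = CompendiumSpec(n_genes=10, n_samples=8, modules=((10, 1.0),),
                              noise_sd=0.0, rng_seed=0)
        comp, truth = gen_compendium(spec)
        corr = np.corrcoef(comp.to_numpy())
        assert np.allclose(corr, 1.0)
        assert (truth["module"] == 0).all()

    def test_zero_latent_r_gives_independent_module_genes(self):
        # under independence E[r^2] = 1/(n_samples - 1); Monte Carlo over
        # all off-diagonal pairs of a 120-gene "module" (>1000 pairs)
        n_samples = 11
        spec = CompendiumSpec(n_genes=120, n_samples=n_samples,
                              modules=((120, 0.0),), rng_seed=3)
        comp, _ = gen_compendium(spec)
        corr = np.corrcoef(comp.to_numpy())
        off = corr[np.triu_indices_from(corr, k=1)] ** 2
        expected = 1.0 / (n_samples - 1)
        assert off.mean() == pytest.approx(expected, rel=0.15)

    def test_same_seed_bit_identical(self):
        spec = CompendiumSpec(n_genes=50, n_samples=12, modules=((20, 0.8),), rng_seed=9)
        a, ta = gen_compendium(spec)
        b, tb = gen_compendium(spec)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_module_truth_partitions_genes(self):
        spec = CompendiumSpec(n_genes=60, n_samples=6, modules=((10, 0.9), (15, 0.7)), rng_seed=1)
        comp, truth = gen_compendium(spec)
        assert len(truth) == 60
        assert (truth["module"] == 0).sum() == 10
        assert (truth["module"] == 1).sum() == 15
        assert (truth["module"] == -1).sum() == 35
        assert np.isfinite(comp.to_numpy()).all()

    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=0, n_samples=5),
        dict(n_genes=10, n_samples=2),
        dict(n_genes=10, n_samples=5, modules=((11, 0.5),)),
        dict(n_genes=10, n_samples=5, modules=((5, 1.5),)),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CompendiumSpec(rng_seed=0, **kwargs)


class TestTwoColor:
    def test_zero_effect_means_no_de_labels(self):
        spec = TwoColorSpec(n_genes=100, n_pairs=3, de_fraction=0.2, effect=0.0,
                            sigma=0.1, rng_seed=0)
        _, truth = gen_two_color(spec)
        assert (truth["effect"] == 0).all()

    def test_noise_free_limit_recovers_effect_with_opposite_swap_sign(self):
        spec = TwoColorSpec(n_genes=50, n_pairs=2, de_fraction=0.2, effect=1.0,
                            sigma=1e-9, rng_seed=1)
        table, truth = gen_two_color(spec)
        de = truth.index[truth["is_de"]]
        fwd = table.values.loc[de, "rep0_fwd"]
        swp = table.values.loc[de, "rep0_swp"]
        assert np.allclose(fwd, 1.0, atol=1e-6)
        assert np.allclose(swp, -1.0, atol=1e-6)

    def test_de_count_is_exact(self):
        spec = TwoColorSpec(n_genes=1000, n_pairs=2, de_fraction=0.1, rng_seed=5)
        _, truth = gen_two_color(spec)
        assert int(truth["is_de"].sum()) == 100

    def test_explicit_de_genes_honored(self):
        spec = TwoColorSpec(n_genes=20, n_pairs=2, rng_seed=2)
        table, truth = gen_two_color(spec, de_genes=["g00003", "g00007"])
        assert set(truth.index[truth["is_de"]]) == {"g00003", "g00007"}
        assert list(table.arrays["orientation"]) == ["forward", "swapped"] * 2

    def test_determinism_and_bad_fraction(self):
        spec = TwoColorSpec(n_genes=30, n_pairs=3, de_fraction=0.5, rng_seed=11)
        a, _ = gen_two_color(spec)
        b, _ = gen_two_color(spec)
        pd.testing.assert_frame_equal(a.values, b.values)
        with pytest.raises(ValueError):
            TwoColorSpec(n_genes=10, n_pairs=2, de_fraction=1.5)


class TestPromoters:
    def test_certain_insertion_recorded_and_present(self):
        spec = PromoterSpec(n_promoters=20, length=200, gc_fraction=0.5,
                            planted=(("GATAAG", 1.0),), rng_seed=0)
        promoters, truth = gen_promoters(spec)
        assert set(truth["promoter_id"]) == set(promoters)
        for pid, _, instance, pos in truth.itertuples(index=False):
            assert promoters[pid][pos:pos + len(instance)] == instance
            assert contains_motif(promoters[pid], "GATAAG")

    def test_zero_insertion_prob_gives_empty_truth(self):
        spec = PromoterSpec(n_promoters=10, length=100, planted=(("GATAAG", 0.0),), rng_seed=1)
        _, truth = gen_promoters(spec)
        assert truth.empty

    def test_gc_fraction_within_three_standard_errors(self):
        spec = PromoterSpec(n_promoters=100, length=1000, gc_fraction=0.5, rng_seed=2)
        promoters, _ = gen_promoters(spec)
        joined = "".join(promoters.values())
        gc = sum(c in "GC" for c in joined) / len(joined)
        se = math.sqrt(0.25 / len(joined))
        assert abs(gc - 0.5) < 3 * se

    def test_degenerate_insertions_match_their_pattern(self):
        spec = PromoterSpec(n_promoters=30, length=150, planted=(("BACGTGKM", 1.0),), rng_seed=3)
        promoters, truth = gen_promoters(spec)
        from ssrnet import expand_iupac
        instances = set(expand_iupac("BACGTGKM"))
        assert set(truth["instance"]) <= instances

    def test_pattern_longer_than_promoter_rejected(self):
        with pytest.raises(ValueError):
            PromoterSpec(n_promoters=5, length=4, planted=(("GATAAG", 1.0),))

    def test_determinism(self):
        spec = PromoterSpec(n_promoters=15, length=120, planted=(("GATAA", 0.5),), rng_seed=4)
        a, ta = gen_promoters(spec)
        b, tb = gen_promoters(spec)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)
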