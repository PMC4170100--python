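"""Boyer-Moore counting and enrichment statistics against independent oracles."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ssrnet import (KmerNullConfig, MotifPattern, PromoterSpec, binomial_enrichment_p,
                    boyer_moore_count, count_motif, gen_promoters,
                    hypergeometric_enrichment_p, kmer_overrepresentation,
                    known_motif_enrichment)
from conftest import naive_count

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)
pat = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestBoyerMoore:
    def test_overlapping_occurrences(self):
        assert boyer_moore_count("AAAAAA", "AAAA") == 3

    def test_single_occurrence(self):
        assert boyer_moore_count("CCGATAACC", "GATAA") == 1

    def test_pattern_longer_than_sequence(self):
        assert boyer_moore_count("ACG", "ACGT") == 0

    @settings(max_examples=500, derandomize=True, deadline=None)
    @given(dna, pat)
    def test_matches_naive_scan(self, sequence, pattern):
        assert boyer_moore_count(sequence, pattern) == naive_count(sequence, pattern)

    def test_exhaustive_small_alphabet(self):
        # every pattern of length <= 4 against every sequence of length <= 8
        # over a two-letter alphabet
        seqs = ["".join(s) for L in range(1, 9) for s in product("AC", repeat=L)]
        pats = ["".join(p) for L in range(1, 5) for p in product("AC", repeat=L)]
        for seq in seqs:
            for p in pats:
                assert boyer_moore_count(seq, p) == naive_count(seq, p)

    def test_iupac_expansion_counts_all_instances(self):
        # R = A/G: GART matches GAAT and GAGT
        assert count_motif("GAATGAGTGATT", "GART") == 2

    def test_reverse_complement_flag_adds_matches(self):
        seq = "CCCCTTATCCCCC"  # contains TTATC; revcomp motif GATAA matches it
        assert count_motif(seq, "GATAA") == 0
        assert count_motif(seq, "GATAA", revcomp=True) == 1


class TestKnownMotifEnrichment:
    def test_published_containment_counts_give_extreme_binomial_tail(self):
        # 89 of 220 promoters containing a motif whose genome containment is
        # 20% is far beyond chance
        assert binomial_enrichment_p(89, 220, 0.20) < 1e-5
        assert binomial_enrichment_p(140, 220, 0.40) < 1e-4

    def test_motif_in_every_promoter_is_maximally_enriched(self):
        subset = {f"p{i}": "TTGATAAGTT" for i in range(30)}
        res = known_motif_enrichment(subset, [MotifPattern("Ibox", "GATAAG")],
                                     {"Ibox": 0.5})
        assert res.loc[0, "subset_hits"] == 30
        assert res.loc[0, "p_value"] == pytest.approx(0.5 ** 30)
        assert res.loc[0, "significant"]

    def test_motif_matching_nothing_gives_p_one(self):
        subset = {"p0": "AAAAAAAA", "p1": "AAAAAAAA"}
        res = known_motif_enrichment(subset, [MotifPattern("Ibox", "GATAAG")],
                                     {"Ibox": 0.3})
        assert res.loc[0, "p_value"] == 1.0

    def test_empty_subset_is_error(self):
        with pytest.raises(ValueError):
            known_motif_enrichment({}, [MotifPattern("Ibox", "GATAAG")], {"Ibox": 0.3})

    def test_p_monotone_decreasing_in_hits(self):
        ps = [binomial_enrichment_p(k, 100, 0.3) for k in range(101)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_hypergeometric_route_on_full_promoterome(self):
        spec = PromoterSpec(n_promoters=300, length=300, gc_fraction=0.5,
                            planted=(("GATAAG", 0.3),), rng_seed=5)
        genome, _ = gen_promoters(spec)
        ids = list(genome)
        subset = {i: genome[i] for i in ids[:50]}
        res = known_motif_enrichment(subset, [MotifPattern("Ibox", "GATAAG")], genome)
        assert res.loc[0, "method"] == "hypergeometric"
        k, n = res.loc[0, "subset_hits"], 50
        K = round(res.loc[0, "background_freq"] * 300)
        assert res.loc[0, "p_value"] == pytest.approx(
            stats.hypergeom.sf(k - 1, 300, K, n))

    def test_null_subsets_give_approximately_uniform_p(self):
        # subsets drawn uniformly from the background promoterome: the
        # hypergeometric containment p-value is (conservatively) uniform
        spec = PromoterSpec(n_promoters=400, length=250, gc_fraction=0.5,
                            planted=(("GATAAG", 0.45),), rng_seed=6)
        genome, _ = gen_promoters(spec)
        ids = list(genome)
        contains = np.array([count_motif(genome[i], "GATAAG") > 0 for i in ids])
        K, N, n = int(contains.sum()), 400, 80
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            pick = rng.choice(N, size=n, replace=False)
            k = int(contains[pick].sum())
            pvals.append(stats.hypergeom.sf(k - 1, N, K, n))
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01 or stat < 0.15  # discrete super-uniformity allowance


class TestKmerNull:
    def test_planted_kmer_absent_from_background_hits_p_floor(self):
        subset = {f"s{i}": "TTTTGATAATTTT" for i in range(10)}
        genome = {f"b{i}": "CCCCCCCCCCCCC" for i in range(100)}
        genome.update(subset)
        cfg = KmerNullConfig(k=5, n_background_sets=99, rng_seed=0)
        res = kmer_overrepresentation(subset, genome, cfg)
        row = res[res["kmer"] == "GATAA"].iloc[0]
        assert row["observed"] == 10
        assert row["p_empirical"] == pytest.approx(1 / 100)

    def test_null_subset_p_bounded_and_centered(self):
        spec = PromoterSpec(n_promoters=200, length=120, gc_fraction=0.5, rng_seed=9)
        genome, _ = gen_promoters(spec)
        ids = list(genome)
        subset = {i: genome[i] for i in ids[:30]}
        cfg = KmerNullConfig(k=5, n_background_sets=199, rng_seed=1)
        res = kmer_overrepresentation(subset, genome, cfg)
        B = 199
        assert (res["p_empirical"] >= 1 / (B + 1)).all()
        assert (res["p_empirical"] <= 1.0).all()
        # sampling the subset from the genome itself: p-values center near 0.5
        assert 0.3 < res["p_empirical"].median() < 0.7

    def test_determinism_given_seed(self):
        spec = PromoterSpec(n_promoters=120, length=100, gc_fraction=0.4, rng_seed=2)
        genome, _ = gen_promoters(spec)
        subset = {i: genome[i] for i in list(genome)[:20]}
        cfg = KmerNullConfig(k=5, n_background_sets=99, rng_seed=3)
        a = kmer_overrepresentation(subset, genome, cfg)
        b = kmer_overrepresentation(subset, genome, cfg)
        assert a.equals(b)

    def test_too_few_background_sets_rejected(self):
        with pytest.raises(ValueError):
            KmerNullConfig(k=5, n_background_sets=50)

    def test_genome_must_exceed_subset(self):
        subset = {"a": "ACGTACGT"}
        with pytest.raises(ValueError):
            kmer_overrepresentation(subset, subset, KmerNullConfig(k=4, n_background_sets=99))

    def test_containment_agrees_with_boyer_moore(self):
        spec = PromoterSpec(n_promoters=40, length=90, gc_fraction=0.5, rng_seed=4)
        genome, _ = gen_promoters(spec)
        subset = {i: genome[i] for i in list(genome)[:15]}
        res = kmer_overrepresentation(subset, genome,
                                      KmerNullConfig(k=6, n_background_sets=99, rng_seed=5))
        sample = res.sample(25, random_state=0)
        for kmer, observed in sample[["kmer", "observed"]].itertuples(index=False):
            direct = sum(boyer_moore_count(s, kmer) > 0 for s in subset.values())
            assert direct == observed
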