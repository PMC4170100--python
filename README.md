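# ssrnet

Guided-gene co-expression network analysis of the plant sugar-starvation
response, packaged as a tested, reusable pipeline.

When photosynthetic carbon runs out — as it does at the end of the night in
starch-deficient *Arabidopsis thaliana* mutants — a coordinated set of
sugar-starvation responsive (SSR) genes is induced. A guided-gene study
reconstructs this transcriptional program in four moves, all implemented
here:

1. **Recursive seed expansion** (`ssrnet.coexpression`). Starting from a
   curated seed list (the 13 SSR genes are bundled in
   `ssrnet.resources.SEED_GENES`), each round computes the squared Pearson
   correlation r² between the current query genes and every gene in an
   expression compendium, keeps edges with r² ≥ 0.36 (|r| ≥ 0.6,
   configurable), and promotes genes with ≥ 5 neighbors to the next query
   set. After 3 rounds the union edge set is pruned to genes with ≥ 2
   neighbors.
2. **Network structure** (`ssrnet.network`). Degree bins (<10, 10–99, ≥100
   neighbors; the last are candidate master regulators), a descriptive
   log–log degree slope, and MCODE module detection: vertex weight = core
   number k × density of the highest k-core of the closed neighborhood;
   greedy expansion from unvisited highest-weight seeds admitting neighbors
   with weight ≥ (1 − cutoff)·w_seed; module score = density × size.
3. **Differential expression** (`ssrnet.diffexpr`). Dye-swap pairs are
   sign-aligned, r_i = (forward − swapped)/2; genes with extreme replicate
   variance (0.1% tails) are excluded; the paired test pools the variance
   over all G genes, s² = Σ_g Σ_i (r_gi − m̄_g)² / (G(n−1)), giving
   t_g = m̄_g /√(s²/n) referred to the standard normal; Bonferroni-adjusted
   p ≤ 0.05 calls a gene up or down.
4. **Promoter motifs and integration** (`ssrnet.motifs`,
   `ssrnet.integrate`). Curated-motif containment counts are tested with
   exact binomial or hypergeometric upper tails (significance at p < 10⁻³);
   exhaustive k-mers are tested against an empirical null of B random
   size-matched promoter sets sampled from the genome set,
   p = (1 + #{null ≥ obs})/(B + 1), with counting by a hand-written
   overlap-aware Boyer–Moore searcher. Finally the network is
   cross-examined with the DE calls: Venn partitions across mutant lines,
   integer percentages (rounded half away from zero), and the DE status of
   each degree class.

A seeded synthetic-data module (`ssrnet.synthetic`) generates all inputs
with known planted structure — co-expression modules built from a shared
latent profile (gene = r·z + √(1−r²)·ε, so expected within-module
correlation is r² at unit noise), dye-swap arrays with an exact planted DE
fraction, and promoters with planted motif instances — so every stage is
testable without downloads.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (600 genes × 60 samples, two planted modules of 40 and 35 genes,
three mutant lines × dawn/dusk, GATAA planted in module-gene promoters):

```
python analysis/01_simulate.py
python analysis/02_expand_network.py
...
python analysis/06_integrate.py
```

`02_expand_network.py` prints the expansion trace — the 12 seeds pull in
the remaining 63 module genes in round 1 and the expansion converges:

```
 round  n_queries  n_edges  n_new_queries
     1         12      408             63
     2         75     1375              0
     3         75     1375              0
final network: 75 nodes, 1375 edges (pruned to degree >= 2)
```

`03_modules_and_hubs.py` recovers exactly the two planted modules
(score = density × size; both are near-cliques at r = 0.95):

```
MCODE found 2 module(s):
  module 1: size 40, score 40.00, seed g00000
  module 2: size 35, score 35.00, seed g00040
```

`05_promoter_motifs.py` flags the planted word against both backgrounds —
61/75 subset promoters contain GATAA vs a 44% genome containment
(hypergeometric p ≈ 3·10⁻¹², and the best empirical 5-mer p = 1/(999+1)):

```
 kmer  observed  null_mean  p_empirical
GATAA        61  33.251251        0.001
```

and `06_integrate.py` reports the cross-examination: all 75 network genes
are induced at dawn in all three mutant lines (100% of the network), none
at dusk, matching the planted design.

The same workflow runs as one call with a manifest:

```python
from ssrnet import run_pipeline, DEFAULT_CONFIG
manifest = run_pipeline({**DEFAULT_CONFIG, "seed": 1}, "out/")
```

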