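# Methods

## Scope and model

The package reconstructs a guided-gene transcriptional network and its
validation. The statistical objects are: (i) an expression compendium
(genes × samples) from which squared Pearson correlations are computed,
(ii) an undirected co-expression network whose edges carry r², (iii)
dye-swap log₂-ratio arrays analyzed with a pooled-variance paired test,
and (iv) promoter sequences tested for motif over-representation. The
working assumption throughout is the guilt-by-association premise of
co-expression analysis: genes acting in one program share expression
profiles across a large, heterogeneous sample compendium.

## Recursive seed expansion

Correlations are query-vs-genome, never all-vs-all: each round computes r²
only between the current query set and every other gene, which matches the
guided-gene design and keeps cost O(|queries|·G·S). "Significantly
co-expressed" is operationalized as r² ≥ `r2_cutoff` with default 0.36
(|r| ≥ 0.6); the cutoff is a first-class configuration value recorded in
the network provenance, because the upstream tool's "default settings" are
not a printed number. Genes with ≥ `expand_min_neighbors` (default 5)
edges in a round's graph become queries of the next round; query sets are
non-decreasing by construction, which makes the final gene set monotone
under cutoff relaxation (a property test). After `rounds` (default 3)
passes, the union edge set is pruned to `final_min_degree` (default 2).
Pruning is iterated (a k-core at k = 2) rather than applied once: a single
pass can leave nodes whose degree drops below the floor when their
neighbors are removed, and the stated invariant — every retained node has
degree ≥ the floor — must hold by construction.

Correlation details: Pearson on the matrix as provided (normalization is
declared upstream, no internal log-transform); pairs are computed on
mutually complete samples; pairs with fewer than 3 complete samples or a
zero-variance profile are omitted and logged; seeds absent from the
compendium are reported, and only an entirely absent seed list is an error.

## Degree classes and MCODE

Degree bins are [0,10), [10,100), [100,∞); genes above 100 neighbors are
hub/master-regulator candidates and genes above 25 neighbors form the
"structural" class checked against the dawn response. The log–log degree
slope is ordinary least squares of log-count on log-degree over degrees
≥ 1, reported descriptively with no significance claim, and flagged
undefined for degenerate (single-degree) networks.

MCODE follows the canonical algorithm: vertex weight = (density of the
highest k-core of the closed neighborhood) × (that core number); complexes
grow breadth-first from unvisited highest-weight seeds, admitting
neighbors with weight ≥ w_seed·(1 − `node_score_cutoff`), to `max_depth`;
haircut reduces a complex to its 2-core; complexes without a
`k_core`-core are discarded; score = density × size. Defaults are the
canonical ones (cutoff 0.2, k-core 2, haircut on, fluff off — fluff adds
periphery and is kept behind a flag since clean module membership is what
the downstream recovery tests score). All orderings are deterministic:
seeds by descending weight then node ID, modules by descending score, then
size, then member IDs; module detection is invariant under node relabeling
up to this tie-break (tested).

## Differential expression

Each biological replicate contributes a forward and a dye-swapped array.
The combination rule is r = (forward − swapped)/2, chosen so a true
log-ratio keeps a consistent sign while any gene-independent dye bias
cancels; note the averaged replicate has noise σ/√2 when each array has
noise σ. Genes with replicate variance outside the empirical
[0.001, 0.999] quantiles are excluded ("too small or too large"
variance), as are genes with fewer than two finite replicates. The paired
test assumes a common log-ratio variance for all genes:
s² = Σ_g Σ_i (r_gi − m̄_g)²/Σ_g (n_g − 1) over included genes, and
t_g = m̄_g/√(s²/n_g). With pooled degrees of freedom in the thousands the
standard normal reference is used; the difference from the matching t
distribution is below 10⁻⁴ in p and the choice is recorded in the output
metadata. Bonferroni uses m = genes surviving exclusion (an override is
provided); calls are up/down at adjusted p ≤ α = 0.05 with the sign of the
mean. Each comparison (mutant × time point) is analyzed independently,
with its own pooled variance; the pipeline accepts any number of dye-swap
pairs ≥ 2 and records the count.

## Motif over-representation

The enrichment statistic is promoter containment — the number of subset
promoters with ≥ 1 match — not the total hit count (a total-count mode
exists behind a flag). Matching is forward-strand by default (promoters
are assumed TSS-oriented); a reverse-complement flag is available and can
only increase containment. Curated motifs use exact tails — binomial when
the background is a containment frequency, hypergeometric when a full
promoterome is supplied — because the interesting p-values are extreme
tails where normal approximations fail. The exhaustive k-mer test samples
B (default 1000, minimum 99) random promoter sets of the subset's size
without replacement from the genome set and reports
p = (1 + #{null ≥ observed})/(B + 1), bounded below by 1/(B+1) and
deterministic given the seed. Counting is by an overlap-aware Boyer–Moore
searcher (bad-character + strong good-suffix tables; after a match the
shift is the pattern period, so "AAAA" occurs 3 times in "AAAAAA");
degenerate IUPAC patterns are expanded to concrete instances before
search. For the exhaustive scan, per-promoter k-mer presence is collected
with a rolling window, which is tested equivalent to per-pattern
Boyer–Moore counting.

## Integration

Venn partitions are computed exactly for 2–3 call sets (more sets are
rejected: the report format is Venn-bounded). Percentages are integer,
rounded half away from zero in exact rational arithmetic — the convention
that reproduces a printed report's 27% from 220/820, 77% from 2549/3332,
23% from 783/3332, 2% from 15/820 and 11% from 89/820. "Induced at dawn"
means call = up in the dawn comparison of a mutant line; time points are
independent comparisons and the report keeps all direction × time cells
per gene without collapsing, so genes down at dawn are counted whether or
not they also move at dusk.

## Synthetic data: what it emulates and what it does not

Planted co-expression modules use a latent-factor construction,
x_g = r·z_m + √(1−r²)·σ_noise·ε_g, chosen because the expected
within-module correlation is analytically known (r² at σ_noise = 1;
r²/(r² + (1−r²)σ²) in general), enabling oracle tests; background genes
are independent noise, under which E[r²] = 1/(S−1) for S samples. The DE
generator assigns exactly round(G·fraction) DE genes (not binomially) so
fixtures can assert exact counts, all with effect of one sign on the
forward array and the opposite on the swap. Promoters are i.i.d.
background at a stated GC fraction with planted instances at uniform
non-overlapping positions, IUPAC degeneracy resolved uniformly at
insertion time so ground truth is concrete.

None of this reproduces the marginal distributions of real microarray
compendia (no intensity-dependent noise, no sample correlation structure,
no array artifacts, no probe-to-gene ambiguity). Passing tests therefore
demonstrate that the algorithms recover structure they are designed to
detect under their own assumptions — not that the original biological
counts would be reproduced, which would require the original compendium
and hybridizations. The published network and overlap counts are bundled
as documented reference values only; the quantities recomputed from them
are their internal arithmetic (percentage identities, binomial tails).

## Problem sizes and numerical choices

The bundled study conditions were sized so each planted effect is
decisively detectable while the whole suite runs in seconds: compendia of
475–600 genes × 60 samples with modules of 35–50 genes at latent r = 0.95;
dye-swap experiments of 600–2000 genes × 3 pairs at σ = 0.25–0.3 with unit
effect; promoter sets of 500–600 × 500 bp at GC 0.5 (where a 5-mer's
natural containment is ≈ 40%, matching the background containment regime
of interest) with the planted word inserted at probability 0.78 to reach
≈ 85% subset containment; empirical nulls at B = 999 for the headline
k-mer check and B = 99–199 inside fast tests. Type-I calibration uses 20
null simulations of 2000 genes × 3 pairs.

Numerical conventions: correlations are clipped to [0,1] against rounding;
percentage rounding uses `fractions.Fraction` so x.5 cases never depend on
binary floating point; a pooled variance of exactly zero (noise-free
fixtures) maps non-zero means to p = 0 rather than dividing by zero; all
writers emit fixed float formats and sorted orderings, making full runs
byte-identical for a given configuration — the run manifest (seeds,
thresholds, versions, output digests) suffices to reproduce a run exactly.

## Known limitations

- The expansion's r² cutoff is a stated default, not a reconstruction of
  the original tool's unpublished setting; conclusions sensitive to it
  should sweep the cutoff (it is monotone: lowering it only adds genes).
- MCODE parameters likewise follow published defaults; the original
  module memberships cannot be validated without the original network.
- The pooled-variance test is anticonservative if the equal-variance
  assumption fails badly; the variance-exclusion step trims only the
  extreme 0.2% and is no substitute for per-gene moderation.
- Sequence shuffling nulls for the k-mer test are not implemented; the
  null is genome-sampled promoter sets, as in the word-counting tool this
  mirrors.
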