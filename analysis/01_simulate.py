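#!/usr/bin/env python
"""Generate the synthetic study inputs with known planted structure.

Emulates the data sources of a guided-gene sugar-starvation network study:
an expression compendium with two planted co-expressed modules (the latent
SSR program), dye-swap log-ratio arrays for three starch-deficient mutant
lines at dawn and dusk (module genes planted as dawn-induced), and 1000-bp
promoters in which the module genes carry a planted GATAA word on top of an
AT-rich background.  Everything is seeded and written under results/data/.
"""

from pathlib import Path

from ssrnet import CompendiumSpec, PromoterSpec, TwoColorSpec, gen_compendium, gen_promoters, gen_two_color
from ssrnet import io as sio

SEED = 1
DATA = Path("results/data")
MUTANTS = ["adg1", "adg1be2be3", "be2be3"]

DATA.mkdir(parents=True, exist_ok=True)

# --- compendium: 600 genes x 60 samples, modules of 40 and 35 genes --------
comp_spec = CompendiumSpec(n_genes=600, n_samples=60,
                           modules=((40, 0.95), (35, 0.95)), noise_sd=1.0,
                           rng_seed=SEED)
compendium, truth = gen_compendium(comp_spec)
sio.write_matrix_tsv(compendium, DATA / "compendium.tsv")
sio.write_table_tsv(truth.reset_index(), DATA / "module_truth.tsv")

module_genes = sorted(truth.index[truth["module"] >= 0])
seeds = (list(truth.index[truth["module"] == 0])[:6]
         + list(truth.index[truth["module"] == 1])[:6])
sio.write_gene_list(seeds, DATA / "seed_genes.txt")
print(f"compendium: {compendium.shape[0]} genes x {compendium.shape[1]} samples, "
      f"{len(module_genes)} genes in 2 planted modules, {len(seeds)} seed genes")

# --- dye-swap arrays: 3 mutants x dawn/dusk, 3 replicate pairs each ---------
gene_ids = list(compendium.index)
for m, mutant in enumerate(MUTANTS):
    for t, timepoint in enumerate(("dawn", "dusk")):
        de_genes = module_genes if timepoint == "dawn" else []
        spec = TwoColorSpec(n_genes=len(gene_ids), n_pairs=3,
                            de_fraction=len(de_genes) / len(gene_ids),
                            effect=1.0, sigma=0.25, rng_seed=SEED + 10 * m + 100 * t + 7)
        table, tr = gen_two_color(spec, de_genes=de_genes, gene_ids=gene_ids)
        label = f"{mutant}_{timepoint}"
        sio.write_ratio_table(table, DATA / f"ratios_{label}.tsv",
                              DATA / f"arrays_{label}.tsv")
        print(f"ratios {label}: {int(tr['is_de'].sum())} planted DE genes, "
              f"{table.values.shape[1]} arrays")

# --- promoters: AT-rich background; module genes carry a planted GATAA ------
bg, _ = gen_promoters(PromoterSpec(n_promoters=len(gene_ids), length=500,
                                   gc_fraction=0.5, rng_seed=SEED + 400))
promoters = dict(zip(gene_ids, bg.values()))
enriched, _ = gen_promoters(PromoterSpec(n_promoters=len(module_genes), length=500,
                                         gc_fraction=0.5,
                                         planted=(("GATAA", 0.78),),
                                         rng_seed=SEED + 401))
for gid, seq in zip(module_genes, enriched.values()):
    promoters[gid] = seq
sio.write_promoters_fasta(promoters, DATA / "promoters.fasta")
print(f"promoters: {len(promoters)} x 500 bp; GATAA planted at p=0.78 "
      f"in the {len(module_genes)} module-gene promoters")
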