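#!/usr/bin/env python
"""Promoter motif over-representation in the dawn-induced network genes.

Two routes: the curated-motif test (hypergeometric against the full
promoterome) on the bundled cis-elements, and the exhaustive 5-mer test
against an empirical null of 999 random size-matched promoter sets.
"""

from pathlib import Path

import pandas as pd

from ssrnet import KmerNullConfig, kmer_overrepresentation, known_motif_enrichment
from ssrnet import io as sio
from ssrnet.resources import KNOWN_MOTIFS

DATA, DE, NET = Path("results/data"), Path("results/de"), Path("results/network")
OUT = Path("results/motifs")
OUT.mkdir(parents=True, exist_ok=True)
MUTANTS = ["adg1", "adg1be2be3", "be2be3"]

promoters = sio.read_promoters_fasta(DATA / "promoters.fasta")
network_genes = set(sio.read_gene_list(NET / "network_genes.txt"))

up_dawn = set()
for mutant in MUTANTS:
    de = pd.read_csv(DE / f"de_{mutant}_dawn.tsv", sep="\t", index_col=0)
    up_dawn |= set(de.index[de["call"] == "up"])
subset_genes = sorted(up_dawn & network_genes)
subset = {g: promoters[g] for g in subset_genes}
print(f"subset: {len(subset)} promoters of dawn-induced network genes "
      f"vs {len(promoters)} genome promoters")

known = known_motif_enrichment(subset, KNOWN_MOTIFS, promoters, threshold=1e-3)
sio.write_table_tsv(known, OUT / "known_motif_enrichment.tsv")
print(known.to_string(index=False))

kmers = kmer_overrepresentation(subset, promoters,
                                KmerNullConfig(k=5, n_background_sets=999, rng_seed=99))
sio.write_table_tsv(kmers, OUT / "kmer_overrepresentation.tsv")
top = kmers.head(8)
print("top 5-mers by empirical p:")
print(top.to_string(index=False))
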