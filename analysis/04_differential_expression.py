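#!/usr/bin/env python
"""Call differential expression per mutant comparison.

For each mutant x time point: sign-align the dye-swap pairs, exclude
extreme-variance genes (0.1% tails), run the pooled-variance paired test,
Bonferroni-adjust, and call genes at adjusted p <= 0.05.
"""

import json
from pathlib import Path

from ssrnet import DEConfig, run_de
from ssrnet import io as sio
from ssrnet.diffexpr import de_summary

DATA, OUT = Path("results/data"), Path("results/de")
OUT.mkdir(parents=True, exist_ok=True)
MUTANTS = ["adg1", "adg1be2be3", "be2be3"]

cfg = DEConfig()
summaries = {}
for mutant in MUTANTS:
    for timepoint in ("dawn", "dusk"):
        label = f"{mutant}_{timepoint}"
        table = sio.read_ratio_table(DATA / f"ratios_{label}.tsv",
                                     DATA / f"arrays_{label}.tsv")
        de = run_de(table, cfg)
        sio.write_table_tsv(de.reset_index(), OUT / f"de_{label}.tsv")
        summaries[label] = de_summary(de)
        s = summaries[label]
        print(f"{label}: {s['n_up']} up, {s['n_down']} down, "
              f"{s['n_excluded']} excluded of {s['n_genes']} "
              f"(Bonferroni m={s['bonferroni_m']}, pooled s2={s['pooled_s2']:.4f})")

(OUT / "de_summaries.json").write_text(json.dumps(summaries, indent=2, sort_keys=True) + "\n")
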