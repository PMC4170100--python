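"""End-to-end synthetic pipeline: simulate, expand, analyze, cross-examine.

``run_pipeline`` executes the whole guided-gene workflow on generated data
with known planted structure: a compendium with planted co-expression
modules; recursive seed expansion to the network; degree/hub and MCODE
module analysis; dye-swap differential expression for three mutant lines at
dawn and dusk (module genes planted as dawn-induced); promoter motif
over-representation on the dawn-induced network genes; and the
cross-examination report.  All artifacts are written as TSV/JSON with fixed
formatting, and a machine-readable run manifest captures seeds, thresholds
and input digests so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .coexpression import ExpansionConfig, expand_seeds
from .diffexpr import DEConfig, de_summary, run_de
from .integrate import DECallSet, cross_examine, report_summary
from .motifs import KmerNullConfig, kmer_overrepresentation, known_motif_enrichment
from .network import (McodeParams, degree_summary, mcode, modules_to_frame,
                      scale_free_summary, write_edgelist_tsv, write_graphml, write_sif)
from .synthetic import CompendiumSpec, PromoterSpec, TwoColorSpec, gen_compendium, gen_promoters, gen_two_color

logger = logging.getLogger(__name__)

REQUIRED_SECTIONS = ("seed", "compendium", "expansion", "de", "promoters")

DEFAULT_CONFIG = {
    "seed": 0,
    "compendium": {"n_genes": 600, "n_samples": 60,
                   "modules": [[40, 0.95], [35, 0.95]], "noise_sd": 1.0},
    "seeds_per_module": 6,
    "expansion": {"r2_cutoff": 0.36, "expand_min_neighbors": 5,
                  "rounds": 3, "final_min_degree": 2},
    "mcode": {"node_score_cutoff": 0.2, "k_core": 2, "haircut": True, "fluff": False},
    "de": {"mutants": ["adg1", "adg1be2be3", "be2be3"], "n_pairs": 3,
           "sigma": 0.25, "effect": 1.0, "dusk_de_fraction": 0.01,
           "alpha": 0.05, "variance_exclusion_quantiles": [0.001, 0.999]},
    "promoters": {"length": 500, "gc_fraction": 0.5,
                  "planted_kmer": "GATAA", "subset_prob": 0.8},
    "kmer": {"k": 5, "n_background_sets": 199},
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _child_seed(seed: int, stage: int) -> int:
    return (int(seed) * 1000003 + 7919 * stage) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate_config(config: dict) -> None:
    missing = [k for k in REQUIRED_SECTIONS if k not in config]
    if missing:
        raise KeyError(f"pipeline config missing required section(s): {missing}")


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage in order and write all artifacts under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).  Any stage
    failure propagates with the stage named in the log.
    """
    _validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"config": config, "stage_seeds": {}, "outputs": {}, "summary": {}}

    # --- simulate: compendium with planted modules -------------------------
    logger.info("stage simulate: compendium")
    comp_cfg = config["compendium"]
    comp_seed = _child_seed(seed, 1)
    spec = CompendiumSpec(n_genes=comp_cfg["n_genes"], n_samples=comp_cfg["n_samples"],
                          modules=tuple(tuple(m) for m in comp_cfg["modules"]),
                          noise_sd=comp_cfg.get("noise_sd", 1.0), rng_seed=comp_seed)
    compendium, module_truth = gen_compendium(spec)
    manifest["stage_seeds"]["compendium"] = comp_seed
    sio.write_matrix_tsv(compendium, out / "compendium.tsv")
    sio.write_table_tsv(module_truth.reset_index(), out / "module_truth.tsv")

    per_module = config.get("seeds_per_module", 6)
    seeds = []
    for m in range(len(spec.modules)):
        members = module_truth.index[module_truth["module"] == m]
        seeds.extend(members[:per_module])
    sio.write_gene_list(seeds, out / "seed_genes.txt")

    # --- coexpress: recursive guided-gene expansion ------------------------
    logger.info("stage coexpress: %d seeds", len(seeds))
    exp_cfg = ExpansionConfig(**config["expansion"])
    expansion = expand_seeds(compendium, seeds, exp_cfg)
    net = expansion.network
    sio.write_table_tsv(expansion.edges, out / "network_edges.tsv")
    sio.write_table_tsv(expansion.round_log, out / "expansion_rounds.tsv")
    write_edgelist_tsv(net, out / "network_edgelist.tsv")
    write_sif(net, out / "network.sif")
    write_graphml(net, out / "network.graphml")

    # --- network: degree structure and MCODE modules -----------------------
    logger.info("stage network: %d nodes / %d edges", net.number_of_nodes(), net.number_of_edges())
    degrees = degree_summary(net)
    deg_frame = degrees.degrees.rename_axis("gene_id").reset_index()
    sio.write_table_tsv(deg_frame, out / "degree_summary.tsv")
    sf = scale_free_summary(net) if net.number_of_nodes() >= 10 else None

    mc_params = McodeParams(**config.get("mcode", {}))
    modules = mcode(net, mc_params)
    sio.write_table_tsv(modules_to_frame(modules), out / "mcode_modules.tsv")

    # --- de: dye-swap comparisons per mutant and time point ----------------
    de_cfg_raw = config["de"]
    de_cfg = DEConfig(alpha=de_cfg_raw.get("alpha", 0.05),
                      variance_exclusion_quantiles=tuple(
                          de_cfg_raw.get("variance_exclusion_quantiles", (0.001, 0.999))))
    gene_ids = list(compendium.index)
    planted = set(module_truth.index[module_truth["module"] >= 0])
    dusk_n = int(round(len(gene_ids) * de_cfg_raw.get("dusk_de_fraction", 0.0)))

    call_sets: list[DECallSet] = []
    de_summaries = {}
    stage = 10
    for mutant in de_cfg_raw["mutants"]:
        for timepoint in ("dawn", "dusk"):
            stage += 1
            s = _child_seed(seed, stage)
            if timepoint == "dawn":
                de_genes = sorted(planted)
            else:
                # a small unrelated set of dusk responders drawn per comparison
                import numpy as np
                rng = np.random.default_rng(s + 1)
                de_genes = sorted(rng.choice(gene_ids, size=dusk_n, replace=False)) if dusk_n else []
            tc_spec = TwoColorSpec(n_genes=len(gene_ids), n_pairs=de_cfg_raw["n_pairs"],
                                   de_fraction=len(de_genes) / len(gene_ids),
                                   effect=de_cfg_raw["effect"], sigma=de_cfg_raw["sigma"],
                                   rng_seed=s)
            table, truth = gen_two_color(tc_spec, de_genes=de_genes, gene_ids=gene_ids)
            label = f"{mutant}_{timepoint}"
            logger.info("stage de: comparison %s", label)
            de = run_de(table, de_cfg)
            sio.write_table_tsv(de.reset_index(), out / f"de_{label}.tsv")
            de_summaries[label] = de_summary(de)
            manifest["stage_seeds"][f"de_{label}"] = s
            call_sets.append(DECallSet(label, mutant, timepoint, de["call"]))
    (out / "de_summaries.json").write_text(json.dumps(de_summaries, indent=2, sort_keys=True) + "\n")

    # --- integrate: cross-examination --------------------------------------
    logger.info("stage integrate")
    report = cross_examine(net, degrees, call_sets)
    overlap = report_summary(report)
    sio.write_table_tsv(report.per_comparison, out / "overlap_per_comparison.tsv")
    sio.write_gene_list(sorted(report.up_dawn_any), out / "up_dawn_any.txt")
    (out / "overlap_summary.json").write_text(json.dumps(overlap, indent=2, sort_keys=True) + "\n")

    # --- motifs: promoter enrichment of dawn-induced network genes ---------
    prom_cfg = config["promoters"]
    subset_genes = sorted(report.up_dawn_any)
    prom_seed = _child_seed(seed, 40)
    kmer_word = prom_cfg.get("planted_kmer", "GATAA")
    logger.info("stage motifs: %d subset promoters", len(subset_genes))

    bg_spec = PromoterSpec(n_promoters=len(gene_ids), length=prom_cfg["length"],
                           gc_fraction=prom_cfg["gc_fraction"], planted=(),
                           rng_seed=prom_seed)
    bg_prom, _ = gen_promoters(bg_spec)
    promoters = dict(zip(gene_ids, bg_prom.values()))
    if subset_genes:
        sub_spec = PromoterSpec(n_promoters=len(subset_genes), length=prom_cfg["length"],
                                gc_fraction=prom_cfg["gc_fraction"],
                                planted=((kmer_word, prom_cfg.get("subset_prob", 0.8)),),
                                rng_seed=_child_seed(seed, 41))
        sub_prom, _ = gen_promoters(sub_spec)
        for gid, seq in zip(subset_genes, sub_prom.values()):
            promoters[gid] = seq
    sio.write_promoters_fasta(promoters, out / "promoters.fasta")
    manifest["stage_seeds"]["promoters"] = prom_seed

    subset = {g: promoters[g] for g in subset_genes}
    kmer_frame = pd.DataFrame()
    if subset:
        kn = KmerNullConfig(k=config.get("kmer", {}).get("k", 5),
                            n_background_sets=config.get("kmer", {}).get("n_background_sets", 199),
                            rng_seed=_child_seed(seed, 42))
        kmer_frame = kmer_overrepresentation(subset, promoters, kn)
        sio.write_table_tsv(kmer_frame, out / "kmer_overrepresentation.tsv")

    # --- manifest -----------------------------------------------------------
    from . import __version__
    manifest["version"] = __version__
    manifest["summary"] = {
        "n_seeds": len(seeds),
        "network_nodes": net.number_of_nodes(),
        "network_edges": net.number_of_edges(),
        "degree_bins": list(degrees.bins),
        "loglog_slope": None if sf is None else sf.slope,
        "n_mcode_modules": len(modules),
        "mcode_scores": [round(m.score, 6) for m in modules[:5]],
        "overlap": overlap,
        "de": de_summaries,
        "planted_kmer": kmer_word,
        "planted_kmer_p": (float(kmer_frame.loc[kmer_frame["kmer"] == kmer_word,
                                                "p_empirical"].iloc[0])
                           if len(kmer_frame) and (kmer_frame["kmer"] == kmer_word).any()
                           else None),
    }
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
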