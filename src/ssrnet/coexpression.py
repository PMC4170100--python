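"""Query-vs-genome squared correlation and recursive guided-gene expansion.

The guided-gene design starts from a curated seed list and computes squared
Pearson correlations between the current query set and every other gene in
the compendium (never all-vs-all).  Genes acquiring enough neighbors above
the r-squared cutoff are promoted to queries for the next round; after a
fixed number of rounds the union edge set is pruned to the genes with at
least ``final_min_degree`` neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpansionConfig:
    """Thresholds of the recursive expansion.

    r2_cutoff
        minimum squared Pearson correlation for an edge (the tool default
        of 0.36 corresponds to |r| >= 0.6).
    expand_min_neighbors
        neighbors a non-query gene needs in a round's graph to become a
        query of the next round.
    rounds
        total correlation passes (an initial pass plus recursive ones).
    final_min_degree
        minimum degree for membership in the final network; pruning is
        iterated so every retained node satisfies it.
    """

    r2_cutoff: float = 0.36
    expand_min_neighbors: int = 5
    rounds: int = 3
    final_min_degree: int = 2

    def __post_init__(self):
        if not 0.0 < self.r2_cutoff < 1.0:
            raise ValueError("r2_cutoff must lie in (0, 1)")
        if self.expand_min_neighbors < 1 or self.final_min_degree < 1:
            raise ValueError("neighbor thresholds must be positive")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


def _validate_compendium(compendium: pd.DataFrame) -> None:
    if compendium.index.has_duplicates:
        dups = compendium.index[compendium.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in compendium: {dups[:5]}")
    if compendium.shape[1] < 3:
        raise ValueError("compendium must have at least 3 samples")


def resolve_queries(compendium: pd.DataFrame, queries) -> list[str]:
    """Intersect a query list with the compendium, reporting absentees.

    Missing queries are logged (never silently dropped); if none resolve, a
    hard error lists them all.
    """
    queries = list(dict.fromkeys(queries))
    if not queries:
        raise ValueError("query set is empty")
    present = [q for q in queries if q in compendium.index]
    absent = [q for q in queries if q not in compendium.index]
    if not present:
        raise ValueError(f"no query gene found in compendium: {absent}")
    if absent:
        logger.warning("%d query gene(s) absent from compendium: %s", len(absent), absent)
    return present


def pairwise_r2(compendium: pd.DataFrame, queries) -> pd.DataFrame:
    """Squared Pearson correlation of each query against every other gene.

    Pairs are computed on mutually complete samples; pairs with fewer than 3
    complete samples or with a zero-variance profile are omitted and logged.
    Returns a table with columns ``query``, ``target``, ``r2``.
    """
    _validate_compendium(compendium)
    present = resolve_queries(compendium, queries)

    values = compendium.to_numpy(dtype=float)
    finite = np.isfinite(values)
    gene_ids = np.asarray(compendium.index)
    qpos = {g: i for i, g in enumerate(gene_ids)}

    out_q, out_t, out_r2 = [], [], []
    n_omitted = 0
    for q in present:
        x = values[qpos[q]]
        fx = finite[qpos[q]]
        mask = finite & fx  # per-gene complete-sample masks vs this query
        counts = mask.sum(axis=1)
        xm = np.where(mask, x, 0.0)
        ym = np.where(mask, values, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_x = xm.sum(axis=1) / counts
            mean_y = ym.sum(axis=1) / counts
            dx = np.where(mask, x - mean_x[:, None], 0.0)
            dy = np.where(mask, values - mean_y[:, None], 0.0)
            sxy = (dx * dy).sum(axis=1)
            sxx = (dx * dx).sum(axis=1)
            syy = (dy * dy).sum(axis=1)
            r2 = (sxy * sxy) / (sxx * syy)
        valid = (counts >= 3) & (sxx > 0) & (syy > 0)
        valid[qpos[q]] = False  # no self-pair
        n_omitted += int((~valid).sum()) - 1
        out_q.append(np.full(valid.sum(), q, dtype=object))
        out_t.append(gene_ids[valid])
        out_r2.append(np.clip(r2[valid], 0.0, 1.0))

    if n_omitted:
        logger.info("pairwise_r2: omitted %d pair(s) (zero variance or <3 complete samples)",
                    n_omitted)
    return pd.DataFrame({
        "query": np.concatenate(out_q) if out_q else [],
        "target": np.concatenate(out_t) if out_t else [],
        "r2": np.concatenate(out_r2) if out_r2 else [],
    })


def threshold_edges(table: pd.DataFrame, r2_cutoff: float) -> pd.DataFrame:
    """Deduplicated undirected edges with r2 >= cutoff.

    (a, b) and (b, a) records collapse onto one edge keyed by the sorted
    pair; each edge keeps its r2 weight.
    """
    if not 0.0 < r2_cutoff < 1.0:
        raise ValueError("r2_cutoff must lie in (0, 1)")
    kept = table.loc[table["r2"] >= r2_cutoff]
    if kept.empty:
        return pd.DataFrame(columns=["u", "v", "r2"])
    u = np.minimum(kept["query"].to_numpy(dtype=object), kept["target"].to_numpy(dtype=object))
    v = np.maximum(kept["query"].to_numpy(dtype=object), kept["target"].to_numpy(dtype=object))
    edges = pd.DataFrame({"u": u, "v": v, "r2": kept["r2"].to_numpy()})
    edges = edges.groupby(["u", "v"], as_index=False, sort=True)["r2"].max()
    return edges


@dataclass
class ExpansionResult:
    """Outcome of the recursive expansion: final network plus a round log."""

    network: nx.Graph
    edges: pd.DataFrame                       # final pruned edge table (u, v, r2)
    genes_per_round: list[set[str]]           # query set entering each round
    round_log: pd.DataFrame                   # n_queries, n_edges, n_new per round
    config: ExpansionConfig


def expand_seeds(compendium: pd.DataFrame, seeds, cfg: ExpansionConfig = ExpansionConfig()
                 ) -> ExpansionResult:
    """Recursive guided-gene expansion from a seed list.

    Round 1 queries are the seeds; each round thresholds the query-vs-genome
    correlations at ``cfg.r2_cutoff`` and promotes genes with at least
    ``cfg.expand_min_neighbors`` neighbors in that round's graph to the next
    query set (query sets are non-decreasing).  After ``cfg.rounds`` rounds
    the union edge set is pruned to nodes of degree >= final_min_degree.
    """
    queries = set(resolve_queries(compendium, seeds))
    all_edges: list[pd.DataFrame] = []
    genes_per_round: list[set[str]] = []
    log_rows = []

    for rnd in range(1, cfg.rounds + 1):
        genes_per_round.append(set(queries))
        table = pairwise_r2(compendium, sorted(queries))
        edges = threshold_edges(table, cfg.r2_cutoff)
        all_edges.append(edges)

        g = nx.Graph()
        g.add_edges_from(zip(edges["u"], edges["v"]))
        promoted = {n for n in g if g.degree[n] >= cfg.expand_min_neighbors}
        new = promoted - queries
        log_rows.append({"round": rnd, "n_queries": len(queries),
                         "n_edges": len(edges), "n_new_queries": len(new)})
        queries |= new
        if not new and rnd < cfg.rounds:
            logger.info("expansion converged after round %d", rnd)

    union = pd.concat(all_edges, ignore_index=True)
    if union.empty:
        logger.warning("expansion produced no edges above r2 >= %.3f", cfg.r2_cutoff)
        net = nx.Graph()
        final_edges = pd.DataFrame(columns=["u", "v", "r2"])
    else:
        union = union.groupby(["u", "v"], as_index=False, sort=True)["r2"].max()
        g = nx.Graph()
        for u, v, r2 in union.itertuples(index=False):
            g.add_edge(u, v, r2=float(r2))
        net = nx.k_core(g, cfg.final_min_degree).copy()
        keep = union["u"].isin(net.nodes) & union["v"].isin(net.nodes)
        final_edges = union.loc[keep].reset_index(drop=True)

    net.graph["expansion_config"] = cfg
    round_log = pd.DataFrame(log_rows)
    return ExpansionResult(net, final_edges, genes_per_round, round_log, cfg)
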