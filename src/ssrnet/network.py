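"""Degree structure, scale-free summary, and MCODE module detection.

The network is a simple undirected :class:`networkx.Graph` whose edges carry
the squared-correlation weight.  Degree classification follows the hub
convention used for guided-gene networks: genes with fewer than 10 neighbors,
10-99 neighbors, and at least 100 neighbors (candidate master regulators),
plus the "structural" class of genes with more than 25 neighbors.

MCODE (molecular complex detection) is implemented from its canonical
description: vertices are weighted by the density of the highest k-core of
their closed neighborhood times that core number; complexes grow greedily
from unvisited highest-weight seeds, admitting neighbors whose weight is
within ``node_score_cutoff`` of the seed weight; an optional haircut removes
singly-connected members; complexes are ranked by score = density x size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEGREE_BIN_EDGES = (10, 100)   # [0,10), [10,100), [100,inf)
HUB_DEGREE = 100               # "more than 100 neighbors"
STRUCTURAL_DEGREE = 25         # "more than 25 neighbors"


@dataclass
class DegreeSummary:
    degrees: pd.Series                 # per-node degree, sorted desc then by ID
    bins: tuple[int, int, int]         # counts in [0,10), [10,100), [100,inf)
    hubs: list[str]                    # degree > 100
    structural: list[str]              # degree > 25 (superset of hubs)


def degree_summary(net: nx.Graph) -> DegreeSummary:
    """Exact per-node degrees, degree-class bins, and hub/structural lists."""
    if net.number_of_nodes() == 0:
        logger.warning("degree_summary called on an empty network")
        return DegreeSummary(pd.Series(dtype=int), (0, 0, 0), [], [])
    deg = pd.Series(dict(net.degree()), name="degree")
    deg = deg.sort_index().sort_values(ascending=False, kind="stable")
    lo, hi = DEGREE_BIN_EDGES
    bins = (int((deg < lo).sum()),
            int(((deg >= lo) & (deg < hi)).sum()),
            int((deg >= hi).sum()))
    hubs = deg.index[deg > HUB_DEGREE].tolist()
    structural = deg.index[deg > STRUCTURAL_DEGREE].tolist()
    return DegreeSummary(deg, bins, hubs, structural)


@dataclass
class ScaleFreeSummary:
    histogram: pd.Series        # degree -> node count, degrees >= 1
    ccdf: pd.Series             # degree -> P(D >= degree)
    slope: float | None         # log-log least-squares slope; None if undefined


def scale_free_summary(net: nx.Graph) -> ScaleFreeSummary:
    """Degree histogram, complementary CDF, and descriptive log-log slope.

    The slope is ordinary least squares of log(count) on log(degree) over
    degrees >= 1; it is reported descriptively, with no significance claim,
    and flagged None when fewer than two distinct degrees exist.
    """
    if net.number_of_nodes() < 10:
        raise ValueError("scale_free_summary needs at least 10 nodes")
    deg = np.array([d for _, d in net.degree()])
    deg = deg[deg >= 1]
    degrees, counts = np.unique(deg, return_counts=True)
    hist = pd.Series(counts, index=degrees, name="count")
    n = counts.sum()
    ccdf = pd.Series(counts[::-1].cumsum()[::-1] / n, index=degrees, name="ccdf")
    if len(degrees) < 2:
        logger.warning("degenerate degree distribution; log-log slope undefined")
        slope = None
    else:
        slope = float(np.polyfit(np.log(degrees), np.log(counts), 1)[0])
    return ScaleFreeSummary(hist, ccdf, slope)


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McodeParams:
    """Canonical MCODE parameters (Bader-Hogue defaults)."""

    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    max_depth: int = 100

    def __post_init__(self):
        if not 0.0 <= self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1)")
        if self.k_core < 1 or self.max_depth < 1:
            raise ValueError("k_core and max_depth must be positive")


@dataclass
class NetworkModule:
    members: tuple[str, ...]    # sorted node IDs
    score: float                # density x size
    seed: str                   # seed vertex the complex grew from

    @property
    def size(self) -> int:
        return len(self.members)


def graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The maximal-k k-core of ``g`` and its core number."""
    if g.number_of_edges() == 0:
        return 0, g.subgraph([])
    core = nx.core_number(g)
    kmax = max(core.values())
    nodes = [v for v, c in core.items() if c == kmax]
    return kmax, g.subgraph(nodes)


def mcode_vertex_weights(net: nx.Graph) -> dict[str, float]:
    """Core-clustering vertex weight: density of the highest k-core of the
    closed neighborhood, multiplied by that core number."""
    weights = {}
    for v in net:
        closed = list(net[v]) + [v]
        k, core = _highest_kcore(net.subgraph(closed))
        weights[v] = k * graph_density(core)
    return weights


def mcode(net: nx.Graph, params: McodeParams = McodeParams()) -> list[NetworkModule]:
    """Rank densely interconnected modules by MCODE score.

    Deterministic: seeds are taken in order of descending weight with
    lexicographic node-ID tie-break; modules are ranked by descending score,
    then size, then member IDs.  With ``haircut`` the complex is reduced to
    its 2-core (iterated removal of singly-connected members); complexes
    whose subgraph contains no ``k_core``-core are discarded.
    """
    if any(u == v for u, v in net.edges()):
        raise ValueError("MCODE requires a simple graph (self-loop found)")
    if net.number_of_nodes() == 0:
        return []
    w = mcode_vertex_weights(net)
    order = sorted(net.nodes, key=lambda v: (-w[v], str(v)))
    visited: set = set()
    modules: list[NetworkModule] = []

    for seed in order:
        if seed in visited or w[seed] <= 0.0:
            continue
        threshold = w[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for node in frontier:
                for nb in sorted(net[node], key=str):
                    if nb in members or nb in visited:
                        continue
                    if w[nb] >= threshold:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        visited |= members

        sub = net.subgraph(members)
        if params.haircut:
            sub = nx.k_core(sub, 2)
        if sub.number_of_nodes() < 2 or sub.number_of_edges() == 0:
            continue
        if max(nx.core_number(sub).values()) < params.k_core:
            continue
        if params.fluff:
            extra = set()
            for v in sorted(sub.nodes, key=str):
                for nb in net[v]:
                    if nb in sub or nb in extra:
                        continue
                    closed = list(net[nb]) + [nb]
                    if graph_density(net.subgraph(closed)) > params.fluff_density_cutoff:
                        extra.add(nb)
            sub = net.subgraph(set(sub.nodes) | extra)
        score = graph_density(sub) * sub.number_of_nodes()
        modules.append(NetworkModule(tuple(sorted(sub.nodes, key=str)), score, seed))

    modules.sort(key=lambda m: (-m.score, -m.size, m.members))
    return modules


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_edgelist_tsv(net: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v), net[u][v].get("r2", float("nan")))
                  for u, v in net.edges())
    with open(path, "w") as fh:
        fh.write("u\tv\tr2\n")
        for u, v, r2 in rows:
            fh.write(f"{u}\t{v}\t{r2:.6g}\n")


def write_sif(net: nx.Graph, path, interaction: str = "co") -> None:
    """Simple interaction format for Cytoscape import."""
    with open(path, "w") as fh:
        for u, v, _ in sorted((min(u, v), max(u, v), 0) for u, v in net.edges()):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in sorted(nx.isolates(net)):
            fh.write(f"{n}\n")


def write_graphml(net: nx.Graph, path) -> None:
    g = net.copy()
    g.graph.pop("expansion_config", None)  # GraphML values must be scalars
    nx.write_graphml(g, path)


def modules_to_frame(modules: list[NetworkModule]) -> pd.DataFrame:
    return pd.DataFrame({
        "module_id": range(1, len(modules) + 1),
        "score": [m.score for m in modules],
        "size": [m.size for m in modules],
        "seed": [m.seed for m in modules],
        "members": [",".join(m.members) for m in modules],
    })
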