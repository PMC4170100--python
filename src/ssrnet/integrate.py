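"""Cross-examination of network membership with differential-expression calls.

This is the validation logic of a guided-gene study: the co-expression
network, built from public compendium data, is confronted with independent
differential-expression calls from mutant comparisons at two diurnal time
points.  The module computes exact Venn partitions over call sets, overlap
counts and integer percentages of the network (rounded half away from
zero, the convention that reproduces printed report percentages from their
own counts), and the per-degree-class DE status table used to check that
highly connected genes respond to the treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

import networkx as nx
import pandas as pd

from .network import DegreeSummary, STRUCTURAL_DEGREE

logger = logging.getLogger(__name__)

CALLS = ("up", "down", "unchanged", "excluded")


def round_pct(count: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero.

    Computed in exact rational arithmetic so boundary cases (x.5) never
    depend on binary floating point.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    q = Fraction(100 * count, denominator)
    return int((2 * q + 1) // 2)  # floor(q + 1/2) for non-negative q


@dataclass
class DECallSet:
    """Per-gene DE calls for one comparison (e.g. one mutant at one time point)."""

    label: str
    mutant: str
    timepoint: str          # "dawn" or "dusk"
    calls: pd.Series        # gene ID -> call in CALLS

    def __post_init__(self):
        bad = set(self.calls.unique()) - set(CALLS)
        if bad:
            raise ValueError(f"unknown calls in {self.label!r}: {sorted(bad)}")
        if self.calls.index.has_duplicates:
            raise ValueError(f"duplicate gene IDs in {self.label!r}")

    def genes(self, direction: str) -> set[str]:
        return set(self.calls.index[self.calls == direction])


def venn_partition(sets: dict[str, set]) -> dict[tuple[str, ...], set]:
    """Exact disjoint Venn regions of 2-3 labelled sets.

    Returns a mapping from the tuple of member labels (each non-empty
    combination, in input label order) to the genes belonging to exactly
    those sets.  More than 3 sets is rejected: the report format is
    Venn-bounded even though the partition math would generalize.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("venn_partition takes 2 or 3 sets")
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], set] = {}
    for flags in product([True, False], repeat=len(labels)):
        if not any(flags):
            continue
        inside = [l for l, f in zip(labels, flags) if f]
        outside = [l for l, f in zip(labels, flags) if not f]
        region = set.intersection(*(sets[l] for l in inside)) if inside else set(universe)
        for l in outside:
            region -= sets[l]
        regions[tuple(inside)] = region
    return regions


def venn_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    return {k: len(v) for k, v in venn_partition(sets).items()}


@dataclass
class OverlapReport:
    """Cross-examination of a network with per-comparison DE calls."""

    network_size: int
    per_comparison: pd.DataFrame       # label, mutant, timepoint, n_up, n_down in network
    up_dawn_any: set
    up_dawn_all: set
    down_dawn_any: set
    down_dawn_all: set
    changed_dusk_any: set              # up or down at dusk in >= 1 mutant
    stable: set                        # network genes unchanged in every comparison
    venn_up_dawn: dict[tuple[str, ...], set]
    percentages: dict[str, int]
    degree_class_table: pd.DataFrame   # per degree class: n, n_up_dawn_any
    structural_up_dawn_fraction: float | None  # fraction of degree > 25 genes up at dawn in >= 1; None if class empty
    unmatched_genes: int


def cross_examine(net: nx.Graph, degrees: DegreeSummary,
                  calls: list[DECallSet]) -> OverlapReport:
    """Confront network membership with DE calls across mutant comparisons.

    Counts network genes up/down per comparison, the genes up at dawn in at
    least one and in all mutant lines, integer percentages of network size,
    and the DE status of each degree class (including the structural check
    that genes with more than 25 neighbors respond at dawn).
    """
    net_genes = set(net.nodes)
    if not net_genes:
        raise ValueError("empty network")
    universe = set().union(*(set(c.calls.index) for c in calls))
    matched = net_genes & universe
    if not matched:
        raise ValueError("no overlap between network gene IDs and DE call gene IDs")
    unmatched = len(net_genes - universe)
    if unmatched:
        logger.warning("%d network gene(s) absent from DE call universe", unmatched)

    dawn = [c for c in calls if c.timepoint == "dawn"]
    dusk = [c for c in calls if c.timepoint == "dusk"]

    rows = []
    for c in calls:
        rows.append({"label": c.label, "mutant": c.mutant, "timepoint": c.timepoint,
                     "n_up": len(c.genes("up") & net_genes),
                     "n_down": len(c.genes("down") & net_genes)})
    per_comparison = pd.DataFrame(rows)

    def any_all(call_sets: list[DECallSet], direction: str) -> tuple[set, set]:
        gene_sets = [c.genes(direction) & net_genes for c in call_sets]
        if not gene_sets:
            return set(), set()
        return set().union(*gene_sets), set.intersection(*gene_sets)

    up_dawn_any, up_dawn_all = any_all(dawn, "up")
    down_dawn_any, down_dawn_all = any_all(dawn, "down")
    dusk_up_any, _ = any_all(dusk, "up")
    dusk_down_any, _ = any_all(dusk, "down")
    changed_dusk_any = dusk_up_any | dusk_down_any
    changed_any = up_dawn_any | down_dawn_any | changed_dusk_any
    stable = net_genes - changed_any

    n = len(net_genes)
    percentages = {
        "up_dawn_any": round_pct(len(up_dawn_any), n),
        "down_dawn_any": round_pct(len(down_dawn_any), n),
        "changed_dusk_any": round_pct(len(changed_dusk_any), n),
        "stable": round_pct(len(stable), n),
    }

    venn_up_dawn = (venn_partition({c.mutant: c.genes("up") & net_genes for c in dawn})
                    if 2 <= len(dawn) <= 3 else {})

    deg = degrees.degrees
    classes = [("<10", deg.index[deg < 10]),
               ("10-99", deg.index[(deg >= 10) & (deg < 100)]),
               (">=100", deg.index[deg >= 100])]
    class_rows = []
    for name, idx in classes:
        members = set(idx)
        class_rows.append({"degree_class": name, "n": len(members),
                           "n_up_dawn_any": len(members & up_dawn_any)})
    degree_class_table = pd.DataFrame(class_rows)

    structural = set(degrees.structural)  # degree > 25
    structural_fraction = (len(structural & up_dawn_any) / len(structural)
                           if structural else None)

    return OverlapReport(
        network_size=n, per_comparison=per_comparison,
        up_dawn_any=up_dawn_any, up_dawn_all=up_dawn_all,
        down_dawn_any=down_dawn_any, down_dawn_all=down_dawn_all,
        changed_dusk_any=changed_dusk_any, stable=stable,
        venn_up_dawn=venn_up_dawn, percentages=percentages,
        degree_class_table=degree_class_table,
        structural_up_dawn_fraction=structural_fraction,
        unmatched_genes=unmatched,
    )


def report_summary(report: OverlapReport) -> dict:
    """Flat JSON-friendly summary of an overlap report."""
    return {
        "network_size": report.network_size,
        "n_up_dawn_any": len(report.up_dawn_any),
        "n_up_dawn_all": len(report.up_dawn_all),
        "n_down_dawn_any": len(report.down_dawn_any),
        "n_down_dawn_all": len(report.down_dawn_all),
        "n_changed_dusk_any": len(report.changed_dusk_any),
        "n_stable": len(report.stable),
        "percentages": report.percentages,
        "venn_up_dawn": {"+".join(k): len(v) for k, v in report.venn_up_dawn.items()},
        "structural_up_dawn_fraction": report.structural_up_dawn_fraction,
        "structural_degree": STRUCTURAL_DEGREE,
        "unmatched_genes": report.unmatched_genes,
    }
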