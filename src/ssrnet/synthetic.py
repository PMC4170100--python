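"""Seeded generators for synthetic pipeline inputs.

Three generators stand in for the data sources a guided-gene network study
draws on: a gene x sample expression compendium with planted co-expressed
modules, two-color dye-swap log-ratio arrays with a planted fraction of
differentially expressed genes, and upstream promoter sequences with planted
cis-element instances.  Every generator takes an explicit integer seed and is
bit-reproducible; every planted feature is returned as ground truth so
downstream stages can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_iupac(pattern: str, max_instances: int = 4096) -> list[str]:
    """Expand an IUPAC degenerate pattern into its concrete DNA instances.

    Raises ValueError on characters outside the IUPAC alphabet or when the
    expansion would exceed ``max_instances`` strings.
    """
    pattern = pattern.upper()
    choices = []
    n = 1
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
        choices.append(IUPAC_CODES[ch])
        n *= len(IUPAC_CODES[ch])
        if n > max_instances:
            raise ValueError(f"pattern {pattern!r} expands to more than {max_instances} instances")
    return ["".join(p) for p in product(*choices)]


# ---------------------------------------------------------------------------
# Expression compendium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompendiumSpec:
    """Parameters of a planted-module expression compendium.

    Each planted module is a (size, latent_r) pair: its genes are built as
    ``latent_r * z + sqrt(1 - latent_r**2) * noise_sd * eps`` where ``z`` is a
    module-shared latent sample profile and ``eps`` gene-specific noise, so
    at ``noise_sd = 1`` the expected pairwise Pearson correlation within a
    module is ``latent_r**2``.  Genes outside any module are independent
    noise with standard deviation ``noise_sd``.
    """

    n_genes: int
    n_samples: int
    modules: tuple[tuple[int, float], ...] = ()
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "modules", tuple((int(s), float(r)) for s, r in self.modules))
        for size, r in self.modules:
            if size <= 0:
                raise ValueError("module sizes must be positive")
            if not 0.0 <= r <= 1.0:
                raise ValueError("latent_r must lie in [0, 1]")
        if sum(s for s, _ in self.modules) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")


def gen_compendium(spec: CompendiumSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a genes x samples compendium with planted co-expression modules.

    Returns ``(compendium, truth)`` where ``compendium`` is a DataFrame
    indexed by gene ID with sample-ID columns, and ``truth`` has one row per
    gene with its planted module index (-1 for background noise genes).
    """
    rng = np.random.default_rng(spec.rng_seed)
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{j:03d}" for j in range(spec.n_samples)]
    values = np.empty((spec.n_genes, spec.n_samples))
    membership = np.full(spec.n_genes, -1, dtype=int)

    row = 0
    for m, (size, latent_r) in enumerate(spec.modules):
        shared = rng.standard_normal(spec.n_samples)
        eps = rng.standard_normal((size, spec.n_samples))
        values[row:row + size] = (
            latent_r * shared
            + math.sqrt(1.0 - latent_r ** 2) * spec.noise_sd * eps
        )
        membership[row:row + size] = m
        row += size
    n_noise = spec.n_genes - row
    if n_noise:
        values[row:] = spec.noise_sd * rng.standard_normal((n_noise, spec.n_samples))

    compendium = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                              columns=sample_ids)
    truth = pd.DataFrame({"gene_id": gene_ids, "module": membership}).set_index("gene_id")
    return compendium, truth


# ---------------------------------------------------------------------------
# Two-color dye-swap arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoColorSpec:
    """Parameters of a dye-swap log-ratio experiment.

    ``n_pairs`` biological replicates each contribute a forward and a
    dye-swapped array.  An exact ``round(n_genes * de_fraction)`` genes are
    differentially expressed with mean log2-ratio ``effect``; all arrays
    carry i.i.d. normal noise of standard deviation ``sigma``.
    """

    n_genes: int
    n_pairs: int
    de_fraction: float = 0.0
    effect: float = 1.0
    sigma: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class RatioTable:
    """Log2-ratio matrix (genes x arrays) with per-array dye orientation."""

    values: pd.DataFrame
    arrays: pd.DataFrame  # columns: array_id, replicate_id, orientation

    def __post_init__(self):
        required = {"array_id", "replicate_id", "orientation"}
        if not required.issubset(self.arrays.columns):
            raise ValueError(f"array metadata needs columns {sorted(required)}")
        bad = set(self.arrays["orientation"]) - {"forward", "swapped"}
        if bad:
            raise ValueError(f"unknown dye orientations: {sorted(bad)}")
        if list(self.arrays["array_id"]) != list(self.values.columns):
            raise ValueError("array metadata does not match ratio columns")


def gen_two_color(spec: TwoColorSpec, de_genes: list[str] | None = None,
                  gene_ids: list[str] | None = None) -> tuple[RatioTable, pd.DataFrame]:
    """Generate dye-swap log-ratio arrays with planted differential expression.

    Each replicate ``j`` contributes arrays ``rep{j}_fwd`` (expected ratio
    ``+effect`` for DE genes) and ``rep{j}_swp`` (dye-swapped, expected
    ``-effect``).  ``de_genes`` optionally fixes which genes carry the
    effect; by default a seeded random subset of exact size
    ``round(n_genes * de_fraction)`` is drawn.

    Returns ``(table, truth)``; ``truth`` has boolean ``is_de`` and the
    planted mean log-ratio per gene.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    elif len(gene_ids) != spec.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    if de_genes is None:
        n_de = int(round(spec.n_genes * spec.de_fraction))
        de_idx = rng.choice(spec.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        de_mask = np.zeros(spec.n_genes, dtype=bool)
        de_mask[de_idx] = True
    else:
        missing = set(de_genes) - set(gene_ids)
        if missing:
            raise ValueError(f"de_genes not in gene_ids: {sorted(missing)[:5]}")
        de_mask = np.isin(gene_ids, list(de_genes))

    delta = np.where(de_mask, spec.effect, 0.0)
    cols, data, meta = [], [], []
    for j in range(spec.n_pairs):
        fwd = delta + rng.normal(0.0, spec.sigma, spec.n_genes)
        swp = -delta + rng.normal(0.0, spec.sigma, spec.n_genes)
        cols += [f"rep{j}_fwd", f"rep{j}_swp"]
        data += [fwd, swp]
        meta += [(f"rep{j}_fwd", f"rep{j}", "forward"),
                 (f"rep{j}_swp", f"rep{j}", "swapped")]

    values = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"),
                          columns=cols)
    arrays = pd.DataFrame(meta, columns=["array_id", "replicate_id", "orientation"])
    truth = pd.DataFrame({"gene_id": gene_ids, "is_de": de_mask, "effect": delta}).set_index("gene_id")
    return RatioTable(values, arrays), truth


# ---------------------------------------------------------------------------
# Promoters with planted motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterSpec:
    """Parameters of a synthetic promoter set.

    Background bases are i.i.d. with the stated GC fraction.  For every
    promoter and every planted (IUPAC pattern, insertion probability) pair, a
    concrete instance of the pattern is written at a uniformly drawn,
    non-overlapping position with that probability.
    """

    n_promoters: int
    length: int = 1000
    gc_fraction: float = 0.36  # A. thaliana upstream regions are AT-rich
    planted: tuple[tuple[str, float], ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_promoters <= 0 or self.length <= 0:
            raise ValueError("n_promoters and length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        object.__setattr__(self, "planted",
                           tuple((str(p).upper(), float(q)) for p, q in self.planted))
        for pattern, prob in self.planted:
            expand_iupac(pattern)  # validates the alphabet
            if len(pattern) > self.length:
                raise ValueError(f"pattern {pattern!r} longer than promoter length {self.length}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("insertion probabilities must lie in [0, 1]")


def gen_promoters(spec: PromoterSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate promoter sequences with planted motif instances.

    Returns ``(promoters, truth)``: an ordered gene->sequence mapping and a
    table of every insertion (promoter_id, pattern, instance, position).
    """
    rng = np.random.default_rng(spec.rng_seed)
    p_gc = spec.gc_fraction / 2.0
    p_at = (1.0 - spec.gc_fraction) / 2.0
    bases = np.array(list("ACGT"))
    probs = np.array([p_at, p_gc, p_gc, p_at])

    promoters: dict[str, str] = {}
    records = []
    for i in range(spec.n_promoters):
        pid = f"p{i:05d}"
        seq = rng.choice(bases, size=spec.length, p=probs)
        occupied: list[tuple[int, int]] = []
        for pattern, prob in spec.planted:
            if rng.random() >= prob:
                continue
            instance = "".join(
                IUPAC_CODES[ch][rng.integers(len(IUPAC_CODES[ch]))] for ch in pattern
            )
            m = len(instance)
            pos = None
            for _ in range(1000):  # rejection-sample a non-overlapping slot
                cand = int(rng.integers(0, spec.length - m + 1))
                if all(cand + m <= a or cand >= b for a, b in occupied):
                    pos = cand
                    break
            if pos is None:
                raise RuntimeError(f"could not place {pattern!r} without overlap in {pid}")
            seq[pos:pos + m] = list(instance)
            occupied.append((pos, pos + m))
            records.append((pid, pattern, instance, pos))
        promoters[pid] = "".join(seq)

    truth = pd.DataFrame(records, columns=["promoter_id", "pattern", "instance", "position"])
    return promoters, truth
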