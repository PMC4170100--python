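"""Promoter motif over-representation.

Two complementary tests are provided:

* ``known_motif_enrichment`` — a curated-motif test in the style of promoter
  databases: for each named IUPAC motif, count the subset promoters that
  contain at least one match and compare against the genome background with
  an exact binomial (background given as a containment frequency) or
  hypergeometric (background given as a full promoter set) upper tail.

* ``kmer_overrepresentation`` — an exhaustive word-counting test: for every
  k-mer occurring in the subset, the promoter-containment count is compared
  with an empirical null built from B random size-matched promoter sets
  sampled without replacement from the genome set.

Pattern matching and counting use a hand-written Boyer-Moore searcher with
bad-character and good-suffix shift tables, counting overlapping
occurrences; degenerate IUPAC patterns are expanded to concrete instances
before the search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import expand_iupac

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Boyer-Moore
# ---------------------------------------------------------------------------

def _bad_character_table(pattern: str) -> dict[str, int]:
    return {ch: i for i, ch in enumerate(pattern)}  # rightmost occurrence


def _good_suffix_table(pattern: str) -> list[int]:
    """Strong good-suffix shifts (border-based preprocessing).

    ``shift[j]`` is the safe shift after a mismatch at pattern position
    ``j - 1`` (``shift[0]`` applies after a full match), which makes the
    searcher overlap-aware: after a match it advances by the pattern's
    period, so overlapping occurrences are all visited.
    """
    m = len(pattern)
    border = [0] * (m + 1)
    shift = [0] * (m + 1)
    i, j = m, m + 1
    border[i] = j
    while i > 0:
        while j <= m and pattern[i - 1] != pattern[j - 1]:
            if shift[j] == 0:
                shift[j] = j - i
            j = border[j]
        i -= 1
        j -= 1
        border[i] = j
    j = border[0]
    for i in range(m + 1):
        if shift[i] == 0:
            shift[i] = j
        if i == j:
            j = border[j]
    return shift


def boyer_moore_count(sequence: str, pattern: str) -> int:
    """Count (overlapping) occurrences of a concrete pattern via Boyer-Moore.

    The pattern must be over {A, C, G, T}; degenerate patterns are expanded
    by the callers before the search.  A pattern longer than the sequence
    yields 0.
    """
    n, m = len(sequence), len(pattern)
    if m == 0:
        raise ValueError("empty pattern")
    if m > n:
        return 0
    bad = _bad_character_table(pattern)
    good = _good_suffix_table(pattern)
    count = 0
    s = 0
    while s <= n - m:
        j = m - 1
        while j >= 0 and pattern[j] == sequence[s + j]:
            j -= 1
        if j < 0:
            count += 1
            s += good[0]
        else:
            s += max(good[j + 1], j - bad.get(sequence[s + j], -1))
    return count


def count_motif(sequence: str, pattern: str, revcomp: bool = False) -> int:
    """Occurrences of an IUPAC motif in one sequence (overlapping).

    Degenerate patterns are expanded to concrete instances and the counts
    summed (distinct instances cannot match at the same offset).  With
    ``revcomp`` the reverse-complement pattern's instances are counted too.
    """
    patterns = {pattern.upper()}
    if revcomp:
        patterns.add(reverse_complement(pattern))
    instances: set[str] = set()
    for p in patterns:
        instances.update(expand_iupac(p))
    return sum(boyer_moore_count(sequence, inst) for inst in sorted(instances))


def contains_motif(sequence: str, pattern: str, revcomp: bool = False) -> bool:
    return count_motif(sequence, pattern, revcomp) > 0


# ---------------------------------------------------------------------------
# Known-motif enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str

    def __post_init__(self):
        if len(self.pattern) < 4:
            raise ValueError("motif patterns must be at least 4 bases long")
        expand_iupac(self.pattern)


def binomial_enrichment_p(hits: int, n: int, background_freq: float) -> float:
    """Exact upper-tail binomial P(X >= hits | n, background_freq)."""
    if not 0 <= hits <= n:
        raise ValueError("hits must lie in [0, n]")
    if not 0.0 <= background_freq <= 1.0:
        raise ValueError("background_freq must lie in [0, 1]")
    return float(stats.binom.sf(hits - 1, n, background_freq))


def hypergeometric_enrichment_p(hits: int, subset_size: int,
                                background_hits: int, background_size: int) -> float:
    """Upper-tail hypergeometric P(X >= hits) for containment counts."""
    return float(stats.hypergeom.sf(hits - 1, background_size, background_hits, subset_size))


def known_motif_enrichment(subset: dict[str, str], motifs: list[MotifPattern],
                           background, threshold: float = 1e-3,
                           revcomp: bool = False,
                           count_mode: str = "containment") -> pd.DataFrame:
    """Over-representation of curated motifs in a promoter subset.

    ``background`` is either a full promoter set (gene -> sequence mapping;
    hypergeometric on containment counts) or a name -> containment-frequency
    mapping (exact binomial).  The statistic is the number of subset
    promoters containing >= 1 match (``count_mode='containment'``) or, behind
    the flag ``count_mode='total'``, the total occurrence count compared
    binomially per position.  Matching is forward-strand by default.
    """
    if not subset:
        raise ValueError("empty promoter subset")
    if count_mode not in ("containment", "total"):
        raise ValueError("count_mode must be 'containment' or 'total'")

    n = len(subset)
    rows = []
    for motif in motifs:
        if count_mode == "containment":
            hits = sum(contains_motif(seq, motif.pattern, revcomp) for seq in subset.values())
        else:
            hits = sum(count_motif(seq, motif.pattern, revcomp) for seq in subset.values())
        if isinstance(background, dict) and background and isinstance(next(iter(background.values())), str):
            bg_hits = sum(contains_motif(seq, motif.pattern, revcomp)
                          for seq in background.values())
            bg_size = len(background)
            p = hypergeometric_enrichment_p(hits, n, bg_hits, bg_size)
            rows.append((motif.name, motif.pattern, hits, n, bg_hits / bg_size,
                         p, "hypergeometric"))
        else:
            freq = float(background[motif.name])
            p = binomial_enrichment_p(hits, n, freq)
            rows.append((motif.name, motif.pattern, hits, n, freq, p, "binomial"))
    out = pd.DataFrame(rows, columns=["name", "pattern", "subset_hits", "subset_size",
                                      "background_freq", "p_value", "method"])
    out["significant"] = out["p_value"] < threshold
    out.attrs["threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# Exhaustive k-mer over-representation with an empirical genome-sampled null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerNullConfig:
    k: int = 5
    n_background_sets: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("k must be >= 4")
        if self.n_background_sets < 99:
            raise ValueError("need >= 99 background sets for usable empirical p resolution")


def _kmer_presence(sequence: str, k: int) -> set[str]:
    """All distinct A/C/G/T k-mers occurring in a sequence (rolling window)."""
    seq = sequence.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        word = seq[i:i + k]
        if "N" not in word:
            out.add(word)
    return out


def kmer_overrepresentation(subset: dict[str, str], genome: dict[str, str],
                            cfg: KmerNullConfig = KmerNullConfig()) -> pd.DataFrame:
    """Empirical over-representation of every k-mer occurring in the subset.

    For each k-mer with at least one subset occurrence, the observed
    promoter-containment count is compared with the same statistic on
    ``cfg.n_background_sets`` random size-matched promoter sets sampled
    without replacement from the genome set; the empirical p-value is
    ``(1 + #{null >= observed}) / (B + 1)``.  Results are sorted by p-value,
    then k-mer.
    """
    if len(genome) <= len(subset):
        raise ValueError("genome promoter set must be larger than the subset")
    B = cfg.n_background_sets
    rng = np.random.default_rng(cfg.rng_seed)

    subset_sets = [_kmer_presence(s, cfg.k) for s in subset.values()]
    kmers = sorted(set().union(*subset_sets)) if subset_sets else []
    if not kmers:
        return pd.DataFrame(columns=["kmer", "observed", "null_mean", "p_empirical"])
    kidx = {km: i for i, km in enumerate(kmers)}

    observed = np.zeros(len(kmers), dtype=np.int64)
    for s in subset_sets:
        for km in s:
            observed[kidx[km]] += 1

    genome_ids = list(genome)
    presence = np.zeros((len(genome_ids), len(kmers)), dtype=bool)
    for gi, gid in enumerate(genome_ids):
        for km in _kmer_presence(genome[gid], cfg.k):
            j = kidx.get(km)
            if j is not None:
                presence[gi, j] = True

    n_sub = len(subset)
    exceed = np.zeros(len(kmers), dtype=np.int64)
    null_sum = np.zeros(len(kmers), dtype=np.float64)
    for _ in range(B):
        pick = rng.choice(len(genome_ids), size=n_sub, replace=False)
        counts = presence[pick].sum(axis=0)
        exceed += counts >= observed
        null_sum += counts
    p = (1.0 + exceed) / (B + 1.0)

    out = pd.DataFrame({"kmer": kmers, "observed": observed,
                        "null_mean": null_sum / B, "p_empirical": p})
    out = out.sort_values(["p_empirical", "kmer"], kind="stable").reset_index(drop=True)
    out.attrs.update({"k": cfg.k, "n_background_sets": B, "subset_size": n_sub,
                      "genome_size": len(genome_ids)})
    return out
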