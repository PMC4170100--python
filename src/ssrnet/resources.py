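"""Bundled reference inputs and published reference values.

The seed list is the curated set of 13 Arabidopsis thaliana
sugar-starvation responsive (SSR) genes (proline catabolism, asparagine
metabolism, branched-chain amino-acid degradation, glutamate metabolism,
cell-wall turnover, trehalose biosynthesis, dormancy) used to start the
guided-gene expansion in the original SSR-network study; the motif table
bundles the cis-elements that study examined.  The ``REFERENCE`` constants
are the values printed in that study's report of the Arabidopsis analysis:
they depend on the original expression compendium and hybridizations and
are documented reference points, not quantities this package recomputes.
"""

from __future__ import annotations

from .motifs import MotifPattern

#: Curated SSR seed genes (AGI codes), keyed by gene name.
SEED_GENES: dict[str, str] = {
    "ERD5": "At3g30775",        # proline dehydrogenase
    "ASN1": "At3g47340",        # asparagine synthetase
    "IVD": "At3g45300",         # isovaleryl-CoA-dehydrogenase
    "BCKDH_E1B": "At3g13450",   # branched-chain alpha-keto acid dehydrogenase
    "BCKDH_E2": "At3g06850",
    "MCCA": "At1g03090",        # 3-methylcrotonyl-CoA carboxylase subunit 1
    "MCCB": "At4g34030",        # 3-methylcrotonyl-CoA carboxylase subunit 2
    "GDH2": "At5g07440",        # glutamate dehydrogenase 2
    "BGAL4": "At5g56870",       # beta-galactosidase
    "BXL1": "At5g49360",        # glycosyl hydrolase family 3
    "TPS11": "At2g18700",       # trehalose-6-phosphate synthase
    "TPS8": "At1g70290",
    "DRM1": "At1g28330",        # dormancy-associated protein
}

#: Cis-elements of interest: the curated ABRE-like and Ibox binding sites,
#: plus the GATAA Ibox core word and the TTATC sugar-repressive fragment
#: found by exhaustive word counting.
KNOWN_MOTIFS: list[MotifPattern] = [
    MotifPattern("ABRE-like binding site", "BACGTGKM"),
    MotifPattern("Ibox", "GATAAG"),
    MotifPattern("GATAA", "GATAA"),
    MotifPattern("TTATC", "TTATC"),
]

#: Published network statistics for the Arabidopsis SSR network
#: (original compendium + CATMA hybridizations; reference only).
REFERENCE_NETWORK = {
    "nodes": 820,
    "edges": 3880,
    "degree_lt10": 717,
    "degree_10_99": 89,
    "degree_ge100": 15,
}

#: Published cross-examination counts (reference only).
REFERENCE_OVERLAP = {
    "up_dawn_any": 220,
    "up_dawn_all": 74,
    "down_dawn_any": 27,
    "de_any_mutant": 3332,
    "de_all_mutants": 545,
    "de_both_timepoints": 783,
    "de_one_timepoint": 2549,
}

#: Published curated-motif enrichment inputs: subset containment counts over
#: the 220 dawn-induced network genes vs genome containment frequencies
#: (reference only; the binomial tails are recomputed from these counts).
REFERENCE_ENRICHMENT = {
    "ABRE-like binding site": {"subset_hits": 89, "subset_size": 220,
                               "background_freq": 0.20, "background_hits": 6258,
                               "p_bound": 1e-5},
    "Ibox": {"subset_hits": 140, "subset_size": 220,
             "background_freq": 0.40, "background_hits": 12259,
             "p_bound": 1e-4},
}
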