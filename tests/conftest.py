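import numpy as np
import pytest

from ssrnet import CompendiumSpec, ExpansionConfig, expand_seeds, gen_compendium


@pytest.fixture(scope="session")
def planted_compendium():
    """Compendium with one tight 50-gene module and 500 noise genes.

    Three of the thirteen "seed" genes belong to the module (mirroring a
    curated seed list that only partly overlaps the latent structure).
    """
    spec = CompendiumSpec(n_genes=550, n_samples=60, modules=((50, 0.95),),
                          noise_sd=1.0, rng_seed=42)
    compendium, truth = gen_compendium(spec)
    module_genes = list(truth.index[truth["module"] == 0])
    noise_genes = list(truth.index[truth["module"] == -1])
    seeds = module_genes[:3] + noise_genes[:10]
    return compendium, truth, seeds


@pytest.fixture(scope="session")
def two_module_network():
    """Final network grown over a two-planted-module compendium."""
    spec = CompendiumSpec(n_genes=475, n_samples=60, modules=((40, 0.95), (35, 0.95)),
                          noise_sd=1.0, rng_seed=7)
    compendium, truth = gen_compendium(spec)
    seeds = (list(truth.index[truth["module"] == 0])[:6]
             + list(truth.index[truth["module"] == 1])[:6])
    result = expand_seeds(compendium, seeds, ExpansionConfig())
    return result, truth


def naive_pearson_r2(x, y):
    """Two-pass textbook Pearson r^2, independent of the implementation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    sxy = ((x - mx) * (y - my)).sum()
    sxx = ((x - mx) ** 2).sum()
    syy = ((y - my) ** 2).sum()
    return (sxy * sxy) / (sxx * syy)


def naive_count(sequence, pattern):
    """Sliding-window occurrence count (overlapping), the string oracle."""
    return sum(1 for i in range(len(sequence) - len(pattern) + 1)
               if sequence[i:i + len(pattern)] == pattern)
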