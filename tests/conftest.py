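import numpy as np
import pytest

from mtphewas import (GenotypeMatrix, SimulationConfig, TraitSpec,
                      simulate_genotypes, split_genomes, nuclear_grm, mito_grm)
from mtphewas.simulate import _psd_root


def random_genotypes(n, m_nuc, m_mt, seed, missing_rate=0.0):
    """Small random genotype matrix, optionally with missing calls."""
    rng = np.random.default_rng(seed)
    nuc = rng.integers(0, 3, size=(n, m_nuc)).astype(float)
    mt = rng.integers(0, 2, size=(n, m_mt)).astype(float)
    calls = np.concatenate([nuc, mt], axis=1)
    if missing_rate:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = np.nan
    m = m_nuc + m_mt
    return GenotypeMatrix(
        calls=calls,
        sample_ids=[f"S{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        chrom=np.array(["1"] * m_nuc + ["MT"] * m_mt, dtype=object),
        pos=np.arange(1, m + 1),
        a1=np.array(["A"] * m, dtype=object),
        a2=np.array(["G"] * m, dtype=object),
        ploidy=np.array([2] * m_nuc + [1] * m_mt),
    )


@pytest.fixture(scope="session")
def small_genotypes():
    return random_genotypes(20, 30, 10, seed=42)


@pytest.fixture(scope="session")
def reml_bench():
    """Shared simulation surface for REML tests: genotypes, GRMs and roots.

    Session-scoped because the GRM eigendecompositions dominate test cost.
    """
    cfg = SimulationConfig(n_samples=600, m_nuc=1200, m_mt=100, n_rare_mt=0,
                           traits=[TraitSpec("q", pve_nuc=0.30, pve_mt=0.05)],
                           seed=101)
    g = simulate_genotypes(cfg)
    g_nuc, g_mt = split_genomes(g)
    a = nuclear_grm(g_nuc).values
    s = mito_grm(g_mt).values
    return {"cfg": cfg, "genotypes": g, "A": a, "S": s,
            "roots": (_psd_root(a), _psd_root(s))}
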