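import numpy as np
import pytest

from hierpop.simulate import SimulationConfig, simulate_study
from hierpop.types import GenotypeMatrix, VariantMap


def make_gm(dosages, pos=None, chrom=None, sample_ids=None):
    """GenotypeMatrix from a plain array, with default coordinates."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = np.full(m, "chr1", dtype=object)
    vm = VariantMap(chrom, pos, np.full(m, "A", dtype=object), np.full(m, "G", dtype=object))
    ids = sample_ids or [f"G{i:03d}" for i in range(n)]
    return GenotypeMatrix(d, vm, ids)


@pytest.fixture(scope="session")
def small_study():
    """Linkage-equilibrium study: 6 rivers / 18 stands / 180 genotypes."""
    cfg = SimulationConfig(
        n_rivers=6,
        n_stands=18,
        n_genotypes=180,
        n_snps=3000,
        chrom_length=3_000_000,
        n_qtn=60,
        traits=("BF", "HT"),
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_fits(small_study):
    """REML fits (variance decomposition + BLUPs) for every trait of small_study."""
    from hierpop import fit_hierarchical_model

    out = {}
    for trait in small_study.config.traits:
        out[trait] = fit_hierarchical_model(small_study.phenotypes, small_study.hierarchy, trait=trait)
    return out


@pytest.fixture(scope="session")
def mosaic_study():
    """Founder-mosaic study with distance-dependent LD and phase structure."""
    cfg = SimulationConfig(
        n_rivers=4,
        n_stands=8,
        n_genotypes=160,
        n_snps=2500,
        chrom_length=1_500_000,
        haplotype_model="founder_mosaic",
        n_qtn=40,
        traits=("HT",),
        seed=5,
    )
    return simulate_study(cfg)
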