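"""Generate a hierarchically structured population and partition trait variance.

Builds a scaled-down version of the default study design (clonal genotypes in
stands in rivers, three replicated test sites), fits the hierarchical REML
model y = site + river + stand(river) + genotype(stand) + e, and contrasts the
trait-level differentiation (Q_ST) with the SNP-level differentiation (F_ST).
"""
import numpy as np

from hierpop import (
    broad_sense_heritability,
    fit_hierarchical_model,
    hierarchical_fstats,
    qst,
)
from hierpop.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_rivers=8, n_stands=40, n_genotypes=360, n_snps=8000, chrom_length=8_000_000,
    n_qtn=100, traits=("HT",), seed=42,
)
study = simulate_study(cfg)

vd, blups = fit_hierarchical_model(study.phenotypes, study.hierarchy, trait="HT")
props = vd.proportions()
h2 = broad_sense_heritability(vd, n_eff=cfg.n_sites * cfg.ramets_per_site)
fst = hierarchical_fstats(study.genotypes, study.hierarchy)

print("genetic variance proportions (trait):")
for level, p in props.items():
    print(f"  {level:9s} {p:6.3f}")
print(f"clone-mean H^2 (within stand): {h2['clone_mean']:.3f}")
print(f"among-stand Q_ST:              {qst(vd):.3f}")
print(f"among-stand F_ST (SNPs):       {fst.fst_among_stand:.4f}")
print()
print(
    "Q_ST far exceeds F_ST: the adaptive trait is much more differentiated\n"
    "among stands and rivers than the (mostly neutral) SNPs, the signature of\n"
    "diversifying selection along the latitudinal gradient."
)
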