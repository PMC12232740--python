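"""Cross-validated genomic prediction, partitioned by hierarchical level.

Trains GBLUP (ridge on a genomic relationship matrix) and ridge models on
climate and geography through one kernel code path, then reports predictive
ability (PA: Pearson correlation of held-out predictions with the true genetic
component) at the whole-population, within-stand and river levels.
"""
import numpy as np

from hierpop import CvScheme, cross_validate, feature_kernel, grm
from hierpop.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_rivers=8, n_stands=40, n_genotypes=360, n_snps=8000, chrom_length=8_000_000,
    n_qtn=100, traits=("HT",), seed=42,
)
study = simulate_study(cfg)
gm = study.genotypes
truth = study.truth["HT"]
hier = study.hierarchy.aligned_to(gm.sample_ids)
clone_means = (
    study.phenotypes.table.groupby("genotype")["value"].mean().loc[gm.sample_ids].to_numpy()
)

refs = {
    "G (all levels)": truth.g_total,
    "genotype (SR)": truth.within_component,
    "river": truth.river_component,
}
groups = {"river": hier.rivers}
scheme = CvScheme(n_folds=10, n_replicates=3, seed=1)

kernels = {
    "GBLUP (SNPs)": grm(gm),
    "climate": feature_kernel(study.climate.values_for(gm.sample_ids), gm.sample_ids)[0],
    "geography": feature_kernel(
        hier.table[["latitude", "longitude", "elevation"]].to_numpy(float), gm.sample_ids
    )[0],
}

print(f"{'predictor':14s}" + "".join(f"{lvl:>16s}" for lvl in refs))
for name, k in kernels.items():
    cv = cross_validate(k, clone_means, refs, groups, scheme)
    s = cv.summary()["mean"]
    print(f"{name:14s}" + "".join(f"{s[lvl]:16.3f}" for lvl in refs))
print()
print(
    "All predictors do well at the river level (population structure carries\n"
    "the signal) but none predicts the within-stand genetic component: the PA\n"
    "of genomic prediction here comes from structure, not from tagging QTN."
)
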