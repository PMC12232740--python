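"""Mixed-model GWAS with and without structure correction.

Scans a structure-confounded trait with the two-step mixed-model approach
(variance components fixed from the null model, then per-SNP GLS). With the
identity-by-state kinship in the model the scan is calibrated; without it,
population structure inflates the test statistics.
"""
import numpy as np

from hierpop import KinshipMatrix, bonferroni_threshold, cluster_hits, fit_null, ibs_kinship, scan
from hierpop.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_rivers=8, n_stands=40, n_genotypes=360, n_snps=6000, chrom_length=6_000_000,
    n_qtn=100, traits=("HT",), seed=42,
)
study = simulate_study(cfg)
gm = study.genotypes
rng = np.random.default_rng(1)
truth = study.truth["HT"]
# a purely structure-driven phenotype: river-level signal plus noise
y = truth.river_component + rng.normal(scale=truth.river_component.std(), size=gm.n_samples)

k = ibs_kinship(gm)
corrected = scan(gm, fit_null(y, k), y)
naive = scan(gm, fit_null(y, KinshipMatrix(np.eye(gm.n_samples), gm.sample_ids, "IBS", 1)), y)

thr = bonferroni_threshold(0.05, corrected.n_tested)
print(f"Bonferroni threshold (alpha=0.05, m={corrected.n_tested}): {thr:.2e}")
print(f"lambda_GC with IBS kinship:    {corrected.lambda_gc():.3f}")
print(f"lambda_GC without correction:  {naive.lambda_gc():.3f}")
print(f"hits below threshold, corrected: {int((corrected.table['p'] < thr).sum())}")
print(f"hits below threshold, naive:     {int((naive.table['p'] < thr).sum())}")
print(f"naive hit clusters (60 kb merge): {len(cluster_hits(naive, thr))}")
print()
print(
    "The kinship-corrected scan stays calibrated (lambda_GC near 1) on a trait\n"
    "whose variation is pure population structure, while the uncorrected scan\n"
    "is badly inflated - the false-positive mechanism of across-population GWAS."
)
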