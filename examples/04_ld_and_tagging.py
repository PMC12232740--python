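"""LD decay, MAF bins, LD extent and the probability of tagging a QTN.

Uses the founder-mosaic generator (small founder pools create realistic
distance-dependent LD within rivers) and reports: the within-river decay of
mean r^2 in 1-kb distance classes, the LD extent (distance where mean r^2
drops below 0.2), MAF bins constructed with the two-locus attainable-r^2 rule,
and how the chance of tagging a causal variant (r^2 >= 0.6 within 10 kb)
grows with marker-panel size.
"""
import numpy as np

from hierpop import ld_curve, ld_extent, make_maf_bins, pairwise_r2, tag_probability
from hierpop.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_rivers=4, n_stands=8, n_genotypes=240, n_snps=6000, chrom_length=2_000_000,
    haplotype_model="founder_mosaic", switch_rate_per_bp=6e-6,
    n_qtn=40, traits=("HT",), seed=42,
)
study = simulate_study(cfg)
hier = study.hierarchy.aligned_to(study.genotypes.sample_ids)

print("within-river LD extent (mean r^2 > 0.2):")
for river in np.unique(hier.rivers):
    idx = np.where(hier.rivers == river)[0]
    pairs = pairwise_r2(study.genotypes, max_dist=30_000, maf_min=0.05, sample_idx=idx)
    curve = ld_curve(pairs)
    extent, status = ld_extent(curve)
    print(f"  {river}: {extent / 1000:5.1f} kb ({status})")

bins = make_maf_bins((0.071, 0.5), min_r2=0.5)
lo, hi = bins.bins[0]
print(f"\nfirst MAF bin under the attainable-r^2 >= 0.5 rule: [{lo:.3f}, {hi:.3f}) "
      f"midpoint {bins.midpoints[0]:.3f}")

one_river = study.genotypes.take_samples(np.where(hier.rivers == hier.rivers[0])[0])
tags = tag_probability(one_river, (100, 500, 2000), reps=100, seed=1)
print("\nprobability of tagging a random QTN within one river (r^2 >= 0.6, 10 kb):")
for _, row in tags.iterrows():
    print(f"  {int(row.n_snps):5d} markers: {row.probability:.2f} +- {row.se:.2f}")
print()
print(
    "LD extent varies among rivers with their founder history, and tagging a\n"
    "causal variant reliably requires marker densities far beyond what the\n"
    "extent of useful LD would naively suggest."
)
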