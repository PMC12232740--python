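# Methods

This note documents the models behind `hierpop`, the choices made where the
design was genuinely open, and what the synthetic generator does and does not
emulate.

## The synthetic generator (`hierpop.simulate`)

The generator emulates a range-wide common-garden study of a riparian tree:
clonally replicated genotypes sampled from stands nested in river drainages,
measured in replicated field trials. Default design constants: 840 genotypes,
91 stands, 16 rivers, three test sites with two ramets per genotype and site,
50,000 biallelic SNPs on one 20-Mb chromosome, 21 climate variables. Rivers
are laid out along a 44–50°N gradient with small stand-level jitter.

**Allele frequencies.** Hierarchical Balding–Nichols sampling: ancestral
frequencies are Uniform(0.05, 0.95); each river draws a frequency from a Beta
with the ancestral mean and variance θ_river·p(1−p); each stand draws around
its river with θ_stand. A fraction of SNPs (default 0.17) is *clinal*: the
river-level mean is shifted by a signed amplitude (≤ 0.08 per SD of river
latitude), producing allele-frequency–latitude correlations and a heavy upper
tail of per-SNP F_ST. Defaults θ_river = 0.01 and θ_stand = 0.03 were chosen
analytically: the combined among-stand differentiation is
1 − (1−θ_r)(1−θ_s) ≈ 0.04, and the expected mean absolute river frequency
difference E|p_i − p_j| ≈ 0.8·√(2 θ_r E[p(1−p)]) ≈ 0.05. Balding–Nichols
sampling was preferred over coalescent simulation because it gives direct,
level-specific control of F_ST and of clines without an external simulator.

**Haplotypes.** Two modes.

* `linkage_equilibrium` (default): every haplotype is an independent
  Bernoulli draw from its stand's frequencies. Markers are unlinked and
  genotypes within stands unrelated beyond frequency sharing — the cleanest
  setting for F_ST recovery, GWAS calibration and level-partitioned
  prediction, and the mode in which realized F_ST matches the
  Balding–Nichols expectation exactly.
* `founder_mosaic`: each stand's haplotypes are crossover mosaics (Poisson
  switch process, default 1e-5 per bp) of a small founder pool (default 4),
  drawn partly from a river-level pool shared among the river's stands
  (default 3 of 4) and partly from the stand's own frequencies. Small pools
  create distance-dependent LD — within-river extent (mean r² > 0.2) in the
  6–18 kb range under the defaults, tunable via pool size and switch rate —
  and elevated haplotype sharing within stands and rivers. The price is that
  a pool of F founders adds drift of order 1/F on top of the Balding–Nichols
  level, so this mode trades exact F_ST control for LD realism. LD analyses
  on mosaic data are therefore run within rivers (as the real analyses
  subsample within rivers); LD pooled across rivers is attenuated because
  founder-pool associations have independent signs across pools.

**Traits.** Each trait draws n_qtn = 200 causal loci, 70% from the clinal
SNPs. Effects are standard normal, rescaled so that the summed causal
variance Σ 2β²·MAF(1−MAF) equals the configured genic variance. At clinal
QTN the sign of β is aligned with the cline direction (the trait-increasing
allele is the one that becomes more frequent with latitude) — the local-
adaptation scenario the study design presumes; without this alignment the
trait–latitude cline is a random-sign sum over QTN and can vanish for some
seeds. The realized genetic value is decomposed into river / stand(river) /
within-stand components by hierarchy means, and the river component is
rescaled so the realized Q_ST = σ²_B/(σ²_B + 2σ²_W) hits the target (default
0.55). The stand and within-stand components remain purely SNP-based, so
GBLUP has a defined oracle; only the river-level amplitude is adjusted.
Residual variance is set from the clone-mean heritability target
(default 0.5): σ²_e = n_eff · σ²_W (1 − H²)/H², n_eff = sites × ramets.
Phenotypes are site effect + genetic value (+ optional genotype×site
deviation) + residual, per ramet.

**Climate.** Each of 21 variables is a linear function of standardized
latitude and elevation plus Gaussian noise; half the variables carry strong
latitude loadings (temperature-like), half weaker mixed loadings
(precipitation-like). Loadings are drawn once per run from the seed.

**What the generator does not emulate:** demographic history (bottlenecks,
admixture, interspecific introgression), dominance and epistasis, selection
during the trials, spatial field heterogeneity, missing data patterns, or
genotyping error. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
property of real resequencing data.

## Hierarchical REML (`hierpop.pheno`)

Model: y = μ + site + R + S(R) + G(SR) [+ G×site] + e with site fixed and
independent random levels. Multi-year measurements are averaged per
genotype–site–ramet before fitting. The restricted likelihood factorizes
exactly into a within-cell part (genotype×site cells; informs σ²_e only) and
a cell-mean part whose covariance lives in genotype space; with
Σ = σ²_R A_R A_R' + σ²_S A_S A_S' + σ²_G I and diagonal cell residuals D, the
Woodbury identities reduce every evaluation to one q×q factorization
(q = genotypes). Parameters are optimized on the log scale (non-negativity by
construction) by Nelder–Mead from moment-based starts plus two dispersed
restarts, with a tight final polish; components below 1e-9 of the phenotypic
variance are snapped to zero. BLUPs at each level are
û_level = σ²_level A'_level (I + EΣ)⁻¹ Z'D⁻¹(y − Xβ̂). On balanced data the
estimates agree with the closed-form nested ANOVA to ~1e-5 (the limit set by
float64 roundoff of the criterion). The genotype×site component is available
(`include_gxs=True`) but off by default.

Q_ST pools the river and stand components as "among-stand" variance, because
a single among-stand differentiation over both levels is the quantity
reported for such designs; `qst(vd, among=("stand",))` switches to the stand
level alone. Heritability is reported both as clone-mean (within-stand
genotypic variance over itself plus σ²_e/n_eff — the headline) and as a
total-structure variant with all three genetic levels in the numerator,
since which of the two a published H² refers to is often ambiguous. The
genetic correlation is the Pearson correlation of combined BLUPs — a
BLUP-based approximation, not a bivariate REML.

## SNP structure (`hierpop.structure`)

Hudson's F_ST uses the small-sample-corrected numerator
(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) over denominator
p₁(1−p₂) + p₂(1−p₁), accumulated as a ratio of averages (robust to rare
alleles). Hierarchical F-statistics come from a per-SNP unbalanced nested
moment ANOVA on haploid allele indicators (river / stand(river) / within),
with Searle coefficients for unequal group sizes; per-SNP components are
summed (negative estimates retained, so genome-wide ratios stay unbiased)
and F-statistics are ratios of the sums. This is the moment analogue of the
likelihood-based hierarchical estimators and agrees with mean pairwise
Hudson F_ST within 0.01 on island-model simulations. SNP PCA centers at 2p
and scales by √(p(1−p)); explained fractions are relative to the total
variance. The cline scan is a per-SNP Pearson correlation of river
frequencies with river latitude and a two-sided t test (uncorrected p < 0.05
for the summary fraction, matching how such fractions are usually reported).
The Mantel test permutes rows/columns of the second matrix with the +1
p-value correction; it is implemented in-package (seeded) and cross-checked
against scikit-bio's implementation in the tests.

## Prediction (`hierpop.predict`)

GBLUP fits the single-ratio mixed model by spectral decomposition of K and a
1-D bounded search of the profile restricted likelihood over
log λ ∈ [log 1e-5, log 1e5] (Brent-style bounded minimization, tolerance
1e-8, rather than literal golden-section — same bracket, faster). Ridge on
geography (3 variables) and climate (21) goes through the identical solver
via the linear kernel XX'/q on standardized columns, so all predictor sets
share one code path and can oracle-test each other; GBLUP with the
ratio-of-sums GRM is identical to ridge on centered markers with penalty
λ·2Σp(1−p) (tested to 1e-6). Cross-validation draws a fresh random k-fold
partition per replicate (default 10 folds × 100 replicates at design scale;
smaller in tests). Level-specific PA correlates held-out predictions with
the reference at that level over the *unique* units in the fold (stand and
river means), avoiding n-inflation from duplicated unit values; the
genotype-replicated variant is available via `per_unit=False`. The reported
SE is the SD of replicate means over √replicates. Training-size curves draw
disjoint training/prediction sets within genotype subsets and report a
Spearman trend of PA on size. Lasso uses scikit-learn coordinate descent
with 10-fold CV (or a fixed penalty for oracle tests).

## GWAS (`hierpop.gwas`)

The two-step approximation: REML variance components are estimated once
under the no-SNP null (y = Xβ + u + e, u ~ N(0, σ²_g K)) and held fixed;
each SNP is then tested by weighted OLS on the spectrally transformed data —
O(n) per SNP after one eigendecomposition, which is what the fast mixed-model
association tools do. Fixed effects are the intercept plus optionally the
first five SNP PCs. p-values come from a t distribution with
n − rank(X) − 1 df. With K = I the scan reproduces ordinary regression
p-values to 1e-10; on structured null traits the kinship-corrected scan keeps
λ_GC in [0.9, 1.1] while the uncorrected scan inflates above 1.2. Hits are
merged into associations when within 60 kb of the running cluster.

## LD and haplotype sharing (`hierpop.ld`)

r² is the squared Pearson correlation of genotype dosages (composite LD),
matching the tooling used on unphased-call real data; phase is used only by
the sharing statistic. Distance classes are 1 kb wide, left-closed; same-
position pairs are excluded. MAF bins are built greedily from the low end:
the bin extends while the two-locus bound p(1−q)/(q(1−p)) between its
extremes stays ≥ 0.5 (grid step 0.001); from a lower limit of 0.071 this
closes at 0.132 (midpoint 0.102). LD extent interpolates linearly between
class midpoints to the first crossing of mean r² = 0.2, with explicit
below-range/beyond-range statuses. Tagging probability resamples a
hypothetical QTN and a random marker panel per replicate (the QTN is excluded
from the panel unless the duplicated-panel mode is on) and reports the
binomial success fraction ± SE; it matches exhaustive enumeration on small
universes. The haplotype-sharing statistic — for a SNP pair and an individual
pair, the mean over the four haplotype pairings of the indicator that both
loci carry identical alleles — is one concrete choice among the
linkage-phase-consistency statistics in the literature; it is
phase-sensitive, frequency-sensitive and bounded in [0, 1], averaged
unweighted over SNP pairs within the window, with SEs over individual pairs.
Sampling caps (individual pairs per category, SNP pairs) keep the cost
quadratic terms bounded; both are seeded. The frequency-matched variant
restricts to SNPs whose per-river MAF lies in [0.01, 0.11) in every river
and widens the pair window to 1 Mb because such SNPs are sparse.

## Seed zones (`hierpop.zones`)

Stand features are per-stand means of genotype-level values
(BLUPs, predictions, geography in raw degrees/m, climate), column-
standardized before clustering. k-means uses k-means++ seeding with
best-of-50 restarts so each benchmark replicate is a stable optimum; truth
partitions from k-means on phenotypes are refit per replicate with their own
seed. Purity is Σ over reconstructed zones of their largest single-truth-zone
overlap, divided by the number of stands; it is label-permutation invariant
and non-decreasing under cluster splits (property-tested against a brute-
force implementation).

## I/O, filtering and seeds (`hierpop.types`, `vcfio`, `filters`, `rng`)

Genotypes travel as VCF v4.2 (cyvcf2 reader; minimal text writer), with
1-based inclusive coordinates; phased records also populate the haplotype
container, and haplotype pair sums always equal dosages. Missing dosages are
mean-imputed per SNP for matrix analyses (the count is logged). Marker
filtering applies, in order: MAF floor → singleton removal → greedy
left-to-right distance thinning → sliding-window LD pruning (50-SNP window,
step 10, drop the later SNP of any pair with r² ≥ threshold; passes repeat to
a fixpoint so the filter is idempotent) → optional fixed-size random
subsample (e.g. a reduced-representation panel emulation). Strict/liberal
filter presets are user configuration, not asserted constants. All
randomness flows from one global seed: every stochastic operation draws a
child generator from (seed, operation name, replicate index) via a stable
32-bit hash, so whole pipelines are byte-reproducible and independent
operations never share a stream.

## Problem sizes used in the shipped checks

The test suite exercises scaled designs (hundreds of genotypes, thousands of
SNPs) chosen so each statistic is comfortably inside its tolerance; the
acceptance script runs the design scale for the quantities that need it
(20,000 SNPs for F_ST recovery; the full 840-genotype, 50,000-SNP design
with 10 CV replicates for level-partitioned PA; three replicate 91-stand
trials for Q_ST recovery, averaging out the ~0.04 sampling SD of a single
trial). These sizes are the package's own defaults for a desk-scale
reproduction.

## Known limitations

* The founder-mosaic mode couples LD strength to founder-pool drift; among-
  stand F_ST in that mode exceeds the Balding–Nichols target by ~1/F.
  Frequency-sensitive analyses should use the linkage-equilibrium mode.
* Bivariate REML (true genetic correlations), spatial trial adjustment,
  admixture/ancestry inference, Bayesian whole-genome regression and
  genomic-offset methods are out of scope.
* The REML optimizer is derivative-free; on very flat likelihoods (e.g.
  K ≈ I) the σ²_g/σ²_e split is weakly identified even though predictions
  are stable — a property of the model, not the optimizer.
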