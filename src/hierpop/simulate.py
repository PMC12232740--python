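"""Synthetic structured populations for exercising the analysis stages.

The generator emulates a range-wide sample of clonal tree genotypes nested in
stands nested in river drainages, measured in replicated clonal field trials:

* allele frequencies follow a hierarchical Balding-Nichols model (river level
  around an ancestral frequency, stand level around the river frequency), with
  a configurable fraction of SNPs whose river frequencies shift monotonically
  with river latitude (clines);
* haplotypes are drawn either at linkage equilibrium within stands (unlinked
  markers, unrelated genotypes) or as recombinant mosaics of a small founder
  pool (which creates distance-dependent LD and within-stand relatedness);
* a polygenic trait is built from quantitative trait nucleotides (QTN) placed
  preferentially on clinal SNPs, with effects calibrated through the
  variance-explained identity PVE_c = 2 * beta^2 * MAF * (1 - MAF);
* phenotypes are observed in multi-site clonal trials with site effects,
  optional genotype-by-site deviations and residual noise, with the true
  river / stand(river) / genotype(stand, river) decomposition returned for
  oracle testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rng import child_rng
from .types import (
    ClimateMatrix,
    GenotypeMatrix,
    HaplotypeSet,
    PhenotypeRecords,
    SampleHierarchy,
    VariantMap,
)

LE = "linkage_equilibrium"
MOSAIC = "founder_mosaic"


@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture parameters of the generator.

    Defaults emulate the reference design: 840 clonal genotypes in 91 stands in
    16 rivers, 50,000 SNPs on one chromosome, among-stand SNP differentiation
    around 0.04 split between the river and stand levels, 17% clinal SNPs, a
    200-QTN polygenic trait with strong river-level clines calibrated to an
    among-stand Q_ST of 0.55, clone-mean within-stand heritability 0.5, and
    three test sites with two ramets per genotype and site.
    """

    n_rivers: int = 16
    n_stands: int = 91
    n_genotypes: int = 840
    # genome
    n_snps: int = 50_000
    chrom_length: int = 20_000_000
    chrom_name: str = "chr1"
    # hierarchical differentiation (Balding-Nichols concentration per level)
    theta_river: float = 0.01
    theta_stand: float = 0.03
    # latitudinal clines
    clinal_fraction: float = 0.17
    cline_strength: float = 0.08  # max frequency shift per SD of river latitude
    # haplotype model
    haplotype_model: str = LE
    founders_per_stand: int = 4
    shared_founder_fraction: float = 0.75
    river_pool_factor: int = 1
    switch_rate_per_bp: float = 1e-5
    # trait architecture
    traits: tuple[str, ...] = ("BF", "BS", "HT")
    n_qtn: int = 200
    qtn_clinal_fraction: float = 0.7
    genic_variance: float = 1.0  # target sum of PVE_c in trait units^2
    qst_target: float | None = 0.55
    h2_within: float = 0.5  # clone-mean heritability at the genotype(SR) level
    # trial design
    n_sites: int = 3
    ramets_per_site: int = 2
    site_sd: float = 1.0
    gxs_sd: float = 0.0
    # climate
    n_climate: int = 21
    climate_noise_sd: float = 0.3
    # geography
    lat_range: tuple[float, float] = (44.0, 50.0)
    lon_range: tuple[float, float] = (-124.0, -121.0)
    elev_range: tuple[float, float] = (10.0, 600.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_river", "theta_stand"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_qtn > self.n_snps:
            raise ValueError("n_qtn cannot exceed n_snps")
        if self.haplotype_model not in (LE, MOSAIC):
            raise ValueError(f"unknown haplotype model {self.haplotype_model!r}")
        if not (0.0 < self.h2_within <= 1.0):
            raise ValueError("h2_within must be in (0, 1]")


@dataclass
class AlleleFrequencies:
    """Per-level allele-frequency tables from the hierarchical model."""

    ancestral: np.ndarray  # (m,)
    river: np.ndarray  # (n_rivers, m)
    stand: np.ndarray  # (n_stands, m)
    clinal: np.ndarray  # (m,) bool
    positions: np.ndarray  # (m,) bp, strictly increasing
    cline_amplitude: np.ndarray | None = None  # signed shift of alt freq per SD latitude


@dataclass
class QtnModel:
    """Causal loci and calibrated allele effects for one trait."""

    indices: np.ndarray  # into the variant map
    beta: np.ndarray  # trait units per alt allele
    maf: np.ndarray
    pve_c: np.ndarray  # per-QTN 2*beta^2*maf*(1-maf)


def pve_causal(beta: np.ndarray | float, maf: np.ndarray | float) -> np.ndarray | float:
    """Variance explained by a causal locus: 2 * beta^2 * MAF * (1 - MAF)."""
    return 2.0 * np.asarray(beta) ** 2 * np.asarray(maf) * (1.0 - np.asarray(maf))


def pve_tagged(r2: np.ndarray | float, pve_c: np.ndarray | float) -> np.ndarray | float:
    """Variance explained through a linked marker: r^2 times the causal PVE."""
    return np.asarray(r2) * np.asarray(pve_c)


# ---------------------------------------------------------------------------
# hierarchy and geography


def _allocate(total: int, groups: int) -> np.ndarray:
    """Split `total` units over `groups` as evenly as integers allow."""
    base = total // groups
    counts = np.full(groups, base, dtype=int)
    counts[: total - base * groups] += 1
    return counts


def make_hierarchy(cfg: SimulationConfig) -> SampleHierarchy:
    """Assign genotypes to stands to rivers and lay rivers out along latitude."""
    rng = child_rng(cfg.seed, "make_hierarchy")
    stands_per_river = _allocate(cfg.n_stands, cfg.n_rivers)
    genos_per_stand = _allocate(cfg.n_genotypes, cfg.n_stands)
    river_lat = np.linspace(*cfg.lat_range, cfg.n_rivers)
    river_lon = rng.uniform(*cfg.lon_range, cfg.n_rivers)

    rows = []
    g = 0
    s = 0
    for r in range(cfg.n_rivers):
        for _ in range(stands_per_river[r]):
            lat = river_lat[r] + rng.normal(0.0, 0.12)
            lon = river_lon[r] + rng.normal(0.0, 0.2)
            elev = rng.uniform(*cfg.elev_range)
            for _ in range(genos_per_stand[s]):
                rows.append(
                    (f"G{g:04d}", f"S{s:03d}", f"R{r:02d}", lat, lon, elev)
                )
                g += 1
            s += 1
    table = pd.DataFrame(
        rows, columns=["genotype", "stand", "river", "latitude", "longitude", "elevation"]
    )
    return SampleHierarchy(table)


# ---------------------------------------------------------------------------
# allele frequencies


def _beta_around(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Balding-Nichols draw: Beta with the given mean and variance theta*m*(1-m)."""
    if theta == 0.0:
        return mean.copy()
    scale = (1.0 - theta) / theta
    m = np.clip(mean, 1e-6, 1.0 - 1e-6)
    return rng.beta(m * scale, (1.0 - m) * scale)


def _distinct_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(m * 1.2) + 16))
    while pos.size < m:
        extra = rng.integers(1, length + 1, size=m)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def simulate_allele_frequencies(
    cfg: SimulationConfig, hierarchy: SampleHierarchy
) -> AlleleFrequencies:
    """Hierarchical Balding-Nichols frequencies with latitudinal clines.

    Ancestral frequencies are Uniform(0.05, 0.95); river frequencies are Beta
    around the (possibly cline-shifted) ancestral mean with variance
    theta_river * p * (1 - p); stand frequencies are Beta around their river's
    frequency with theta_stand. For the clinal fraction of SNPs the river-level
    mean shifts monotonically with standardized river latitude.
    """
    rng = child_rng(cfg.seed, "simulate_allele_frequencies")
    m = cfg.n_snps
    anc = rng.uniform(0.05, 0.95, m)
    positions = _distinct_positions(rng, m, cfg.chrom_length)

    clinal = np.zeros(m, dtype=bool)
    n_clinal = int(round(cfg.clinal_fraction * m))
    clinal[rng.choice(m, size=n_clinal, replace=False)] = True

    river_lat = hierarchy.river_latitudes().sort_index()
    z = (river_lat.to_numpy() - river_lat.mean()) / max(river_lat.std(ddof=0), 1e-12)

    # cline: signed amplitude per clinal SNP, applied to the river-level mean
    amp = np.zeros(m)
    amp[clinal] = rng.uniform(0.5, 1.0, n_clinal) * rng.choice([-1.0, 1.0], n_clinal)
    amp *= cfg.cline_strength

    n_rivers = len(river_lat)
    river_mean = np.clip(anc[None, :] + z[:, None] * amp[None, :], 0.01, 0.99)
    river = np.empty((n_rivers, m))
    for r in range(n_rivers):
        river[r] = _beta_around(child_rng(cfg.seed, "river_freq", r), river_mean[r], cfg.theta_river)

    stand_river = hierarchy.river_of_stand().sort_index()
    river_ids = list(river_lat.index)
    stand = np.empty((len(stand_river), m))
    for s_idx, (_, riv) in enumerate(stand_river.items()):
        r = river_ids.index(riv)
        stand[s_idx] = _beta_around(child_rng(cfg.seed, "stand_freq", s_idx), river[r], cfg.theta_stand)

    return AlleleFrequencies(anc, river, stand, clinal, positions, amp)


# ---------------------------------------------------------------------------
# haplotypes and genotypes


def _mosaic(
    rng: np.random.Generator,
    founders: np.ndarray,
    positions: np.ndarray,
    length: int,
    rate: float,
    n_haps: int,
) -> np.ndarray:
    """Recombinant haplotype mosaics of `founders` with per-bp switch rate."""
    out = np.empty((n_haps, founders.shape[1]), dtype=np.int8)
    f = founders.shape[0]
    for h in range(n_haps):
        n_cross = rng.poisson(rate * length)
        if n_cross == 0:
            out[h] = founders[rng.integers(f)]
            continue
        cuts = np.sort(rng.uniform(0, length, n_cross))
        seg = np.searchsorted(cuts, positions)
        donors = rng.integers(f, size=n_cross + 1)
        out[h] = founders[donors[seg], np.arange(founders.shape[1])]
    return out


def simulate_haplotypes(
    freqs: AlleleFrequencies, cfg: SimulationConfig, hierarchy: SampleHierarchy
) -> tuple[HaplotypeSet, GenotypeMatrix]:
    """Draw phased haplotypes per stand and pair them into diploid genotypes.

    In linkage-equilibrium mode every haplotype is an independent Bernoulli
    draw from its stand's frequencies (unlinked markers, no within-stand
    relatedness beyond frequency sharing). In founder-mosaic mode each stand's
    haplotypes are crossover mosaics of a small founder pool, partially shared
    with the other stands of the same river, which creates distance-dependent
    LD and elevated within-stand haplotype sharing. Note that a pool of F
    founders adds drift of order 1/F to among-stand differentiation on top of
    the Balding-Nichols level, so the mosaic mode trades exact F_ST control
    for LD realism.
    """
    stand_ids = sorted(hierarchy.table["stand"].unique())
    river_ids = sorted(hierarchy.table["river"].unique())
    stand_river = hierarchy.river_of_stand()
    sizes = hierarchy.table.groupby("stand").size()
    m = cfg.n_snps

    hap_blocks: list[np.ndarray] = []
    sample_ids: list[str] = []

    if cfg.haplotype_model == MOSAIC and cfg.founders_per_stand < 2:
        raise ValueError("founder_mosaic requires at least 2 founders per stand")

    river_pools: dict[str, np.ndarray] = {}
    if cfg.haplotype_model == MOSAIC:
        pool_size = cfg.river_pool_factor * cfg.founders_per_stand
        for r_idx, riv in enumerate(river_ids):
            rng = child_rng(cfg.seed, "river_pool", r_idx)
            river_pools[riv] = (rng.random((pool_size, m)) < freqs.river[r_idx]).astype(np.int8)

    for s_idx, sid in enumerate(stand_ids):
        rng = child_rng(cfg.seed, "stand_haplotypes", s_idx)
        genos = hierarchy.table.loc[hierarchy.table["stand"] == sid, "genotype"].tolist()
        n_haps = 2 * len(genos)
        p = freqs.stand[s_idx]
        if cfg.haplotype_model == LE:
            haps = (rng.random((n_haps, m)) < p).astype(np.int8)
        else:
            f = cfg.founders_per_stand
            n_shared = int(round(cfg.shared_founder_fraction * f))
            pool = river_pools[stand_river[sid]]
            shared = pool[rng.choice(pool.shape[0], size=n_shared, replace=False)]
            private = (rng.random((f - n_shared, m)) < p).astype(np.int8)
            founders = np.vstack([shared, private])
            haps = _mosaic(rng, founders, freqs.positions, cfg.chrom_length, cfg.switch_rate_per_bp, n_haps)
        hap_blocks.append(haps)
        sample_ids.extend(genos)

    haplotypes = np.vstack(hap_blocks)
    vm = VariantMap(
        np.full(m, cfg.chrom_name, dtype=object),
        freqs.positions,
        np.full(m, "A", dtype=object),
        np.full(m, "G", dtype=object),
    )
    hs = HaplotypeSet(haplotypes, vm, sample_ids)
    return hs, hs.to_genotypes()


# ---------------------------------------------------------------------------
# QTN and phenotypes


def assign_qtn(
    gm: GenotypeMatrix,
    cfg: SimulationConfig,
    freqs: AlleleFrequencies,
    trait: str = "HT",
) -> QtnModel:
    """Pick QTN (preferentially clinal SNPs) and calibrate effect sizes.

    Effects are drawn standard normal and rescaled so the summed causal
    variance sum_j 2*beta_j^2*MAF_j*(1-MAF_j) equals ``cfg.genic_variance``.
    """
    rng = child_rng(cfg.seed, f"assign_qtn.{trait}")
    maf_all = gm.minor_allele_frequencies()
    eligible = maf_all > 0
    clin_pool = np.where(freqs.clinal & eligible)[0]
    other_pool = np.where(~freqs.clinal & eligible)[0]
    if clin_pool.size + other_pool.size < cfg.n_qtn:
        raise ValueError("not enough eligible SNPs for the requested QTN architecture")
    n_clin = min(int(round(cfg.qtn_clinal_fraction * cfg.n_qtn)), clin_pool.size)
    n_other = cfg.n_qtn - n_clin
    if other_pool.size < n_other:  # borrow from the clinal pool instead
        n_clin = cfg.n_qtn - other_pool.size
        n_other = other_pool.size
    idx = np.concatenate(
        [
            rng.choice(clin_pool, size=n_clin, replace=False),
            rng.choice(other_pool, size=n_other, replace=False),
        ]
    )
    idx = np.sort(idx)
    beta = rng.normal(0.0, 1.0, idx.size)
    # local adaptation along the gradient: at clinal QTN the trait-increasing
    # allele is the one whose frequency rises with latitude
    if freqs.cline_amplitude is not None:
        amp = freqs.cline_amplitude[idx]
        sign = np.where(amp != 0, np.sign(amp), 1.0)
        beta = np.abs(beta) * np.where(freqs.clinal[idx], sign, np.sign(beta))
    maf = maf_all[idx]
    raw = float(np.sum(pve_causal(beta, maf)))
    if raw > 0 and cfg.genic_variance > 0:
        beta *= np.sqrt(cfg.genic_variance / raw)
    elif cfg.genic_variance == 0:
        beta[:] = 0.0
    return QtnModel(idx, beta, maf, np.asarray(pve_causal(beta, maf)))


@dataclass
class TraitTruth:
    """True genetic decomposition of one simulated trait, per genotype."""

    genotype_ids: list[str]
    g_total: np.ndarray
    river_component: np.ndarray
    stand_component: np.ndarray
    within_component: np.ndarray
    residual_sd: float
    qst: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": self.genotype_ids,
                "g_total": self.g_total,
                "river": self.river_component,
                "stand": self.stand_component,
                "within": self.within_component,
            }
        )


def _group_means(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    counts = np.bincount(codes, minlength=n_groups)
    return sums / np.maximum(counts, 1)


def simulate_phenotypes(
    gm: GenotypeMatrix,
    qtn: QtnModel,
    cfg: SimulationConfig,
    hierarchy: SampleHierarchy,
    trait: str = "HT",
) -> tuple[PhenotypeRecords, TraitTruth]:
    """Multi-site clonal-trial observations plus the true genetic decomposition.

    The genetic value is the additive QTN score; its river-level component is
    rescaled (when ``qst_target`` is set) so that the realized among-stand
    Q_ST = sigma_B^2 / (sigma_B^2 + 2 sigma_W^2) matches the target, keeping
    the stand- and within-stand components purely SNP-based. The residual
    standard deviation is set from the clone-mean heritability target
    h2 = sigma_W^2 / (sigma_W^2 + sigma_e^2 / n_eff) with
    n_eff = n_sites * ramets_per_site.
    """
    hier = hierarchy.aligned_to(gm.sample_ids)
    x = gm.imputed()
    g = x[:, qtn.indices] @ qtn.beta
    g = g - g.mean()

    stand_codes, stand_ids = pd.factorize(hier.stands)
    river_codes, river_ids = pd.factorize(hier.rivers)
    stand_mean = _group_means(g, stand_codes, len(stand_ids))[stand_codes]
    river_mean = _group_means(g, river_codes, len(river_ids))[river_codes]

    r_comp = river_mean
    s_comp = stand_mean - river_mean
    w_comp = g - stand_mean

    var_r = float(np.var(r_comp))
    var_s = float(np.var(s_comp))
    var_w = float(np.var(w_comp))

    if cfg.qst_target is not None and var_r > 0 and var_w > 0:
        tau = cfg.qst_target
        need = tau * 2.0 * var_w / (1.0 - tau) - var_s
        c = np.sqrt(max(need, 0.0) / var_r)
        r_comp = c * r_comp
        var_r = float(np.var(r_comp))

    g_final = r_comp + s_comp + w_comp
    var_b = var_r + var_s
    qst = var_b / (var_b + 2.0 * var_w) if (var_b + var_w) > 0 else float("nan")

    n_eff = cfg.n_sites * cfg.ramets_per_site
    if var_w > 0:
        resid_var = n_eff * var_w * (1.0 - cfg.h2_within) / cfg.h2_within
    else:
        resid_var = 1.0
    resid_sd = float(np.sqrt(resid_var))

    rng = child_rng(cfg.seed, f"simulate_phenotypes.{trait}")
    site_effects = rng.normal(0.0, cfg.site_sd, cfg.n_sites)
    n = len(gm.sample_ids)
    rows = []
    for s in range(cfg.n_sites):
        gxs = rng.normal(0.0, cfg.gxs_sd, n) if cfg.gxs_sd > 0 else np.zeros(n)
        for rep in range(cfg.ramets_per_site):
            eps = rng.normal(0.0, resid_sd, n)
            y = site_effects[s] + g_final + gxs + eps
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": gm.sample_ids,
                        "site": f"site{s}",
                        "year": 2000,
                        "ramet": rep,
                        "trait": trait,
                        "value": y,
                    }
                )
            )
    records = PhenotypeRecords(pd.concat(rows, ignore_index=True))
    truth = TraitTruth(list(gm.sample_ids), g_final, r_comp, s_comp, w_comp, resid_sd, qst)
    return records, truth


# ---------------------------------------------------------------------------
# climate / geography


def simulate_climate_geography(
    hierarchy: SampleHierarchy, cfg: SimulationConfig
) -> tuple[ClimateMatrix, pd.DataFrame]:
    """Climate variables as linear functions of latitude and elevation plus noise.

    Roughly half of the variables emulate temperature-derived quantities
    (strong latitude loadings) and half precipitation-derived ones (weaker,
    mixed loadings); the geography table is latitude/longitude/elevation per
    genotype.
    """
    rng = child_rng(cfg.seed, "simulate_climate_geography")
    t = hierarchy.table
    lat = t["latitude"].to_numpy()
    elev = t["elevation"].to_numpy()
    lat_z = (lat - lat.mean()) / max(lat.std(ddof=0), 1e-12)
    elev_z = (elev - elev.mean()) / max(elev.std(ddof=0), 1e-12)

    cols = {}
    for k in range(cfg.n_climate):
        temp_like = k < (cfg.n_climate + 1) // 2
        a = rng.uniform(0.7, 1.0) if temp_like else rng.uniform(0.2, 0.6)
        a *= rng.choice([-1.0, 1.0])
        b = rng.uniform(0.1, 0.5) * rng.choice([-1.0, 1.0])
        noise = rng.normal(0.0, cfg.climate_noise_sd, len(lat))
        name = f"{'T' if temp_like else 'P'}{k:02d}"
        cols[name] = a * lat_z + b * elev_z + noise
    climate = ClimateMatrix(pd.DataFrame(cols, index=t["genotype"]))
    geography = t[["genotype", "latitude", "longitude", "elevation"]].set_index("genotype")
    return climate, geography


# ---------------------------------------------------------------------------
# one-call study generator


@dataclass
class SimulatedStudy:
    """Everything one run of the generator produces."""

    config: SimulationConfig
    hierarchy: SampleHierarchy
    frequencies: AlleleFrequencies
    haplotypes: HaplotypeSet
    genotypes: GenotypeMatrix
    qtn: dict[str, QtnModel]
    phenotypes: PhenotypeRecords
    truth: dict[str, TraitTruth]
    climate: ClimateMatrix
    geography: pd.DataFrame


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: hierarchy, genotypes, traits, climate."""
    hierarchy = make_hierarchy(cfg)
    freqs = simulate_allele_frequencies(cfg, hierarchy)
    hs, gm = simulate_haplotypes(freqs, cfg, hierarchy)
    qtn: dict[str, QtnModel] = {}
    truth: dict[str, TraitTruth] = {}
    all_records = []
    for trait in cfg.traits:
        q = assign_qtn(gm, cfg, freqs, trait=trait)
        rec, tr = simulate_phenotypes(gm, q, cfg, hierarchy, trait=trait)
        qtn[trait] = q
        truth[trait] = tr
        all_records.append(rec.table)
    records = PhenotypeRecords(pd.concat(all_records, ignore_index=True))
    climate, geography = simulate_climate_geography(hierarchy, cfg)
    return SimulatedStudy(cfg, hierarchy, freqs, hs, gm, qtn, records, truth, climate, geography)
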