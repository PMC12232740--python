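"""Linkage disequilibrium and haplotype sharing.

Pairwise r^2 (composite LD on genotype dosages) by physical distance, 1-kb
distance-class decay curves, MAF bins built with the two-locus attainable-r^2
rule, LD extent, QTN tagging probability by marker-panel resampling, and
phase-sensitive haplotype sharing across the sampling hierarchy.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rng import child_rng
from .types import GenotypeMatrix, HaplotypeSet, SampleHierarchy

log = logging.getLogger("hierpop")


# ---------------------------------------------------------------------------
# pairwise r^2 and decay curves


def pairwise_r2(
    gm: GenotypeMatrix,
    max_dist: int = 10_000,
    maf_min: float = 0.0,
    maf_range: tuple[float, float] | None = None,
    sample_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """r^2 for every SNP pair within `max_dist` bp on the same chromosome.

    r^2 is the squared Pearson correlation of dosage vectors (composite LD).
    Pairs at distance 0 are excluded; monomorphic SNPs (in the possibly
    subsampled individuals) are skipped. Returns columns dist, r2, maf1, maf2.
    """
    if sample_idx is not None:
        gm = gm.take_samples(sample_idx)
    maf = gm.minor_allele_frequencies()
    if maf_range is not None:
        keep = (maf >= maf_range[0]) & (maf < maf_range[1])
    else:
        keep = maf >= maf_min
    keep &= maf > 0
    gm = gm.take_snps(np.where(keep)[0])
    maf = maf[keep]
    x = gm.imputed()
    z = x - x.mean(axis=0)
    norm = np.sqrt((z**2).sum(axis=0))
    z = z / norm
    pos = gm.variants.pos
    chrom = gm.variants.chrom
    m = pos.size
    dists, r2s, m1, m2 = [], [], [], []
    hi = np.searchsorted(pos, pos + max_dist, side="right")
    for i in range(m):
        j_end = hi[i]
        js = np.arange(i + 1, j_end)
        if js.size == 0:
            continue
        js = js[chrom[js] == chrom[i]]
        if js.size == 0:
            continue
        r = z[:, js].T @ z[:, i]
        dists.append(pos[js] - pos[i])
        r2s.append(r**2)
        m1.append(np.full(js.size, maf[i]))
        m2.append(maf[js])
    if not dists:
        return pd.DataFrame(columns=["dist", "r2", "maf1", "maf2"])
    out = pd.DataFrame(
        {
            "dist": np.concatenate(dists),
            "r2": np.concatenate(r2s),
            "maf1": np.concatenate(m1),
            "maf2": np.concatenate(m2),
        }
    )
    return out[out["dist"] > 0].reset_index(drop=True)


def equalized_river_sample(
    hierarchy: SampleHierarchy, seed: int = 0
) -> dict[str, np.ndarray]:
    """Per-river index sets of equal size (random subsampling to the minimum)."""
    t = hierarchy.table
    sizes = t.groupby("river").size()
    n = int(sizes.min())
    rng = child_rng(seed, "equalized_river_sample")
    out = {}
    for river, sub in t.groupby("river"):
        idx = sub.index.to_numpy()
        out[river] = np.sort(rng.choice(idx, size=n, replace=False))
    return out


def ld_curve(pairs: pd.DataFrame, class_width: int = 1000) -> pd.DataFrame:
    """Mean r^2 per left-closed distance class [k*w, (k+1)*w)."""
    if pairs.empty:
        return pd.DataFrame(columns=["midpoint", "mean_r2", "n_pairs"])
    cls = (pairs["dist"] // class_width).astype(int)
    g = pairs.groupby(cls)["r2"]
    out = pd.DataFrame(
        {
            "midpoint": (g.mean().index + 0.5) * class_width,
            "mean_r2": g.mean().to_numpy(),
            "n_pairs": g.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def ld_extent(curve: pd.DataFrame, threshold: float = 0.2) -> tuple[float, str]:
    """Distance (bp) at which mean r^2 first drops below the threshold.

    Linear interpolation between class midpoints; returns (distance, status)
    with status 'ok', 'below_range' (already below in the first class) or
    'beyond_range' (never drops within the curve; distance is the last
    midpoint, an open lower bound).
    """
    if len(curve) < 2:
        raise ValueError("extent needs at least two distance classes")
    mid = curve["midpoint"].to_numpy(dtype=float)
    r2 = curve["mean_r2"].to_numpy(dtype=float)
    if r2[0] < threshold:
        return float(mid[0]), "below_range"
    for i in range(1, len(r2)):
        if r2[i] < threshold:
            frac = (r2[i - 1] - threshold) / (r2[i - 1] - r2[i])
            return float(mid[i - 1] + frac * (mid[i] - mid[i - 1])), "ok"
    return float(mid[-1]), "beyond_range"


# ---------------------------------------------------------------------------
# MAF bins with the attainable-r^2 rule


def max_attainable_r2(p: float, q: float) -> float:
    """Upper bound of r^2 between loci with minor allele frequencies p <= q.

    For 0 < p <= q <= 0.5 the maximum over haplotype configurations is
    p(1-q) / (q(1-p)).
    """
    if not (0.0 < p <= q <= 0.5):
        raise ValueError("need 0 < p <= q <= 0.5")
    return p * (1.0 - q) / (q * (1.0 - p))


@dataclass
class MafBins:
    """Contiguous MAF bins within which any locus pair can reach `min_r2`."""

    bins: list[tuple[float, float]]  # [low, high)
    min_r2: float
    step: float

    @property
    def midpoints(self) -> list[float]:
        return [(lo + hi) / 2.0 for lo, hi in self.bins]

    def assign(self, maf: np.ndarray) -> np.ndarray:
        """Bin index per MAF (-1 outside all bins)."""
        out = np.full(len(maf), -1)
        for b, (lo, hi) in enumerate(self.bins):
            out[(maf >= lo) & (maf < hi)] = b
        return out


def make_maf_bins(
    maf_range: tuple[float, float] = (0.001, 0.5), min_r2: float = 0.5, step: float = 0.001
) -> MafBins:
    """Greedy bin construction on a MAF grid.

    Starting from the low end, extend the bin's upper limit while the
    attainable-r^2 bound between the bin's extremes stays at least `min_r2`;
    close the bin and start the next at that limit. When even one grid step
    violates the bound (very rare MAFs under a strict rule) the bin is the
    single step — the irreducible minimum on the grid.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = maf_range
    n = int(round((hi - lo) / step))
    grid = np.round(lo + step * np.arange(n + 1), 10)
    grid = grid[grid <= hi + 1e-12]
    bins = []
    i = 0
    while i < len(grid) - 1:
        p = grid[i]
        j = i + 1
        while j < len(grid) and max_attainable_r2(min(p, grid[j]), min(max(p, grid[j]), 0.5)) >= min_r2 and grid[j] <= 0.5:
            j += 1
        upper = grid[j - 1] if j - 1 > i else grid[i + 1]
        bins.append((float(p), float(upper)))
        i = int(np.searchsorted(grid, upper))
        if grid[i] != upper:  # guard against float drift
            i = j - 1
    return MafBins(bins, min_r2, step)


# ---------------------------------------------------------------------------
# QTN tagging probability


def tag_probability(
    gm: GenotypeMatrix,
    n_snps_list: tuple[int, ...],
    r2_min: float = 0.6,
    window: int = 10_000,
    reps: int = 100,
    seed: int = 0,
    qtn_maf_min: float = 0.0,
    allow_self: bool = False,
) -> pd.DataFrame:
    """Probability that a random hypothetical QTN is tagged by a marker panel.

    Per replicate a QTN is drawn uniformly from SNPs with MAF >= qtn_maf_min
    and a random marker panel of each requested size is drawn from the other
    SNPs (the QTN itself is excluded unless ``allow_self``). Tagging succeeds
    when at least one panel marker within `window` bp has r^2 >= `r2_min` with
    the QTN. Returns probability and binomial SE per panel size.
    """
    x = gm.imputed()
    z = x - x.mean(axis=0)
    norm = np.sqrt((z**2).sum(axis=0))
    poly = norm > 0
    z = np.where(poly[None, :], z / np.where(poly, norm, 1.0), 0.0)
    pos = gm.variants.pos
    chrom = gm.variants.chrom
    m = pos.size
    maf = gm.minor_allele_frequencies()
    qtn_pool = np.where(poly & (maf >= qtn_maf_min))[0]
    if qtn_pool.size == 0:
        raise ValueError("no eligible QTN")
    max_n = max(n_snps_list)
    if max_n > (m if allow_self else m - 1):
        raise ValueError("marker panel larger than the SNP universe")

    successes = {n: 0 for n in n_snps_list}
    any_candidates = False
    for rep in range(reps):
        rng = child_rng(seed, "tag_probability", rep)
        q = int(rng.choice(qtn_pool))
        others = np.arange(m) if allow_self else np.delete(np.arange(m), q)
        panel = rng.choice(others, size=max_n, replace=False)
        lo = np.searchsorted(pos, pos[q] - window, side="left")
        hi = np.searchsorted(pos, pos[q] + window, side="right")
        for n in n_snps_list:
            sub = panel[:n]
            cand = sub[(sub >= lo) & (sub < hi)]
            cand = cand[chrom[cand] == chrom[q]]
            if not allow_self:
                cand = cand[cand != q]
            if cand.size == 0:
                continue
            any_candidates = True
            r = z[:, cand].T @ z[:, q]
            if np.any(r**2 >= r2_min):
                successes[n] += 1
    if not any_candidates:
        warnings.warn("no panel markers ever fell within the window; probability 0")
    rows = []
    for n in n_snps_list:
        p = successes[n] / reps
        rows.append({"n_snps": n, "probability": p, "se": float(np.sqrt(p * (1 - p) / reps))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# haplotype sharing


@dataclass
class HaplotypeSharingResult:
    """Mean two-locus haplotype sharing per hierarchy category."""

    mean: dict[str, float]
    se: dict[str, float]
    n_individual_pairs: dict[str, int]
    n_snp_pairs: int
    window: int

    CATEGORIES = ("same_stand", "same_river", "different_river")


def _snp_pairs_within(pos: np.ndarray, chrom: np.ndarray, window: int) -> np.ndarray:
    hi = np.searchsorted(pos, pos + window, side="right")
    pairs = []
    for i in range(pos.size):
        js = np.arange(i + 1, hi[i])
        js = js[(chrom[js] == chrom[i]) & (pos[js] > pos[i])]
        if js.size:
            pairs.append(np.column_stack([np.full(js.size, i), js]))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.vstack(pairs)


def _category_pairs(
    hierarchy: SampleHierarchy, sample_ids: list[str], max_pairs: int, seed: int
) -> dict[str, np.ndarray]:
    hier = hierarchy.aligned_to(sample_ids)
    stands = hier.stands
    rivers = hier.rivers
    n = len(sample_ids)
    cats: dict[str, list[tuple[int, int]]] = {c: [] for c in HaplotypeSharingResult.CATEGORIES}
    for i in range(n):
        for j in range(i + 1, n):
            if stands[i] == stands[j]:
                cats["same_stand"].append((i, j))
            elif rivers[i] == rivers[j]:
                cats["same_river"].append((i, j))
            else:
                cats["different_river"].append((i, j))
    out = {}
    for c, pairs in cats.items():
        if len(pairs) < 1:
            continue
        arr = np.asarray(pairs)
        if len(arr) > max_pairs:
            rng = child_rng(seed, f"hapshare_pairs.{c}")
            arr = arr[rng.choice(len(arr), size=max_pairs, replace=False)]
        out[c] = arr
    return out


def _sharing_for_pairs(
    h: np.ndarray, snp_pairs: np.ndarray, ind_pairs: np.ndarray
) -> np.ndarray:
    """Mean sharing per individual pair: for each SNP pair and each of the 4
    haplotype pairings, the indicator that both loci carry identical alleles."""
    a = snp_pairs[:, 0]
    b = snp_pairs[:, 1]
    out = np.empty(len(ind_pairs))
    for k, (i, j) in enumerate(ind_pairs):
        total = 0.0
        for hi_ in (2 * i, 2 * i + 1):
            for hj in (2 * j, 2 * j + 1):
                eq = h[hi_] == h[hj]
                total += float(np.mean(eq[a] & eq[b]))
        out[k] = total / 4.0
    return out


def haplotype_sharing(
    hs: HaplotypeSet,
    hierarchy: SampleHierarchy,
    window: int = 10_000,
    maf_min: float = 0.01,
    thin_bp: int = 300,
    max_pairs_per_category: int = 300,
    max_snp_pairs: int = 30_000,
    seed: int = 0,
) -> HaplotypeSharingResult:
    """Two-locus haplotype sharing by hierarchy category.

    SNPs are filtered to MAF >= maf_min and thinned to `thin_bp`; sharing for a
    pair of individuals is the mean over SNP pairs within `window` and the four
    haplotype pairings of the indicator that both loci match. Categories (same
    stand / different stand, same river / different river) use identical SNP
    sets; the SE is over individual pairs.
    """
    from .filters import thin_by_distance

    gm = hs.to_genotypes()
    maf = gm.minor_allele_frequencies()
    keep = np.where(maf >= maf_min)[0]
    if thin_bp > 0:
        kept = thin_by_distance(hs.variants.pos[keep], hs.variants.chrom[keep], thin_bp)
        keep = keep[kept]
    sub = hs.take_snps(keep)
    snp_pairs = _snp_pairs_within(sub.variants.pos, sub.variants.chrom, window)
    if len(snp_pairs) == 0:
        raise ValueError("no SNP pairs within the window after filtering")
    if len(snp_pairs) > max_snp_pairs:
        rng = child_rng(seed, "hapshare_snp_pairs")
        snp_pairs = snp_pairs[rng.choice(len(snp_pairs), size=max_snp_pairs, replace=False)]
    cat_pairs = _category_pairs(hierarchy, sub.sample_ids, max_pairs_per_category, seed)
    mean, se, npairs = {}, {}, {}
    for c, pairs in cat_pairs.items():
        vals = _sharing_for_pairs(sub.haplotypes, snp_pairs, pairs)
        mean[c] = float(np.mean(vals))
        se[c] = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        npairs[c] = len(pairs)
    return HaplotypeSharingResult(mean, se, npairs, len(snp_pairs), window)


def frequency_matched_sharing(
    hs: HaplotypeSet,
    hierarchy: SampleHierarchy,
    maf_window: tuple[float, float] = (0.01, 0.11),
    pair_window: int = 1_000_000,
    max_pairs_per_category: int = 300,
    max_snp_pairs: int = 30_000,
    seed: int = 0,
) -> HaplotypeSharingResult:
    """Haplotype sharing restricted to SNPs frequency-matched in every river.

    Only SNPs whose minor allele frequency lies in ``maf_window`` within every
    river are used; because such SNPs are rare the pair window is widened (1 Mb
    by default). Matching on frequency isolates the linkage-phase component of
    sharing from the allele-frequency component.
    """
    from .structure import group_allele_frequencies

    gm = hs.to_genotypes()
    ft = group_allele_frequencies(gm, hierarchy, level="river")
    maf_by_river = np.minimum(ft.freq, 1.0 - ft.freq)
    ok = np.all((maf_by_river >= maf_window[0]) & (maf_by_river < maf_window[1]), axis=0)
    keep = np.where(ok)[0]
    if keep.size < 2:
        raise ValueError("fewer than 2 SNPs pass the per-river MAF window")
    sub = hs.take_snps(keep)
    return haplotype_sharing(
        sub,
        hierarchy,
        window=pair_window,
        maf_min=0.0,
        thin_bp=0,
        max_pairs_per_category=max_pairs_per_category,
        max_snp_pairs=max_snp_pairs,
        seed=seed,
    )
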