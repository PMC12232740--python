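"""SNP-side population structure.

Group allele frequencies, Hudson's pairwise F_ST (ratio of averages),
hierarchical F-statistics from a nested moment ANOVA on allele indicators,
SNP PCA with allele-frequency scaling, a per-SNP latitude cline scan, and a
permutation Mantel test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rng import child_rng
from .types import MISSING, FilterSpec, GenotypeMatrix, SampleHierarchy

log = logging.getLogger("hierpop")


@dataclass
class FreqTable:
    """Alt-allele frequencies per SNP and group with haploid call counts."""

    freq: np.ndarray  # (groups x snps)
    n_haploid: np.ndarray  # (groups x snps)
    group_ids: list[str]
    level: str

    def mean_abs_pairwise_diff(self) -> tuple[float, float]:
        """Mean and SD of |freq_i - freq_j| over group pairs and SNPs."""
        g = len(self.group_ids)
        diffs = []
        for i in range(g):
            for j in range(i + 1, g):
                diffs.append(np.abs(self.freq[i] - self.freq[j]))
        d = np.concatenate(diffs)
        return float(np.mean(d)), float(np.std(d))


def group_allele_frequencies(
    gm: GenotypeMatrix, hierarchy: SampleHierarchy, level: str = "river"
) -> FreqTable:
    """Alt-allele frequency per SNP within each river or stand."""
    if level not in ("river", "stand"):
        raise ValueError("level must be 'river' or 'stand'")
    hier = hierarchy.aligned_to(gm.sample_ids)
    labels = hier.rivers if level == "river" else hier.stands
    groups = sorted(pd.unique(labels))
    freq = np.empty((len(groups), gm.n_snps))
    n_hap = np.empty((len(groups), gm.n_snps))
    d = gm.dosages
    miss = d == MISSING
    for gi, g in enumerate(groups):
        rows = labels == g
        if not rows.any():
            warnings.warn(f"empty group {g!r} excluded")
            continue
        sub = d[rows].astype(np.float64)
        sub_miss = miss[rows]
        called = (~sub_miss).sum(axis=0)
        sub[sub_miss] = 0.0
        n_hap[gi] = 2 * called
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[gi] = np.where(called > 0, sub.sum(axis=0) / np.maximum(2 * called, 1), np.nan)
    return FreqTable(freq, n_hap, [str(g) for g in groups], level)


# ---------------------------------------------------------------------------
# Hudson F_ST


def hudson_fst(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, float]:
    """Hudson's F_ST with small-sample correction.

    Per SNP: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
             den = p1(1-p2) + p2(1-p1);
    genome-wide value is the ratio of averages sum(num)/sum(den), which is
    robust to rare alleles. SNPs with n <= 1 haploid calls in either group are
    skipped (NaN per SNP, excluded from the sums).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    ok = (n1 > 1) & (n2 > 1) & np.isfinite(p1) & np.isfinite(p2)
    num = np.full(p1.shape, np.nan)
    den = np.full(p1.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        num[ok] = (
            (p1[ok] - p2[ok]) ** 2
            - p1[ok] * (1 - p1[ok]) / (n1[ok] - 1)
            - p2[ok] * (1 - p2[ok]) / (n2[ok] - 1)
        )
        den[ok] = p1[ok] * (1 - p2[ok]) + p2[ok] * (1 - p1[ok])
    per_snp = np.where(ok & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    use = ok & (den > 0)
    genome = float(num[use].sum() / den[use].sum()) if use.any() else float("nan")
    return per_snp, genome


def pairwise_fst_matrix(freqs: FreqTable) -> pd.DataFrame:
    """Genome-wide Hudson F_ST for every pair of groups (symmetric, 0 diagonal)."""
    g = len(freqs.group_ids)
    mat = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            _, fst = hudson_fst(freqs.freq[i], freqs.n_haploid[i], freqs.freq[j], freqs.n_haploid[j])
            mat[i, j] = mat[j, i] = fst
    return pd.DataFrame(mat, index=freqs.group_ids, columns=freqs.group_ids)


# ---------------------------------------------------------------------------
# hierarchical F-statistics (nested moment ANOVA on allele indicators)


@dataclass
class FstResult:
    """Hierarchical SNP variance components and derived F-statistics.

    Components are sums over SNPs of per-SNP moment estimates (negative
    per-SNP estimates retained so the genome-wide ratios stay unbiased).
    """

    sigma2_river: float
    sigma2_stand: float
    sigma2_within: float
    n_snps: int

    @property
    def fst_among_stand(self) -> float:
        """Differentiation over both grouping levels: (R + S) / total."""
        t = self.sigma2_river + self.sigma2_stand + self.sigma2_within
        return (self.sigma2_river + self.sigma2_stand) / t

    @property
    def fst_river(self) -> float:
        t = self.sigma2_river + self.sigma2_stand + self.sigma2_within
        return self.sigma2_river / t

    @property
    def fst_stand_within_river(self) -> float:
        return self.sigma2_stand / (self.sigma2_stand + self.sigma2_within)

    def proportions(self) -> dict[str, float]:
        t = self.sigma2_river + self.sigma2_stand + self.sigma2_within
        return {
            "river": self.sigma2_river / t,
            "stand": self.sigma2_stand / t,
            "within": self.sigma2_within / t,
        }


def hierarchical_fstats(gm: GenotypeMatrix, hierarchy: SampleHierarchy) -> FstResult:
    """Method-of-moments nested ANOVA of allele indicators.

    Each haploid allele copy is an observation nested in stand nested in river
    (HWE within stands assumed, so the 2n copies per stand are exchangeable).
    Per SNP, unbalanced nested ANOVA sums of squares yield moment estimates of
    the among-river, among-stand-within-river and within-stand components;
    components are summed over SNPs and ratios of the sums reported.
    Monomorphic SNPs contribute zero to every sum.
    """
    hier = hierarchy.aligned_to(gm.sample_ids)
    stands, stand_idx = np.unique(hier.stands, return_inverse=True)
    rivers_of_stand = hier.river_of_stand().loc[stands].to_numpy()
    rivers, river_of_stand_idx = np.unique(rivers_of_stand, return_inverse=True)
    a = len(rivers)
    s = len(stands)
    if a < 2 or s <= a:
        raise ValueError("need at least 2 rivers with at least 2 stands overall")

    d = gm.dosages
    miss = d == MISSING
    dd = np.where(miss, 0, d).astype(np.float64)

    # per-stand alt counts and haploid sizes (per SNP)
    m = gm.n_snps
    alt_s = np.zeros((s, m))
    n_s = np.zeros((s, m))
    for si in range(s):
        rows = stand_idx == si
        alt_s[si] = dd[rows].sum(axis=0)
        n_s[si] = 2.0 * (~miss[rows]).sum(axis=0)

    alt_r = np.zeros((a, m))
    n_r = np.zeros((a, m))
    for ri in range(a):
        sel = river_of_stand_idx == ri
        alt_r[ri] = alt_s[sel].sum(axis=0)
        n_r[ri] = n_s[sel].sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p_s = np.where(n_s > 0, alt_s / np.maximum(n_s, 1), 0.0)
        p_r = np.where(n_r > 0, alt_r / np.maximum(n_r, 1), 0.0)
    n_tot = n_s.sum(axis=0)
    p_tot = alt_s.sum(axis=0) / np.maximum(n_tot, 1)

    # sums of squares
    ss_w = (n_s * p_s * (1.0 - p_s)).sum(axis=0)
    p_r_of_stand = p_r[river_of_stand_idx]
    ss_s = (n_s * (p_s - p_r_of_stand) ** 2).sum(axis=0)
    ss_r = (n_r * (p_r - p_tot[None, :]) ** 2).sum(axis=0)

    # unbalanced nested ANOVA coefficients (Searle)
    sum_nij2_over_ni = np.zeros(m)
    for ri in range(a):
        sel = river_of_stand_idx == ri
        sum_nij2_over_ni += (n_s[sel] ** 2).sum(axis=0) / np.maximum(n_r[ri], 1)
    sum_nij2_over_n = (n_s**2).sum(axis=0) / np.maximum(n_tot, 1)
    sum_ni2_over_n = (n_r**2).sum(axis=0) / np.maximum(n_tot, 1)

    df_w = n_tot - s
    df_s = float(s - a)
    df_r = float(a - 1)

    ms_w = ss_w / np.maximum(df_w, 1)
    ms_s = ss_s / df_s
    ms_r = ss_r / df_r
    c1 = (n_tot - sum_nij2_over_ni) / df_s
    c2 = (sum_nij2_over_ni - sum_nij2_over_n) / df_r
    c3 = (n_tot - sum_ni2_over_n) / df_r

    sig_w = ms_w
    with np.errstate(invalid="ignore", divide="ignore"):
        sig_s = (ms_s - ms_w) / c1
        sig_r = (ms_r - ms_w - c2 * sig_s) / c3

    poly = (p_tot > 0) & (p_tot < 1) & (n_tot > 0)
    return FstResult(
        float(sig_r[poly].sum()), float(sig_s[poly].sum()), float(sig_w[poly].sum()), int(poly.sum())
    )


# ---------------------------------------------------------------------------
# SNP PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame  # individuals x PCs
    eigenvalues: np.ndarray
    explained: np.ndarray  # fractions of total SNP variance
    loadings: np.ndarray | None


def snp_pca(
    gm: GenotypeMatrix,
    filter_spec: FilterSpec | None = None,
    n_components: int = 5,
    return_loadings: bool = False,
) -> PcaResult:
    """PCA of mean-centered dosages scaled by sqrt(p(1-p)) per SNP.

    Zero-variance SNPs are dropped; the explained fractions are relative to
    the total variance over all components, not only the returned ones.
    """
    from .filters import filter_markers

    if filter_spec is not None:
        gm = filter_markers(gm, filter_spec)
    x = gm.imputed()
    p = x.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    x = x[:, keep]
    p = p[keep]
    if x.shape[1] < n_components:
        raise ValueError("fewer polymorphic SNPs than requested components")
    z = (x - 2.0 * p) / np.sqrt(p * (1.0 - p))
    n = z.shape[0]
    cov = (z @ z.T) / z.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    scores = vecs[:, :n_components] * np.sqrt(np.maximum(vals[:n_components], 0))
    total = vals.sum()
    explained = vals[:n_components] / total if total > 0 else vals[:n_components]
    loadings = None
    if return_loadings:
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings = z.T @ vecs[:, :n_components] / np.sqrt(np.maximum(vals[:n_components], 1e-30)) / np.sqrt(n)
    frame = pd.DataFrame(
        scores, index=gm.sample_ids, columns=[f"SPC{i + 1}" for i in range(n_components)]
    )
    return PcaResult(frame, vals[:n_components], explained, loadings)


# ---------------------------------------------------------------------------
# latitude cline scan


def cline_scan(freqs: FreqTable, latitudes: pd.Series) -> pd.DataFrame:
    """Pearson correlation of group allele frequency with group latitude.

    Returns per-SNP r and two-sided t-test p; monomorphic-across-groups SNPs
    are excluded (NaN rows). Attach ``.attrs['fraction_significant']`` for the
    p < 0.05 summary.
    """
    lat = latitudes.loc[freqs.group_ids].to_numpy(dtype=float)
    g = len(lat)
    if g < 3:
        raise ValueError("cline scan needs at least 3 groups")
    f = freqs.freq
    fc = f - f.mean(axis=0)
    lc = lat - lat.mean()
    sf = np.sqrt((fc**2).sum(axis=0))
    sl = np.sqrt((lc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (lc @ fc) / (sf * sl)
    r = np.where(sf > 0, r, np.nan)
    df = g - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-30))
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    pval = np.where(np.isfinite(r), pval, np.nan)
    out = pd.DataFrame({"r": r, "p": pval})
    valid = out["p"].notna()
    out.attrs["fraction_significant"] = float((out.loc[valid, "p"] < 0.05).mean()) if valid.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# Mantel test


def mantel(
    a: np.ndarray, b: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Mantel test: Pearson r over off-diagonal pairs of two symmetric
    distance/similarity matrices; p is the fraction of |r| under row/column
    permutations of B that reach |r_obs| (with the +1 correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(bm):
        x = a[iu]
        y = bm[iu]
        xm = x - x.mean()
        ym = y - y.mean()
        denom = np.sqrt((xm @ xm) * (ym @ ym))
        return float(xm @ ym / denom) if denom > 0 else float("nan")

    r_obs = corr(b)
    rng = child_rng(seed, "mantel")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(b[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p
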