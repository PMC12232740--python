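"""Two-step mixed-model association scan.

Variance components are estimated once by REML under the no-SNP null model
y = X beta + u + e, u ~ N(0, sigma2_g K), then held fixed while every SNP is
tested by generalized least squares on the spectrally transformed data (the
standard two-step approximation used by the fast mixed-model association
tools). This is O(n) per SNP after a single eigendecomposition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .predict import GblupModel, KinshipMatrix, fit_gblup
from .types import GenotypeMatrix

log = logging.getLogger("hierpop")


@dataclass
class NullModel:
    """Spectral transform and variance components under the no-SNP model."""

    delta: float  # sigma2_e / sigma2_g
    sigma2_g: float
    sigma2_e: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    x: np.ndarray  # fixed-effect design (intercept + optional PCs)
    degenerate: bool = False


def fit_null(
    y: np.ndarray, k: KinshipMatrix, covariates: np.ndarray | None = None
) -> NullModel:
    """REML of the null mixed model; components are fixed for the scan."""
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        n = y.size
        lam, u = np.linalg.eigh(k.values + 1e-8 * np.eye(n))
        x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
        log.warning("fit_null: constant phenotype; degenerate null model")
        return NullModel(1.0, 0.0, 0.0, np.maximum(lam, 0), u, x, degenerate=True)
    model: GblupModel = fit_gblup(y, k, covariates=covariates)
    n = y.size
    lam, u = np.linalg.eigh(k.values + 1e-8 * np.eye(n))
    lam = np.maximum(lam, 0.0)
    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    return NullModel(model.llambda, model.sigma2_g, model.sigma2_e, lam, u, x)


@dataclass
class ScanResult:
    """Per-SNP effect estimates and tests plus scan metadata."""

    table: pd.DataFrame  # chrom, pos, beta, se, stat, p (NaN for skipped SNPs)
    n_tested: int
    n_skipped: int
    trait: str = ""

    def lambda_gc(self) -> float:
        """Genomic inflation factor: median chi-square over its null median."""
        p = self.table["p"].dropna()
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def scan(
    gm: GenotypeMatrix, null: NullModel, y: np.ndarray, trait: str = "", chunk: int = 2048
) -> ScanResult:
    """GLS association test of every SNP at the null model's variance ratio.

    The transformed model is weighted OLS of U'y on [U'X, U'g]; the SNP effect
    is tested with a two-sided t test on n - rank(X) - 1 degrees of freedom.
    Monomorphic SNPs are skipped (NaN) and counted.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if null.degenerate:
        raise ValueError("cannot scan against a degenerate null model")
    u, lam, x = null.eigenvectors, null.eigenvalues, null.x
    w = 1.0 / (lam + null.delta)
    sw = np.sqrt(w)
    ty = sw * (u.T @ y)
    tx = sw[:, None] * (u.T @ x)
    # residualize phenotype on the fixed effects under the transformed metric
    xtx_inv = np.linalg.inv(tx.T @ tx)
    yq = ty - tx @ (xtx_inv @ (tx.T @ ty))
    yy = float(yq @ yq)
    p_fixed = x.shape[1]
    df = n - p_fixed - 1

    m = gm.n_snps
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_skipped = 0
    dos = gm.imputed()
    for start in range(0, m, chunk):
        block = dos[:, start : start + chunk]
        poly = block.std(axis=0) > 0
        tg = sw[:, None] * (u.T @ block)
        gq = tg - tx @ (xtx_inv @ (tx.T @ tg))
        gg = (gq**2).sum(axis=0)
        gy = gq.T @ yq
        ok = poly & (gg > 1e-12)
        n_skipped += int((~ok).sum())
        b = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
        rss = yy - b**2 * gg
        rss = np.maximum(rss, 0.0)
        s = np.sqrt(rss / df / np.where(ok, gg, 1.0))
        t = b / s
        idx = slice(start, start + block.shape[1])
        beta[idx] = np.where(ok, b, np.nan)
        se[idx] = np.where(ok, s, np.nan)
        tstat[idx] = np.where(ok, t, np.nan)
        pval[idx] = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    table = pd.DataFrame(
        {
            "chrom": gm.variants.chrom,
            "pos": gm.variants.pos,
            "beta": beta,
            "se": se,
            "stat": tstat,
            "p": pval,
        }
    )
    if n_skipped:
        log.info("scan: skipped %d monomorphic SNPs", n_skipped)
    return ScanResult(table, m - n_skipped, n_skipped, trait)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def cluster_hits(
    result: ScanResult, threshold: float, window: int = 60_000
) -> pd.DataFrame:
    """Merge significant SNPs within `window` bp into associations.

    A significant SNP joins the running cluster when it lies within `window`
    of the cluster's current end (per chromosome). Returns one row per
    association with its span and top SNP.
    """
    t = result.table
    sig = t[t["p"] < threshold].sort_values(["chrom", "pos"])
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        start = end = None
        members = []

        def close():
            top = min(members, key=lambda r: r.p)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "span": end - start,
                    "n_snps": len(members),
                    "top_pos": top.pos,
                    "top_p": top.p,
                }
            )

        for rec in sub.itertuples():
            if start is None:
                start = end = rec.pos
                members = [rec]
            elif rec.pos - end <= window:
                end = rec.pos
                members.append(rec)
            else:
                close()
                start = end = rec.pos
                members = [rec]
        if members:
            close()
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "span", "n_snps", "top_pos", "top_p"])
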