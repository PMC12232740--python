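"""Hierarchical mixed model for clonal-trial phenotypes.

Model (one trait):  y = mu + site + R + S(R) + G(SR) + [G x site] + e
with site fixed and river, stand-within-river and genotype-within-stand random
and mutually independent. Variance components are estimated by REML; random
effects (BLUPs) are solutions of the mixed-model equations at the converged
components. Multi-year measurements are averaged per genotype-site-ramet
before fitting.

The restricted likelihood is evaluated on genotype-by-site cell means: the
within-cell contrasts carry information only about the residual variance, so
the likelihood factorizes exactly into a within-cell part and a cell-mean part
whose random structure lives in genotype space (a q x q system rather than an
N x N one).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .types import PhenotypeRecords, SampleHierarchy

log = logging.getLogger("hierpop")


@dataclass
class VarianceDecomposition:
    """REML variance components (squared trait units) for one trait."""

    sigma2_river: float
    sigma2_stand: float
    sigma2_geno: float
    sigma2_gxs: float
    sigma2_resid: float
    loglik: float
    converged: bool
    n_obs: int
    trait: str = ""

    def components(self) -> dict[str, float]:
        return {
            "river": self.sigma2_river,
            "stand": self.sigma2_stand,
            "genotype": self.sigma2_geno,
            "gxs": self.sigma2_gxs,
            "residual": self.sigma2_resid,
        }

    def proportions(self, include_residual: bool = False) -> dict[str, float]:
        """Relative proportions of variance; genetic levels only by default."""
        keys = ["river", "stand", "genotype"]
        if include_residual:
            keys += ["gxs", "residual"]
        comps = self.components()
        total = sum(comps[k] for k in keys)
        if total <= 0:
            return {k: float("nan") for k in keys}
        return {k: comps[k] / total for k in keys}


@dataclass
class BlupSet:
    """Predicted random effects per level plus the combined genotypic value."""

    river: pd.Series  # indexed by river id
    stand: pd.Series  # indexed by stand id
    genotype: pd.Series  # indexed by genotype id, within-stand effect
    combined: pd.Series  # river + stand + genotype effect per genotype
    trait: str = ""


@dataclass
class _Design:
    """Sufficient statistics of the cell-mean representation."""

    ybar: np.ndarray  # cell means (C,)
    r_c: np.ndarray  # observations per cell
    x_cell: np.ndarray  # fixed-effect design on cells (C x p)
    geno_of_cell: np.ndarray  # genotype index per cell
    ssw: float  # within-cell sum of squares
    dfw: int  # within-cell degrees of freedom
    same_stand: np.ndarray  # (q x q) indicator
    same_river: np.ndarray  # (q x q) indicator
    genotype_ids: list[str]
    stand_of_geno: np.ndarray
    river_of_geno: np.ndarray
    site_names: list[str]


def _build_design(records: PhenotypeRecords, hierarchy: SampleHierarchy, trait: str) -> _Design:
    data = records.year_means(trait)
    if data.empty:
        raise ValueError(f"no records for trait {trait!r}")
    known = set(hierarchy.table["genotype"])
    unknown = set(data["genotype"]) - known
    if unknown:
        raise ValueError(f"genotypes not in hierarchy: {sorted(unknown)[:5]}")

    cells = data.groupby(["genotype", "site"])["value"]
    ybar = cells.mean()
    r_c = cells.count().to_numpy()
    cell_index = ybar.index
    ybar = ybar.to_numpy()
    ssq = cells.apply(lambda v: float(np.sum((v - v.mean()) ** 2))).to_numpy()
    ssw = float(ssq.sum())
    dfw = int((r_c - 1).sum())

    genotype_ids = sorted(data["genotype"].unique())
    geno_pos = {g: i for i, g in enumerate(genotype_ids)}
    geno_of_cell = np.array([geno_pos[g] for g, _ in cell_index])

    site_names = sorted(data["site"].unique())
    p = len(site_names)
    x_cell = np.zeros((len(ybar), p))
    x_cell[:, 0] = 1.0
    site_pos = {s: i for i, s in enumerate(site_names)}
    for row, (_, site) in enumerate(cell_index):
        j = site_pos[site]
        if j > 0:
            x_cell[row, j] = 1.0

    hier = hierarchy.table.set_index("genotype").loc[genotype_ids]
    stands = hier["stand"].to_numpy()
    rivers = hier["river"].to_numpy()
    same_stand = (stands[:, None] == stands[None, :]).astype(float)
    same_river = (rivers[:, None] == rivers[None, :]).astype(float)
    return _Design(
        ybar, r_c, x_cell, geno_of_cell, ssw, dfw,
        same_stand, same_river, genotype_ids, stands, rivers, site_names,
    )


def _cell_reml_pieces(d: _Design, gamma: np.ndarray, resid_over: np.ndarray):
    """Core REML quantities for cell means with diagonal residual `resid_over`
    (the per-cell residual variance divided by sigma2_e is NOT assumed; values
    are absolute). `gamma` are absolute (sigma2_R, sigma2_S, sigma2_G)."""
    q = len(d.genotype_ids)
    sigma = (
        gamma[0] * d.same_river + gamma[1] * d.same_stand + gamma[2] * np.eye(q)
    )
    dinv = 1.0 / resid_over
    # E = Z' D^-1 Z is diagonal in genotype space; F = Z' D^-1 [X | y]
    e_diag = np.bincount(d.geno_of_cell, weights=dinv, minlength=q)
    xw = d.x_cell * dinv[:, None]
    yw = d.ybar * dinv
    ztx = np.vstack(
        [np.bincount(d.geno_of_cell, weights=xw[:, j], minlength=q) for j in range(d.x_cell.shape[1])]
    ).T
    zty = np.bincount(d.geno_of_cell, weights=yw, minlength=q)

    c_mat = np.eye(q) + e_diag[:, None] * sigma
    lu, piv = linalg.lu_factor(c_mat)
    sign, logdet_c = np.linalg.slogdet(c_mat)
    if sign <= 0:
        return None

    def vinv_quad(a_z, a_direct):
        # computes A' V^-1 B style products given Z'D^-1 A and direct D^-1 products
        return a_direct - a_z.T @ (sigma @ linalg.lu_solve((lu, piv), a_z))

    xtvx = vinv_quad(ztx, d.x_cell.T @ xw)
    xtvy = (d.x_cell.T @ yw) - ztx.T @ (sigma @ linalg.lu_solve((lu, piv), zty))
    ytvy = float(d.ybar @ yw - zty @ (sigma @ linalg.lu_solve((lu, piv), zty)))
    logdet_d = float(np.sum(np.log(resid_over)))
    return xtvx, xtvy, ytvy, logdet_c + logdet_d, (lu, piv, sigma, zty, ztx)


def _neg2_restricted_loglik(d: _Design, s2: np.ndarray, include_gxs: bool) -> float:
    """-2 x restricted log-likelihood (up to a constant) at absolute components
    s2 = (sigma2_R, sigma2_S, sigma2_G, sigma2_GxS, sigma2_e)."""
    s2r, s2s, s2g, s2gs, s2e = s2
    resid = s2e / d.r_c + (s2gs if include_gxs else 0.0)
    pieces = _cell_reml_pieces(d, np.array([s2r, s2s, s2g]), resid)
    if pieces is None:
        return np.inf
    xtvx, xtvy, ytvy, logdet_v, _ = pieces
    try:
        beta = np.linalg.solve(xtvx, xtvy)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
    except np.linalg.LinAlgError:
        return np.inf
    quad = ytvy - float(beta @ xtvy)
    within = d.dfw * np.log(s2e) + d.ssw / s2e if d.dfw > 0 else 0.0
    return within + logdet_v + logdet_x + quad


def _moment_starts(d: _Design) -> np.ndarray:
    """Rough method-of-moments starting values from hierarchical means."""
    q = len(d.genotype_ids)
    g_mean = np.zeros(q)
    counts = np.bincount(d.geno_of_cell, minlength=q)
    np.add.at(g_mean, d.geno_of_cell, d.ybar)
    g_mean /= np.maximum(counts, 1)
    df_geno = pd.DataFrame({"g": g_mean, "stand": d.stand_of_geno, "river": d.river_of_geno})
    stand_means = df_geno.groupby("stand")["g"].mean()
    river_means = df_geno.groupby("river")["g"].mean()
    v_tot = float(np.var(g_mean)) or 1.0
    v_r = float(np.var(river_means)) if len(river_means) > 1 else 0.1 * v_tot
    v_s = max(
        float(np.var(stand_means)) - v_r if len(stand_means) > 1 else 0.1 * v_tot, 0.05 * v_tot
    )
    v_g = max(v_tot - v_r - v_s, 0.05 * v_tot)
    v_e = d.ssw / d.dfw if d.dfw > 0 else 0.5 * v_tot
    return np.array([max(v_r, 1e-4 * v_tot), v_s, v_g, 0.1 * v_e if v_e else 1e-3, max(v_e, 1e-4 * v_tot)])


def fit_hierarchical_model(
    records: PhenotypeRecords,
    hierarchy: SampleHierarchy,
    trait: str | None = None,
    include_gxs: bool = False,
    tol: float = 1e-10,
) -> tuple[VarianceDecomposition, BlupSet]:
    """REML fit of the river / stand(river) / genotype(stand,river) model.

    Returns the variance decomposition and the BLUPs at each level. Variance
    parameters are optimized on the log scale (non-negativity by construction)
    with a small multi-start around moment estimates.
    """
    if trait is None:
        traits = records.traits()
        if len(traits) != 1:
            raise ValueError(f"trait must be given when records hold several: {traits}")
        trait = traits[0]
    d = _build_design(records, hierarchy, trait)

    y_var = float(np.var(d.ybar))
    if y_var < 1e-24:
        # degenerate: all observations equal
        q = len(d.genotype_ids)
        vd = VarianceDecomposition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, True, len(d.ybar), trait)
        zero_g = pd.Series(np.zeros(q), index=d.genotype_ids)
        blups = BlupSet(
            pd.Series(0.0, index=pd.unique(d.river_of_geno)),
            pd.Series(0.0, index=pd.unique(d.stand_of_geno)),
            zero_g,
            zero_g.copy(),
            trait,
        )
        return vd, blups

    start = _moment_starts(d)
    n_par = 5 if include_gxs else 4

    def pack(s2):
        return np.log(np.maximum(s2, 1e-12))

    def unpack(theta):
        s2 = np.exp(theta)
        if include_gxs:
            return np.array([s2[0], s2[1], s2[2], s2[3], s2[4]])
        return np.array([s2[0], s2[1], s2[2], 0.0, s2[3]])

    def objective(theta):
        return _neg2_restricted_loglik(d, unpack(theta), include_gxs)

    starts = [start]
    starts.append(start * np.array([0.2, 0.2, 1.0, 1.0, 1.0]))
    starts.append(start * np.array([3.0, 3.0, 0.5, 1.0, 1.0]))
    best = None
    for s0 in starts:
        theta0 = pack(s0 if include_gxs else s0[[0, 1, 2, 4]])
        res = optimize.minimize(
            objective, theta0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": tol, "maxiter": 4000, "maxfev": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish from the best point; the effort is sized to the problem so that
    # small balanced designs reach near-machine precision while large fits
    # stay fast (each evaluation factors a q x q system)
    q = len(d.genotype_ids)
    budget = 20000 if q <= 200 else 1500
    res = optimize.minimize(
        objective, best.x, method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": budget, "maxfev": budget},
    )
    if res.fun > best.fun:
        res = best
    converged = bool(res.success or res.fun <= best.fun + tol)
    if not converged:
        warnings.warn(f"REML did not converge for trait {trait!r}; returning last iterate")

    s2 = unpack(res.x)
    s2 = np.where(s2 < 1e-9 * y_var, 0.0, s2)  # snap numerically-zero components
    vd = VarianceDecomposition(
        float(s2[0]), float(s2[1]), float(s2[2]), float(s2[3]), float(s2[4]),
        -0.5 * float(res.fun), converged, int(np.sum(d.r_c)), trait,
    )
    blups = _solve_blups(d, s2, include_gxs, trait)
    return vd, blups


def _solve_blups(d: _Design, s2: np.ndarray, include_gxs: bool, trait: str) -> BlupSet:
    s2r, s2s, s2g, s2gs, s2e = np.maximum(s2, 0.0)
    resid = s2e / d.r_c + (s2gs if include_gxs else 0.0)
    resid = np.maximum(resid, 1e-12)
    pieces = _cell_reml_pieces(d, np.array([max(s2r, 1e-12), max(s2s, 1e-12), max(s2g, 1e-12)]), resid)
    xtvx, xtvy, _, _, (lu, piv, sigma, zty, ztx) = pieces
    beta = np.linalg.solve(xtvx, xtvy)
    # w = Z' V^-1 (y - X beta); with C = I + E Sigma this collapses to C^-1 Z'D^-1 r
    zt_res = zty - ztx @ beta
    w = linalg.lu_solve((lu, piv), zt_res)

    q = len(d.genotype_ids)
    stands = pd.unique(d.stand_of_geno)
    rivers = pd.unique(d.river_of_geno)
    stand_pos = {s: i for i, s in enumerate(stands)}
    river_pos = {r: i for i, r in enumerate(rivers)}
    a_s = np.zeros((q, len(stands)))
    a_r = np.zeros((q, len(rivers)))
    for i in range(q):
        a_s[i, stand_pos[d.stand_of_geno[i]]] = 1.0
        a_r[i, river_pos[d.river_of_geno[i]]] = 1.0
    u_r = s2r * (a_r.T @ w)
    u_s = s2s * (a_s.T @ w)
    u_g = s2g * w
    combined = a_r @ u_r + a_s @ u_s + u_g
    return BlupSet(
        pd.Series(u_r, index=list(rivers)).sort_index(),
        pd.Series(u_s, index=list(stands)).sort_index(),
        pd.Series(u_g, index=d.genotype_ids),
        pd.Series(combined, index=d.genotype_ids),
        trait,
    )


def broad_sense_heritability(vd: VarianceDecomposition, n_eff: float) -> dict[str, float]:
    """Clone-mean broad-sense heritability (and the total-structure variant).

    ``clone_mean`` uses the within-stand genotypic variance only:
    H^2 = sigma2_G / (sigma2_G + sigma2_e / n_eff); ``total`` puts all three
    genetic levels in the numerator.
    """
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    denom_e = vd.sigma2_resid / n_eff + (vd.sigma2_gxs if vd.sigma2_gxs else 0.0)
    g = vd.sigma2_geno
    tot = vd.sigma2_river + vd.sigma2_stand + vd.sigma2_geno
    clone = g / (g + denom_e) if (g + denom_e) > 0 else float("nan")
    total = tot / (tot + denom_e) if (tot + denom_e) > 0 else float("nan")
    return {"clone_mean": clone, "total": total}


def qst(vd: VarianceDecomposition, among: tuple[str, ...] = ("river", "stand")) -> float:
    """Q_ST = sigma2_B / (sigma2_B + 2 sigma2_W).

    The among-stand variance sigma2_B pools the river and stand(river)
    components by default (a single "among-stand" differentiation over both
    levels); pass ``among=("stand",)`` for the stand level alone. The
    within variance is the genotype(SR) component.
    """
    comps = vd.components()
    s_b = sum(comps[k] for k in among)
    s_w = vd.sigma2_geno
    if s_b + s_w <= 0:
        warnings.warn("all variance components are zero; Q_ST undefined")
        return float("nan")
    return s_b / (s_b + 2.0 * s_w)


def trait_pca(blups: dict[str, BlupSet]) -> dict:
    """PCA of combined genotypic BLUPs across traits (column-standardized).

    Returns scores per genotype, explained-variance fractions and loadings.
    Constant traits are dropped with a warning.
    """
    if len(blups) < 2:
        raise ValueError("trait PCA needs at least two traits")
    frame = pd.DataFrame({t: b.combined for t, b in blups.items()})
    keep = [c for c in frame.columns if frame[c].std(ddof=0) > 0]
    dropped = set(frame.columns) - set(keep)
    if dropped:
        warnings.warn(f"dropping constant traits from PCA: {sorted(dropped)}")
    z = (frame[keep] - frame[keep].mean()) / frame[keep].std(ddof=0)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    scores = pd.DataFrame(
        u * s, index=frame.index, columns=[f"QPC{i + 1}" for i in range(len(s))]
    )
    loadings = pd.DataFrame(vt.T, index=keep, columns=scores.columns)
    return {"scores": scores, "explained": explained, "loadings": loadings}


def genetic_correlation(blups_a: BlupSet, blups_b: BlupSet) -> float:
    """Pearson correlation of combined genotypic BLUPs (a BLUP-based
    approximation to the genetic correlation, not a bivariate REML)."""
    joined = pd.concat([blups_a.combined, blups_b.combined], axis=1, join="inner")
    if len(joined) < 3:
        raise ValueError("genetic correlation needs at least 3 genotypes")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    return float(np.corrcoef(a, b)[0, 1])
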