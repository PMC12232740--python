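"""Genomic (and geographic/climatic) prediction.

Kinship construction (IBS and GRM), GBLUP through a single-variance-ratio REML
solved by spectral decomposition of the kinship matrix, ridge regression on
feature matrices via the equivalent kernel (one code path for SNP, geography
and climate predictors), lasso for predictor ranking, replicated random
k-fold cross-validation with predictive ability partitioned by hierarchical
level, and training-size curves.

Predictive ability (PA) is the Pearson correlation between predictions for
held-out genotypes and the reference phenotype at a given level (a BLUP from
the field data, or a true simulated component).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.linear_model import LassoCV

from .rng import child_rng
from .types import GenotypeMatrix

log = logging.getLogger("hierpop")


@dataclass
class KinshipMatrix:
    values: np.ndarray
    sample_ids: list[str]
    kind: str  # "IBS", "GRM" or "feature-kernel"
    n_snps: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        self.values = (v + v.T) / 2.0


def ibs_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: K_ij = mean over SNPs of 1 - |g_i - g_j| / 2."""
    x = gm.imputed(dtype=np.float64)
    m = x.shape[1]
    # |a-b| = (a-b)^2 - 2*[both homozygous, opposite]; avoids an n x n x m loop
    sq = (x**2).sum(axis=1)
    cross = x @ x.T
    sum_sq_diff = sq[:, None] + sq[None, :] - 2.0 * cross
    hom0 = (gm.dosages == 0).astype(np.float64)
    hom2 = (gm.dosages == 2).astype(np.float64)
    opp = hom0 @ hom2.T
    sum_abs = sum_sq_diff - 2.0 * (opp + opp.T)
    k = 1.0 - sum_abs / (2.0 * m)
    return KinshipMatrix(k, list(gm.sample_ids), "IBS", m)


def grm(gm: GenotypeMatrix, method: str = "ratio_of_sums") -> KinshipMatrix:
    """Genomic relationship matrix from centered dosages.

    ``ratio_of_sums``: G = W W' / (2 sum p(1-p)) with W = dosages - 2p;
    ``per_snp_standardized``: average over SNPs of the per-SNP standardized
    products (g_i - 2p)(g_j - 2p) / (2p(1-p)). Monomorphic SNPs are excluded.
    """
    x = gm.imputed(dtype=np.float64)
    p = x.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    x = x[:, keep]
    p = p[keep]
    w = x - 2.0 * p
    if method == "ratio_of_sums":
        denom = 2.0 * np.sum(p * (1.0 - p))
        g = (w @ w.T) / denom
    elif method == "per_snp_standardized":
        ws = w / np.sqrt(2.0 * p * (1.0 - p))
        g = (ws @ ws.T) / w.shape[1]
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    return KinshipMatrix(g, list(gm.sample_ids), "GRM", int(keep.sum()))


def exclude_relatives(k: KinshipMatrix, max_kinship: float) -> np.ndarray:
    """Indices of a subset with no pairwise kinship above the threshold.

    Greedy curation filter: while any off-diagonal entry exceeds
    ``max_kinship``, drop the individual involved in the most such pairs.
    """
    v = k.values.copy()
    np.fill_diagonal(v, -np.inf)
    alive = np.ones(v.shape[0], dtype=bool)
    while True:
        over = (v > max_kinship) & alive[:, None] & alive[None, :]
        counts = over.sum(axis=1)
        if counts.max() == 0:
            break
        alive[int(np.argmax(counts))] = False
    return np.where(alive)[0]


def feature_kernel(x: np.ndarray, sample_ids: list[str]) -> tuple[KinshipMatrix, np.ndarray]:
    """Linear kernel K = X X' / q on column-standardized features.

    Constant columns are dropped. Returns the kernel and the standardized
    feature matrix (for cross-kernels against new samples).
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.info("feature_kernel: dropping %d constant columns", int((~keep).sum()))
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    q = z.shape[1]
    return KinshipMatrix(z @ z.T / q, list(sample_ids), "feature-kernel", q), z


# ---------------------------------------------------------------------------
# GBLUP via spectral REML


@dataclass
class GblupModel:
    """Fitted single-kernel mixed model y = X beta + g + e, g ~ N(0, sigma2_g K)."""

    sigma2_g: float
    sigma2_e: float
    llambda: float  # ridge parameter sigma2_e / sigma2_g
    beta: np.ndarray
    alpha: np.ndarray  # (K_TT + lambda I)^-1 (y - X beta), training space
    x_train: np.ndarray
    sample_ids: list[str]
    loglik: float
    fitted_g: np.ndarray = field(repr=False, default=None)


def _reml_neg2(log_delta: float, lam: np.ndarray, ty: np.ndarray, tx: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    xw = tx * w[:, None]
    xtx = tx.T @ xw
    xty = xw.T @ ty
    try:
        beta = np.linalg.solve(xtx, xty)
        sign, logdet_x = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
    except np.linalg.LinAlgError:
        return np.inf
    r = ty - tx @ beta
    quad = float(r @ (w * r))
    n, p = tx.shape
    df = n - p
    if quad <= 0:
        return np.inf
    sigma2 = quad / df
    return df * np.log(sigma2) + float(np.sum(np.log(lam + delta))) + logdet_x + df


def fit_gblup(
    y: np.ndarray,
    k: KinshipMatrix,
    covariates: np.ndarray | None = None,
    log_lambda_bounds: tuple[float, float] = (np.log(1e-5), np.log(1e5)),
    jitter: float = 1e-8,
) -> GblupModel:
    """REML fit of the variance ratio by 1-D search after eigendecomposition.

    The profile restricted likelihood over delta = sigma2_e / sigma2_g is
    optimized by bounded scalar minimization on log delta; BLUPs are
    g_hat = K (K + delta I)^-1 (y - X beta_hat).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    kv = k.values + jitter * np.eye(n)
    lam, u = np.linalg.eigh(kv)
    if lam.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.maximum(lam, 0.0)
    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    ty = u.T @ y
    tx = u.T @ x

    res = optimize.minimize_scalar(
        _reml_neg2,
        bounds=log_lambda_bounds,
        args=(lam, ty, tx),
        method="bounded",
        options={"xatol": 1e-8},
    )
    # flat-likelihood guard: compare against the boundary values
    lo = _reml_neg2(log_lambda_bounds[0], lam, ty, tx)
    hi = _reml_neg2(log_lambda_bounds[1], lam, ty, tx)
    best = min((res.fun, float(res.x)), (lo, log_lambda_bounds[0]), (hi, log_lambda_bounds[1]))
    if abs(lo - hi) < 1e-10 and abs(lo - res.fun) < 1e-10:
        log.warning("fit_gblup: restricted likelihood is flat in the variance ratio")
    delta = float(np.exp(best[1]))

    w = 1.0 / (lam + delta)
    xw = tx * w[:, None]
    beta = np.linalg.solve(tx.T @ xw, xw.T @ ty)
    r = ty - tx @ beta
    df = n - x.shape[1]
    sigma2_g = float(r @ (w * r)) / df
    sigma2_e = sigma2_g * delta
    # alpha in original space: (K + delta I)^-1 (y - X beta) = U w (ty - tx beta)
    alpha = u @ (w * r)
    fitted_g = kv @ alpha
    return GblupModel(
        sigma2_g, sigma2_e, delta, beta, alpha, x, list(k.sample_ids), -0.5 * best[0], fitted_g
    )


def predict_gblup(
    model: GblupModel, k_cross: np.ndarray, covariates_new: np.ndarray | None = None
) -> np.ndarray:
    """Predict new samples: g_hat_P = K_PT alpha + X_P beta.

    ``k_cross`` has one row per prediction sample and one column per training
    sample (in training order).
    """
    k_cross = np.atleast_2d(np.asarray(k_cross, dtype=float))
    if k_cross.shape[1] != model.alpha.size:
        raise ValueError("cross-kinship columns must match the training set")
    n_new = k_cross.shape[0]
    if covariates_new is None:
        x_new = np.ones((n_new, 1))
    else:
        x_new = np.column_stack([np.ones(n_new), covariates_new])
    if x_new.shape[1] != model.beta.size:
        raise ValueError("covariate dimension does not match the fitted model")
    return k_cross @ model.alpha + x_new @ model.beta


def ridge_features(
    y: np.ndarray, x: np.ndarray, sample_ids: list[str], covariates: np.ndarray | None = None
) -> tuple[GblupModel, np.ndarray]:
    """Ridge regression on standardized features via the equivalent kernel.

    The penalty is chosen by the same REML criterion as GBLUP, so geography,
    climate and SNP predictors share one code path. Returns the model and the
    standardized feature matrix used to form cross-kernels.
    """
    k, z = feature_kernel(x, sample_ids)
    return fit_gblup(y, k, covariates=covariates), z


def lasso_weights(
    y: np.ndarray,
    x: np.ndarray,
    names: list[str] | None = None,
    cv: int = 10,
    seed: int = 0,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Coordinate-descent lasso with k-fold cross-validated penalty.

    Returns coefficients at the CV-optimal penalty (or a fixed ``alpha`` when
    given) ranked by |coefficient|; predictors are column-standardized.
    """
    import warnings as _warnings

    from sklearn.linear_model import Lasso

    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    if alpha is not None:
        model = Lasso(alpha=alpha, max_iter=200_000, tol=1e-12)
    else:
        model = LassoCV(cv=cv, random_state=int(seed) % (2**31), max_iter=50_000)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model.fit(z, np.asarray(y, dtype=float) - np.mean(y))
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
    kept_names = [n for n, k_ in zip(names, keep) if k_]
    out = pd.DataFrame({"variable": kept_names, "coefficient": model.coef_})
    out["abs"] = out["coefficient"].abs()
    out = out.sort_values("abs", ascending=False).drop(columns="abs").reset_index(drop=True)
    out.attrs["alpha"] = float(alpha if alpha is not None else model.alpha_)
    return out


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CvScheme:
    n_folds: int = 10
    n_replicates: int = 100
    seed: int = 0


@dataclass
class CvResult:
    """Per-replicate predictive abilities and their summary.

    ``per_replicate`` has one row per (replicate, level); the summary reports
    the mean over replicates and SE = SD of replicate means / sqrt(replicates).
    """

    per_replicate: pd.DataFrame
    levels: list[str]

    def summary(self) -> pd.DataFrame:
        g = self.per_replicate.groupby("level")["pa"]
        out = pd.DataFrame({"mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.count())})
        return out.loc[[l for l in self.levels if l in out.index]]


def _level_pa(
    preds: np.ndarray,
    fold_idx: np.ndarray,
    references: dict[str, np.ndarray],
    groups: dict[str, np.ndarray],
    per_unit: bool = True,
) -> dict[str, float]:
    """PA per level for one held-out fold.

    For grouped levels the correlation is over the unique units present in the
    fold (means of predictions per unit vs the unit's reference value) unless
    ``per_unit`` is False, in which case genotype-replicated values are used.
    """
    out = {}
    for level, ref in references.items():
        grp = groups.get(level)
        if grp is None:
            a, b = preds, ref[fold_idx]
        else:
            labels = grp[fold_idx]
            if per_unit:
                frame = pd.DataFrame({"g": labels, "p": preds, "r": ref[fold_idx]})
                agg = frame.groupby("g").mean()
                a, b = agg["p"].to_numpy(), agg["r"].to_numpy()
            else:
                a, b = preds, ref[fold_idx]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            out[level] = np.nan
        else:
            out[level] = float(np.corrcoef(a, b)[0, 1])
    return out


def cross_validate(
    k: KinshipMatrix,
    y: np.ndarray,
    references: dict[str, np.ndarray],
    groups: dict[str, np.ndarray] | None = None,
    scheme: CvScheme | None = None,
    covariates: np.ndarray | None = None,
    per_unit: bool = True,
) -> CvResult:
    """Replicated random k-fold CV of a kernel predictor with level-wise PA.

    ``y`` is the training phenotype (one value per genotype, aligned to the
    kernel); ``references[level]`` is the reference vector correlated with the
    held-out predictions for that level; ``groups[level]`` (optional) maps
    genotypes to the unit (stand or river) over which predictions are averaged
    before correlating. Folds with an undefined correlation (zero variance)
    are excluded and counted.
    """
    scheme = scheme or CvScheme()
    groups = groups or {}
    n = y.size
    rows = []
    n_dropped = 0
    for rep in range(scheme.n_replicates):
        rng = child_rng(scheme.seed, "cross_validate", rep)
        perm = rng.permutation(n)
        folds = np.array_split(perm, scheme.n_folds)
        fold_pas: dict[str, list[float]] = {lvl: [] for lvl in references}
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            k_tt = KinshipMatrix(k.values[np.ix_(train, train)], [k.sample_ids[i] for i in train], k.kind, k.n_snps)
            cov_t = covariates[train] if covariates is not None else None
            model = fit_gblup(y[train], k_tt, covariates=cov_t)
            cov_p = covariates[fold] if covariates is not None else None
            preds = predict_gblup(model, k.values[np.ix_(fold, train)], cov_p)
            pas = _level_pa(preds, fold, references, groups, per_unit=per_unit)
            for lvl, pa in pas.items():
                if np.isnan(pa):
                    n_dropped += 1
                else:
                    fold_pas[lvl].append(pa)
        for lvl, vals in fold_pas.items():
            rows.append({"replicate": rep, "level": lvl, "pa": float(np.mean(vals)) if vals else np.nan})
    if n_dropped:
        log.info("cross_validate: %d fold-level PAs undefined and excluded", n_dropped)
    return CvResult(pd.DataFrame(rows), list(references))


def training_size_curve(
    k: KinshipMatrix,
    y: np.ndarray,
    reference: np.ndarray,
    subsets: dict[str, np.ndarray],
    sizes: tuple[int, ...] = (24, 48, 96),
    prediction_size: int = 64,
    n_replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """PA as a function of training population size within genotype subsets.

    For each subset (e.g. single rivers, a pooled core, or everything) and each
    training size, a random training set of that size and a disjoint random
    prediction set of ``prediction_size`` are drawn per replicate. Subsets too
    small for size + prediction_size are skipped with a warning. The returned
    table carries mean PA, SE and the Spearman trend of PA on size per subset.
    """
    import warnings

    rows = []
    for name, idx in subsets.items():
        idx = np.asarray(idx)
        for size in sizes:
            if idx.size < size + prediction_size:
                warnings.warn(f"subset {name!r} too small for training size {size}; skipped")
                continue
            pas = []
            for rep in range(n_replicates):
                rng = child_rng(seed, f"training_size.{name}.{size}", rep)
                perm = rng.permutation(idx)
                train, pred = perm[:size], perm[size : size + prediction_size]
                k_tt = KinshipMatrix(k.values[np.ix_(train, train)], [k.sample_ids[i] for i in train], k.kind, k.n_snps)
                model = fit_gblup(y[train], k_tt)
                p = predict_gblup(model, k.values[np.ix_(pred, train)])
                ref = reference[pred]
                if np.std(p) == 0 or np.std(ref) == 0:
                    continue
                pas.append(float(np.corrcoef(p, ref)[0, 1]))
            if pas:
                rows.append(
                    {
                        "subset": name,
                        "size": size,
                        "pa": float(np.mean(pas)),
                        "se": float(np.std(pas, ddof=1) / np.sqrt(len(pas))) if len(pas) > 1 else np.nan,
                        "n_reps": len(pas),
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty:
        from scipy import stats as _st

        trends = {}
        for name, sub in out.groupby("subset"):
            if len(sub) > 1:
                trends[name] = float(_st.spearmanr(sub["size"], sub["pa"]).statistic)
        out.attrs["trend"] = trends
    return out
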