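import numpy as np
import pytest

from hierpop import (
    CvScheme,
    KinshipMatrix,
    cross_validate,
    exclude_relatives,
    feature_kernel,
    fit_gblup,
    grm,
    ibs_kinship,
    lasso_weights,
    predict_gblup,
    ridge_features,
    training_size_curve,
)

from conftest import make_gm


# ---------------------------------------------------------------------------
# kinship


def test_ibs_examples():
    gm = make_gm([[0, 1, 2], [0, 1, 0]])
    k = ibs_kinship(gm).values
    assert k[0, 0] == pytest.approx(1.0)
    assert k[0, 1] == pytest.approx((1 + 1 + 0) / 3)
    gm = make_gm([[0, 0], [2, 2]])
    assert ibs_kinship(gm).values[0, 1] == pytest.approx(0.0)


def test_grm_single_snp_hand_value():
    gm = make_gm([[0, 0], [2, 2]])  # p = 0.5 at both SNPs
    g = grm(gm, "ratio_of_sums").values
    assert np.allclose(g, [[2, -2], [-2, 2]])


def test_grm_mean_diagonal_near_one():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.1, 0.9, 3000)
    d = rng.binomial(2, p, size=(150, 3000)).astype(np.int8)
    g = grm(make_gm(d)).values
    assert np.diag(g).mean() == pytest.approx(1.0, abs=0.05)


def test_grm_methods_agree_for_common_maf():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, 0.5, size=(40, 300)).astype(np.int8)
    # force every SNP to the same realized frequency by construction checks
    g1 = grm(make_gm(d), "ratio_of_sums").values
    g2 = grm(make_gm(d), "per_snp_standardized").values
    # frequencies vary slightly around 0.5, so allow a small tolerance
    assert np.allclose(g1, g2, atol=0.05)


def test_exclude_relatives_removes_clones():
    rng = np.random.default_rng(20)
    d = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(10, 400)).astype(np.int8)
    d = np.vstack([d, d[:2]])  # two clones appended
    k = ibs_kinship(make_gm(d))
    keep = exclude_relatives(k, max_kinship=0.95)
    assert len(keep) == 10
    v = k.values[np.ix_(keep, keep)]
    np.fill_diagonal(v, 0)
    assert v.max() <= 0.95


# ---------------------------------------------------------------------------
# GBLUP oracles


def _sim_kernel_trait(n, m, h2, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m)
    d = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    gm = make_gm(d)
    beta = rng.normal(0, 1, m)
    g = (d - 2 * p) @ beta
    g = (g - g.mean()) / g.std()
    e = rng.normal(0, np.sqrt((1 - h2) / h2), n) if h2 < 1 else np.zeros(n)
    return gm, g + e, g


def test_gblup_matches_direct_mixed_model_solve():
    gm, y, _ = _sim_kernel_trait(12, 60, 0.6, 2)
    k = grm(gm)
    model = fit_gblup(y, k)
    kv = k.values + 1e-8 * np.eye(12)
    v = kv + model.llambda * np.eye(12)
    vi = np.linalg.inv(v)
    x = np.ones((12, 1))
    beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    ghat = kv @ vi @ (y - x @ beta)
    assert model.beta == pytest.approx(beta, abs=1e-8)
    assert np.allclose(model.fitted_g, ghat, atol=1e-8)


def test_gblup_zero_signal_predicts_the_mean():
    """With no genetic signal, held-out predictions collapse toward the mean.

    (With K close to the identity the sigma2_g / sigma2_e split itself is only
    weakly identified, so the contract is about out-of-sample predictions.)
    """
    rng = np.random.default_rng(3)
    gm, _, _ = _sim_kernel_trait(80, 200, 0.5, 4)
    y = rng.normal(10.0, 1.0, 80)  # unrelated to the kinship
    k = grm(gm)
    tr, pr = np.arange(60), np.arange(60, 80)
    k_tt = KinshipMatrix(k.values[np.ix_(tr, tr)], [f"G{i}" for i in tr], "GRM", 200)
    model = fit_gblup(y[tr], k_tt)
    preds = predict_gblup(model, k.values[np.ix_(pr, tr)])
    assert np.std(preds) < 0.3 * np.std(y)
    assert preds.mean() == pytest.approx(y[tr].mean(), abs=0.5)


def test_gblup_infinite_shrinkage_limit():
    gm, y, _ = _sim_kernel_trait(30, 100, 0.6, 5)
    model = fit_gblup(y, grm(gm), log_lambda_bounds=(np.log(1e9), np.log(1e10)))
    assert np.abs(model.fitted_g).max() < 1e-6 * np.abs(y - y.mean()).max() * 1e3


def test_predict_gblup_joint_fit_oracle():
    """Predicting held-out samples equals the joint-model conditional mean."""
    gm, y, _ = _sim_kernel_trait(15, 80, 0.6, 6)
    k_full = grm(gm).values + 1e-8 * np.eye(15)
    tr, pr = np.arange(10), np.arange(10, 15)
    k_tt = KinshipMatrix(k_full[np.ix_(tr, tr)], [f"G{i}" for i in tr], "GRM", 80)
    model = fit_gblup(y[tr], k_tt, jitter=0.0)
    preds = predict_gblup(model, k_full[np.ix_(pr, tr)])
    # independent route: conditional expectation under the joint Gaussian
    s2g, s2e = model.sigma2_g, model.sigma2_e
    v_tt = s2g * k_full[np.ix_(tr, tr)] + s2e * np.eye(10)
    x_t = np.ones((10, 1))
    vi = np.linalg.inv(v_tt)
    beta = np.linalg.solve(x_t.T @ vi @ x_t, x_t.T @ vi @ y[tr])
    cond = s2g * k_full[np.ix_(pr, tr)] @ vi @ (y[tr] - x_t @ beta) + beta[0]
    assert np.allclose(preds, cond, atol=1e-8)


def test_predict_gblup_degenerate_cases():
    gm, y, _ = _sim_kernel_trait(20, 80, 0.6, 7)
    k = grm(gm)
    model = fit_gblup(y, k)
    zero = predict_gblup(model, np.zeros((3, 20)))
    assert np.allclose(zero, model.beta[0])  # fixed-effect part only
    self_pred = predict_gblup(model, k.values[:1] + 1e-8 * np.eye(20)[:1])
    fitted = model.fitted_g[0] + model.beta[0]
    assert self_pred[0] == pytest.approx(fitted, abs=1e-6)
    with pytest.raises(ValueError):
        predict_gblup(model, np.zeros((2, 7)))


def test_gblup_equals_marker_ridge():
    gm, y, _ = _sim_kernel_trait(30, 200, 0.6, 8)
    k = grm(gm, "ratio_of_sums")
    model = fit_gblup(y, k, jitter=0.0)
    x = gm.imputed()
    p = x.mean(axis=0) / 2
    w = x - 2 * p
    c = 2 * np.sum(p * (1 - p))
    r = y - model.beta[0]
    coef = np.linalg.solve(w.T @ w + model.llambda * c * np.eye(200), w.T @ r)
    assert np.allclose(model.fitted_g, w @ coef, atol=1e-6)


# ---------------------------------------------------------------------------
# ridge / lasso on features


def test_ridge_perfect_linear_signal():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(60, 3))
    y = 5.0 + x @ np.array([1.0, -2.0, 0.5])
    model, z = ridge_features(y, x, [f"G{i}" for i in range(60)])
    assert np.corrcoef(model.fitted_g + model.beta[0], y)[0, 1] > 0.999


def test_ridge_null_signal():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(100, 5))
    y = rng.normal(size=100)
    model, _ = ridge_features(y, x, [f"G{i}" for i in range(100)])
    assert np.var(model.fitted_g) < 0.25 * np.var(y)


def test_ridge_small_penalty_equals_ols():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(50, 4))
    y = 1.0 + x @ rng.normal(size=4) + rng.normal(scale=0.3, size=50)
    k, z = feature_kernel(x, [f"G{i}" for i in range(50)])
    model = fit_gblup(y, k, log_lambda_bounds=(np.log(1e-10), np.log(1e-9)), jitter=0.0)
    xd = np.column_stack([np.ones(50), z])
    ols = xd @ np.linalg.lstsq(xd, y, rcond=None)[0]
    assert np.allclose(model.fitted_g + model.beta[0], ols, atol=1e-5)


def test_lasso_zero_penalty_equals_ols():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(80, 6))
    y = x @ rng.normal(size=6) + rng.normal(scale=0.2, size=80)
    res = lasso_weights(y, x, alpha=1e-10)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    ols = np.linalg.lstsq(z, y - y.mean(), rcond=None)[0]
    got = res.set_index("variable")["coefficient"]
    for i in range(6):
        assert got[f"x{i}"] == pytest.approx(ols[i], abs=1e-6)


def test_lasso_huge_penalty_zeroes_everything():
    rng = np.random.default_rng(13)
    x = rng.normal(size=(40, 5))
    y = x[:, 0] + rng.normal(size=40)
    res = lasso_weights(y, x, alpha=1e6)
    assert (res["coefficient"] == 0).all()


def test_lasso_selects_the_true_predictor():
    hits = 0
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=(120, 10))
        y = 2.0 * x[:, 1] + rng.normal(scale=0.5, size=120)
        res = lasso_weights(y, x, seed=seed)
        top = res.iloc[0]
        others = res.set_index("variable")["coefficient"].drop("x1").abs()
        if top["variable"] == "x1" and (others < 0.2).all():
            hits += 1
    assert hits == 6


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_reference_predictor_is_perfect(small_study):
    truth = small_study.truth["HT"]
    ref = truth.g_total
    ids = small_study.genotypes.sample_ids
    k, _ = feature_kernel(ref[:, None], ids)
    cv = cross_validate(k, ref, {"G": ref}, scheme=CvScheme(5, 2, seed=1))
    assert cv.summary().loc["G", "mean"] > 0.999


def test_cv_noise_predictor_is_null(small_study):
    rng = np.random.default_rng(14)
    ids = small_study.genotypes.sample_ids
    noise = rng.normal(size=(len(ids), 10))
    k, _ = feature_kernel(noise, ids)
    ref = small_study.truth["HT"].g_total
    y = rng.normal(size=len(ids))
    cv = cross_validate(k, y, {"G": ref}, scheme=CvScheme(5, 3, seed=2))
    assert abs(cv.summary().loc["G", "mean"]) < 0.15


def test_cv_level_ordering_mirrors_structure(small_study):
    """River-level PA exceeds stand-level PA exceeds within-stand PA."""
    truth = small_study.truth["HT"]
    gm = small_study.genotypes
    hier = small_study.hierarchy.aligned_to(gm.sample_ids)
    clone_means = (
        small_study.phenotypes.table.query("trait == 'HT'")
        .groupby("genotype")["value"].mean().loc[gm.sample_ids].to_numpy()
    )
    refs = {
        "within": truth.within_component,
        "stand": truth.stand_component,
        "river": truth.river_component,
    }
    groups = {"stand": hier.stands, "river": hier.rivers}
    cv = cross_validate(grm(gm), clone_means, refs, groups, CvScheme(10, 3, seed=3))
    s = cv.summary()["mean"]
    assert s["river"] > s["stand"] > s["within"]
    assert s["within"] < 0.2
    assert s["river"] > 0.8


def test_pa_decomposes_over_orthogonal_components(small_study):
    """The across-level PA is the variance-share-weighted sum of level PAs
    (by linearity of covariance over the true decomposition), so it is bounded
    by the weighted sum of their magnitudes."""
    truth = small_study.truth["HT"]
    gm = small_study.genotypes
    k = grm(gm)
    rng = np.random.default_rng(21)
    tr = rng.permutation(gm.n_samples)
    train, pred = tr[:-40], tr[-40:]
    k_tt = KinshipMatrix(k.values[np.ix_(train, train)], [f"G{i}" for i in train], "GRM", k.n_snps)
    clone_means = (
        small_study.phenotypes.table.query("trait == 'HT'")
        .groupby("genotype")["value"].mean().loc[gm.sample_ids].to_numpy()
    )
    model = fit_gblup(clone_means[train], k_tt)
    p = predict_gblup(model, k.values[np.ix_(pred, train)])
    comps = [truth.river_component[pred], truth.stand_component[pred], truth.within_component[pred]]
    g = truth.g_total[pred]
    pa_g = np.corrcoef(p, g)[0, 1]
    contribs = [np.corrcoef(p, c)[0, 1] * np.std(c) / np.std(g) for c in comps]
    assert pa_g == pytest.approx(sum(contribs), abs=1e-10)
    assert abs(pa_g) <= sum(abs(c) for c in contribs) + 1e-10


def test_cv_se_shrinks_with_replicates(small_study):
    truth = small_study.truth["HT"]
    gm = small_study.genotypes
    rng = np.random.default_rng(15)
    y = truth.g_total + rng.normal(scale=truth.g_total.std(), size=gm.n_samples)
    k = grm(gm)
    few = cross_validate(k, y, {"G": truth.g_total}, scheme=CvScheme(5, 4, seed=4))
    many = cross_validate(k, y, {"G": truth.g_total}, scheme=CvScheme(5, 16, seed=4))
    ratio = few.summary().loc["G", "se"] / many.summary().loc["G", "se"]
    assert 1.1 < ratio < 4.0  # ~2 expected from 1/sqrt(reps)


# ---------------------------------------------------------------------------
# training-size curves


def test_training_size_flat_without_heritability(small_study):
    rng = np.random.default_rng(16)
    gm = small_study.genotypes
    y = rng.normal(size=gm.n_samples)
    ref = rng.normal(size=gm.n_samples)
    out = training_size_curve(
        grm(gm), y, ref, {"all": np.arange(gm.n_samples)}, sizes=(24, 96),
        prediction_size=40, n_replicates=20, seed=5,
    )
    assert out["pa"].abs().max() < 0.15


def test_training_size_monotone_with_signal(mosaic_study):
    truth = mosaic_study.truth["HT"]
    gm = mosaic_study.genotypes
    out = training_size_curve(
        grm(gm), truth.g_total + 0.5 * truth.g_total.std() * np.random.default_rng(17).normal(size=gm.n_samples),
        truth.g_total,
        {"all": np.arange(gm.n_samples)}, sizes=(24, 48, 96),
        prediction_size=40, n_replicates=25, seed=6,
    )
    pa = out.set_index("size")["pa"]
    assert pa[96] > pa[24]
    assert out.attrs["trend"]["all"] > 0


def test_training_size_skips_small_subsets(small_study):
    gm = small_study.genotypes
    with pytest.warns(UserWarning, match="too small"):
        out = training_size_curve(
            grm(gm), np.zeros(gm.n_samples), np.zeros(gm.n_samples),
            {"tiny": np.arange(10)}, sizes=(24,), prediction_size=64, n_replicates=2, seed=7,
        )
    assert out.empty


def test_within_river_beats_pooled_for_within_stand_component(mosaic_study):
    """When QTN frequencies diverge among rivers, within-river training is
    better at predicting the within-stand genetic component."""
    truth = mosaic_study.truth["HT"]
    gm = mosaic_study.genotypes
    hier = mosaic_study.hierarchy.aligned_to(gm.sample_ids)
    clone_means = (
        mosaic_study.phenotypes.table.groupby("genotype")["value"].mean().loc[gm.sample_ids].to_numpy()
    )
    k = grm(gm)
    rivers = hier.rivers
    subsets = {r: np.where(rivers == r)[0] for r in np.unique(rivers)[:2]}
    subsets["pooled"] = np.arange(gm.n_samples)
    out = training_size_curve(
        k, clone_means, truth.within_component, subsets, sizes=(24,),
        prediction_size=16, n_replicates=30, seed=8,
    )
    pa = out.set_index("subset")["pa"]
    within = pa.drop("pooled").mean()
    assert within > pa["pooled"]
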