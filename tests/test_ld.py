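import itertools

import numpy as np
import pandas as pd
import pytest

from hierpop import (
    HaplotypeSet,
    SampleHierarchy,
    frequency_matched_sharing,
    haplotype_sharing,
    ld_curve,
    ld_extent,
    make_maf_bins,
    max_attainable_r2,
    pairwise_r2,
    tag_probability,
)
from hierpop.types import VariantMap

from conftest import make_gm


def hier_frame(stands, rivers, ids):
    return SampleHierarchy(
        pd.DataFrame(
            {
                "genotype": ids,
                "stand": stands,
                "river": rivers,
                "latitude": 45.0,
                "longitude": -122.0,
                "elevation": 50.0,
            }
        )
    )


def haps_from(rows, ids):
    h = np.asarray(rows, dtype=np.int8)
    m = h.shape[1]
    vm = VariantMap(
        np.full(m, "chr1", dtype=object), np.arange(1, m + 1) * 500,
        np.full(m, "A", dtype=object), np.full(m, "G", dtype=object),
    )
    return HaplotypeSet(h, vm, ids)


# ---------------------------------------------------------------------------
# pairwise r^2


def test_duplicated_snp_has_r2_one():
    col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
    gm = make_gm(np.column_stack([col, col]))
    pairs = pairwise_r2(gm, max_dist=10_000)
    assert pairs["r2"].iloc[0] == pytest.approx(1.0)


def test_textbook_haplotype_configurations():
    # coupling: AB and ab only -> r^2 = 1 at both loci MAF 0.5
    # (individuals carry AB/AB, ab/ab, AB/ab so dosages vary)
    coup = haps_from(
        [[1, 1], [1, 1], [0, 0], [0, 0], [1, 1], [0, 0], [0, 0], [1, 1]] * 2,
        [f"G{i}" for i in range(8)],
    )
    pairs = pairwise_r2(coup.to_genotypes(), max_dist=10_000)
    assert pairs["r2"].iloc[0] == pytest.approx(1.0)
    # all four haplotypes equally frequent -> r^2 = 0
    # homozygotes for each of the four equally frequent haplotypes
    eq = haps_from(
        [[1, 1], [1, 1], [1, 0], [1, 0], [0, 1], [0, 1], [0, 0], [0, 0]] * 2,
        [f"G{i}" for i in range(8)],
    )
    pairs = pairwise_r2(eq.to_genotypes(), max_dist=10_000)
    assert pairs["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_independent_snps_have_sampling_floor_r2():
    rng = np.random.default_rng(0)
    n, m = 150, 200
    d = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(np.int8)
    pairs = pairwise_r2(make_gm(d, pos=np.arange(1, m + 1) * 10), max_dist=10_000)
    mean = pairs["r2"].mean()
    assert 0.3 / n < mean < 3.0 / n


def test_zero_distance_pairs_excluded_and_curve_recomposes(mosaic_study):
    pairs = pairwise_r2(mosaic_study.genotypes, max_dist=10_000, maf_min=0.05)
    assert (pairs["dist"] > 0).all()
    curve = ld_curve(pairs)
    recomposed = float((curve["mean_r2"] * curve["n_pairs"]).sum() / curve["n_pairs"].sum())
    assert recomposed == pytest.approx(pairs["r2"].mean(), abs=1e-12)


# ---------------------------------------------------------------------------
# attainable r^2 and MAF bins


def test_max_attainable_r2_values():
    assert max_attainable_r2(0.3, 0.3) == pytest.approx(1.0)
    assert max_attainable_r2(0.071, 0.132) == pytest.approx(0.5026, abs=2e-4)
    assert max_attainable_r2(0.01, 0.5) == pytest.approx(0.0101, abs=1e-4)
    for bad in [(0.0, 0.3), (0.3, 0.6), (0.4, 0.2)]:
        with pytest.raises(ValueError):
            max_attainable_r2(*bad)


def test_maf_bin_construction_printed_bin():
    bins = make_maf_bins((0.071, 0.5), min_r2=0.5, step=0.001)
    lo, hi = bins.bins[0]
    assert lo == pytest.approx(0.071)
    assert hi == pytest.approx(0.132)
    assert round(bins.midpoints[0], 3) == 0.102


def test_maf_bins_satisfy_their_constraint_and_are_contiguous():
    bins = make_maf_bins((0.01, 0.5), min_r2=0.5, step=0.001)
    for (lo, hi), (lo2, _) in zip(bins.bins, bins.bins[1:]):
        assert hi == pytest.approx(lo2)  # contiguous
    for lo, hi in bins.bins:
        assert max_attainable_r2(lo, min(hi, 0.5)) >= 0.5 - 1e-9


def test_maf_bins_zero_rule_gives_single_bin():
    bins = make_maf_bins((0.05, 0.5), min_r2=0.0, step=0.001)
    assert len(bins.bins) == 1
    assert bins.bins[0] == (pytest.approx(0.05), pytest.approx(0.5))


def test_ld_extent_interpolation():
    curve = pd.DataFrame({"midpoint": [500, 1500, 2500], "mean_r2": [0.5, 0.3, 0.15], "n_pairs": 10})
    ext, status = ld_extent(curve)
    assert status == "ok"
    assert ext == pytest.approx(1500 + 2 / 3 * 1000, abs=1)
    flat = pd.DataFrame({"midpoint": [500, 1500], "mean_r2": [0.1, 0.1], "n_pairs": 10})
    ext, status = ld_extent(flat)
    assert status == "below_range" and ext == 500
    high = pd.DataFrame({"midpoint": [500, 1500], "mean_r2": [0.6, 0.5], "n_pairs": 10})
    ext, status = ld_extent(high)
    assert status == "beyond_range"


def test_founder_count_controls_ld_extent():
    """Halving the founder pool lengthens within-river LD."""
    from hierpop.simulate import SimulationConfig, simulate_study

    extents = {}
    for f in (4, 8):
        exts = []
        for seed in (21, 22, 23):
            cfg = SimulationConfig(
                n_rivers=2, n_stands=4, n_genotypes=80, n_snps=1500, chrom_length=900_000,
                haplotype_model="founder_mosaic", founders_per_stand=f,
                n_qtn=10, traits=("HT",), seed=seed,
            )
            st = simulate_study(cfg)
            hier = st.hierarchy.aligned_to(st.genotypes.sample_ids)
            idx = np.where(hier.rivers == hier.rivers[0])[0]
            pairs = pairwise_r2(st.genotypes, max_dist=40_000, maf_min=0.05, sample_idx=idx)
            curve = ld_curve(pairs, 2000)
            # use the area under the decay curve: robust to threshold crossings
            exts.append(float(curve["mean_r2"].head(10).mean()))
        extents[f] = np.mean(exts)
    assert extents[4] > extents[8]


# ---------------------------------------------------------------------------
# tagging probability


def test_tag_probability_duplicated_panel_is_certain():
    col = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2])
    gm = make_gm(np.column_stack([col, col, 2 - col]), pos=np.array([100, 200, 300]))
    res = tag_probability(gm, (3,), reps=20, allow_self=True, seed=1)
    assert res["probability"].iloc[0] == 1.0


def test_tag_probability_matches_exhaustive_enumeration():
    rng = np.random.default_rng(2)
    n, m = 60, 8
    d = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 30_000), size=m, replace=False))
    gm = make_gm(d, pos=pos)
    x = d.astype(float)
    z = x - x.mean(axis=0)
    z /= np.sqrt((z**2).sum(axis=0))
    corr2 = (z.T @ z) ** 2
    window, r2_min, size = 10_000, 0.6, 3

    def tags(q, panel):
        return any(
            abs(pos[j] - pos[q]) <= window and corr2[q, j] >= r2_min for j in panel if j != q
        )

    # exact probability over uniform QTN and uniform panels
    total, hits = 0, 0
    for q in range(m):
        others = [j for j in range(m) if j != q]
        for panel in itertools.combinations(others, size):
            total += 1
            hits += tags(q, panel)
    exact = hits / total
    res = tag_probability(gm, (size,), r2_min=r2_min, window=window, reps=500, seed=3)
    p = res["probability"].iloc[0]
    se = np.sqrt(exact * (1 - exact) / 500)
    assert abs(p - exact) <= 2 * se + 1e-9


def test_tag_probability_monotone_in_panel_size(mosaic_study):
    res = tag_probability(mosaic_study.genotypes, (50, 200, 800), reps=60, seed=4)
    probs = res.set_index("n_snps")["probability"]
    assert probs[50] <= probs[200] <= probs[800]


# ---------------------------------------------------------------------------
# haplotype sharing


def test_clones_share_everything():
    hap = np.random.default_rng(5).integers(0, 2, size=40).astype(np.int8)
    rows = [hap, hap, hap, hap]  # two individuals, identical haplotypes
    hs = haps_from(rows, ["G0", "G1"])
    h = hier_frame(["s1", "s1"], ["r1", "r1"], ["G0", "G1"])
    res = haplotype_sharing(hs, h, window=50_000, maf_min=0.0, thin_bp=0)
    assert res.mean["same_stand"] == pytest.approx(1.0)


def test_opposite_haplotypes_share_nothing():
    hap = np.random.default_rng(6).integers(0, 2, size=40).astype(np.int8)
    rows = [hap, hap, 1 - hap, 1 - hap]
    hs = haps_from(rows, ["G0", "G1"])
    h = hier_frame(["s1", "s1"], ["r1", "r1"], ["G0", "G1"])
    res = haplotype_sharing(hs, h, window=50_000, maf_min=0.0, thin_bp=0)
    assert res.mean["same_stand"] == pytest.approx(0.0)


def test_sharing_invariant_to_consistent_allele_relabeling(mosaic_study):
    hs = mosaic_study.haplotypes.take_snps(np.arange(400))
    flipped = HaplotypeSet(1 - hs.haplotypes, hs.variants, hs.sample_ids)
    kw = dict(window=10_000, maf_min=0.05, thin_bp=0, max_pairs_per_category=60,
              max_snp_pairs=2000, seed=7)
    a = haplotype_sharing(hs, mosaic_study.hierarchy, **kw)
    b = haplotype_sharing(flipped, mosaic_study.hierarchy, **kw)
    for c in a.mean:
        assert a.mean[c] == pytest.approx(b.mean[c], abs=1e-12)


def test_sharing_hierarchy_ordering(mosaic_study):
    res = haplotype_sharing(
        mosaic_study.haplotypes, mosaic_study.hierarchy,
        max_pairs_per_category=150, max_snp_pairs=8000, seed=8,
    )
    assert res.mean["same_stand"] > res.mean["same_river"] > res.mean["different_river"]


def test_frequency_matching_shrinks_the_river_gap():
    """Restricting to frequency-matched SNPs removes most of the among-river
    sharing deficit (the allele-frequency component of linkage-phase sharing)."""
    from hierpop.simulate import SimulationConfig, simulate_study

    gaps_raw, gaps_matched = [], []
    for seed in (31, 32):
        cfg = SimulationConfig(
            n_rivers=4, n_stands=8, n_genotypes=120, n_snps=2000, chrom_length=1_200_000,
            haplotype_model="founder_mosaic", theta_river=0.05, n_qtn=10,
            traits=("HT",), seed=seed,
        )
        st = simulate_study(cfg)
        kw = dict(max_pairs_per_category=100, max_snp_pairs=4000, seed=seed)
        raw = haplotype_sharing(st.haplotypes, st.hierarchy, maf_min=0.01, thin_bp=0, **kw)
        matched = frequency_matched_sharing(
            st.haplotypes, st.hierarchy, maf_window=(0.05, 0.45), pair_window=1_000_000, **kw
        )
        gaps_raw.append(raw.mean["same_stand"] - raw.mean["different_river"])
        gaps_matched.append(matched.mean["same_stand"] - matched.mean["different_river"])
    assert np.mean(gaps_matched) < np.mean(gaps_raw)


def test_single_river_collapses_categories():
    rng = np.random.default_rng(9)
    rows = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
    hs = haps_from(rows, [f"G{i}" for i in range(4)])
    h = hier_frame(["s1", "s1", "s2", "s2"], ["r1"] * 4, hs.sample_ids)
    res = haplotype_sharing(hs, h, window=50_000, maf_min=0.0, thin_bp=0)
    assert set(res.mean) <= {"same_stand", "same_river"}
    assert "different_river" not in res.mean
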